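import numpy as np
import pytest

from blotkit.io import Sample, WBDataset, WBRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_dataset(
    n_groups=2,
    n_subjects=3,
    n_replicates=3,
    rng=None,
    target_base=10.0,
    loading_base=5.0,
):
    """Small deterministic-ish dataset for unit tests (not the simulator)."""
    rng = rng or np.random.default_rng(0)
    records = []
    for g in range(n_groups):
        group = chr(ord("A") + g)
        for s in range(n_subjects):
            sid = f"{group}{s + 1}"
            for r in range(1, n_replicates + 1):
                records.append(
                    WBRecord(
                        subject_id=sid,
                        group=group,
                        replicate=r,
                        target_density=float(target_base + g + rng.normal(0, 1)),
                        loading_density=float(loading_base + rng.normal(0, 0.5)),
                    )
                )
    return WBDataset(records)


@pytest.fixture
def small_dataset():
    return make_dataset()


@pytest.fixture
def design_csv(tmp_path):
    """16 subjects in 4 groups of 4 (2x2 factorial style)."""
    path = tmp_path / "design.csv"
    lines = ["SubjectID,Group"]
    for g, group in enumerate(["WT-Drug", "WT-Veh", "TG-Drug", "TG-Veh"]):
        for s in range(4):
            lines.append(f"s{g * 4 + s + 1},{group}")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def samples_16():
    return [
        Sample(f"s{g * 4 + s + 1}", group)
        for g, group in enumerate(["WT-Drug", "WT-Veh", "TG-Drug", "TG-Veh"])
        for s in range(4)
    ]
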