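"""Domain types and CSV input/output for densitometry experiments.

The unit of design is the :class:`Sample` (one biological subject assigned to
one experimental group).  Quantified band densities live in a
:class:`WBDataset`: one :class:`WBRecord` per subject x technical replicate,
carrying the target-protein band density and the loading-control band density
from the same lane.

All files are plain comma-separated UTF-8 with a header row.  Group labels and
subject IDs are whitespace-trimmed but case-sensitive ("WT" != "wt"): silent
case-folding would hide exactly the data-entry errors the QC step exists to
catch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, InputError, ValidationError

__all__ = [
    "Sample",
    "WBRecord",
    "WBDataset",
    "QCReport",
    "ColumnMap",
    "LoadReport",
    "read_design_table",
    "validate_unique_groups",
    "read_measurements",
    "write_template",
    "TEMPLATE_COLUMNS",
]

#: Column order of the gel-map template written by :func:`write_template`.
TEMPLATE_COLUMNS = (
    "Gel",
    "Lane",
    "SubjectID",
    "Group",
    "Replicate",
    "TargetProtein",
    "LoadingControl",
)


@dataclass(frozen=True)
class Sample:
    """One biological subject and its experimental group."""

    subject_id: str
    group: str

    def __post_init__(self):
        if not self.subject_id:
            raise ValidationError("subject_id must be non-empty")
        if not self.group:
            raise ValidationError("group must be non-empty")


@dataclass(frozen=True)
class WBRecord:
    """One quantified lane: a subject on one technical replicate gel.

    Densities are in arbitrary fluorescence units.  ``loading_density`` must
    be strictly positive because it serves both as a ratio divisor and as a
    covariate.
    """

    subject_id: str
    group: str
    replicate: int
    target_density: float
    loading_density: float
    gel_id: str | None = None
    lane: int | None = None

    def __post_init__(self):
        if self.replicate < 1:
            raise ValidationError(
                f"replicate must be >= 1, got {self.replicate} for subject "
                f"{self.subject_id!r}"
            )
        if not math.isfinite(self.target_density) or self.target_density < 0:
            raise ValidationError(
                f"target_density must be finite and >= 0 for subject "
                f"{self.subject_id!r}, got {self.target_density}"
            )
        if not math.isfinite(self.loading_density) or self.loading_density <= 0:
            raise ValidationError(
                f"loading_density must be finite and > 0 for subject "
                f"{self.subject_id!r}, got {self.loading_density}"
            )


@dataclass(frozen=True)
class ColumnMap:
    """Maps user column names onto the five semantic roles of a densitometry
    table, plus the optional design-metadata columns of the template."""

    subject: str = "SubjectID"
    group: str = "Group"
    replicate: str = "Replicate"
    target: str = "TargetProtein"
    loading: str = "LoadingControl"
    gel: str | None = "Gel"
    lane: str | None = "Lane"

    def required(self) -> dict[str, str]:
        return {
            "subject": self.subject,
            "group": self.group,
            "replicate": self.replicate,
            "target": self.target,
            "loading": self.loading,
        }


@dataclass
class LoadReport:
    """What happened while reading a measurement file."""

    n_rows: int = 0
    n_loaded: int = 0
    n_dropped_blank: int = 0
    messages: list[str] = field(default_factory=list)


@dataclass
class QCReport:
    """Result of the subject-uniqueness quality check.

    ``passed`` is ``True`` iff no subject ID appears in two or more distinct
    experimental groups.  Exact duplicate rows (same subject, same group) are
    reported as warnings in ``messages`` but do not fail the check.
    """

    passed: bool
    duplicated_subjects: list[tuple[str, frozenset[str]]] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)


class WBDataset:
    """Long-format densitometry records with their column mapping.

    Invariants: every subject maps to exactly one group; each
    (subject, replicate) pair appears at most once.
    """

    def __init__(
        self,
        records: Sequence[WBRecord],
        column_map: ColumnMap | None = None,
        load_report: LoadReport | None = None,
    ):
        records = list(records)
        _check_dataset_invariants(records)
        self.records: list[WBRecord] = records
        self.column_map = column_map or ColumnMap()
        self.load_report = load_report

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.subject_id)
        return list(seen)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.group)
        return list(seen)

    @property
    def replicates(self) -> list[int]:
        return sorted({r.replicate for r in self.records})

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.records],
                "group": [r.group for r in self.records],
                "replicate": [r.replicate for r in self.records],
                "target_density": [r.target_density for r in self.records],
                "loading_density": [r.loading_density for r in self.records],
                "gel_id": [r.gel_id for r in self.records],
                "lane": [r.lane for r in self.records],
            }
        )


def _check_dataset_invariants(records: Sequence[WBRecord]) -> None:
    group_of: dict[str, str] = {}
    seen_pairs: set[tuple[str, int]] = set()
    for rec in records:
        prev = group_of.setdefault(rec.subject_id, rec.group)
        if prev != rec.group:
            qc = validate_unique_groups(
                [Sample(r.subject_id, r.group) for r in records]
            )
            raise ValidationError(
                f"subject {rec.subject_id!r} appears in groups {prev!r} and "
                f"{rec.group!r}; each subject must belong to exactly one group",
                qc_report=qc,
            )
        key = (rec.subject_id, rec.replicate)
        if key in seen_pairs:
            raise ValidationError(
                f"duplicate record for subject {rec.subject_id!r}, replicate "
                f"{rec.replicate}"
            )
        seen_pairs.add(key)


def read_design_table(path: str | Path, id_col: str = "SubjectID", group_col: str = "Group") -> list[Sample]:
    """Read a design CSV (one row per subject) into a list of :class:`Sample`.

    Column names are matched exactly; a trailing space in the file's header is
    a configuration error, not something to be silently repaired.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"design table not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in (id_col, group_col):
        if col not in df.columns:
            raise ConfigurationError(
                f"column {col!r} not found in {path.name}; available columns: "
                f"{list(df.columns)}"
            )
    samples: list[Sample] = []
    for _, row in df.iterrows():
        sid = str(row[id_col]).strip()
        grp = str(row[group_col]).strip()
        if not sid and not grp:
            continue  # fully blank row
        samples.append(Sample(sid, grp))
    if not samples:
        raise InputError(f"design table {path.name} contains no sample rows")
    return samples


def validate_unique_groups(samples: Iterable[Sample]) -> QCReport:
    """Check that each subject ID is found in only one experimental group.

    Never raises: QC reports, the caller decides.  A subject ID repeated
    within the *same* group is flagged as a message (possible duplicate row)
    but does not fail the check.
    """
    groups_of: dict[str, set[str]] = {}
    counts: dict[tuple[str, str], int] = {}
    for s in samples:
        groups_of.setdefault(s.subject_id, set()).add(s.group)
        counts[(s.subject_id, s.group)] = counts.get((s.subject_id, s.group), 0) + 1

    duplicated = [
        (sid, frozenset(gs)) for sid, gs in groups_of.items() if len(gs) > 1
    ]
    messages = [
        f"subject {sid!r} appears in multiple groups: {sorted(gs)}"
        for sid, gs in duplicated
    ]
    for (sid, grp), n in counts.items():
        if n > 1:
            messages.append(
                f"subject {sid!r} listed {n} times in group {grp!r} "
                "(duplicate rows of the same record?)"
            )
    return QCReport(passed=not duplicated, duplicated_subjects=duplicated, messages=messages)


def _parse_density(value, row_number: int, col: str) -> float | None:
    """Parse one density cell; ``None`` for blank, InputError for junk."""
    if value is None:
        return None
    text = str(value).strip()
    if text == "" or text.lower() == "nan":
        return None
    try:
        return float(text)
    except ValueError:
        raise InputError(
            f"non-numeric value {text!r} in column {col!r} at row {row_number}"
        ) from None


def read_measurements(path: str | Path, column_map: ColumnMap | None = None) -> WBDataset:
    """Read a long-format densitometry CSV into a :class:`WBDataset`.

    Rows whose target or loading cell is blank are excluded (the template is
    filled incrementally at the bench) and counted in the dataset's
    ``load_report``.  A zero or negative loading density, a subject in two
    groups, or a duplicated (subject, replicate) pair is an error.
    """
    cmap = column_map or ColumnMap()
    path = Path(path)
    if not path.exists():
        raise InputError(f"measurement file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for role, col in cmap.required().items():
        if col not in df.columns:
            raise ConfigurationError(
                f"column {col!r} (role: {role}) not found in {path.name}; "
                f"available columns: {list(df.columns)}"
            )
    has_gel = cmap.gel is not None and cmap.gel in df.columns
    has_lane = cmap.lane is not None and cmap.lane in df.columns

    report = LoadReport(n_rows=len(df))
    records: list[WBRecord] = []
    for i, row in df.iterrows():
        row_number = i + 2  # 1-based + header line
        target = _parse_density(row[cmap.target], row_number, cmap.target)
        loading = _parse_density(row[cmap.loading], row_number, cmap.loading)
        if target is None or loading is None:
            report.n_dropped_blank += 1
            continue
        if loading <= 0:
            raise ValidationError(
                f"loading control density must be > 0 (row {row_number}: "
                f"{loading})"
            )
        try:
            replicate = int(str(row[cmap.replicate]).strip())
        except ValueError:
            raise InputError(
                f"non-integer replicate {row[cmap.replicate]!r} at row "
                f"{row_number}"
            ) from None
        lane = None
        if has_lane and str(row[cmap.lane]).strip():
            lane = int(str(row[cmap.lane]).strip())
        gel_id = None
        if has_gel and str(row[cmap.gel]).strip():
            gel_id = str(row[cmap.gel]).strip()
        records.append(
            WBRecord(
                subject_id=str(row[cmap.subject]).strip(),
                group=str(row[cmap.group]).strip(),
                replicate=replicate,
                target_density=target,
                loading_density=loading,
                gel_id=gel_id,
                lane=lane,
            )
        )
    if not records:
        raise InputError(f"no complete measurement rows in {path.name}")
    report.n_loaded = len(records)
    if report.n_dropped_blank:
        report.messages.append(
            f"excluded {report.n_dropped_blank} row(s) with blank density cells"
        )
    return WBDataset(records, column_map=cmap, load_report=report)


def write_template(gelmap, path: str | Path) -> Path:
    """Write a gel map as a fill-in-the-densities CSV template.

    One row per loaded lane per replicate, ordered by replicate, gel, lane.
    Ladder and empty lanes are omitted from the data rows; their positions are
    implied by the lane numbering.
    """
    path = Path(path)
    rows = []
    for a in gelmap.sample_assignments():
        rows.append(
            {
                "Gel": f"R{a.replicate}G{a.gel_index}",
                "Lane": a.lane,
                "SubjectID": a.content.subject_id,
                "Group": a.content.group,
                "Replicate": a.replicate,
                "TargetProtein": "",
                "LoadingControl": "",
            }
        )
    df = pd.DataFrame(rows, columns=list(TEMPLATE_COLUMNS))
    df.to_csv(path, index=False)
    return path
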