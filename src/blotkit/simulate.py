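"""Synthetic densitometry data with the variance structure the models assume.

The generator draws, for subject *i* in group *g* on replicate gel *j*,

    a_ij = beta0 + effect_g + u_i + v_j + gamma * (x_ij - mu_x) + e_ij,

with subject intercepts ``u_i ~ N(0, sd_subject^2)``, gel-run intercepts
``v_j ~ N(0, sd_replicate^2)`` shared by every subject on that replicate,
lane noise ``e_ij ~ N(0, sd_residual^2)``, and a loading-control density
``x_ij`` drawn from a truncated normal (positive support).  The loading
control enters centered so that ``beta0`` stays the mean density of the
reference group regardless of the covariate slope.

Optionally the latent abundance passes through a saturating response
``d = d_max * a / (k + a)`` before being recorded, emulating band densities
outside the antibody's linear range; the recorded density is clipped at 0.

Defaults mirror a typical rodent-tissue experiment: technical triplicates,
unit-scale subject/gel/residual variation, and a loading control with a 10%
coefficient of variation (pipetting-scale error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .io import WBDataset, WBRecord

__all__ = [
    "SaturationParams",
    "SimulationParams",
    "DilutionSeries",
    "simulate_dataset",
    "simulate_dilution_series",
    "saturating_response",
]


@dataclass(frozen=True)
class SaturationParams:
    """Hyperbolic (binding-site limited) signal response."""

    d_max: float
    k: float

    def __post_init__(self):
        if self.d_max <= 0 or self.k <= 0:
            raise InputError("saturation requires d_max > 0 and k > 0")


@dataclass(frozen=True)
class SimulationParams:
    n_groups: int = 2
    n_subjects_per_group: int = 10
    n_replicates: int = 3
    beta0: float = 10.0
    group_effects: tuple[float, ...] = (0.0, 0.0)
    sd_subject: float = 1.0
    sd_replicate: float = 1.0
    sd_residual: float = 1.0
    loading_mean: float = 10.0
    loading_sd: float = 1.0  # CV 10% at the default mean
    loading_slope: float = 1.0
    saturation: SaturationParams | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_groups < 1 or self.n_subjects_per_group < 1 or self.n_replicates < 1:
            raise InputError("counts must be >= 1")
        if len(self.group_effects) != self.n_groups:
            raise InputError("group_effects must have one entry per group")
        if self.group_effects[0] != 0.0:
            raise InputError("the first (reference) group effect must be 0")
        if min(self.sd_subject, self.sd_replicate) < 0 or self.sd_residual <= 0:
            raise InputError("SDs must be >= 0 and sd_residual > 0")
        if self.loading_mean <= 0 or self.loading_sd < 0:
            raise InputError("loading_mean must be > 0 and loading_sd >= 0")


@dataclass(frozen=True)
class DilutionSeries:
    """A serial 1:2 dilution ladder and its measured band densities."""

    concentrations: tuple[float, ...]
    densities: tuple[float, ...]

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        if len(c) < 4:
            raise InputError("a dilution series needs >= 4 points")
        if np.any(c <= 0):
            raise InputError("concentrations must be positive")
        if not np.allclose(c[:-1] / c[1:], 2.0):
            raise InputError("concentrations must halve at each step (serial 1:2)")
        if len(self.densities) != len(c):
            raise InputError("densities and concentrations differ in length")
        if any(d < 0 for d in self.densities):
            raise InputError("densities must be >= 0")

    def __len__(self) -> int:
        return len(self.concentrations)


def saturating_response(a: np.ndarray, sat: SaturationParams) -> np.ndarray:
    """d = d_max * a / (k + a), clipped at 0 for non-positive abundance."""
    a = np.maximum(np.asarray(a, dtype=float), 0.0)
    return sat.d_max * a / (sat.k + a)


def _truncated_normal(rng, mean, sd, size):
    """Normal(mean, sd) restricted to positive values, by resampling."""
    if sd == 0:
        return np.full(size, float(mean))
    x = rng.normal(mean, sd, size)
    bad = x <= 0
    while np.any(bad):
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = x <= 0
    return x


def simulate_dataset(params: SimulationParams) -> WBDataset:
    """Draw one complete experiment: every subject on every replicate gel."""
    rng = np.random.default_rng(params.seed)
    groups = [f"G{g + 1}" for g in range(params.n_groups)]
    n_subj = params.n_groups * params.n_subjects_per_group

    u = rng.normal(0.0, params.sd_subject, n_subj)
    v = rng.normal(0.0, params.sd_replicate, params.n_replicates)

    records: list[WBRecord] = []
    si = 0
    for g, group in enumerate(groups):
        for s in range(params.n_subjects_per_group):
            subject = f"{group}_S{s + 1:02d}"
            for j in range(params.n_replicates):
                x = float(
                    _truncated_normal(rng, params.loading_mean, params.loading_sd, 1)[0]
                )
                a = (
                    params.beta0
                    + params.group_effects[g]
                    + u[si]
                    + v[j]
                    + params.loading_slope * (x - params.loading_mean)
                    + rng.normal(0.0, params.sd_residual)
                )
                if params.saturation is not None:
                    density = float(saturating_response(np.array([a]), params.saturation)[0])
                else:
                    density = max(a, 0.0)
                records.append(
                    WBRecord(
                        subject_id=subject,
                        group=group,
                        replicate=j + 1,
                        target_density=density,
                        loading_density=x,
                    )
                )
            si += 1
    return WBDataset(records)


def simulate_dilution_series(
    top_concentration: float,
    n_dilutions: int,
    d_max: float,
    k: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DilutionSeries:
    """Serial 1:2 dilution ladder through a saturating response plus noise.

    Concentrations are ``top / 2**m`` for m = 0..n-1; densities are
    ``d_max * c / (k + c)`` with additive normal noise, clipped at 0.
    """
    if n_dilutions < 4:
        raise InputError("n_dilutions must be >= 4")
    rng = np.random.default_rng(seed)
    c = top_concentration / 2.0 ** np.arange(n_dilutions)
    d = d_max * c / (k + c)
    if noise_sd > 0:
        d = d + rng.normal(0.0, noise_sd, n_dilutions)
    d = np.maximum(d, 0.0)
    return DilutionSeries(tuple(c), tuple(d))
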