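"""Linear-range detection for antibody dilution series.

Band density tracks loaded protein linearly only inside a window of
concentrations; at high load the signal saturates and at very low load it
falls into the noise floor.  Quantitative comparisons (and every linear
model downstream) assume measurements stay inside that window, so it must
be found first from a serial-dilution ladder.

There is no universally agreed criterion for "linear enough"; this module's
definition is a dual one, applied to every contiguous window of the series:

* the least-squares fit of density on concentration has r^2 >= ``r2_min``;
* every point's relative deviation from that fit is <= ``max_rel_dev``.

The per-point bound matters because r^2 alone barely moves when a single
edge point saturates.  Among qualifying windows the longest wins; ties go to
the higher r^2.  The fit is on the natural scale (not log-log) because the
downstream models assume density linear in protein amount.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InputError
from .simulate import DilutionSeries

__all__ = ["LinearRange", "estimate_linear_range"]


@dataclass(frozen=True)
class LinearRange:
    """A qualifying window of a dilution series (inclusive indices)."""

    start_index: int
    end_index: int
    slope: float
    intercept: float
    r_squared: float
    max_relative_deviation: float

    @property
    def n_points(self) -> int:
        return self.end_index - self.start_index + 1


def _window_stats(c: np.ndarray, d: np.ndarray):
    fit = stats.linregress(c, d)
    pred = fit.intercept + fit.slope * c
    denom = np.where(np.abs(pred) > 0, np.abs(pred), np.inf)
    rel_dev = float(np.max(np.abs(d - pred) / denom))
    return fit.slope, fit.intercept, float(fit.rvalue**2), rel_dev


def estimate_linear_range(
    series: DilutionSeries,
    min_points: int = 4,
    r2_min: float = 0.99,
    max_rel_dev: float = 0.10,
) -> LinearRange | None:
    """Longest contiguous window where density responds linearly to load.

    Scans all O(n^2) contiguous windows of length >= ``min_points`` and
    returns the longest one meeting both criteria (ties: higher r^2), or
    ``None`` when no window qualifies.
    """
    n = len(series)
    if n < min_points:
        raise InputError(
            f"series has {n} points but min_points={min_points}"
        )
    c = np.asarray(series.concentrations, dtype=float)
    d = np.asarray(series.densities, dtype=float)

    best: LinearRange | None = None
    for start in range(n - min_points + 1):
        for end in range(start + min_points - 1, n):
            slope, intercept, r2, rel_dev = _window_stats(
                c[start : end + 1], d[start : end + 1]
            )
            if r2 < r2_min or rel_dev > max_rel_dev:
                continue
            cand = LinearRange(start, end, slope, intercept, r2, rel_dev)
            if (
                best is None
                or cand.n_points > best.n_points
                or (cand.n_points == best.n_points and cand.r_squared > best.r_squared)
            ):
                best = cand
    return best
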