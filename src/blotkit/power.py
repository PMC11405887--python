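"""Monte Carlo observed power by parametric simulation from a fitted model.

Responses are simulated unconditionally from the fitted fixed effects and
variance components — fresh random-intercept and residual draws each time,
not conditioned on the estimated subject/gel effects — and the same strategy
is refitted to each simulated outcome.  Observed power is the fraction of
refits whose group p-value clears the significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

import numpy as np

from .errors import InputError
from .models import (
    FitResult,
    ModelTable,
    Replication,
    build_design,
    fit_strategy,
)

__all__ = ["PowerResult", "simulate_from_fit", "monte_carlo_power"]


@dataclass
class PowerResult:
    n_sim: int
    alpha: float
    power: float
    mc_se: float
    n_failed_fits: int
    seed: int
    warnings: list[str] = field(default_factory=list)


def simulate_from_fit(
    fit: FitResult, table: ModelTable, rng: np.random.Generator
) -> np.ndarray:
    """One simulated outcome vector from the fitted model.

    Mixed-model fits draw fresh subject and replicate-batch intercepts from
    the estimated variance components plus residual noise; least-squares
    fits draw residual noise only.  The design (groups, covariate values,
    replicate structure) is taken from the original table unchanged.
    """
    X, names, _, Zs, Zr, _ = build_design(table)
    beta = np.array([fit.beta[name] for name in names])
    mu = X @ beta
    if fit.variance_components is not None:
        vc = fit.variance_components
        u = rng.normal(0.0, sqrt(max(vc["subject"], 0.0)), Zs.shape[1])
        v = rng.normal(0.0, sqrt(max(vc["replicate"], 0.0)), Zr.shape[1])
        eps = rng.normal(0.0, sqrt(max(vc["residual"], 0.0)), len(mu))
        return mu + Zs @ u + Zr @ v + eps
    # OLS: residual variance from the fit's own residuals
    resid_var = _ols_residual_variance(fit, table, X, beta)
    return mu + rng.normal(0.0, sqrt(resid_var), len(mu))


def _ols_residual_variance(fit, table, X, beta):
    y = table.data["y"].to_numpy(dtype=float)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    if dof <= 0:
        raise InputError("no residual degrees of freedom to simulate from")
    return float(resid @ resid / dof)


def monte_carlo_power(
    fit: FitResult,
    table: ModelTable,
    n_sim: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PowerResult:
    """Observed power: simulate, refit the same strategy, count rejections.

    Refits that fail or do not converge are excluded from the denominator
    and counted; if more than 20% fail, the estimate carries a reliability
    warning.
    """
    if n_sim < 1:
        raise InputError("n_sim must be >= 1")
    if not (0 < alpha <= 1):
        raise InputError("alpha must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_sig = 0
    n_failed = 0
    for _ in range(n_sim):
        y_star = simulate_from_fit(fit, table, rng)
        try:
            refit = fit_strategy(table.with_outcome(y_star))
        except Exception:
            n_failed += 1
            continue
        if not refit.converged:
            n_failed += 1
            continue
        if refit.p_group < alpha:
            n_sig += 1
    n_eff = n_sim - n_failed
    warnings = []
    if n_eff == 0:
        raise InputError("every simulated refit failed")
    power = n_sig / n_eff
    mc_se = sqrt(power * (1 - power) / n_eff)
    if n_failed > 0.2 * n_sim:
        warnings.append(
            f"{n_failed}/{n_sim} refits failed; power estimate may be unreliable"
        )
    return PowerResult(
        n_sim=n_sim,
        alpha=alpha,
        power=power,
        mc_se=mc_se,
        n_failed_fits=n_failed,
        seed=seed,
        warnings=warnings,
    )
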