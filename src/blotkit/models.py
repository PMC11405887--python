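"""Analysis strategies for replicated densitometry data.

The outcome is the target-protein band density of subject *i* on technical
replicate gel *j*.  The recommended model is a linear mixed model with
crossed random intercepts,

    y_ij = b0 + b_group(i) + g * x_ij + u_i + v_j + e_ij,

where ``x_ij`` is the loading-control density of the same lane (covariate),
``u_i ~ N(0, s2_subject)`` captures biological subject-to-subject variation,
``v_j ~ N(0, s2_replicate)`` captures the shared gel-run (batch) shift of
replicate *j*, and ``e_ij ~ N(0, s2_residual)`` is lane noise.  Variance
components are estimated by restricted maximum likelihood (REML) with the
fixed effects profiled out; the group p-value comes from a likelihood-ratio
test between maximum-likelihood fits with and without the group factor (REML
log-likelihoods are not comparable across fixed-effect structures).

Replication is modelled as a *crossed* batch effect rather than literally
nested within subject: with a single observation per subject x replicate
cell, a per-cell intercept is confounded with the residual.  The nested form
is available behind ``nested=True`` and emits an identifiability warning.

Alternative strategies — dropping replicates, treating them as independent,
averaging them, and dividing by the loading control instead of covarying on
it — are provided so their consequences can be compared on equal footing.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .errors import ModelError, StrategyError
from .io import WBDataset

__all__ = [
    "Replication",
    "Loading",
    "StrategySpec",
    "ModelTable",
    "FitResult",
    "SummaryTable",
    "prepare_table",
    "fit_ols",
    "fit_lmm",
    "fit_strategy",
    "standardized_effect",
    "summarize_groups",
    "build_design",
]


class Replication(str, enum.Enum):
    """How technical replicates enter the analysis."""

    FIRST_ONLY = "first_only"     # ignore replication: lowest replicate index
    INDEPENDENT = "independent"   # pseudoreplication: every row a "subject"
    MEAN = "mean"                 # collapse to per-subject means
    RANDOM_EFFECT = "random_effect"  # replicate batch as a random intercept


class Loading(str, enum.Enum):
    """How the loading control enters the analysis."""

    RATIO = "ratio"          # y = target / loading
    COVARIATE = "covariate"  # y = target, loading on the right-hand side


@dataclass(frozen=True)
class StrategySpec:
    replication: Replication
    loading: Loading

    def label(self) -> str:
        return f"{self.replication.value}+{self.loading.value}"


@dataclass
class ModelTable:
    """Long-format table ready for fitting: one row per analysis unit."""

    data: pd.DataFrame  # columns: subject_id, group, replicate, y [, x_loading]
    strategy: StrategySpec

    @property
    def has_covariate(self) -> bool:
        return "x_loading" in self.data.columns

    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def n_replicates(self) -> int:
        return self.data["replicate"].nunique()

    def with_outcome(self, y: np.ndarray) -> "ModelTable":
        df = self.data.copy()
        df["y"] = np.asarray(y, dtype=float)
        return ModelTable(df, self.strategy)


@dataclass
class FitResult:
    strategy: StrategySpec
    beta: dict[str, float]
    se: dict[str, float]
    p_group: float
    effect_size_std: float
    loglik: float
    converged: bool
    n_obs: int
    n_subjects: int
    n_replicates: int
    variance_components: dict[str, float] | None = None
    wald_p_group: float | None = None
    boundary: bool = False
    diagnostics: list[str] = field(default_factory=list)


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    sem: float | None
    ci95_low: float | None
    ci95_high: float | None


@dataclass
class SummaryTable:
    groups: list[GroupSummary]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(g) for g in self.groups])


def prepare_table(
    data: WBDataset,
    strategy: StrategySpec,
    ratio_of_means: bool = False,
) -> ModelTable:
    """Reduce a dataset to the analysis table a strategy implies.

    ``FIRST_ONLY`` keeps the lowest replicate index per subject; ``MEAN``
    collapses to per-subject means; ``INDEPENDENT`` and ``RANDOM_EFFECT``
    keep all rows.  Under ``RATIO`` the outcome is target/loading computed
    per lane and, for ``MEAN``, averaged afterwards (mean of ratios; set
    ``ratio_of_means=True`` for the other order).
    """
    df = data.to_dataframe()[
        ["subject_id", "group", "replicate", "target_density", "loading_density"]
    ].copy()

    rep, load = strategy.replication, strategy.loading
    if rep is Replication.RANDOM_EFFECT and df["replicate"].nunique() < 2:
        raise StrategyError(
            "random-effect replication requires >= 2 technical replicates"
        )

    if rep is Replication.FIRST_ONLY:
        df = df.loc[df.groupby("subject_id")["replicate"].transform("min") == df["replicate"]]
        df = df.reset_index(drop=True)

    if rep is Replication.MEAN:
        if load is Loading.RATIO and not ratio_of_means:
            df["ratio"] = df["target_density"] / df["loading_density"]
            out = df.groupby(["subject_id", "group"], as_index=False, sort=False).agg(
                y=("ratio", "mean")
            )
        else:
            out = df.groupby(["subject_id", "group"], as_index=False, sort=False).agg(
                target=("target_density", "mean"),
                loading=("loading_density", "mean"),
            )
            if load is Loading.RATIO:
                out["y"] = out["target"] / out["loading"]
            else:
                out["y"] = out["target"]
                out["x_loading"] = out["loading"]
            out = out.drop(columns=["target", "loading"])
        out["replicate"] = 1
        cols = ["subject_id", "group", "replicate", "y"]
        if "x_loading" in out.columns:
            cols.append("x_loading")
        return ModelTable(out[cols], strategy)

    if load is Loading.RATIO:
        df["y"] = df["target_density"] / df["loading_density"]
        cols = ["subject_id", "group", "replicate", "y"]
    else:
        df["y"] = df["target_density"]
        df["x_loading"] = df["loading_density"]
        cols = ["subject_id", "group", "replicate", "y", "x_loading"]
    return ModelTable(df[cols].reset_index(drop=True), strategy)


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def build_design(table: ModelTable):
    """Build fixed- and random-effect design matrices from a model table.

    Returns ``(X, names, group_cols, Zs, Zr, y)`` where ``X`` uses treatment
    contrasts against the alphabetically first group, ``group_cols`` indexes
    the group-contrast columns of ``X``, and ``Zs`` / ``Zr`` are subject and
    replicate-batch indicator matrices.
    """
    df = table.data
    y = df["y"].to_numpy(dtype=float)
    n = len(df)
    groups = sorted(df["group"].unique())
    names = ["Intercept"]
    cols = [np.ones(n)]
    group_cols = []
    for g in groups[1:]:
        names.append(f"group[{g}]")
        cols.append((df["group"] == g).to_numpy(dtype=float))
        group_cols.append(len(cols) - 1)
    if table.has_covariate:
        names.append("loading")
        cols.append(df["x_loading"].to_numpy(dtype=float))
    X = np.column_stack(cols)

    subj = pd.Categorical(df["subject_id"])
    Zs = np.zeros((n, len(subj.categories)))
    Zs[np.arange(n), subj.codes] = 1.0
    rep = pd.Categorical(df["replicate"])
    Zr = np.zeros((n, len(rep.categories)))
    Zr[np.arange(n), rep.codes] = 1.0
    return X, names, group_cols, Zs, Zr, y


# ---------------------------------------------------------------------------
# ordinary least squares
# ---------------------------------------------------------------------------

def fit_ols(table: ModelTable) -> FitResult:
    """Least-squares fit of y ~ group (+ loading covariate).

    The group p-value is the sequential F-test of the group factor after the
    covariate (extra sum of squares between the covariate-only and the full
    model).
    """
    import statsmodels.api as sm

    df = table.data
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ModelError("at least two experimental groups are required")
    counts = df["group"].value_counts()
    if counts.min() < 2:
        raise ModelError("each group needs >= 2 observations for an F-test")

    X, names, group_cols, _, _, y = build_design(table)
    full = sm.OLS(y, X).fit()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("singular design matrix")

    reduced_cols = [i for i in range(X.shape[1]) if i not in group_cols]
    reduced = sm.OLS(y, X[:, reduced_cols]).fit()
    q = len(group_cols)
    df_resid = full.df_resid
    f_stat = ((reduced.ssr - full.ssr) / q) / (full.ssr / df_resid)
    p_group = float(stats.f.sf(f_stat, q, df_resid))

    beta = dict(zip(names, full.params))
    se = dict(zip(names, full.bse))
    result = FitResult(
        strategy=table.strategy,
        beta=beta,
        se=se,
        p_group=p_group,
        effect_size_std=float("nan"),
        loglik=float(full.llf),
        converged=True,
        n_obs=table.n_obs,
        n_subjects=table.n_subjects,
        n_replicates=table.n_replicates,
        wald_p_group=p_group,
    )
    result.effect_size_std = standardized_effect(result, table)
    return result


# ---------------------------------------------------------------------------
# linear mixed model (profiled REML / ML, crossed random intercepts)
# ---------------------------------------------------------------------------

_LOG_PHI_MIN, _LOG_PHI_MAX = -14.0, 10.0


def _profiled_neg2ll(log_phi, X, y, Zs, Zr, reml):
    """-2 log-likelihood with beta and the residual variance profiled out.

    ``phi`` are the variance ratios s2_subject/s2_resid and
    s2_replicate/s2_resid; V = I + phi_s Zs Zs' + phi_r Zr Zr'.
    """
    n, p = X.shape
    phi_s, phi_r = np.exp(log_phi)
    V = np.eye(n) + phi_s * (Zs @ Zs.T) + phi_r * (Zr @ Zr.T)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return np.inf, None
    logdet_V = 2.0 * np.sum(np.log(np.diag(L)))
    Xi = np.linalg.solve(L, X)
    yi = np.linalg.solve(L, y)
    XtVX = Xi.T @ Xi
    try:
        beta = np.linalg.solve(XtVX, Xi.T @ yi)
    except np.linalg.LinAlgError:
        return np.inf, None
    r = yi - Xi @ beta
    rss = float(r @ r)
    if rss <= 0:
        return np.inf, None
    if reml:
        dof = n - p
        sigma2 = rss / dof
        sign, logdet_XtVX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf, None
        crit = (
            dof * np.log(2 * np.pi * sigma2)
            + logdet_V
            + logdet_XtVX
            + dof
        )
    else:
        sigma2 = rss / n
        crit = n * np.log(2 * np.pi * sigma2) + logdet_V + n
    return crit, (beta, sigma2, XtVX)


def _optimize_variances(X, y, Zs, Zr, reml, tol=1e-10):
    """Minimize the profiled criterion over the two log variance ratios."""
    starts = [
        np.log([0.5, 0.5]),
        np.log([1e-4, 1e-4]),
        np.log([2.0, 0.1]),
    ]
    results = [
        minimize(
            lambda lp: _profiled_neg2ll(lp, X, y, Zs, Zr, reml)[0],
            x0,
            method="L-BFGS-B",
            bounds=[(_LOG_PHI_MIN, _LOG_PHI_MAX)] * 2,
            options={"ftol": tol, "gtol": 1e-9},
        )
        for x0 in starts
    ]
    best_fun = min(r.fun for r in results)
    # among starts that reached (numerically) the same optimum, prefer one
    # with a clean optimizer status: line searches can fail on the last step
    # of an already-converged path
    near = [r for r in results if r.fun <= best_fun + 1e-6 * (1 + abs(best_fun))]
    clean = [r for r in near if r.success]
    best = min(clean or near, key=lambda r: r.fun)
    return best, bool(clean)


def fit_lmm(table: ModelTable, nested: bool = False) -> FitResult:
    """REML fit of the crossed random-intercepts mixed model.

    Fixed effects: intercept, group contrasts and (optionally) the loading
    covariate.  Random intercepts: subject and replicate batch.  Variance
    estimates are constrained non-negative; a component driven to the lower
    boundary is reported as (numerically) zero with ``boundary=True``, not
    an error.  ``p_group`` is the likelihood-ratio chi-square between ML
    refits with and without the group factor; a Wald p-value is reported
    alongside for transparency.
    """
    df = table.data
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ModelError("at least two experimental groups are required")
    if df["replicate"].nunique() < 2:
        raise StrategyError("the mixed model needs >= 2 replicate batches")
    per_group_subjects = df.groupby("group")["subject_id"].nunique()
    if per_group_subjects.min() < 2:
        raise ModelError("each group needs >= 2 subjects")
    if nested:
        warnings.warn(
            "nested replicate-within-subject intercepts are confounded with "
            "the residual at one observation per cell; estimates may sit on "
            "the boundary",
            stacklevel=2,
        )

    X, names, group_cols, Zs, Zr, y = build_design(table)
    if nested:
        # one indicator per subject x replicate cell
        cell = pd.Categorical(
            df["subject_id"].astype(str) + ":" + df["replicate"].astype(str)
        )
        Zr = np.zeros((len(df), len(cell.categories)))
        Zr[np.arange(len(df)), cell.codes] = 1.0

    best, converged = _optimize_variances(X, y, Zs, Zr, reml=True)
    crit, aux = _profiled_neg2ll(best.x, X, y, Zs, Zr, reml=True)
    if aux is None:
        raise ModelError("REML criterion is degenerate on these data")
    beta_hat, sigma2_e, XtVX = aux
    phi = np.exp(best.x)
    boundary = bool(np.any(best.x <= _LOG_PHI_MIN + 1e-6))
    sigma2_s = float(phi[0] * sigma2_e)
    sigma2_r = float(phi[1] * sigma2_e)
    # snap numerically-zero boundary components to exactly zero for reporting
    if best.x[0] <= _LOG_PHI_MIN + 1e-6:
        sigma2_s = 0.0
    if best.x[1] <= _LOG_PHI_MIN + 1e-6:
        sigma2_r = 0.0

    cov_beta = sigma2_e * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov_beta))

    # likelihood-ratio test for the group factor, both fits by ML
    full_ml, conv_full = _optimize_variances(X, y, Zs, Zr, reml=False)
    reduced_cols = [i for i in range(X.shape[1]) if i not in group_cols]
    red_ml, conv_red = _optimize_variances(X[:, reduced_cols], y, Zs, Zr, reml=False)
    lr = max(0.0, red_ml.fun - full_ml.fun)
    q = len(group_cols)
    p_group = float(stats.chi2.sf(lr, q))

    # Wald test on the group contrasts at the REML variance estimates
    Lmat = np.zeros((q, X.shape[1]))
    for k, j in enumerate(group_cols):
        Lmat[k, j] = 1.0
    Lb = Lmat @ beta_hat
    wald = float(Lb @ np.linalg.solve(Lmat @ cov_beta @ Lmat.T, Lb))
    wald_p = float(stats.chi2.sf(wald, q))

    result = FitResult(
        strategy=table.strategy,
        beta=dict(zip(names, beta_hat)),
        se=dict(zip(names, se)),
        p_group=p_group,
        effect_size_std=float("nan"),
        loglik=float(-0.5 * crit),
        converged=bool(converged and conv_full and conv_red),
        n_obs=table.n_obs,
        n_subjects=table.n_subjects,
        n_replicates=table.n_replicates,
        variance_components={
            "subject": sigma2_s,
            "replicate": sigma2_r,
            "residual": float(sigma2_e),
        },
        wald_p_group=wald_p,
        boundary=boundary,
    )
    if not result.converged:
        result.diagnostics.append("optimizer did not report clean convergence")
    result.effect_size_std = standardized_effect(result, table)
    return result


def fit_strategy(table: ModelTable) -> FitResult:
    """Dispatch to the model class a strategy implies (LMM for
    random-effect replication, OLS otherwise)."""
    if table.strategy.replication is Replication.RANDOM_EFFECT:
        return fit_lmm(table)
    return fit_ols(table)


def standardized_effect(fit: FitResult, table: ModelTable) -> float:
    """Group coefficient in outcome-standard-deviation units.

    Equivalent to refitting the model on z-scored y and reading off the raw
    group coefficient (the refit path is exercised in the test suite).  With
    more than two groups, the first contrast is reported.
    """
    sd = float(np.std(table.data["y"].to_numpy(dtype=float), ddof=1))
    if sd == 0:
        raise ModelError("outcome has zero variance; standardized effect undefined")
    contrasts = [k for k in fit.beta if k.startswith("group[")]
    if not contrasts:
        raise ModelError("fit has no group coefficient")
    return float(fit.beta[contrasts[0]] / sd)


def summarize_groups(data: WBDataset, conf_level: float = 0.95) -> SummaryTable:
    """Per-group mean, SEM and t-based confidence interval.

    Computed on per-subject replicate means — one value per subject — so the
    error bars reflect biological n, not pseudoreplicated lane counts.  A
    single-subject group gets its mean with SEM/CI flagged unavailable.
    """
    df = data.to_dataframe()
    per_subject = df.groupby(["group", "subject_id"], as_index=False, sort=False)[
        "target_density"
    ].mean()
    out: list[GroupSummary] = []
    for group, sub in per_subject.groupby("group", sort=True):
        vals = sub["target_density"].to_numpy(dtype=float)
        n = len(vals)
        mean = float(np.mean(vals))
        if n < 2:
            out.append(GroupSummary(group, n, mean, None, None, None))
            continue
        sem = float(np.std(vals, ddof=1) / np.sqrt(n))
        tcrit = float(stats.t.ppf(0.5 + conf_level / 2, n - 1))
        out.append(
            GroupSummary(group, n, mean, sem, mean - tcrit * sem, mean + tcrit * sem)
        )
    return SummaryTable(out)
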