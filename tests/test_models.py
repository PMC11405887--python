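"""Strategy preparation, OLS/LMM fits, effect sizes and group summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import blotkit as bk
from blotkit.errors import ModelError, StrategyError
from blotkit.io import WBDataset, WBRecord
from blotkit.models import (
    Loading,
    ModelTable,
    Replication,
    StrategySpec,
    build_design,
    fit_lmm,
    fit_ols,
    prepare_table,
    standardized_effect,
    summarize_groups,
)

from conftest import make_dataset

RE_COV = StrategySpec(Replication.RANDOM_EFFECT, Loading.COVARIATE)


class TestPrepareTable:
    @pytest.fixture
    def tiny(self):
        recs = []
        for s, grp in (("s1", "WT"), ("s2", "WT"), ("s3", "TG")):
            for r, (t, l) in enumerate([(10.0, 2.0), (12.0, 4.0), (14.0, 6.0)], 1):
                recs.append(WBRecord(s, grp, r, t + (s == "s3"), l))
        return WBDataset(recs)

    def test_mean_covariate_averages_target_and_loading(self, tiny):
        t = prepare_table(tiny, StrategySpec(Replication.MEAN, Loading.COVARIATE))
        row = t.data.set_index("subject_id").loc["s1"]
        assert row["y"] == pytest.approx(12.0)
        assert row["x_loading"] == pytest.approx(4.0)
        assert t.n_obs == t.n_subjects == 3

    def test_ratio_outcome(self, tiny):
        t = prepare_table(tiny, StrategySpec(Replication.FIRST_ONLY, Loading.RATIO))
        row = t.data.set_index("subject_id").loc["s1"]
        assert row["y"] == pytest.approx(10.0 / 2.0)
        assert not t.has_covariate

    def test_independent_triples_the_apparent_n(self, tiny):
        ind = prepare_table(tiny, StrategySpec(Replication.INDEPENDENT, Loading.COVARIATE))
        first = prepare_table(tiny, StrategySpec(Replication.FIRST_ONLY, Loading.COVARIATE))
        assert ind.n_obs == 9 == 3 * first.n_obs

    def test_mean_of_ratios_vs_ratio_of_means(self, tiny):
        spec = StrategySpec(Replication.MEAN, Loading.RATIO)
        mor = prepare_table(tiny, spec).data.set_index("subject_id").loc["s1", "y"]
        rom = prepare_table(tiny, spec, ratio_of_means=True).data.set_index(
            "subject_id"
        ).loc["s1", "y"]
        assert mor == pytest.approx(np.mean([10 / 2, 12 / 4, 14 / 6]))
        assert rom == pytest.approx(12.0 / 4.0)

    def test_random_effect_needs_replicates(self):
        one_rep = WBDataset(
            [WBRecord("s1", "A", 1, 10, 5), WBRecord("s2", "B", 1, 9, 5)]
        )
        with pytest.raises(StrategyError):
            prepare_table(one_rep, RE_COV)


class TestFitOLS:
    def test_two_group_anova_equals_t_test(self):
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(8)],
                "group": ["A"] * 4 + ["B"] * 4,
                "replicate": 1,
                "y": [1.0, 2.0, 3.0, 4.0, 3.0, 4.0, 5.0, 7.0],
            }
        )
        fit = fit_ols(ModelTable(df, StrategySpec(Replication.FIRST_ONLY, Loading.RATIO)))
        t = stats.ttest_ind(df.y[df.group == "B"], df.y[df.group == "A"])
        assert fit.p_group == pytest.approx(t.pvalue, rel=1e-10)

    def test_perfect_covariate_absorbs_everything(self, rng):
        x = rng.uniform(1, 10, 12)
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(12)],
                "group": ["A"] * 6 + ["B"] * 6,
                "replicate": 1,
                "y": 2.0 * x,
                "x_loading": x,
            }
        )
        fit = fit_ols(ModelTable(df, StrategySpec(Replication.MEAN, Loading.COVARIATE)))
        assert fit.beta["loading"] == pytest.approx(2.0, abs=1e-10)
        assert fit.p_group > 0.999

    def test_matches_normal_equations(self, rng):
        for _ in range(5):
            n = 15
            df = pd.DataFrame(
                {
                    "subject_id": [f"s{i}" for i in range(n)],
                    "group": rng.choice(["A", "B", "C"], n).tolist() + [],
                    "replicate": 1,
                    "y": rng.normal(size=n),
                    "x_loading": rng.uniform(1, 5, n),
                }
            )
            if df.group.nunique() < 3 or df.group.value_counts().min() < 2:
                continue
            table = ModelTable(df, StrategySpec(Replication.MEAN, Loading.COVARIATE))
            fit = fit_ols(table)
            X, names, _, _, _, y = build_design(table)
            beta = np.linalg.solve(X.T @ X, X.T @ y)  # independent oracle
            for name, b in zip(names, beta):
                assert fit.beta[name] == pytest.approx(b, abs=1e-8)

    def test_p_value_scale_invariant(self):
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(10)],
                "group": ["A"] * 5 + ["B"] * 5,
                "replicate": 1,
                "y": [1.0, 2, 3, 4, 5, 4, 5, 6, 7, 9],
            }
        )
        spec = StrategySpec(Replication.FIRST_ONLY, Loading.RATIO)
        p1 = fit_ols(ModelTable(df, spec)).p_group
        df2 = df.assign(y=1000.0 * df.y + 7.0)
        p2 = fit_ols(ModelTable(df2, spec)).p_group
        assert p1 == pytest.approx(p2, rel=1e-10)

    def test_single_group_is_a_model_error(self):
        df = pd.DataFrame(
            {"subject_id": ["a", "b", "c"], "group": "A", "replicate": 1,
             "y": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ModelError):
            fit_ols(ModelTable(df, StrategySpec(Replication.MEAN, Loading.RATIO)))


def _lmm_table(seed=0, effect=1.0, sd_s=1.0, sd_r=1.0, n_subj=8):
    params = bk.SimulationParams(
        n_subjects_per_group=n_subj,
        group_effects=(0.0, effect),
        sd_subject=sd_s,
        sd_replicate=sd_r,
        seed=seed,
    )
    return prepare_table(bk.simulate_dataset(params), RE_COV)


class TestFitLMM:
    def test_degenerate_limit_matches_ols(self):
        # all subjects share the same replicate-residual pattern (cyclic
        # -1/0/+1), so subject means and replicate means carry no excess
        # spread: both variance components are driven to the zero boundary
        # and the fixed effects collapse onto least squares
        rows = []
        pattern = [-1.0, 0.0, 1.0]
        for g, grp in enumerate(["A", "B"]):
            for s in range(6):
                for r in range(3):
                    rows.append(
                        {
                            "subject_id": f"{grp}{s}",
                            "group": grp,
                            "replicate": r + 1,
                            "y": 10.0 + 0.5 * g + pattern[(r + s) % 3],
                        }
                    )
        table = ModelTable(pd.DataFrame(rows), StrategySpec(
            Replication.RANDOM_EFFECT, Loading.RATIO))
        lmm = fit_lmm(table)
        ols = fit_ols(ModelTable(table.data, table.strategy))
        assert lmm.boundary
        assert lmm.variance_components["subject"] == pytest.approx(0.0, abs=1e-4)
        assert lmm.variance_components["replicate"] == pytest.approx(0.0, abs=1e-4)
        for name in lmm.beta:
            assert lmm.beta[name] == pytest.approx(ols.beta[name], abs=1e-6)

    def test_beta_is_gls_at_the_estimated_variances(self):
        # dense-matrix GLS oracle: with V assembled by brute force from the
        # fitted variance components, (X'V^-1X)^-1 X'V^-1 y must reproduce
        # the mixed-model fixed effects
        table = _lmm_table(seed=9)
        fit = fit_lmm(table)
        X, names, _, Zs, Zr, y = build_design(table)
        vc = fit.variance_components
        V = (
            vc["residual"] * np.eye(len(y))
            + vc["subject"] * Zs @ Zs.T
            + vc["replicate"] * Zr @ Zr.T
        )
        Vi = np.linalg.inv(V)
        beta = np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi @ y
        for name, b in zip(names, beta):
            assert fit.beta[name] == pytest.approx(b, abs=1e-6)

    def test_agrees_with_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        table = _lmm_table(seed=3)
        fit = fit_lmm(table)
        df = table.data
        sm_fit = smf.mixedlm(
            "y ~ C(group) + x_loading",
            df,
            groups=np.ones(len(df)),
            vc_formula={
                "subject": "0 + C(subject_id)",
                "replicate": "0 + C(replicate)",
            },
            re_formula="0",
        ).fit(reml=True)
        assert fit.beta["group[G2]"] == pytest.approx(
            sm_fit.params["C(group)[T.G2]"], abs=1e-4
        )
        assert fit.variance_components["residual"] == pytest.approx(
            sm_fit.scale, rel=1e-3
        )
        assert sorted(
            [fit.variance_components["subject"], fit.variance_components["replicate"]]
        ) == pytest.approx(sorted(sm_fit.vcomp), rel=1e-2)

    def test_variances_nonnegative_and_relabel_invariant(self):
        table = _lmm_table(seed=21)
        fit = fit_lmm(table)
        assert all(v >= 0 for v in fit.variance_components.values())
        # relabel groups and subjects; variance estimates must not move
        df = table.data.copy()
        df["group"] = df["group"].map({"G1": "zebra", "G2": "aard"})
        df["subject_id"] = "x_" + df["subject_id"]
        fit2 = fit_lmm(ModelTable(df, table.strategy))
        for k in fit.variance_components:
            assert fit.variance_components[k] == pytest.approx(
                fit2.variance_components[k], rel=1e-5
            )
        assert fit2.p_group == pytest.approx(fit.p_group, rel=1e-5)

    def test_nested_form_warns(self):
        table = _lmm_table(seed=4)
        with pytest.warns(UserWarning, match="confounded"):
            fit_lmm(table, nested=True)

    def test_too_few_subjects_per_group(self):
        df = _lmm_table(seed=0).data
        df = df[df.subject_id.isin(["G1_S01", "G2_S01", "G2_S02"])]
        with pytest.raises(ModelError):
            fit_lmm(ModelTable(df.reset_index(drop=True), RE_COV))


class TestStandardizedEffect:
    def test_divide_by_sd(self):
        table = _lmm_table(seed=2)
        fit = fit_lmm(table)
        sd = np.std(table.data["y"], ddof=1)
        assert fit.effect_size_std == pytest.approx(fit.beta["group[G2]"] / sd)

    def test_matches_refit_on_zscored_outcome(self):
        # two-path oracle: z-score y upfront and refit; the raw group
        # coefficient must equal the standardized effect of the raw fit
        for seed in range(3):
            table = _lmm_table(seed=seed)
            fit = fit_lmm(table)
            y = table.data["y"].to_numpy()
            z = (y - y.mean()) / y.std(ddof=1)
            refit = fit_lmm(table.with_outcome(z))
            assert refit.beta["group[G2]"] == pytest.approx(
                fit.effect_size_std, abs=1e-6
            )

    def test_zero_variance_is_signalled(self):
        fit = fit_lmm(_lmm_table(seed=2))
        df = _lmm_table(seed=2).data.assign(y=1.0)
        with pytest.raises(ModelError):
            standardized_effect(fit, ModelTable(df, RE_COV))


class TestSummarizeGroups:
    def test_hand_computed_ci(self):
        recs = [
            WBRecord(f"s{i}", "A", 1, float(v), 5.0) for i, v in enumerate([1, 2, 3])
        ] + [WBRecord(f"t{i}", "B", 1, 4.0, 5.0) for i in range(2)]
        summary = summarize_groups(WBDataset(recs))
        a = next(g for g in summary.groups if g.group == "A")
        assert a.mean == pytest.approx(2.0)
        assert a.sem == pytest.approx(0.5774, abs=1e-4)
        # t(0.975, 2) = 4.3027
        assert a.ci95_low == pytest.approx(-0.4841, abs=1e-3)
        assert a.ci95_high == pytest.approx(4.4841, abs=1e-3)

    def test_uses_per_subject_means_not_lanes(self):
        data = make_dataset(n_subjects=4, n_replicates=3)
        summary = summarize_groups(data)
        assert all(g.n == 4 for g in summary.groups)

    def test_single_subject_group_has_no_ci(self):
        recs = [WBRecord("s1", "A", 1, 5.0, 5.0),
                WBRecord("s2", "B", 1, 6.0, 5.0),
                WBRecord("s3", "B", 1, 7.0, 5.0)]
        summary = summarize_groups(WBDataset(recs))
        a = next(g for g in summary.groups if g.group == "A")
        assert a.mean == 5.0 and a.sem is None and a.ci95_low is None

    def test_identical_values_degenerate_ci(self):
        recs = [WBRecord(f"s{i}", "A", 1, 3.0, 5.0) for i in range(3)] + [
            WBRecord("t1", "B", 1, 4.0, 5.0), WBRecord("t2", "B", 1, 5.0, 5.0)
        ]
        a = next(g for g in summarize_groups(WBDataset(recs)).groups if g.group == "A")
        assert a.sem == 0.0 and a.ci95_low == a.ci95_high == a.mean == 3.0
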