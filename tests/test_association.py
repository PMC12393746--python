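import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
import statsmodels.api as sm

from conftest import make_cohort
from lipidratios.association import (
    _interaction_pvalues, bh_adjust, concordance, fit_association, fit_linear,
    group_difference, p_gain, sex_interaction,
)
from lipidratios.io import RatioDefinition, resolve_selector, read_ratio_definitions, default_ratio_definitions_path
from lipidratios.ratios import compute_ratio_matrix
from lipidratios.simulate import SyntheticConfig, simulate_cohort


class TestPGain:
    # worked examples from the published class- and species-ratio tables
    @pytest.mark.parametrize(
        "components,ratio_p,printed",
        [
            ((4.31e-22, 3.36e-35), 4.30e-68, 7.80e32),
            ((3.05e-3, 3.36e-35), 4.41e-39, 7.60e3),
            ((3.48e-78, 1.38e-9), 1.09e-133, 3.20e55),
            ((9.68e-1, 1.59e-31), 4.8e-105, 3.32e73),
            ((8.99e-7, 4.35e-15), 7.31e-52, 5.95e36),
            ((3.98e-28, 3.36e-35), 2.38e-123, 1.41e88),
        ],
    )
    def test_published_worked_examples(self, components, ratio_p, printed):
        value, significant = p_gain(ratio_p, components, n_tests=82)
        assert value == pytest.approx(printed, rel=0.02)
        assert significant  # all these exceed 10 x 82 = 820

    def test_equal_p_gives_unit_gain(self):
        value, significant = p_gain(1e-5, [1e-5, 0.5], n_tests=82)
        assert value == 1.0
        assert not significant

    def test_threshold_is_ten_times_n_tests(self):
        value, significant = p_gain(1e-4, [8.3e-2], n_tests=82)
        assert value == pytest.approx(830)
        assert significant  # 830 > 820
        value, significant = p_gain(1e-4, [8.1e-2], n_tests=82)
        assert not significant  # 810 < 820

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            p_gain(0.0, [0.5], 82)
        with pytest.raises(ValueError):
            p_gain(0.5, [0.0], 82)
        with pytest.raises(ValueError):
            p_gain(0.5, [0.5], 0)


class TestBH:
    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == 0.3

    def test_empty(self):
        assert bh_adjust([]).size == 0

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        adj = bh_adjust(p)
        adj_perm = bh_adjust(p[perm])
        np.testing.assert_allclose(adj[perm], adj_perm)

    def test_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(1)
        p = np.sort(rng.uniform(size=40))
        adj = bh_adjust(p)
        assert (np.diff(adj) >= -1e-15).all()
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1).all()


class TestFitLinear:
    def test_matches_statsmodels(self):
        rng = np.random.default_rng(2)
        n = 50
        design = pd.DataFrame(
            rng.standard_normal((n, 3)), columns=["WC", "age", "sex"],
            index=[f"s{i}" for i in range(n)],
        )
        targets = pd.DataFrame(
            rng.standard_normal((n, 4)), columns=list("abcd"), index=design.index
        )
        fit = fit_linear(targets, design)
        X = sm.add_constant(design.to_numpy())
        for col in targets.columns:
            ref = sm.OLS(targets[col].to_numpy(), X).fit()
            assert fit.loc[col, "beta"] == pytest.approx(ref.params[1], abs=1e-10)
            assert fit.loc[col, "se"] == pytest.approx(ref.bse[1], abs=1e-10)
            assert fit.loc[col, "p"] == pytest.approx(ref.pvalues[1], abs=1e-12)

    def test_t_equals_beta_over_se(self):
        rng = np.random.default_rng(3)
        design = pd.DataFrame({"WC": rng.standard_normal(30)},
                              index=[f"s{i}" for i in range(30)])
        targets = pd.DataFrame({"y": rng.standard_normal(30)}, index=design.index)
        fit = fit_linear(targets, design)
        assert fit.loc["y", "t"] == pytest.approx(
            fit.loc["y", "beta"] / fit.loc["y", "se"], abs=1e-10
        )

    def test_covariate_rescaling_leaves_outcome_beta(self):
        rng = np.random.default_rng(4)
        n = 200
        idx = [f"s{i}" for i in range(n)]
        design = pd.DataFrame(
            {"WC": rng.standard_normal(n), "age": rng.normal(50, 10, n)}, index=idx
        )
        targets = pd.DataFrame({"y": rng.standard_normal(n)}, index=idx)
        b1 = fit_linear(targets, design).loc["y", "beta"]
        design2 = design.copy()
        design2["age"] = design2["age"] * 12 + 7  # affine covariate change
        b2 = fit_linear(targets, design2).loc["y", "beta"]
        assert b1 == pytest.approx(b2, abs=1e-12)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(5)
        n = 5000
        idx = [f"s{i}" for i in range(n)]
        design = pd.DataFrame(
            {"WC": rng.standard_normal(n), "age": rng.normal(50, 10, n),
             "sex": rng.binomial(1, 0.5, n)}, index=idx,
        )
        targets = pd.DataFrame(
            rng.standard_normal((n, 200)),
            columns=[f"t{j}" for j in range(200)], index=idx,
        )
        p = fit_linear(targets, design)["p"].to_numpy()
        assert st.kstest(p, "uniform").pvalue > 0.01

    def test_constant_outcome_errors(self):
        design = pd.DataFrame({"WC": np.ones(20)}, index=[f"s{i}" for i in range(20)])
        targets = pd.DataFrame({"y": np.arange(20.0)}, index=design.index)
        with pytest.raises(ValueError, match="constant outcome"):
            fit_linear(targets, design)


def test_association_records_internally_consistent(small_cohort_a, small_config):
    ds, cohort = small_cohort_a
    defs = [
        RatioDefinition("PE(P)/PE", resolve_selector("PE(P)", ds.annotations),
                        resolve_selector("PE", ds.annotations), "PE(P)", "PE"),
        RatioDefinition("PC(P)/PC", resolve_selector("PC(P)", ds.annotations),
                        resolve_selector("PC", ds.annotations), "PC(P)", "PC"),
    ]
    rm = compute_ratio_matrix(ds, defs)
    records = fit_association(rm, ds, defs, cohort, "WC", n_tests=82)
    for r in records:
        assert r.t == pytest.approx(r.beta / r.se, abs=1e-10)
        assert 0 < r.p <= 1
        assert r.p_bh >= r.p - 1e-15
        # stored p-gain recomputes exactly from stored component p-values
        comp = [c["p_bh"] for c in r.component_results.values()]
        value, sig = p_gain(r.p_bh, comp, 82)
        assert value == r.p_gain
        assert sig == r.p_gain_significant
    # the simulated ether-class effect is negative against WC
    assert records[1].beta < 0


class TestSexInteraction:
    def _simulated(self, seed=31):
        config = SyntheticConfig(
            n_samples=(1500, 50), n_species=30, n_classes=6,
            effect_wc={"PC": 0.004}, effect_wc_sex={"PC": -0.008},
            genetics=None, seed=seed,
        )
        ds, cohort = simulate_cohort(config, cohort="a")
        defs = [RatioDefinition("PC/PE", resolve_selector("PC", ds.annotations),
                                resolve_selector("PE", ds.annotations), "PC", "PE")]
        rm = compute_ratio_matrix(ds, defs)
        return rm, ds, defs, cohort

    def test_stratified_betas_match_joint_model(self):
        rm, ds, defs, cohort = self._simulated()
        recs = sex_interaction(rm, ds, defs, cohort, "WC")
        r = recs[0]
        # joint fully-interacted fit implies per-sex slopes equal to the
        # stratified fits; cross-check the male slope via direct OLS
        t = cohort.table
        for sex, rec in ((0, r.female), (1, r.male)):
            sub = t.index[t["sex"] == sex]
            X = sm.add_constant(t.loc[sub, ["WC", "age"]].to_numpy())
            ref = sm.OLS(rm.values.loc[sub, "PC/PE"].to_numpy(), X).fit()
            assert rec.beta == pytest.approx(ref.params[1], abs=1e-8)

    def test_opposite_slopes_detected(self):
        rm, ds, defs, cohort = self._simulated()
        r = sex_interaction(rm, ds, defs, cohort, "WC")[0]
        assert r.interaction_p_bh < 0.05
        assert np.sign(r.female.beta) != np.sign(r.male.beta)

    def test_single_sex_cohort_rejected(self):
        rm, ds, defs, cohort = self._simulated()
        from lipidratios.io import CohortTable
        t = cohort.table.copy()
        t["sex"] = 1
        with pytest.raises(ValueError, match="both sexes"):
            sex_interaction(rm, ds, defs, CohortTable(t), "WC")

    def test_null_interaction_type1_error(self):
        # no interaction effect: rejection rate at 0.05 within 3 MC SE
        rng = np.random.default_rng(6)
        n, reps = 400, 1000
        idx = pd.Index([f"s{i}" for i in range(n)])
        sex = rng.binomial(1, 0.5, n).astype(float)
        X = pd.DataFrame(
            {"outcome": rng.standard_normal(n), "age": rng.normal(50, 10, n),
             "sex": sex}, index=idx,
        )
        X["outcome_sex"] = X["outcome"] * X["sex"]
        X["age_sex"] = X["age"] * X["sex"]
        Y = pd.DataFrame(rng.standard_normal((n, reps)), index=idx)
        p = _interaction_pvalues(Y, X)
        rate = (p < 0.05).mean()
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)


class TestConcordance:
    def _table(self, seed=0, n=82):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"beta": rng.standard_normal(n), "p_bh": rng.uniform(0, 0.04, n)},
            index=[f"r{i}" for i in range(n)],
        )

    def test_self_comparison_fully_concordant(self):
        t = self._table()
        rep = concordance(t, t)
        assert rep["n_concordant"] == 82
        assert rep["pearson_r"] == pytest.approx(1.0)

    def test_single_flipped_sign_listed(self):
        t = self._table()
        t2 = t.copy()
        t2.loc["r7", "beta"] = -t2.loc["r7", "beta"]
        rep = concordance(t, t2)
        assert rep["n_concordant"] == 81
        assert rep["discordant"] == ["r7"]

    def test_counts_match_brute_force_recount(self):
        rng = np.random.default_rng(7)
        a = self._table(1)
        b = a.copy()
        b["beta"] = b["beta"] + rng.standard_normal(len(b))
        b["p_bh"] = rng.uniform(0, 0.1, len(b))
        rep = concordance(a, b)
        manual = sum(
            (np.sign(a.loc[i, "beta"]) == np.sign(b.loc[i, "beta"]))
            and a.loc[i, "p_bh"] < 0.05 and b.loc[i, "p_bh"] < 0.05
            for i in a.index
        )
        assert rep["n_concordant"] == manual
        assert 0 < rep["pearson_r"] < 1

    def test_no_shared_labels_errors(self):
        a, b = self._table(), self._table()
        b.index = [f"x{i}" for i in range(len(b))]
        with pytest.raises(ValueError):
            concordance(a, b)


class TestMannWhitney:
    def test_exact_enumeration_small_groups(self):
        # {1,2,3} vs {4,5,6}: U = 0 and the exact two-sided p over all
        # 20 assignments is 2/20 = 0.1
        expr = pd.DataFrame({"g": [1, 2, 3, 4, 5, 6.0]},
                            index=[f"s{i}" for i in range(6)])
        groups = pd.Series([1, 1, 1, 2, 2, 2], index=expr.index)
        res = group_difference(expr, groups)
        assert res.loc["g", "U"] == 0
        assert res.loc["g", "p"] == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        expr = pd.DataFrame({"g": [1.0, 2.0, 1.0, 2.0]},
                            index=[f"s{i}" for i in range(4)])
        groups = pd.Series([1, 1, 2, 2], index=expr.index)
        assert group_difference(expr, groups).loc["g", "p"] == 1.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(40)
        expr1 = pd.DataFrame({"g": x}, index=[f"s{i}" for i in range(40)])
        expr2 = pd.DataFrame({"g": np.exp(x)}, index=expr1.index)
        groups = pd.Series([1] * 20 + [2] * 20, index=expr1.index)
        p1 = group_difference(expr1, groups).loc["g", "p"]
        p2 = group_difference(expr2, groups).loc["g", "p"]
        assert p1 == pytest.approx(p2)
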