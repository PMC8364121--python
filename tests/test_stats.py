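"""Z-scoring, adjusted OLS, multiplicity correction, mediation, group tests."""

import numpy as np
import pandas as pd
import pytest

from gmnet.stats import (
    LinearMediation,
    adjust_pvalues,
    compare_groups,
    fit_linear_association,
    mediation_analysis,
    run_association_suite,
    zscore_to_reference,
)
from gmnet.synthetic import simulate_association_table, simulate_mediation_table


class TestZscore:
    def test_reference_group_standardised_to_mean_zero_sd_one(self, rng):
        x = rng.normal(5, 2, 100)
        mask = np.zeros(100, bool)
        mask[:40] = True
        z = zscore_to_reference(x, mask)
        assert np.mean(z[mask]) == pytest.approx(0.0, abs=1e-12)
        assert np.std(z[mask], ddof=1) == pytest.approx(1.0)

    def test_reference_mean_maps_to_zero_and_one_sd_to_one(self):
        x = np.array([1.0, 3.0, 2.0, 99.0])
        mask = np.array([True, True, True, False])
        z = zscore_to_reference(x, mask)
        sd = np.std([1, 3, 2], ddof=1)
        assert zscore_to_reference(np.array([2.0, 1, 3, 2]), np.array([False, True, True, True]))[0] == pytest.approx(0.0)
        assert z[3] == pytest.approx((99 - 2) / sd)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError):
            zscore_to_reference(np.array([1.0, 1.0, 5.0]), np.array([True, True, False]))
        with pytest.raises(ValueError):
            zscore_to_reference(np.array([1.0, 2.0]), np.array([True, False]))


class TestLinearAssociation:
    def test_outcome_identical_to_predictor_gives_unit_slope(self, rng):
        x = rng.normal(size=40)
        table = pd.DataFrame({"y": x, "x": x})
        res = fit_linear_association(table, "y", "x")
        assert res.beta == pytest.approx(1.0, abs=1e-10)
        assert res.se == pytest.approx(0.0, abs=1e-8)

    def test_orthogonal_predictor_gives_near_zero_slope(self, rng):
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        y -= np.polyfit(x, y, 1)[0] * x  # exact orthogonalisation
        res = fit_linear_association(pd.DataFrame({"y": y, "x": x}), "y", "x")
        assert res.beta == pytest.approx(0.0, abs=1e-10)
        assert abs(res.t) < 1e-8

    def test_beta_and_se_match_normal_equations_oracle(self, rng):
        n = 120
        table = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "age": rng.normal(70, 8, n),
                "sex": rng.integers(0, 2, n),
            }
        )
        table["y"] = -0.4 * table["x"] + 0.02 * table["age"] + rng.normal(size=n)
        res = fit_linear_association(table, "y", "x", covariates=("age", "sex"))
        X = np.column_stack(
            [np.ones(n), table["x"], table["age"], table["sex"]]
        )
        y = table["y"].to_numpy()
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ X.T @ y
        resid = y - X @ beta
        sigma2 = resid @ resid / (n - 4)
        se = np.sqrt(sigma2 * np.diag(xtx_inv))
        assert res.beta == pytest.approx(beta[1], abs=1e-8)
        assert res.se == pytest.approx(se[1], abs=1e-8)
        assert res.t == pytest.approx(beta[1] / se[1], abs=1e-8)
        assert res.n == n

    def test_interaction_term_is_reported(self, rng):
        n = 300
        x = rng.normal(size=n)
        g = rng.integers(0, 2, n).astype(float)
        y = x * g * 0.8 + rng.normal(size=n)
        table = pd.DataFrame({"y": y, "x": x, "g": g})
        res = fit_linear_association(table, "y", "x", interaction_with="g")
        assert res.predictor == "x:g"
        assert res.beta == pytest.approx(0.8, abs=0.2)
        assert res.p < 1e-6

    def test_rank_deficient_design_names_collinear_columns(self, rng):
        x = rng.normal(size=50)
        table = pd.DataFrame({"y": rng.normal(size=50), "x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="x2|x"):
            fit_linear_association(table, "y", "x", covariates=("x2",))

    def test_too_few_residual_dof_rejected(self, rng):
        table = pd.DataFrame({"y": rng.normal(size=8), "x": rng.normal(size=8)})
        with pytest.raises(ValueError, match="degrees of freedom"):
            fit_linear_association(table, "y", "x")


class TestAdjustPvalues:
    def test_single_p_unchanged_under_both_methods(self):
        for method in ("fdr_bh", "bonferroni"):
            assert adjust_pvalues([0.031], method)[0] == pytest.approx(0.031)

    def test_bonferroni_arithmetic(self):
        out = adjust_pvalues([0.01, 0.2, 0.5, 0.04, 0.3], "bonferroni")
        assert out[0] == pytest.approx(0.05)
        assert out[3] == pytest.approx(0.2)
        assert np.all(out >= [0.01, 0.2, 0.5, 0.04, 0.3])
        assert np.all(out <= 1.0)

    def test_bh_matches_step_up_oracle(self):
        pvals = [0.001, 0.01, 0.02, 0.8]
        m = len(pvals)
        order = np.argsort(pvals)
        ranked = np.array(pvals)[order]
        raw = ranked * m / (np.arange(m) + 1)
        stepped = np.minimum.accumulate(raw[::-1])[::-1]  # enforce monotonicity
        expected = np.empty(m)
        expected[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(adjust_pvalues(pvals, "fdr_bh"), expected, atol=1e-12)

    def test_bh_preserves_raw_ordering(self, rng):
        p = rng.random(25)
        adj = adjust_pvalues(p, "fdr_bh")
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-15)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2])
        with pytest.raises(ValueError):
            adjust_pvalues([0.5], method="sidak")


class TestAssociationSuite:
    def test_single_outcome_reduces_to_plain_fit(self):
        table = simulate_association_table(100, seed=1)
        suite = run_association_suite(
            table, ["sigma"], "tau", {"sigma": ["age", "sex", "tiv"]},
            zscore_outcomes=False,
        )
        assert len(suite) == 1
        direct = fit_linear_association(
            table, "sigma", "tau", covariates=("age", "sex", "tiv")
        )
        assert suite[0].beta == pytest.approx(direct.beta)
        assert suite[0].p_adjusted == pytest.approx(suite[0].p)

    def test_injected_negative_tau_effect_is_recovered_significant(self):
        effects = {m: -0.5 for m in ("clustering", "path_length", "gamma", "lambda_", "sigma")}
        table = simulate_association_table(200, effects=effects, seed=2)
        suite = run_association_suite(
            table,
            ["size", "degree", "density", "clustering", "path_length", "gamma", "lambda_", "sigma"],
            "tau",
            lambda o: ["age", "sex", "tiv"],
        )
        by_outcome = {r.outcome: r for r in suite}
        for m in effects:
            assert by_outcome[m].beta < 0
            assert by_outcome[m].p_adjusted < 0.05

    def test_stratified_tiers_adjust_within_group(self):
        table = simulate_association_table(240, seed=3)
        table["group"] = np.repeat(["a", "b", "c"], 80)
        suite = run_association_suite(
            table, ["sigma", "gamma"], "tau", lambda o: ["age"], group_col="group"
        )
        groups = {r.group for r in suite}
        assert groups == {None, "a", "b", "c"}
        assert len(suite) == 2 * 4


class TestMediation:
    def test_mediator_independent_of_treatment_gives_zero_acme(self):
        table = simulate_mediation_table(600, a=0.0, b=1.0, c_prime=1.0, seed=4)
        res = mediation_analysis(table, "treatment", "mediator", "outcome", seed=0)
        assert res.acme == pytest.approx(0.0, abs=0.1)
        assert abs(res.prop_mediated) < 0.1

    def test_zero_direct_effect_gives_full_mediation(self):
        table = simulate_mediation_table(600, a=1.0, b=1.0, c_prime=0.0, seed=5)
        res = mediation_analysis(table, "treatment", "mediator", "outcome", seed=0)
        assert res.prop_mediated == pytest.approx(1.0, abs=0.1)

    def test_recovers_analytic_proportion_mediated(self):
        a0, b0, cp0 = 1.0, 1.0, 1.0
        table = simulate_mediation_table(
            500, a=a0, b=b0, c_prime=cp0, seed=6, mediator_sd=0.5, outcome_sd=0.25
        )
        res = mediation_analysis(
            table, "treatment", "mediator", "outcome", n_boot=1000, seed=7
        )
        truth = a0 * b0 / (a0 * b0 + cp0)
        assert res.prop_mediated == pytest.approx(truth, abs=0.05)
        assert res.ci["prop_mediated"][0] < truth < res.ci["prop_mediated"][1]

    def test_total_effect_decomposes_exactly_in_every_bootstrap_replicate(self):
        table = simulate_mediation_table(200, a=0.5, b=0.8, c_prime=0.3, seed=8)
        res = mediation_analysis(table, "treatment", "mediator", "outcome", seed=9)
        boot = res.bootstrap_samples
        gap = boot["c"] - boot["c_prime"] - boot["acme"]
        assert np.max(np.abs(gap)) < 1e-10
        assert res.c - res.c_prime == pytest.approx(res.acme, abs=1e-10)

    def test_bootstrap_determinism(self):
        table = simulate_mediation_table(150, a=0.5, b=0.5, c_prime=0.5, seed=10)
        r1 = mediation_analysis(table, "treatment", "mediator", "outcome", seed=11)
        r2 = mediation_analysis(table, "treatment", "mediator", "outcome", seed=11)
        assert r1.prop_mediated == r2.prop_mediated
        assert r1.ci == r2.ci

    def test_estimator_wrapper_exposes_fitted_paths(self):
        table = simulate_mediation_table(200, a=0.7, b=0.7, c_prime=0.2, seed=12)
        est = LinearMediation(
            treatment="treatment", mediator="mediator", outcome="outcome", random_state=3
        ).fit(table)
        assert est.acme_ == pytest.approx(est.a_ * est.b_)
        assert est.get_params()["n_boot"] == 1000

    def test_small_bootstrap_count_rejected(self):
        table = simulate_mediation_table(100, a=1, b=1, c_prime=0, seed=13)
        with pytest.raises(ValueError):
            mediation_analysis(table, "treatment", "mediator", "outcome", n_boot=100)


class TestGroupComparison:
    def test_homogeneous_contingency_table_gives_zero_chi2(self):
        table = pd.DataFrame(
            {"g": ["a"] * 20 + ["b"] * 20, "v": (["x"] * 10 + ["y"] * 10) * 2}
        )
        res = compare_groups(table, "v", "g")
        assert res.test == "chi-squared"
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_identical_group_samples_give_zero_f(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        table = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4, "v": vals * 2})
        res = compare_groups(table, "v", "g")
        assert res.test == "anova"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_f_statistic_matches_sums_of_squares_oracle(self, rng):
        groups = ["a"] * 30 + ["b"] * 30 + ["c"] * 30
        vals = np.concatenate(
            [rng.normal(0, 1, 30), rng.normal(0.5, 1, 30), rng.normal(1.0, 1, 30)]
        )
        table = pd.DataFrame({"g": groups, "v": vals})
        res = compare_groups(table, "v", "g")
        grand = vals.mean()
        ss_between = sum(
            30 * (vals[i * 30 : (i + 1) * 30].mean() - grand) ** 2 for i in range(3)
        )
        ss_within = sum(
            ((vals[i * 30 : (i + 1) * 30] - vals[i * 30 : (i + 1) * 30].mean()) ** 2).sum()
            for i in range(3)
        )
        f = (ss_between / 2) / (ss_within / (90 - 3))
        assert res.statistic == pytest.approx(f, abs=1e-8)

    def test_undersized_group_rejected(self):
        table = pd.DataFrame({"g": ["a", "a", "b"], "v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            compare_groups(table, "v", "g")


def test_null_cohort_type_one_error_controlled():
    """FDR-significant fraction on null cohorts stays near the nominal level."""
    outcomes = ["size", "degree", "density", "clustering", "path_length", "gamma", "lambda_", "sigma"]
    hits = total = 0
    for rep in range(200):
        table = simulate_association_table(150, seed=10_000 + rep)
        suite = run_association_suite(
            table, outcomes, "tau", lambda o: ["age", "sex", "tiv"]
        )
        hits += sum(r.p_adjusted < 0.05 for r in suite)
        total += len(suite)
    assert hits / total <= 0.05 + 0.03
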