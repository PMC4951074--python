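"""Arm comparisons, Fisher exact, screening, stepwise selection, pseudo-R2."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from carat.analysis import (
    DegenerateTestError,
    InvalidFitError,
    TestKind as StatTest,
    compare_arms,
    compare_means_from_summary,
    fisher_exact_p,
    forward_stepwise_wald,
    pseudo_r2_from_ll,
    univariate_screen,
)
from carat.records import StrokeRiskFactors

from conftest import make_patient


def _arm_cohort(per_arm_flags):
    """Cohort where stroke.diabetes encodes an arbitrary binary variable."""
    cohort = []
    i = 0
    for arm, flags in per_arm_flags.items():
        for flag in flags:
            i += 1
            cohort.append(
                make_patient(
                    patient_id=f"p{i:05d}",
                    gp_id=f"{arm[0]}gp{i % 5}",
                    arm=arm,
                    stroke=StrokeRiskFactors(diabetes=bool(flag)),
                )
            )
    return cohort


class TestCompareArms:
    def test_identical_arms_give_p_one(self):
        cohort = _arm_cohort(
            {"intervention": [1] * 10 + [0] * 10, "control": [1] * 10 + [0] * 10}
        )
        c = compare_arms(cohort, "stroke.diabetes")
        assert c.test is StatTest.chi_square
        assert c.p_value == pytest.approx(1.0)

    def test_sparse_table_switches_to_fisher(self):
        cohort = _arm_cohort({"intervention": [1] * 2 + [0] * 30, "control": [0] * 30})
        c = compare_arms(cohort, "stroke.diabetes")
        assert c.test is StatTest.fisher_exact
        assert "expected cell" in c.note

    def test_continuous_variable_uses_welch(self):
        cohort = [
            make_patient(patient_id=f"p{i:05d}", arm=arm, chronic_condition_count=k)
            for i, (arm, k) in enumerate(
                [("intervention", k) for k in (4, 5, 6, 7, 8)]
                + [("control", k) for k in (3, 4, 5, 5, 6)]
            )
        ]
        c = compare_arms(cohort, "chronic_condition_count")
        t, p = stats.ttest_ind([4, 5, 6, 7, 8], [3, 4, 5, 5, 6], equal_var=False)
        assert c.test is StatTest.t_or_anova
        assert (abs(c.statistic), c.p_value) == pytest.approx((abs(t), p), abs=1e-12)

    def test_ordinal_variable_uses_rank_test(self):
        cohort = [
            make_patient(patient_id=f"p{i:05d}", arm=arm, afib_duration=d)
            for i, (arm, d) in enumerate(
                [("intervention", d) for d in ("lt_3mo", "lt_12mo", "lt_2y", "ge_5y")]
                + [("control", d) for d in ("lt_2y", "lt_5y", "ge_5y", "ge_5y")]
            )
        ]
        assert compare_arms(cohort, "afib_duration").test is StatTest.mann_whitney

    def test_constant_variable_is_degenerate(self):
        cohort = _arm_cohort({"intervention": [0] * 5, "control": [0] * 5})
        with pytest.raises(DegenerateTestError):
            compare_arms(cohort, "stroke.diabetes")

    def test_summary_stat_t_matches_printed_chronic_condition_contrast(self):
        t, p = compare_means_from_summary(6.1, 2.7, 206, 5.4, 2.3, 187)
        assert round(t, 2) == 2.77
        assert p < 0.01


class TestFisherExact:
    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            t = rng.integers(0, 25, size=(2, 2))
            assert fisher_exact_p(t) == pytest.approx(
                stats.fisher_exact(t)[1], abs=1e-10
            )

    def test_degenerate_margins_give_p_one(self):
        assert fisher_exact_p([[0, 0], [3, 4]]) == 1.0
        assert fisher_exact_p([[2, 0], [3, 0]]) == 1.0

    def test_one_sided_extreme_table(self):
        # all successes in one row: p = C(206,9)/C(393,9)-style hypergeometric tail
        p = fisher_exact_p([[9, 197], [0, 187]])
        assert p == pytest.approx(stats.fisher_exact([[9, 197], [0, 187]])[1], abs=1e-12)
        assert p < 0.005

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_p([[1, -1], [2, 3]])


def _logistic_data(n, beta, seed, k_noise=0):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n).astype(float)
    y = (rng.random(n) < expit(beta * x - beta / 2)).astype(float)
    X = pd.DataFrame({"signal": x})
    for j in range(k_noise):
        X[f"noise{j}"] = rng.integers(0, 2, n).astype(float)
    return y, X


class TestUnivariateScreen:
    def test_strong_predictor_selected(self):
        y, X = _logistic_data(1000, math.log(3.0), seed=2)
        res = univariate_screen(y, X)
        assert "signal" in res.selected

    def test_null_covariate_usually_excluded(self):
        excluded = 0
        for s in range(40):
            rng = np.random.default_rng(100 + s)
            y = rng.integers(0, 2, 400).astype(float)
            X = pd.DataFrame({"noise": rng.integers(0, 2, 400).astype(float)})
            if "noise" not in univariate_screen(y, X, alpha=0.10).selected:
                excluded += 1
        assert excluded >= 30  # exclusion rate ~0.9 at alpha 0.10

    def test_constant_covariate_excluded_with_warning(self):
        y, X = _logistic_data(200, 1.0, seed=3)
        X["flat"] = 1.0
        res = univariate_screen(y, X)
        assert "flat" in res.excluded_constant
        assert "flat" not in res.selected

    def test_separated_covariate_flagged_and_retained(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 2, 100).astype(float)
        res = univariate_screen(x, pd.DataFrame({"mirror": x}))
        assert "mirror" in res.separation_flagged
        assert "mirror" in res.selected

    def test_constant_outcome_rejected(self):
        with pytest.raises(DegenerateTestError):
            univariate_screen(np.ones(50), pd.DataFrame({"x": np.arange(50.0)}))


class TestForwardStepwise:
    def test_recovers_single_true_predictor_among_noise(self):
        y, X = _logistic_data(2000, math.log(3.0), seed=5, k_noise=10)
        model = forward_stepwise_wald(y, X)
        names = [t.name for t in model.terms]
        assert "signal" in names
        assert 2.0 <= model.term("signal").odds_ratio <= 4.5

    def test_null_candidates_give_near_empty_model(self):
        sizes = []
        for s in range(30):
            rng = np.random.default_rng(200 + s)
            y = rng.integers(0, 2, 300).astype(float)
            X = pd.DataFrame(
                {f"n{j}": rng.integers(0, 2, 300).astype(float) for j in range(8)}
            )
            sizes.append(len(forward_stepwise_wald(y, X).terms))
        assert np.mean(sizes) <= 1.0
        assert np.mean([s <= 1 for s in sizes]) >= 0.7

    def test_candidate_order_invariance(self):
        y, X = _logistic_data(800, math.log(2.5), seed=6, k_noise=5)
        a = forward_stepwise_wald(y, X)
        b = forward_stepwise_wald(y, X[list(X.columns)[::-1]])
        assert [t.name for t in a.terms] == [t.name for t in b.terms]

    def test_separated_candidate_skipped(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 200).astype(float)
        X = pd.DataFrame({"mirror": y.copy(), "noise": rng.integers(0, 2, 200).astype(float)})
        model = forward_stepwise_wald(y, X)
        assert "mirror" in model.skipped

    def test_cluster_robust_final_inference(self):
        y, X = _logistic_data(600, math.log(3.0), seed=8)
        groups = np.repeat(np.arange(30), 20)
        model = forward_stepwise_wald(y, X, groups=groups)
        assert model.cluster_adjusted
        t = model.term("signal")
        assert t.ci_low <= t.odds_ratio <= t.ci_high
        assert np.isfinite([t.ci_low, t.ci_high]).all()

    def test_ci_brackets_or_for_every_term(self):
        y, X = _logistic_data(1000, math.log(2.0), seed=9, k_noise=3)
        model = forward_stepwise_wald(y, X)
        for t in model.terms:
            assert t.ci_low <= t.odds_ratio <= t.ci_high


def test_cluster_robust_ci_coverage_near_nominal():
    """95% CI coverage for a known cluster-level odds ratio stays within
    3 percentage points of nominal over 500 simulated trials."""
    from carat.studies import or_recovery_study

    res = or_recovery_study(n_trials=500, true_or=3.0, icc=0.03, seed=42)
    assert res.n_selected >= 480
    assert abs(res.ci_coverage - 0.95) <= 0.03
    # unbiasedness of the recovered OR within Monte-Carlo error
    assert abs(res.mean_or - 3.0) <= 0.25


class TestPseudoR2:
    def test_null_model_is_zero(self):
        assert pseudo_r2_from_ll(-10.0, -10.0, 20) == (0.0, 0.0)

    def test_closed_form_toy_case(self):
        cs, nk = pseudo_r2_from_ll(-10.0, -5.0, 20)
        assert cs == pytest.approx(1 - math.exp(-0.5))
        assert nk == pytest.approx(cs / (1 - math.exp(-1.0)))

    def test_nagelkerke_never_below_cox_snell(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            n = int(rng.integers(10, 500))
            ll0 = -rng.uniform(1, n)
            ll1 = ll0 + rng.uniform(0, -ll0)  # ll0 <= ll1 <= 0
            cs, nk = pseudo_r2_from_ll(ll0, ll1, n)
            assert 0.0 <= cs <= 1.0
            assert nk >= cs - 1e-12

    def test_invalid_fit_signalled(self):
        with pytest.raises(InvalidFitError):
            pseudo_r2_from_ll(-5.0, -10.0, 20)

    def test_fitted_logit_values_consistent(self):
        import statsmodels.api as sm
        from carat.analysis import pseudo_r2

        y, X = _logistic_data(500, 1.0, seed=11)
        fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        cs, nk = pseudo_r2(fit)
        assert cs == pytest.approx(1 - math.exp(2 * (fit.llnull - fit.llf) / fit.nobs))
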