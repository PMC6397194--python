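import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from repairimmune.stats_core import (
    anova_tukey,
    cox_breslow_loglik,
    km_logrank_hr,
    multinomial_logit,
    pearson,
    storey_q,
    t_test,
    two_proportion_z,
)


class TestTwoProportionZ:
    def test_equal_proportions_give_zero(self):
        res = two_proportion_z(10, 40, 5, 20)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # pooled p = 45/100 = 0.45; z = 0.3 / sqrt(0.2475 * 0.04)
        res = two_proportion_z(30, 50, 15, 50)
        assert res.statistic == pytest.approx(3.015, abs=1e-3)
        assert res.p == pytest.approx(0.00257, abs=5e-5)

    def test_swapping_arms_negates_z(self):
        a = two_proportion_z(30, 50, 15, 50)
        b = two_proportion_z(15, 50, 30, 50)
        assert b.statistic == pytest.approx(-a.statistic)
        assert b.p == pytest.approx(a.p)

    def test_degenerate_pooled_proportion_reported_missing(self):
        res = two_proportion_z(0, 10, 0, 10)
        assert np.isnan(res.statistic) and np.isnan(res.p)

    def test_empty_arm_is_an_error(self):
        with pytest.raises(ValueError):
            two_proportion_z(0, 0, 1, 10)


class TestTTest:
    def test_identical_arms(self):
        res = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == pytest.approx(1.0)

    def test_textbook_value(self):
        res = t_test([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(-3.674, abs=1e-3)
        assert res.p == pytest.approx(0.0213, abs=1e-3)
        assert res.df == 4

    def test_welch_equals_student_for_balanced_equal_variance(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        assert t_test(a, b, welch=True).statistic == pytest.approx(t_test(a, b).statistic)

    def test_ci_brackets_estimate(self):
        res = t_test([1, 2, 3, 4], [2, 4, 6, 9])
        assert res.ci[0] < res.estimate < res.ci[1]

    def test_short_arm_is_an_error(self):
        with pytest.raises(ValueError):
            t_test([1.0], [1.0, 2.0])


class TestAnovaTukey:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        res = anova_tukey({"a": g, "b": g, "c": g})
        assert res.f == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_two_groups_tukey_equals_anova(self):
        rng = np.random.default_rng(0)
        res = anova_tukey({"a": rng.normal(0, 1, 10), "b": rng.normal(0.5, 1, 12)})
        assert res.pairwise["p_adj"].iloc[0] == pytest.approx(res.p, rel=1e-6)

    def test_matches_permutation_reference(self):
        rng = np.random.default_rng(3)
        groups = {"a": rng.normal(0, 1, 8), "b": rng.normal(0.6, 1, 8), "c": rng.normal(0.2, 1, 8)}
        res = anova_tukey(groups)
        data = np.concatenate(list(groups.values()))
        labels = np.repeat([0, 1, 2], 8)
        perm_rng = np.random.default_rng(4)
        B = 5000
        count = 0
        for _ in range(B):
            perm = perm_rng.permutation(labels)
            f, _ = sps.f_oneway(*(data[perm == k] for k in range(3)))
            count += f >= res.f
        assert count / B == pytest.approx(res.p, abs=0.02)

    def test_fewer_than_two_groups_is_an_error(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [1.0, 2.0]})


class TestPearson:
    def test_perfect_correlation(self):
        a = [1.0, 2.0, 3.0, 4.0]
        assert pearson(a, a).statistic == pytest.approx(1.0)
        assert pearson(a, [-x for x in a]).statistic == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        r = np.cov(a, b, ddof=1)[0, 1] / (np.std(a, ddof=1) * np.std(b, ddof=1))
        assert pearson(a, b).statistic == pytest.approx(r)

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestStoreyQ:
    def test_hand_example_reduces_to_bh(self):
        q = storey_q([0.2, 0.4, 0.6, 0.8])
        np.testing.assert_allclose(q, [0.8, 0.8, 0.8, 0.8])

    def test_equals_bh_whenever_pi0_is_one(self):
        from statsmodels.stats.multitest import fdrcorrection

        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.uniform(0.3, 1.0, 40)  # >half above lambda => pi0 clamps at 1
            m = p.size
            pi0 = min(1.0, np.sum(p > 0.5) / (0.5 * m))
            if pi0 < 1.0:
                continue
            _, bh = fdrcorrection(p, alpha=0.05, method="indep")
            np.testing.assert_allclose(storey_q(p), bh, rtol=1e-12)

    def test_all_ones(self):
        np.testing.assert_allclose(storey_q([1.0, 1.0, 1.0]), 1.0)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_p_and_bounded(self, pvals):
        q = storey_q(pvals)
        assert (q <= 1.0 + 1e-12).all()
        order = np.argsort(pvals)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            storey_q([0.5, 1.5])


class TestMultinomialLogit:
    def test_two_levels_reduce_to_binary_logit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 300
        x = rng.normal(0, 1, n)
        logit = -0.3 + 1.2 * x
        y = np.where(rng.random(n) < 1 / (1 + np.exp(-logit)), "case", "ctl")
        X = pd.DataFrame({"x": x})
        fit = multinomial_logit(X, y, baseline="ctl")
        ref = sm.Logit((y == "case").astype(int), sm.add_constant(X)).fit(disp=False)
        assert fit.levels == ("case",)
        assert fit.coef.loc["case", "x"] == pytest.approx(ref.params["x"], abs=1e-5)
        assert fit.se.loc["case", "x"] == pytest.approx(ref.bse["x"], abs=1e-5)

    def test_recovers_planted_coefficients(self):
        rng = np.random.default_rng(6)
        hits = 0
        for rep in range(10):
            n = 2000
            x = rng.normal(0, 1, n)
            # 3 outcomes, baseline has linear predictor 0; beta=1 for level B
            eta_b, eta_c = 1.0 * x, -0.5 * x
            denom = 1 + np.exp(eta_b) + np.exp(eta_c)
            u = rng.random(n)
            pb, pc = np.exp(eta_b) / denom, np.exp(eta_c) / denom
            y = np.where(u < pb, "B", np.where(u < pb + pc, "C", "A"))
            fit = multinomial_logit(pd.DataFrame({"x": x}), y, baseline="A")
            hits += abs(fit.coef.loc["B", "x"] - 1.0) < 0.15
        assert hits >= 9

    def test_baseline_must_be_present(self):
        with pytest.raises(ValueError, match="baseline"):
            multinomial_logit(pd.DataFrame({"x": [1.0, 2.0]}), ["a", "b"], baseline="zz")

    def test_collinear_predictors_detected(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [2.0, 4.0, 6.0, 8.0]})
        with pytest.raises(ValueError, match="collinear"):
            multinomial_logit(X, ["a", "b", "a", "b"], baseline="a")


class TestSurvival:
    def test_identical_arms(self):
        t = np.array([5.0, 8.0, 12.0, 20.0] * 2)
        e = np.array([True, True, False, True] * 2)
        g = ["A"] * 4 + ["B"] * 4
        res = km_logrank_hr(t, e, g)
        assert res.logrank_chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.logrank_p == pytest.approx(1.0)
        assert res.hr == pytest.approx(1.0)

    def test_toy_beta_matches_grid_maximization(self):
        t = np.array([5.0, 8.0, 12.0, 20.0, 25.0, 30.0])
        e = np.array([True, True, False, True, True, False])
        x = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        res = km_logrank_hr(t, e, np.where(x == 0, "A", "B"))
        grid = np.linspace(-3, 3, 60001)
        ll = np.array([cox_breslow_loglik(t, e, x, b) for b in grid])
        assert res.cox_beta == pytest.approx(grid[ll.argmax()], abs=1e-4)

    def test_matches_lifelines_on_untied_data(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(8)
        n = 60
        x = np.repeat([0.0, 1.0], n // 2)
        t = rng.exponential(100 * np.exp(-0.5 * x))
        e = np.ones(n, dtype=bool)
        res = km_logrank_hr(t, e, np.where(x == 0, "A", "B"))
        cf = CoxPHFitter().fit(pd.DataFrame({"t": t, "e": e.astype(int), "x": x}), "t", "e")
        assert res.cox_beta == pytest.approx(float(cf.params_.iloc[0]), abs=1e-6)
        assert res.cox_se == pytest.approx(float(cf.standard_errors_.iloc[0]), abs=1e-6)

    def test_breslow_beta_maximizes_partial_likelihood_with_ties(self):
        t = np.array([5.0, 5.0, 8.0, 8.0, 12.0, 20.0, 20.0, 25.0])
        e = np.array([1, 1, 1, 0, 1, 1, 1, 0], dtype=bool)
        x = np.array([0.0, 1.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        res = km_logrank_hr(t, e, np.where(x == 0, "A", "B"))
        grid = np.linspace(-3, 3, 60001)
        ll = np.array([cox_breslow_loglik(t, e, x, b) for b in grid])
        assert res.cox_beta == pytest.approx(grid[ll.argmax()], abs=1e-4)

    def test_no_events_in_one_arm_reports_missing_hr(self):
        t = np.array([5.0, 8.0, 12.0, 20.0])
        e = np.array([True, True, False, False])
        g = ["A", "A", "B", "B"]
        res = km_logrank_hr(t, e, g)
        assert res.hr is None
        assert np.isfinite(res.logrank_p)

    def test_km_curves_start_at_one(self):
        t = np.array([5.0, 8.0, 12.0, 20.0])
        e = np.array([True, True, True, True])
        res = km_logrank_hr(t, e, ["A", "A", "B", "B"])
        for curve in res.km_curves.values():
            assert curve.iloc[0, 0] == pytest.approx(1.0)
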