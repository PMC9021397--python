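"""Kaplan-Meier, log-rank and Cox implementations against oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nmrfp import survival as sv


def _sim_two_group(n, beta, rng, base_rate=0.2, censor=8.0):
    g = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0 / (base_rate * np.exp(beta * g)))
    e = (t <= censor).astype(int)
    return np.minimum(t, censor), e, g


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # (1, death), (2, censored), (3, death): S = 2/3 on [1,3), 0 at 3
        km = sv.km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        np.testing.assert_allclose(km.event_times, [1.0, 3.0])
        np.testing.assert_allclose(km.survival, [2 / 3, 0.0])
        assert km.survival_at([0.5, 1.5, 3.5]) == pytest.approx(
            [1.0, 2 / 3, 0.0])

    def test_all_censored_is_flat_one(self):
        km = sv.km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.survival_at([0.0, 5.0]) == pytest.approx([1.0, 1.0])

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(3.0, 80)
        km = sv.km_estimate(t, np.ones(80, dtype=int))
        for tt in km.event_times:
            assert km.survival_at(tt)[0] == pytest.approx(np.mean(t > tt))

    def test_matches_lifelines_oracle(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(1)
        t, e, _ = _sim_two_group(200, 0.0, rng)
        km = sv.km_estimate(t, e)
        kf = lifelines.KaplanMeierFitter().fit(t, e)
        theirs = kf.survival_function_at_times(km.event_times).to_numpy()
        np.testing.assert_allclose(km.survival_at(km.event_times), theirs,
                                   atol=1e-10)

    def test_risk_strip_counts(self):
        km = sv.km_estimate([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 0])
        np.testing.assert_array_equal(km.number_at_risk([0.0, 2.5]), [4, 2])
        np.testing.assert_array_equal(km.cumulative_events([2.5, 5.0]), [1, 2])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sv.km_estimate([], [])


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 0, 1, 1, 0, 1])
        g = np.array([0, 0, 0, 1, 1, 1])
        res = sv.logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_hypergeometric_single_death(self):
        # one death at t=1 in group 0; both groups fully at risk (n=2 each)
        t = np.array([1.0, 5.0, 5.0, 5.0])
        e = np.array([1, 0, 0, 0])
        g = np.array([0, 0, 1, 1])
        res = sv.logrank_test(t, e, g)
        assert res.observed[0] - res.expected[0] == pytest.approx(0.5)
        assert res.statistic == pytest.approx(1.0)

    def test_matches_lifelines_two_group(self):
        lls = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(2)
        t, e, g = _sim_two_group(300, 0.8, rng)
        res = sv.logrank_test(t, e, g)
        oracle = lls.logrank_test(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert res.statistic == pytest.approx(oracle.test_statistic, abs=1e-8)

    def test_matches_lifelines_three_group(self):
        lls = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(3)
        t = rng.exponential(4.0, 150)
        g = rng.integers(0, 3, 150)
        t = t / np.exp(0.4 * g)
        e = (t <= 6.0).astype(int)
        t = np.minimum(t, 6.0)
        res = sv.logrank_test(t, e, g)
        oracle = lls.multivariate_logrank_test(t, g, e)
        assert res.df == 2
        assert res.statistic == pytest.approx(oracle.test_statistic, abs=1e-8)

    def test_equals_cox_score_test_without_ties(self):
        rng = np.random.default_rng(4)
        t, e, g = _sim_two_group(150, 0.6, rng)
        assert np.unique(t[e == 1]).size == e.sum()  # tie-free
        res = sv.logrank_test(t, e, g)
        _, grad, hess = sv._cox_loglik_grad_hess(
            np.zeros(1), g[:, None], t, e, "breslow")
        score_stat = grad[0] ** 2 / (-hess[0, 0])
        assert res.statistic == pytest.approx(score_stat, abs=1e-8)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            sv.logrank_test([1.0, 2.0], [1, 1], [0, 0])


class TestCox:
    def test_null_covariate_small_coefficient(self):
        rng = np.random.default_rng(5)
        t, e, _ = _sim_two_group(1000, 0.0, rng)
        x = rng.normal(size=1000)
        res = sv.cox_fit(pd.DataFrame({"x": x}), t, e)
        assert abs(res.coefficients["x"]) < 0.1

    def test_matches_lifelines_multivariate(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(6)
        n = 300
        X = pd.DataFrame({"a": rng.normal(size=n),
                          "b": rng.integers(0, 2, n).astype(float)})
        t = rng.exponential(1.0 / (0.2 * np.exp(0.5 * X["a"] - 0.7 * X["b"])))
        e = (t <= 8).astype(int)
        t = np.minimum(t, 8.0)
        res = sv.cox_fit(X, t, e)
        df = X.assign(T=t, E=e)
        cf = lifelines.CoxPHFitter().fit(df, "T", "E")
        # the oracle's own convergence tolerance bounds the agreement
        np.testing.assert_allclose(res.coefficients.to_numpy(),
                                   cf.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(res.se.to_numpy(),
                                   cf.standard_errors_.to_numpy(), atol=1e-5)
        assert res.loglik == pytest.approx(cf.log_likelihood_, abs=1e-6)

    def test_efron_ties_match_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(7)
        n = 120
        x = rng.normal(size=n)
        t = np.ceil(rng.exponential(1.0 / (0.3 * np.exp(0.5 * x))))  # ties
        e = (t <= 6).astype(int)
        t = np.minimum(t, 6.0)
        res = sv.cox_fit(pd.DataFrame({"x": x}), t, e, tie_method="efron")
        cf = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"x": x, "T": t, "E": e}), "T", "E")
        assert res.coefficients["x"] == pytest.approx(cf.params_["x"],
                                                      abs=1e-5)

    def test_six_patient_toy_brute_force_maximum(self):
        # golden-section maximization of the written-out partial likelihood
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 0, 1, 0, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])

        def pll(beta):
            ll = 0.0
            for i in range(6):
                if e[i]:
                    risk = t >= t[i]
                    ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return ll

        from scipy.optimize import minimize_scalar
        opt = minimize_scalar(lambda b: -pll(b), bounds=(-5, 5),
                              method="bounded",
                              options={"xatol": 1e-10})
        res = sv.cox_fit(pd.DataFrame({"x": x}), t, e)
        assert res.coefficients["x"] == pytest.approx(opt.x, abs=1e-4)

    def test_hr_identity_and_loglik_ordering(self):
        rng = np.random.default_rng(8)
        t, e, g = _sim_two_group(200, 0.9, rng)
        res = sv.cox_fit(pd.DataFrame({"g": g}), t, e)
        assert res.hr["g"] == pytest.approx(np.exp(res.coefficients["g"]))
        assert res.loglik >= res.loglik_null

    def test_large_sample_recovers_rate_ratio(self):
        rng = np.random.default_rng(9)
        t, e, g = _sim_two_group(5000, np.log(3.0), rng, censor=np.inf)
        res = sv.cox_fit(pd.DataFrame({"g": g}), t, e)
        assert res.hr["g"] == pytest.approx(3.0, rel=0.05)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sv.cox_fit(pd.DataFrame({"c": np.ones(10)}),
                       np.arange(1, 11, dtype=float), np.ones(10, dtype=int))

    def test_separation_flagged(self):
        # perfectly separating covariate: monotone likelihood
        t = np.array([1.0, 2, 3, 4, 9, 10, 11, 12])
        e = np.array([1, 1, 1, 1, 1, 1, 1, 1])
        x = np.array([1.0, 1, 1, 1, 0, 0, 0, 0])
        try:
            res = sv.cox_fit(pd.DataFrame({"x": x}), t, e)
            assert res.separation_flag
        except sv.ConvergenceError:
            pass  # also acceptable: the error names the gradient norm


class TestLikelihoodRatio:
    def test_statistic_is_twice_delta_loglik(self):
        rng = np.random.default_rng(10)
        t, e, g = _sim_two_group(150, 0.7, rng)
        res = sv.cox_fit(pd.DataFrame({"g": g}), t, e)
        stat, p = sv.likelihood_ratio_test(res)
        assert stat == pytest.approx(2 * (res.loglik - res.loglik_null))
        assert p == pytest.approx(stats.chi2.sf(stat, 1), abs=1e-12)

    def test_negative_statistic_rejected(self):
        rng = np.random.default_rng(11)
        t, e, g = _sim_two_group(100, 0.5, rng)
        res = sv.cox_fit(pd.DataFrame({"g": g}), t, e)
        with pytest.raises(ValueError, match="negative"):
            sv.likelihood_ratio_test(res, null_loglik=res.loglik + 1.0)

    def test_summary_renders(self):
        rng = np.random.default_rng(12)
        t, e, g = _sim_two_group(100, 0.5, rng)
        res = sv.cox_fit(pd.DataFrame({"g": g}), t, e)
        text = res.summary()
        assert "HR" in text and "LRT" in text
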