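import numpy as np
import pytest
from scipy import stats as sps
from scipy.optimize import minimize
from scipy.special import expit

import pandas as pd

from voltiscan.stats_core import (
    FitError,
    batch_logistic,
    fit_binomial_glm,
    fit_linear_model,
    fit_negbin_glm,
    likelihood_ratio_test,
    mcfadden_r2,
    profile_odds_ratio,
)


def _logistic_data(rng, n, b0=-0.3, b1=0.8):
    x = rng.normal(size=n)
    y = (rng.random(n) < expit(b0 + b1 * x)).astype(float)
    return y, x


def _direct_mle(y, X):
    def nll(beta):
        eta = X @ beta
        return np.sum(np.logaddexp(0.0, np.where(y > 0.5, -eta, eta)))

    out = minimize(nll, np.zeros(X.shape[1]), method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 5000})
    return out.x


class TestBinomialGlm:
    def test_intercept_only_balanced(self):
        y = np.array([0, 1] * 10, dtype=float)
        fit = fit_binomial_glm(y, None)
        assert fit.params[0] == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(fit.fitted, 0.5)

    def test_perfect_separation_flagged(self):
        fit = fit_binomial_glm([0, 0, 1, 1], [1, 2, 3, 4])
        assert fit.separation

    def test_matches_direct_maximization(self):
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 20:
            y, x = _logistic_data(rng, 25)
            if y.min() == y.max():
                continue
            fit = fit_binomial_glm(y, x)
            if fit.separation:
                continue
            ref = _direct_mle(y, fit.X)
            assert np.max(np.abs(fit.params - ref)) < 1e-6
            checked += 1

    def test_score_equations_satisfied(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            y, x = _logistic_data(rng, 80)
            fit = fit_binomial_glm(y, x)
            if fit.separation:
                continue
            score = fit.X.T @ (y - fit.fitted)
            assert np.max(np.abs(score)) < 1e-8

    def test_constant_covariate_rejected(self):
        with pytest.raises(FitError, match="constant"):
            fit_binomial_glm([0, 1, 0, 1], [2, 2, 2, 2])

    def test_adding_covariate_never_decreases_loglik(self):
        rng = np.random.default_rng(2)
        y, x1 = _logistic_data(rng, 60)
        x2 = rng.normal(size=60)
        small = fit_binomial_glm(y, x1)
        big = fit_binomial_glm(y, np.column_stack([x1, x2]))
        assert big.loglik >= small.loglik - 1e-9
        assert mcfadden_r2(big) >= mcfadden_r2(small) - 1e-12


class TestBatchLogistic:
    def test_agrees_with_single_fits(self):
        rng = np.random.default_rng(3)
        y, _ = _logistic_data(rng, 50)
        covs = rng.normal(size=(8, 50)) + y[None, :]
        out = batch_logistic(y, covs)
        for i in range(8):
            single = fit_binomial_glm(y, covs[i])
            if single.separation:
                continue
            assert out["b0"][i] == pytest.approx(single.params[0], abs=1e-6)
            assert out["b1"][i] == pytest.approx(single.params[1], abs=1e-6)
            assert out["loglik"][i] == pytest.approx(single.loglik, abs=1e-8)


class TestProfileOddsRatio:
    def test_close_to_wald_at_large_n(self):
        rng = np.random.default_rng(4)
        y, x = _logistic_data(rng, 2000)
        fit = fit_binomial_glm(y, x)
        orr = profile_odds_ratio(fit)
        z = sps.norm.ppf(0.975)
        wald_lo = np.exp(fit.params[1] - z * fit.bse[1])
        wald_hi = np.exp(fit.params[1] + z * fit.bse[1])
        assert orr.lower == pytest.approx(wald_lo, rel=0.05)
        assert orr.upper == pytest.approx(wald_hi, rel=0.05)
        assert orr.lower < orr.point < orr.upper

    def test_interval_contains_mle(self):
        rng = np.random.default_rng(5)
        y, x = _logistic_data(rng, 100, b1=1.5)
        fit = fit_binomial_glm(y, x)
        orr = profile_odds_ratio(fit)
        assert orr.lower < np.exp(fit.params[1]) < orr.upper

    def test_separation_rejected(self):
        fit = fit_binomial_glm([0, 0, 1, 1], [1, 2, 3, 4])
        with pytest.raises(FitError):
            profile_odds_ratio(fit)


class TestMcFadden:
    def test_null_model_is_zero(self):
        y = np.array([0, 1, 1, 0, 1] * 4, dtype=float)
        fit = fit_binomial_glm(y, None)
        assert mcfadden_r2(fit) == pytest.approx(0.0, abs=1e-10)

    def test_direct_formula(self):
        rng = np.random.default_rng(6)
        y, x = _logistic_data(rng, 40)
        fit = fit_binomial_glm(y, x)
        eta = fit.X @ fit.params
        ll = -np.sum(np.logaddexp(0.0, np.where(y > 0.5, -eta, eta)))
        p = y.mean()
        ll0 = len(y) * (p * np.log(p) + (1 - p) * np.log(1 - p))
        assert mcfadden_r2(fit) == pytest.approx(1 - ll / ll0, abs=1e-12)


class TestLinearModel:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = fit_linear_model(2 * x, x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.resid_se == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_and_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        x = rng.normal(size=10)
        y = 1.5 + 0.7 * x + rng.normal(size=10)
        fit = fit_linear_model(y, x)
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert fit.slope == pytest.approx(expected, abs=1e-12)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.slope == pytest.approx(ref.params[1], abs=1e-10)
        assert fit.t == pytest.approx(ref.tvalues[1], abs=1e-8)
        assert fit.pvalue == pytest.approx(ref.pvalues[1], abs=1e-10)
        assert fit.t == pytest.approx(fit.slope / fit.slope_se)

    def test_intercept_equals_mean_for_centred_x(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = np.array([1.0, 3.0, 2.0, 1.0, 3.0])
        fit = fit_linear_model(y, x)
        assert fit.intercept == pytest.approx(y.mean())

    def test_constant_covariate_rejected(self):
        with pytest.raises(FitError):
            fit_linear_model([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestNegbinGlm:
    def test_intercept_only_constant_counts(self):
        fit = fit_negbin_glm(np.full(30, 7), None)
        assert fit.coefficients["intercept"] == pytest.approx(np.log(7), abs=1e-3)
        assert fit.large_k

    def test_poisson_limit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        y = rng.poisson(np.exp(1.0 + 0.3 * x))
        fit = fit_negbin_glm(y, pd.DataFrame({"x": x}))
        X = sm.add_constant(x)
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert fit.loglik == pytest.approx(pois.llf, abs=1e-3)
        assert fit.large_k

    def test_dispersion_recovery(self):
        rng = np.random.default_rng(9)
        k_true = 2.0
        mu = np.exp(1.5 + 0.4 * rng.normal(size=500))
        y = rng.negative_binomial(k_true, k_true / (k_true + mu))
        fit = fit_negbin_glm(y, pd.DataFrame({"x": np.log(mu) - 1.5}))
        assert 1.2 < fit.k < 3.3   # within ~3 SE of truth at n=500

    def test_non_integer_rejected(self):
        with pytest.raises(FitError):
            fit_negbin_glm(np.array([1.5, 2.0, 3.0]), None)


class TestLikelihoodRatio:
    def test_model_against_itself(self):
        rng = np.random.default_rng(10)
        y, x = _logistic_data(rng, 40)
        fit = fit_binomial_glm(y, x)
        res = likelihood_ratio_test(fit, fit)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_nested_pair_direct_evaluation(self):
        rng = np.random.default_rng(11)
        y, x = _logistic_data(rng, 60, b1=1.0)
        full = fit_binomial_glm(y, x)
        null = fit_binomial_glm(y, None)
        res = likelihood_ratio_test(full, null)
        assert res.statistic == pytest.approx(2 * (full.loglik - null.loglik))
        assert res.df == 1
        assert res.pvalue == pytest.approx(sps.chi2.sf(res.statistic, 1))

    def test_statistic_at_chi2_critical_value(self):
        class Stub:
            def __init__(self, ll, k):
                self.loglik, self.n_params, self.nobs = ll, k, 30

        res = likelihood_ratio_test(Stub(-10.0, 2), Stub(-10.0 - 3.84 / 2, 1))
        assert res.statistic == pytest.approx(3.84)
        assert res.pvalue == pytest.approx(0.05, abs=0.001)

    def test_differing_rows_rejected(self):
        rng = np.random.default_rng(12)
        y1, x1 = _logistic_data(rng, 40)
        y2, x2 = _logistic_data(rng, 50)
        f1 = fit_binomial_glm(y1, x1)
        f2 = fit_binomial_glm(y2, x2)
        with pytest.raises(FitError, match="different row sets"):
            likelihood_ratio_test(f1, f2)
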