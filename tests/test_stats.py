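"""Logistic GLMM, beta-binomial regression, AICc, AUC."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import optimize, special

from mosaicspeech.stats import (
    BetaBinomial,
    LogisticGLMM,
    aicc,
    auc,
    build_design_matrix,
)
from mosaicspeech.synthetic import simulate_betabinomial


class TestAicc:
    def test_zero_parameters(self):
        assert aicc(-50.0, 0, 100) == 100.0

    def test_arithmetic(self):
        # 200 + 6 + 24/46
        assert aicc(-100.0, 3, 50) == pytest.approx(206.5217391304)

    def test_large_n_limit_approaches_aic(self):
        aic = -2 * (-100.0) + 2 * 3
        assert aicc(-100.0, 3, 10**7) == pytest.approx(aic, abs=1e-4)

    def test_undefined_for_small_n(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_uninformative_constant(self):
        assert auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_null_simulation_near_half(self, rng):
        y = rng.integers(0, 2, 1000)
        p = rng.random(1000)
        assert abs(auc(y, p) - 0.5) < 0.05

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 200)
        p = rng.random(200)
        assert auc(y, p) == pytest.approx(auc(y, np.exp(5 * p) + 3))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 1, 1], [0.2, 0.5, 0.9])


def _glmm_data(rng, n_groups=8, n_per=50, beta=(0.4, -0.7), sigma_u=0.6):
    n = n_groups * n_per
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    g = np.repeat(np.arange(n_groups), n_per)
    u = rng.normal(0, sigma_u, n_groups)
    p = special.expit(X @ np.asarray(beta) + u[g])
    y = (rng.random(n) < p).astype(float)
    return y, X, g


class TestLogisticGLMM:
    def test_quadrature_matches_bruteforce_integration(self, rng):
        """Adaptive Gauss-Hermite vs scipy.quad on a tiny dataset."""
        y, X, g = _glmm_data(rng, n_groups=3, n_per=5)
        mod = LogisticGLMM(y, X, g)
        for theta in ([0.3, 0.8, np.log(0.7)], [0.0, -0.5, np.log(0.2)]):
            theta = np.asarray(theta)
            assert mod.loglike(theta) == pytest.approx(
                mod.loglike_bruteforce(theta), abs=1e-4
            )

    def test_analytic_score_matches_finite_differences(self, rng):
        y, X, g = _glmm_data(rng, n_groups=5, n_per=30)
        mod = LogisticGLMM(y, X, g)
        err = optimize.check_grad(
            mod.loglike, mod.score, np.array([0.2, -0.4, np.log(0.5)])
        )
        assert err < 1e-5

    def test_reduces_to_glm_without_heterogeneity(self, rng):
        """sigma_u = 0 data: fitted variance ~ 0 and coefficients match an
        ordinary logistic fit within a fraction of its standard errors."""
        y, X, g = _glmm_data(rng, n_groups=20, n_per=100, sigma_u=0.0)
        res = LogisticGLMM(y, X, g).fit()
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert res.sigma_u < 0.05
        np.testing.assert_allclose(res.params, np.asarray(glm.params), atol=2e-2)

    def test_recovers_generating_parameters(self, rng):
        beta, sigma_u = (0.5, -0.9), 0.5
        y, X, g = _glmm_data(rng, n_groups=25, n_per=120, beta=beta, sigma_u=sigma_u)
        res = LogisticGLMM(y, X, g).fit()
        for est, se, true in zip(res.params, res.bse, beta):
            assert abs(est - true) < 2.5 * se
        assert 0.25 < res.sigma_u < 0.9

    def test_wald_chi2_is_squared_z(self, rng):
        y, X, g = _glmm_data(rng)
        res = LogisticGLMM(y, X, g).fit()
        tbl = res.wald_table()
        np.testing.assert_allclose(
            tbl["wald_chi2"].to_numpy(), (res.params / res.bse) ** 2
        )

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame(
            {"correct": [0, 1, 1, 0], "language": ["jp"] * 4, "participant": [0, 0, 1, 1]}
        )
        with pytest.raises(ValueError, match="single level"):
            LogisticGLMM.from_dataframe(df, "correct", ["language"], "participant")

    def test_complete_separation_flagged(self):
        x = np.repeat([0.0, 1.0], 50)
        X = np.column_stack([np.ones(100), x])
        g = np.tile([0, 1, 2, 3], 25)
        with pytest.warns(RuntimeWarning, match="separation"):
            LogisticGLMM(x.copy(), X, g).fit()

    def test_needs_two_groups(self, rng):
        y, X, _ = _glmm_data(rng, n_groups=1, n_per=20)
        with pytest.raises(ValueError, match="groups"):
            LogisticGLMM(y, X, np.zeros(len(y)))

    def test_summary_mentions_key_quantities(self, rng):
        y, X, g = _glmm_data(rng)
        res = LogisticGLMM(y, X, g, exog_names=["Intercept", "x"]).fit()
        text = res.summary()
        for token in ("AICc", "AUC", "sigma_u", "Intercept"):
            assert token in text
        d = res.to_dict()
        assert set(d["coefficients"]) == {"Intercept", "x"}


class TestBetaBinomial:
    def test_loglik_approaches_binomial_in_rho_zero_limit(self, rng):
        n = 150
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        tot = np.full(n, 12)
        k = simulate_betabinomial(X, [0.2, 0.6], 0.0, tot, seed=1)
        bb = BetaBinomial(k, tot, X)
        beta = np.array([0.2, 0.6])
        ll_bb = bb.loglike(np.append(beta, special.logit(1e-6)))
        mu = special.expit(X @ beta)
        ll_binom = float(
            np.sum(
                special.gammaln(tot + 1)
                - special.gammaln(k + 1)
                - special.gammaln(tot - k + 1)
                + k * np.log(mu)
                + (tot - k) * np.log1p(-mu)
            )
        )
        assert abs(ll_bb - ll_binom) < 0.01

    def test_analytic_score_matches_finite_differences(self, rng):
        X = np.column_stack([np.ones(60), rng.normal(size=60)])
        tot = np.full(60, 10)
        k = simulate_betabinomial(X, [0.3, 0.5], 0.2, tot, seed=4)
        bb = BetaBinomial(k, tot, X)
        err = optimize.check_grad(bb.loglike, bb.score, np.array([0.2, 0.4, -1.5]))
        assert err < 1e-4

    def test_recovers_generating_parameters(self, rng):
        beta_true, rho_true = np.array([0.3, 0.7]), 0.15
        X = np.column_stack([np.ones(400), rng.normal(size=400)])
        tot = np.full(400, 15)
        k = simulate_betabinomial(X, beta_true, rho_true, tot, seed=7)
        res = BetaBinomial(k, tot, X).fit()
        for est, se, true in zip(res.params, res.bse, beta_true):
            assert abs(est - true) < 2.5 * se
        assert 0.08 < res.rho < 0.25

    def test_all_correct_boundary_flagged(self):
        X = np.ones((20, 1))
        with pytest.warns(RuntimeWarning):
            BetaBinomial(np.full(20, 10), np.full(20, 10), X).fit()

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            BetaBinomial([5], [4], np.ones((1, 1)))
        with pytest.raises(ValueError):
            BetaBinomial([0], [0], np.ones((1, 1)))


class TestDesignMatrix:
    def test_categorical_interaction_coding(self):
        df = pd.DataFrame(
            {
                "language": ["jp", "zh", "jp", "zh"],
                "d": [1.0, 2.0, 3.0, 4.0],
            }
        )
        X, names = build_design_matrix(df, ["language", "d", "language:d"])
        assert names == ["Intercept", "language[zh]", "d", "language[zh]:d"]
        np.testing.assert_allclose(X[:, 3], [0, 2, 0, 4])

    def test_rank_deficiency_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]})
        with pytest.raises(ValueError, match="rank"):
            build_design_matrix(df, ["a", "b"])
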