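"""Fixed-effects beta regression: squeeze, fitting, Wald machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, gammaln, logit

from dualmark.betareg import BetaRegFit, fit_betareg, squeeze, wald


class TestSqueeze:
    @pytest.mark.parametrize(
        "y,eps,expected",
        [(0.0, 1e-6, 1e-6), (0.5, 1e-6, 0.5), (1.0, 1e-6, 1.0 - 1e-6)],
    )
    def test_clamps(self, y, eps, expected):
        assert squeeze(y, eps) == pytest.approx(expected, abs=1e-15)

    def test_idempotent_and_vectorized(self):
        y = np.array([0.0, 0.3, 1.0])
        once = squeeze(y, 1e-4)
        assert np.array_equal(squeeze(once, 1e-4), once)

    @pytest.mark.parametrize("eps", [0.0, 0.5, -1e-3, 0.7])
    def test_rejects_bad_epsilon(self, eps):
        with pytest.raises(ValueError):
            squeeze(0.5, eps)


def _beta_loglik(y, mu, phi):
    a, b = mu * phi, (1 - mu) * phi
    return np.sum(
        gammaln(phi) - gammaln(a) - gammaln(b)
        + (a - 1) * np.log(y) + (b - 1) * np.log(1 - y)
    )


def _intercept_grid_oracle(y, coarse=1e-3, fine=1e-4):
    """Profile the likelihood over mu on a grid (phi profiled numerically),
    coarse pass then refinement at the fine step."""
    from scipy.optimize import minimize_scalar

    def profile(mu):
        res = minimize_scalar(
            lambda lp: -_beta_loglik(y, mu, np.exp(lp)), bounds=(-2, 9),
            method="bounded", options={"xatol": 1e-8},
        )
        return -res.fun

    lo, hi = y.min() / 2, (1 + y.max()) / 2
    grid = np.arange(lo, hi, coarse)
    best = grid[int(np.argmax([profile(m) for m in grid]))]
    grid2 = np.arange(best - 2 * coarse, best + 2 * coarse, fine)
    grid2 = grid2[(grid2 > 0) & (grid2 < 1)]
    return grid2[int(np.argmax([profile(m) for m in grid2]))]


class TestFitBetareg:
    def test_symmetric_sample_gives_zero_intercept(self):
        # the sample {0.3, 0.7, 0.4, 0.6} is invariant under y -> 1 - y,
        # so the fitted mean must be exactly 0.5 (intercept 0 on the logit)
        y = np.array([0.3, 0.7, 0.4, 0.6])
        X = pd.DataFrame({"intercept": np.ones(4)})
        fit = fit_betareg(X, y)
        assert fit.converged
        assert fit.coef["intercept"] == pytest.approx(0.0, abs=1e-6)

    def test_parameter_recovery_within_3se(self):
        rng = np.random.default_rng(11)
        n, phi = 500, 30.0
        x = rng.normal(size=n)
        mu = expit(-1 + 1 * x)
        y = rng.beta(mu * phi, (1 - mu) * phi)
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        fit = fit_betareg(X, y)
        assert fit.converged
        for term, truth in (("intercept", -1.0), ("x", 1.0)):
            assert abs(fit.coef[term] - truth) < 3 * fit.se[term]

    def test_intercept_only_matches_profile_grid_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(8):
            n = int(rng.integers(8, 20))
            mu0 = rng.uniform(0.2, 0.8)
            y = np.clip(rng.beta(mu0 * 20, (1 - mu0) * 20, n), 1e-4, 1 - 1e-4)
            fit = fit_betareg(pd.DataFrame({"intercept": np.ones(n)}), y)
            mu_hat = expit(fit.coef["intercept"])
            mu_grid = _intercept_grid_oracle(y)
            assert abs(mu_hat - mu_grid) < 2e-4

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(2)
        n = 60
        x = rng.normal(size=n)
        mu = expit(0.5 * x)
        y = rng.beta(mu * 25, (1 - mu) * 25)
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        fit = fit_betareg(X, y)
        perm = rng.permutation(n)
        fit_p = fit_betareg(X.iloc[perm].reset_index(drop=True), y[perm])
        assert np.allclose(fit.coef, fit_p.coef, atol=1e-6)

    def test_loglik_at_optimum_beats_truth(self):
        rng = np.random.default_rng(8)
        n, phi = 100, 30.0
        x = rng.normal(size=n)
        mu = expit(-0.5 + 0.8 * x)
        y = rng.beta(mu * phi, (1 - mu) * phi)
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        fit = fit_betareg(X, y)
        truth_ll = _beta_loglik(y, expit(-0.5 + 0.8 * x), phi)
        assert fit.loglik >= truth_ll - 1e-6

    def test_rank_deficient_design_rejected(self):
        X = pd.DataFrame({"intercept": np.ones(10), "dup": np.ones(10)})
        with pytest.raises(ValueError, match="rank"):
            fit_betareg(X, np.full(10, 0.4))

    def test_boundary_response_rejected(self):
        X = pd.DataFrame({"intercept": np.ones(3)})
        with pytest.raises(ValueError, match="squeeze"):
            fit_betareg(X, np.array([0.0, 0.5, 0.6]))


def _zfit(coef, se, df=float("inf")):
    idx = list(coef)
    return BetaRegFit(
        coef=pd.Series(coef), se=pd.Series(se), log_precision=3.0,
        loglik=0.0, converged=True, n_obs=10, df_resid=df,
    )


class TestWald:
    def test_null_coefficient(self):
        z, p = wald(_zfit({"b": 0.0}, {"b": 1.0}), "b")
        assert z == 0.0 and p == 1.0

    def test_standard_normal_quantile(self):
        # infinite df: the generic z-test path
        _, p = wald(_zfit({"b": 1.959964}, {"b": 1.0}), "b")
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_t_reference_is_heavier_tailed(self):
        _, p_norm = wald(_zfit({"b": 2.0}, {"b": 1.0}), "b")
        _, p_t = wald(_zfit({"b": 2.0}, {"b": 1.0}, df=20), "b")
        assert p_t > p_norm

    def test_matches_numerical_hessian_curvature(self):
        """The reported z agrees with one from a numeric-Hessian SE within 5%."""
        rng = np.random.default_rng(21)
        n, phi = 200, 25.0
        x = rng.normal(size=n)
        mu = expit(0.4 + 0.6 * x)
        y = rng.beta(mu * phi, (1 - mu) * phi)
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        fit = fit_betareg(X, y)

        def negll(theta):
            m = expit(X.to_numpy() @ theta[:2])
            return -_beta_loglik(y, m, np.exp(theta[2]))

        theta = np.r_[fit.coef.to_numpy(), fit.log_precision]
        h = 1e-5
        H = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                ei, ej = np.zeros(3), np.zeros(3)
                ei[i], ej[j] = h, h
                H[i, j] = (
                    negll(theta + ei + ej) - negll(theta + ei - ej)
                    - negll(theta - ei + ej) + negll(theta - ei - ej)
                ) / (4 * h * h)
        se_x = np.sqrt(np.linalg.inv(H)[1, 1])
        z_fit, _ = wald(fit, "x")
        z_hess = fit.coef["x"] / se_x
        assert abs(z_fit - z_hess) / abs(z_hess) < 0.05

    def test_unknown_term(self):
        with pytest.raises(KeyError):
            wald(_zfit({"b": 1.0}, {"b": 1.0}), "nope")

    def test_nonconverged_propagates_nan(self):
        fit = _zfit({"b": 1.0}, {"b": 1.0})
        fit.converged = False
        z, p = wald(fit, "b")
        assert np.isnan(z) and np.isnan(p)
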