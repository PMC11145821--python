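"""MCP selection and de-biased Lasso inference."""

import numpy as np
import pytest
from scipy import stats

from hdmediation import (
    SimulationConfig,
    fit_debiased_lasso,
    fit_mcp,
    mcp_penalty,
    screen_mediators,
    simulate_dataset,
)
from hdmediation._solvers import cd_penalized_gram


def firm_threshold(z, lam, delta):
    """Closed-form MCP solution for a single orthonormal coordinate."""
    if abs(z) > delta * lam:
        return z
    return np.sign(z) * max(abs(z) - lam, 0.0) / (1.0 - 1.0 / delta)


def ista_lasso(G, c, lam, pf, n_iter=100_000, step=None):
    """Independent proximal-gradient Lasso oracle on the Gram formulation."""
    P = G.shape[0]
    if step is None:
        step = 1.0 / np.linalg.eigvalsh(G).max()
    b = np.zeros(P)
    for _ in range(n_iter):
        g = G @ b - c
        z = b - step * g
        new = np.sign(z) * np.maximum(np.abs(z) - step * lam * pf, 0.0)
        if np.max(np.abs(new - b)) < 1e-12:
            return new
        b = new
    return b


class TestMcpPenalty:
    def test_zero_and_plateau(self):
        assert mcp_penalty(0.0, 1.0, 3.0) == 0.0
        # beyond |b| = delta*lam the penalty is flat at lam^2*delta/2
        assert mcp_penalty(3.0, 1.0, 3.0) == pytest.approx(1.5)
        assert mcp_penalty(10.0, 1.0, 3.0) == pytest.approx(1.5)

    def test_inner_branch_value(self):
        assert mcp_penalty(1.5, 1.0, 3.0) == pytest.approx(1.125)

    def test_continuity_at_join(self):
        lam, delta = 0.7, 2.5
        eps = 1e-9
        below = mcp_penalty(delta * lam - eps, lam, delta)
        above = mcp_penalty(delta * lam + eps, lam, delta)
        assert abs(below - above) < 1e-7

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            mcp_penalty(1.0, -1.0, 3.0)
        with pytest.raises(ValueError):
            mcp_penalty(1.0, 1.0, 0.0)


class TestCoordinateDescent:
    @pytest.mark.parametrize("z", [-2.5, -0.8, -0.3, 0.0, 0.4, 1.2, 4.0])
    def test_single_coordinate_equals_firm_thresholding(self, z):
        G = np.ones((1, 1))
        c = np.array([z])
        lam, delta = 1.0, 3.0
        b = np.zeros(1)
        cd_penalized_gram(G, c, lam, delta, np.ones(1), b)
        assert b[0] == pytest.approx(firm_threshold(z, lam, delta), abs=1e-10)

    def test_objective_nonincreasing_over_sweeps(self, rng):
        n, P = 80, 12
        D = rng.normal(size=(n, P))
        D = (D - D.mean(0)) / D.std(0)
        y = D[:, 0] * 1.0 - D[:, 3] * 0.5 + rng.normal(size=n)
        G, c = D.T @ D / n, D.T @ y / n
        lam, delta = 0.2, 3.0
        pf = np.ones(P)

        def objective(b):
            pen = sum(mcp_penalty(abs(x), lam, delta) for x in b)
            return 0.5 * (y @ y / n - 2 * c @ b + b @ G @ b) + pen

        prev = np.inf
        for sweeps in range(1, 8):
            b = np.zeros(P)
            cd_penalized_gram(G, c, lam, delta, pf, b, max_iter=sweeps, tol=0.0)
            val = objective(b)
            assert val <= prev + 1e-12
            prev = val

    def test_large_delta_recovers_lasso(self, rng):
        n, P = 120, 15
        D = rng.normal(size=(n, P))
        D = (D - D.mean(0)) / D.std(0)
        y = D @ (np.arange(P) % 3 - 1.0) * 0.3 + rng.normal(size=n)
        G, c = D.T @ D / n, D.T @ y / n
        pf = np.ones(P)
        lam = 0.15
        b_mcp = np.zeros(P)
        cd_penalized_gram(G, c, lam, 1e6, pf, b_mcp, tol=1e-12)
        b_lasso = ista_lasso(G, c, lam, pf)
        assert np.allclose(b_mcp, b_lasso, atol=1e-6)

    def test_unpenalized_columns_are_not_shrunk(self, rng):
        n, P = 100, 6
        D = rng.normal(size=(n, P))
        D = (D - D.mean(0)) / D.std(0)
        y = 2.0 * D[:, 0] + rng.normal(size=n)
        G, c = D.T @ D / n, D.T @ y / n
        pf = np.ones(P)
        pf[0] = 0.0
        b = np.zeros(P)
        cd_penalized_gram(G, c, 5.0, -1.0, pf, b, tol=1e-12)
        # huge lambda kills all penalized coords; column 0 keeps its OLS value
        assert np.all(b[1:] == 0.0)
        assert b[0] == pytest.approx(c[0] / G[0, 0], rel=1e-8)


class TestFitMcp:
    def test_pure_noise_selects_nothing(self, rng):
        n = 150
        X = rng.binomial(1, 0.5, n).astype(float)
        M = rng.normal(size=(n, 10))
        Y = rng.normal(size=n)
        fit = fit_mcp(Y, X, M, lambda_grid=[5.0])
        assert fit.selected.size == 0

    def test_recovers_true_mediators(self):
        ds = simulate_dataset(SimulationConfig(n=400, p=100), seed=17)
        screen = screen_mediators(ds, "ra")
        fit = fit_mcp(ds.Y, ds.X, ds.M[:, screen.kept], ds.C)
        picked = set(screen.kept[fit.selected].tolist())
        # beta-active mediators are 0-3 and 6-7; the four true ones must show
        assert {0, 1, 2, 3}.issubset(picked)

    def test_estimates_on_original_scale(self, rng):
        n = 500
        X = rng.binomial(1, 0.5, n).astype(float)
        M = rng.normal(size=(n, 5)) * np.array([1.0, 10.0, 0.1, 1.0, 1.0])
        Y = 1.5 + 0.5 * X + 0.8 * M[:, 0] + 0.08 * M[:, 1] + rng.normal(size=n)
        fit = fit_mcp(Y, X, M)
        assert fit.coefficients[0] == pytest.approx(0.8, abs=0.15)
        assert fit.coefficients[1] == pytest.approx(0.08, abs=0.015)

    def test_d_not_below_n_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_mcp(rng.normal(size=20), rng.binomial(1, 0.5, 20).astype(float),
                    rng.normal(size=(20, 25)))


class TestDebiasedLasso:
    def test_pvalue_formula(self):
        # |b|/s = 1.959964 must give p = 0.05 by the two-sided normal formula
        assert 2 * (1 - stats.norm.cdf(1.959964)) == pytest.approx(0.05, abs=5e-5)

    def test_matches_ols_in_low_dimension(self, rng):
        n, d = 2000, 5
        X = rng.binomial(1, 0.5, n).astype(float)
        M = rng.normal(size=(n, d))
        Y = 0.5 * X + M @ np.array([0.3, 0.0, -0.2, 0.0, 0.1]) + rng.normal(size=n)
        deb = fit_debiased_lasso(Y, X, M, seed=3)
        import statsmodels.api as sm

        ols = sm.OLS(Y, sm.add_constant(np.column_stack([X, M]))).fit()
        assert np.allclose(deb.beta_hat, ols.params[2:], atol=0.02)
        assert np.allclose(deb.sigma_hat, ols.bse[2:], rtol=0.10)

    def test_contract_on_simulated_replication(self):
        ds = simulate_dataset(SimulationConfig(n=300, p=200), seed=23)
        screen = screen_mediators(ds, "ow")
        deb = fit_debiased_lasso(ds.Y, ds.X, ds.M[:, screen.kept], ds.C, seed=1)
        assert np.all(deb.sigma_hat > 0)
        assert np.all((deb.p_values > 0) | (deb.p_values == 0.0))
        assert np.all(deb.p_values <= 1)
        # the p-value identity p = 2(1 - Phi(|b|/s)) holds exactly
        recomputed = 2 * (1 - stats.norm.cdf(np.abs(deb.beta_hat) / deb.sigma_hat))
        assert np.allclose(deb.p_values, recomputed, atol=1e-12)

    def test_scaling_equivariance(self):
        ds = simulate_dataset(SimulationConfig(n=250, p=40), seed=29)
        M = ds.M.copy()
        deb1 = fit_debiased_lasso(ds.Y, ds.X, M, ds.C, seed=7)
        M2 = M.copy()
        M2[:, 2] *= 5.0
        deb2 = fit_debiased_lasso(ds.Y, ds.X, M2, ds.C, seed=7)
        assert deb2.beta_hat[2] == pytest.approx(deb1.beta_hat[2] / 5.0, rel=1e-6)
        assert deb2.p_values[2] == pytest.approx(deb1.p_values[2], abs=1e-9)
        assert np.allclose(deb2.beta_hat[:2], deb1.beta_hat[:2], rtol=1e-6)

    def test_deterministic_given_seed(self):
        ds = simulate_dataset(SimulationConfig(n=200, p=50), seed=31)
        a = fit_debiased_lasso(ds.Y, ds.X, ds.M, ds.C, seed=5)
        b = fit_debiased_lasso(ds.Y, ds.X, ds.M, ds.C, seed=5)
        assert np.array_equal(a.beta_hat, b.beta_hat)
        assert np.array_equal(a.p_values, b.p_values)
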