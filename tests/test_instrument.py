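import numpy as np
import pytest
from scipy.optimize import minimize

from funcalib.basis import BSplineBasis, FourierBasis, MonomialBasis
from funcalib.fdata import FunctionalSample, expand, inner_product, make_grid, trapezoid_weights
from funcalib.instrument import (
    ConcurrentRegressor,
    fit_bivariate,
    fit_concurrent,
    select_q_cv,
)
from funcalib.simulate import ScenarioConfig, estimation_error, gen_dataset


def _sample(grid, values):
    return FunctionalSample(grid, values)


class TestFitConcurrent:
    def test_identity_slope_recovered_exactly(self, grid, rng):
        Z = _sample(grid, rng.standard_normal((30, 5)) @ BSplineBasis(5).evaluate(grid).T)
        fit = fit_concurrent(Z, Z, phi=MonomialBasis(3))
        assert np.allclose(fit.theta_fun(), 1.0, atol=1e-8)
        assert np.allclose(fit.vhat.values, Z.values, atol=1e-8)

    def test_estimating_equation_residual_vanishes(self, grid, rng):
        n = 50
        Z = _sample(grid, rng.standard_normal((n, 5)) @ BSplineBasis(5).evaluate(grid).T)
        W = _sample(grid, Z.values * grid[None, :] + 0.1 * rng.standard_normal((n, grid.size)))
        fit = fit_concurrent(W, Z, q=4)
        w = trapezoid_weights(grid)
        Phi = fit.theta_coefs.basis.evaluate(grid)
        resid = W.values - fit.vhat.values
        S = Phi.T @ (w * np.sum(resid * Z.values, axis=0))
        assert np.linalg.norm(S) <= 1e-8 * n

    def test_linear_slope_close_to_gridwise_oracle(self, grid):
        rng = np.random.default_rng(3)
        n = 2000
        Z = _sample(grid, rng.standard_normal((n, 5)) @ BSplineBasis(5).evaluate(grid).T)
        h = np.diff(grid)
        bm = np.concatenate(
            [np.zeros((n, 1)), np.cumsum(rng.standard_normal((n, grid.size - 1)) * np.sqrt(h), axis=1)],
            axis=1,
        )
        W = _sample(grid, grid[None, :] * Z.values + bm)
        fit = fit_concurrent(W, Z, q=4)
        assert estimation_error(fit.theta_fun(), grid, grid) < 1e-2
        # independent oracle: pointwise least squares smoothed onto the basis
        ratio = np.sum(W.values * Z.values, axis=0) / np.sum(Z.values**2, axis=0)
        oracle = expand(ratio, fit.theta_coefs.basis, grid).reconstruct(grid)
        assert estimation_error(fit.theta_fun(), oracle, grid) < 1e-2

    def test_closed_form_equals_numerical_minimizer(self, grid):
        rng = np.random.default_rng(7)
        n, q = 20, 3
        Z = _sample(grid, rng.standard_normal((n, 5)) @ BSplineBasis(5).evaluate(grid).T)
        W = _sample(grid, Z.values * (1 + grid)[None, :] + 0.2 * rng.standard_normal((n, grid.size)))
        phi = MonomialBasis(q)
        fit = fit_concurrent(W, Z, phi=phi)
        w = trapezoid_weights(grid)
        Phi = phi.evaluate(grid)

        def objective(theta):
            resid = W.values - Z.values * (Phi @ theta)[None, :]
            return float(np.sum(resid**2 * w[None, :]))

        res = minimize(objective, np.zeros(q), method="BFGS", tol=1e-12)
        assert np.allclose(fit.theta_coefs.coefs, res.x, atol=1e-6)

    def test_linearity_in_the_response_curves(self, grid, rng):
        Z = _sample(grid, rng.standard_normal((25, 5)) @ BSplineBasis(5).evaluate(grid).T)
        W = _sample(grid, Z.values * (2 - grid)[None, :])
        f1 = fit_concurrent(W, Z, q=4)
        f3 = fit_concurrent(_sample(grid, 3.0 * W.values), Z, q=4)
        assert np.allclose(f3.theta_coefs.coefs, 3.0 * f1.theta_coefs.coefs, atol=1e-12)

    def test_degenerate_instrument_raises(self, grid):
        Z = _sample(grid, np.zeros((10, grid.size)))
        with pytest.raises(np.linalg.LinAlgError):
            fit_concurrent(Z, Z, q=4)

    def test_step1_consistency_in_n(self):
        """Median θ-ISE decreases along n = 100, 500, 3000 (weak consistency)."""
        medians = []
        for n in (100, 500, 3000):
            ises = []
            for r in range(10):
                ds = gen_dataset(ScenarioConfig(n=n, scenario=1, l=0.05, seed=300 + r))
                fit = fit_concurrent(ds.W, ds.Z, q=4)
                ises.append(estimation_error(fit.theta_fun(), ds.theta_true, ds.W.grid))
            medians.append(np.median(ises))
        assert medians[2] < medians[1] < medians[0]


class TestSelectQ:
    def test_single_candidate_returned(self, grid, rng):
        Z = _sample(grid, rng.standard_normal((40, 5)) @ BSplineBasis(5).evaluate(grid).T)
        W = _sample(grid, Z.values * grid[None, :])
        assert select_q_cv(W, Z, candidates=[6], seed=0) == 6

    def test_duplicate_candidates_equivalent(self, grid, rng):
        Z = _sample(grid, rng.standard_normal((40, 5)) @ BSplineBasis(5).evaluate(grid).T)
        W = _sample(grid, Z.values * grid[None, :] + 0.3 * rng.standard_normal((40, grid.size)))
        a = select_q_cv(W, Z, candidates=[4, 6], seed=1)
        b = select_q_cv(W, Z, candidates=[4, 4, 6, 6], seed=1)
        assert a == b

    def test_empty_candidates_rejected(self, grid, rng):
        Z = _sample(grid, rng.standard_normal((10, 5)) @ BSplineBasis(5).evaluate(grid).T)
        with pytest.raises(ValueError):
            select_q_cv(Z, Z, candidates=[], seed=0)

    def test_average_selected_q_matches_reference_range(self):
        """Scenario-1 CV spreads over {4, 6} with mean near 4.8."""
        sel = []
        for r in range(40):
            ds = gen_dataset(ScenarioConfig(n=500, scenario=1, l=0.05, seed=700 + r))
            sel.append(select_q_cv(ds.W, ds.Z, seed=700 + r))
        assert np.mean(sel) == pytest.approx(4.8, abs=0.4)


class TestBivariate:
    def test_zero_response_gives_zero_coefficients(self, grid, rng):
        Z = _sample(grid, rng.standard_normal((30, 5)) @ BSplineBasis(5).evaluate(grid).T)
        W = _sample(grid, np.zeros_like(Z.values))
        alpha, vhat = fit_bivariate(W, Z, FourierBasis(3), FourierBasis(3))
        assert np.allclose(alpha, 0.0, atol=1e-10)
        assert np.allclose(vhat.values, 0.0, atol=1e-10)

    def test_one_by_one_matches_scalar_least_squares(self, grid, rng):
        Z = _sample(grid, rng.standard_normal((40, 5)) @ BSplineBasis(5).evaluate(grid).T)
        W = _sample(grid, Z.values * (1 + grid)[None, :])
        phi = FourierBasis(1)
        psi = FourierBasis(1)
        alpha, _ = fit_bivariate(W, Z, phi, psi)
        # 1-parameter least squares: alpha = <g, W> / <g, g> with
        # g_i(t) = phi_1(t) * int psi_1 Z_i
        w = trapezoid_weights(grid)
        zpsi = Z.values @ (w * psi.evaluate(grid)[:, 0])
        g = zpsi[:, None] * phi.evaluate(grid)[:, 0][None, :]
        num = np.sum(w[None, :] * g * W.values)
        den = np.sum(w[None, :] * g * g)
        assert alpha[0, 0] == pytest.approx(num / den, abs=1e-10)

    def test_recovers_separable_kernel(self, grid):
        rng = np.random.default_rng(21)
        n = 2000
        psi = FourierBasis(2)
        phi = FourierBasis(2)
        Z = _sample(grid, rng.standard_normal((n, 5)) @ BSplineBasis(5).evaluate(grid).T)
        w = trapezoid_weights(grid)
        # X(t) = phi_1(t) * int psi_1(s) Z(s) ds, i.e. alpha = e_11
        zpsi1 = Z.values @ (w * psi.evaluate(grid)[:, 0])
        W = _sample(grid, zpsi1[:, None] * phi.evaluate(grid)[:, 0][None, :])
        alpha, _ = fit_bivariate(W, Z, phi, psi)
        assert alpha[0, 0] == pytest.approx(1.0, abs=5e-2)
        assert np.allclose(alpha.ravel()[1:], 0.0, atol=5e-2)


class TestConcurrentRegressor:
    def test_sklearn_interface(self, grid, rng):
        Z = rng.standard_normal((50, 5)) @ BSplineBasis(5).evaluate(grid).T
        W = Z * grid[None, :]
        est = ConcurrentRegressor(q=4).fit(Z, W)
        assert est.q_ == 4
        assert est.get_params()["q"] == 4
        transformed = est.transform(Z)
        assert transformed.shape == W.shape
        est2 = ConcurrentRegressor(**est.get_params()).fit(Z, W)
        assert np.allclose(est.theta_coefs_, est2.theta_coefs_)
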