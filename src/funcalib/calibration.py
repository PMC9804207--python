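"""Step 2: scalar-on-function regression on the calibrated regressor.

With V̂ᵢ(t) = θ̂(t)Zᵢ(t) from Step 1 expanded on a basis ψ, the score vector
V̂cᵢ = (1, ⟨V̂ᵢ,ψ₁⟩, …, ⟨V̂ᵢ,ψ_p⟩)′ enters an ordinary least-squares fit

    β̂c = (Σᵢ V̂cᵢ V̂cᵢ′)⁻¹ (Σᵢ Yᵢ V̂cᵢ),

and the coefficient function is reconstructed as β̂(t) = ψ(t)′(β̂₁…β̂_p)′.
The naive estimator applies the same least squares directly to the basis
coefficients of the contaminated curves W, ignoring measurement error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .basis import Basis, FourierBasis
from .fdata import FunctionalSample, expand_matrix, fpca, trapezoid_weights
from .instrument import ConcurrentRegressor, _cv_folds


@dataclass
class CalibrationFit:
    """Scalar-on-function OLS output (calibrated or naive)."""

    beta0: float
    beta_coefs: np.ndarray      # β̂₁ … β̂_p on psi
    psi: Basis
    scores: np.ndarray          # n × (p+1), leading column of ones
    grid: np.ndarray
    beta_fun: np.ndarray = field(init=False)

    def __post_init__(self):
        self.beta_coefs = np.asarray(self.beta_coefs, dtype=float).ravel()
        self.beta_fun = self.psi.evaluate(self.grid)[:, : self.p] @ self.beta_coefs

    @property
    def p(self) -> int:
        return self.beta_coefs.size

    @property
    def coef_full(self) -> np.ndarray:
        """(β̂₀, β̂₁, …, β̂_p) — the vector entering the test statistic."""
        return np.concatenate([[self.beta0], self.beta_coefs])


def compute_scores(vhat: FunctionalSample, psi: Basis, p: int) -> np.ndarray:
    """Score matrix: row i = (1, ⟨V̂ᵢ, ψ₁⟩, …, ⟨V̂ᵢ, ψ_p⟩) by quadrature.

    For a non-orthonormal ψ the entries are projection coefficients.
    """
    if p < 1 or p > psi.size:
        raise ValueError("need 1 <= p <= psi.size")
    coefs = expand_matrix(vhat.values, psi, vhat.grid)[:, :p]
    return np.column_stack([np.ones(vhat.n), coefs])


def _ols(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    xtx = design.T @ design
    rank = np.linalg.matrix_rank(xtx)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError(
            "rank-deficient score matrix (degenerate calibrated regressor)"
        )
    return np.linalg.solve(xtx, design.T @ y)


def fit_calibrated(
    Y: np.ndarray,
    scores: np.ndarray,
    psi: Basis,
    grid: np.ndarray,
) -> CalibrationFit:
    """OLS of Y on the score matrix; closed form of the Step-2 minimizer."""
    Y = np.asarray(Y, dtype=float).ravel()
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != Y.size:
        raise ValueError("Y and scores have mismatched lengths")
    if scores.shape[0] <= scores.shape[1]:
        raise ValueError("need n > p + 1")
    coef = _ols(scores, Y)
    return CalibrationFit(float(coef[0]), coef[1:], psi, scores, grid)


def select_p_cv(
    Y: np.ndarray,
    vhat: FunctionalSample,
    psi: Basis,
    candidates=(2, 3, 4, 5, 6),
    folds: int = 5,
    seed: int = 0,
    n_repeats: int = 1,
) -> int:
    """Pick the number of ψ-scores by K-fold CV on held-out squared error.

    Ties break toward the smaller p.  ``n_repeats`` > 1 averages the CV
    error over several seeded fold partitions (repeated K-fold); the FPCA
    score spectrum of a finite-rank calibrated regressor decays fast, so
    single-partition selection between adjacent p is noisy and repeating
    stabilizes it.
    """
    cands = sorted(set(int(c) for c in candidates))
    if not cands:
        raise ValueError("candidate list must be nonempty")
    Y = np.asarray(Y, dtype=float).ravel()
    n = Y.size
    if folds < 2 or n < folds:
        raise ValueError("need folds >= 2 and n >= folds")
    full = compute_scores(vhat, psi, max(cands))
    errors = np.zeros(len(cands))
    for rep in range(n_repeats):
        for test in _cv_folds(n, folds, seed + 7919 * rep):
            mask = np.ones(n, dtype=bool)
            mask[test] = False
            for j, p in enumerate(cands):
                cols = full[:, : p + 1]
                try:
                    coef = _ols(cols[mask], Y[mask])
                except np.linalg.LinAlgError:
                    errors[j] += np.inf
                    continue
                resid = Y[test] - cols[test] @ coef
                errors[j] += float(resid @ resid)
    return cands[int(np.argmin(errors))]


def select_p_fve(eigvals, threshold: float = 0.99, p_max: int | None = None) -> int:
    """Number of FPCA components needed to reach a variance-explained fraction.

    The smallest p with Σ_{j≤p} λ_j / Σ_j λ_j ≥ threshold.  A
    response-independent truncation of the calibrated regressor's spectrum:
    it keeps the frugal representation while leaving the significance
    test's null calibration untouched (unlike selection on the response).
    """
    ev = np.asarray(eigvals, dtype=float)
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    tot = ev.sum()
    if tot <= 0:
        raise ValueError("nonpositive eigenvalue total")
    p = int(np.searchsorted(np.cumsum(ev) / tot, threshold) + 1)
    p = min(p, ev.size)
    if p_max is not None:
        p = min(p, int(p_max))
    return p


NAIVE_P_CANDIDATES = tuple(range(2, 15))


def fit_naive(
    Y: np.ndarray,
    W: FunctionalSample,
    basis: Basis | None = None,
    p: int | None = None,
    candidates=NAIVE_P_CANDIDATES,
    folds: int = 5,
    seed: int = 0,
) -> CalibrationFit:
    """Naive estimator: OLS of Y on basis coefficients of the contaminated W.

    Uses the orthonormal Fourier coefficients of Wᵢ(·) by default and the
    same 5-fold CV protocol to choose p when not given.  An intercept column
    is included for comparability with the calibrated fit.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    if basis is None:
        basis = FourierBasis(max(candidates) if p is None else p)
    if p is None:
        p = select_p_cv(Y, W, basis, candidates, folds, seed)
    scores = compute_scores(W, basis, p)
    return fit_calibrated(Y, scores, basis, W.grid)


class CalibratedFunctionalRegressor(RegressorMixin, BaseEstimator):
    """Two-step instrument-calibrated scalar-on-function regression.

    Step 1 regresses the error-prone curves W on the instrument curves Z
    under the concurrent model, giving the calibrated regressor
    V̂(t) = θ̂(t)Z(t).  Step 2 regresses the scalar response on the leading
    FPCA scores of V̂ by ordinary least squares; both basis sizes are picked
    by K-fold cross-validation.

    ``fit(X, y, instrument=Z)`` takes X = W curves and Z as (n, T) arrays on
    a shared equispaced grid.

    Attributes (after fit)
    ----------------------
    q_, p_ : selected basis sizes.
    theta_fun_ : θ̂ evaluated on the grid.
    beta0_, beta_coefs_, beta_fun_ : Step-2 intercept, ψ-coefficients, and
        reconstructed coefficient function β̂(t).
    psi_ : the (empirical FPCA) ψ basis; scores_ : n×(p+1) design.
    """

    def __init__(self, q=None, p=None, q_candidates=(4, 6, 8, 10),
                 p_candidates=(2, 3, 4, 5, 6), theta_basis="bspline",
                 psi_basis="fpca", p_select="fve", fve_threshold=0.99,
                 cv=5, q_cv_repeats=3, q_one_se=True, p_cv_repeats=10,
                 random_state=0, grid=None):
        self.q = q
        self.p = p
        self.q_candidates = q_candidates
        self.p_candidates = p_candidates
        self.theta_basis = theta_basis
        self.psi_basis = psi_basis
        self.p_select = p_select
        self.fve_threshold = fve_threshold
        self.cv = cv
        self.q_cv_repeats = q_cv_repeats
        self.q_one_se = q_one_se
        self.p_cv_repeats = p_cv_repeats
        self.random_state = random_state
        self.grid = grid

    def fit(self, X, y, instrument=None):
        if instrument is None:
            raise ValueError("fit requires instrument curves: fit(W, y, instrument=Z)")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        step1 = ConcurrentRegressor(
            q=self.q, q_candidates=self.q_candidates, basis_kind=self.theta_basis,
            cv=self.cv, cv_repeats=self.q_cv_repeats, one_se=self.q_one_se,
            random_state=self.random_state, grid=self.grid,
        ).fit(instrument, X)
        grid = step1._grid(X)
        vhat = FunctionalSample(grid, step1.transform(instrument))

        if self.psi_basis == "fpca":
            max_p = max(self.p_candidates) if self.p is None else self.p
            psi, eigvals = fpca(vhat, min(max_p, min(vhat.n, grid.size)))
            self.psi_eigenvalues_ = eigvals
        else:
            from .basis import make_basis

            psi = make_basis(self.psi_basis,
                             max(self.p_candidates) if self.p is None else self.p)
        p = self.p
        if p is None:
            if self.p_select == "fve" and self.psi_basis == "fpca":
                p = select_p_fve(self.psi_eigenvalues_, self.fve_threshold,
                                 p_max=max(self.p_candidates))
            else:
                cands = [c for c in self.p_candidates if c <= psi.size]
                p = select_p_cv(y, vhat, psi, cands, folds=self.cv,
                                seed=self.random_state,
                                n_repeats=self.p_cv_repeats)
        scores = compute_scores(vhat, psi, p)
        fit = fit_calibrated(y, scores, psi, grid)

        self.step1_ = step1
        self.q_ = step1.q_
        self.theta_fun_ = step1.theta_fun_
        self.vhat_ = vhat
        self.psi_ = psi
        self.p_ = p
        self.scores_ = scores
        self.beta0_ = fit.beta0
        self.beta_coefs_ = fit.beta_coefs
        self.beta_fun_ = fit.beta_fun
        self.fit_ = fit
        self.y_ = y
        self.grid_ = grid
        return self

    def predict(self, X=None, instrument=None):
        """Predict the response for new instrument curves."""
        Z = instrument if instrument is not None else X
        if Z is None:
            raise ValueError("predict needs instrument curves")
        vhat = FunctionalSample(self.grid_, self.step1_.transform(Z))
        scores = compute_scores(vhat, self.psi_, self.p_)
        return scores @ self.fit_.coef_full

    def significance_test(self):
        """Normalized-χ² test of H₀: β = 0 (see :mod:`funcalib.inference`)."""
        from .inference import gamma_hat, test_statistic

        gamma = gamma_hat(self.scores_, self.y_)
        return test_statistic(self.fit_, gamma, len(self.y_))

    def confidence_band(self, alpha=0.05):
        """Asymptotic (1−α) confidence band for β̂(t)."""
        from .inference import confidence_band, gamma_hat

        gamma = gamma_hat(self.scores_, self.y_)
        return confidence_band(self.fit_, gamma, alpha, self.grid_)


class NaiveFunctionalRegressor(RegressorMixin, BaseEstimator):
    """Scalar-on-function OLS that ignores measurement error.

    Regresses y on the Fourier coefficients of the observed (contaminated)
    curves; the benchmark the calibrated estimator is compared against.
    """

    def __init__(self, p=None, p_candidates=NAIVE_P_CANDIDATES, cv=5,
                 random_state=0, grid=None):
        self.p = p
        self.p_candidates = p_candidates
        self.cv = cv
        self.random_state = random_state
        self.grid = grid

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        from .fdata import make_grid

        grid = make_grid(X.shape[1]) if self.grid is None else np.asarray(self.grid)
        W = FunctionalSample(grid, X)
        fit = fit_naive(y, W, p=self.p, candidates=self.p_candidates,
                        folds=self.cv, seed=self.random_state)
        self.p_ = fit.p
        self.psi_ = fit.psi
        self.scores_ = fit.scores
        self.beta0_ = fit.beta0
        self.beta_coefs_ = fit.beta_coefs
        self.beta_fun_ = fit.beta_fun
        self.fit_ = fit
        self.y_ = y
        self.grid_ = grid
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        W = FunctionalSample(self.grid_, X)
        scores = compute_scores(W, self.psi_, self.p_)
        return scores @ self.fit_.coef_full

    def significance_test(self):
        from .inference import naive_test

        return naive_test(self.fit_, self.scores_[:, 1:], self.y_)


__all__ = [
    "CalibrationFit",
    "CalibratedFunctionalRegressor",
    "NaiveFunctionalRegressor",
    "compute_scores",
    "fit_calibrated",
    "select_p_cv",
    "fit_naive",
]
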