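"""Step 1: concurrent functional regression of the proxy on the instrument.

The contaminated curve W(t) relates to the instrument Z(t) through the
concurrent model E{W(t)|Z(t)} = θ(t) Z(t).  With θ expanded on a basis φ of
size q, the least-squares estimate has the closed form

    θ̂c = [ Σᵢ ∫ Zᵢ²(t) φ(t) φ′(t) dt ]⁻¹ Σᵢ ∫ Wᵢ(t) Zᵢ(t) φ(t) dt,

all integrals by trapezoid quadrature on the shared grid.  The calibrated
regressor is V̂ᵢ(t) = θ̂(t) Zᵢ(t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .basis import Basis, BSplineBasis, make_basis
from .fdata import CoefVector, FunctionalSample, trapezoid_weights

#: condition-number guard for the Step-1 Gram matrix; beyond this the
#: bounded-eigenvalue assumption on Σᵢ∫Zᵢ²φφ′ is considered violated.
MAX_GRAM_CONDITION = 1e10


@dataclass
class ConcurrentFit:
    """Step-1 output: θ̂ coefficients, Gram matrix, and calibrated curves."""

    theta_coefs: CoefVector
    gram: np.ndarray
    vhat: FunctionalSample

    @property
    def q(self) -> int:
        return self.theta_coefs.basis.size

    def theta_fun(self, grid: np.ndarray | None = None) -> np.ndarray:
        g = self.vhat.grid if grid is None else grid
        return self.theta_coefs.reconstruct(g)


def _concurrent_solve(W, Z, Phi, w):
    """Closed-form θ̂c given curve matrices and basis evaluations."""
    szz = np.sum(Z * Z, axis=0) * w          # Σᵢ Zᵢ²(t) · w(t)
    swz = np.sum(W * Z, axis=0) * w          # Σᵢ Wᵢ(t)Zᵢ(t) · w(t)
    gram = Phi.T @ (szz[:, None] * Phi)
    rhs = Phi.T @ swz
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > MAX_GRAM_CONDITION:
        raise np.linalg.LinAlgError(
            f"ill-conditioned concurrent Gram matrix (cond={cond:.2e}); "
            "the instrument may be degenerate"
        )
    return np.linalg.solve(gram, rhs), gram


def fit_concurrent(
    W: FunctionalSample,
    Z: FunctionalSample,
    phi: Basis | None = None,
    q: int | None = None,
) -> ConcurrentFit:
    """Fit the concurrent model W(t) ≈ θ(t) Z(t) by the closed form.

    Parameters
    ----------
    W, Z : functional samples on the same grid with equal n.
    phi : basis for θ (default: cubic B-splines of size ``q``).
    q : basis size when ``phi`` is not given.
    """
    if W.values.shape != Z.values.shape or not np.array_equal(W.grid, Z.grid):
        raise ValueError("W and Z must share grid and sample size")
    if phi is None:
        if q is None:
            raise ValueError("either phi or q must be given")
        phi = BSplineBasis(q)
    elif q is not None and q != phi.size:
        raise ValueError("q must equal phi.size")
    grid = W.grid
    w = trapezoid_weights(grid)
    Phi = phi.evaluate(grid)
    theta_c, gram = _concurrent_solve(W.values, Z.values, Phi, w)
    theta_t = Phi @ theta_c
    vhat = FunctionalSample(grid, Z.values * theta_t[None, :])
    return ConcurrentFit(CoefVector(theta_c, phi), gram, vhat)


def _cv_folds(n: int, folds: int, seed: int):
    """Contiguous blocks after a seeded permutation of subject indices."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return np.array_split(perm, folds)


def select_q_cv(
    W: FunctionalSample,
    Z: FunctionalSample,
    candidates=(4, 6, 8, 10),
    folds: int = 5,
    seed: int = 0,
    basis_kind: str = "bspline",
    n_repeats: int = 1,
    one_se: bool = False,
) -> int:
    """Pick the θ-basis size by K-fold cross-validated prediction error.

    The score for q is the mean held-out quadrature error
    Σᵢ ∫ {Wᵢ(t) − θ̂(t)Zᵢ(t)}² dt; ties break toward the smaller q.
    ``n_repeats`` > 1 averages the CV error over several seeded fold
    partitions before selecting (repeated K-fold).  With ``one_se`` the
    smallest candidate whose error is within one standard error (across
    folds) of the minimum is returned — the usual parsimony-preferring
    variant.
    """
    cands = sorted(set(int(c) for c in candidates))
    if not cands:
        raise ValueError("candidate list must be nonempty")
    if folds < 2 or W.n < folds:
        raise ValueError("need folds >= 2 and n >= folds")
    grid = W.grid
    w = trapezoid_weights(grid)
    fold_err = np.zeros((n_repeats * folds, len(cands)))
    Phis = [make_basis(basis_kind, q).evaluate(grid) for q in cands]
    row = 0
    for rep in range(n_repeats):
        for test in _cv_folds(W.n, folds, seed + 7919 * rep):
            mask = np.ones(W.n, dtype=bool)
            mask[test] = False
            Wtr, Ztr = W.values[mask], Z.values[mask]
            Wte, Zte = W.values[test], Z.values[test]
            for j, Phi in enumerate(Phis):
                theta_c, _ = _concurrent_solve(Wtr, Ztr, Phi, w)
                resid = Wte - Zte * (Phi @ theta_c)[None, :]
                fold_err[row, j] = float(np.sum(resid * resid * w[None, :]))
            row += 1
    errors = fold_err.sum(axis=0)
    best = int(np.argmin(errors))
    if one_se and fold_err.shape[0] > 1:
        se = float(np.std(fold_err[:, best], ddof=1) * np.sqrt(fold_err.shape[0]))
        for j in range(len(cands)):
            if errors[j] <= errors[best] + se:
                return cands[j]
    return cands[best]


def fit_bivariate(
    W: FunctionalSample,
    Z: FunctionalSample,
    phi: Basis,
    psi: Basis,
):
    """Bivariate-kernel alternative to the concurrent model.

    Models X(t) = ∫ α(s,t) Z(s) ds with α(s,t) = Σ_{k,m} α_{km} φ_k(t) ψ_m(s)
    and solves the K·M-parameter least-squares problem
    min Σᵢ ∫ {Wᵢ(t) − α′gᵢ(t)}² dt.

    Returns
    -------
    (alpha, vhat) : the (K, M) coefficient matrix and the fitted curves
        V̂ᵢ(t) = Σ_{k,m} α̂_{km} φ_k(t) ∫ ψ_m(s) Zᵢ(s) ds.
    """
    if W.values.shape != Z.values.shape or not np.array_equal(W.grid, Z.grid):
        raise ValueError("W and Z must share grid and sample size")
    grid = W.grid
    w = trapezoid_weights(grid)
    K, M = phi.size, psi.size
    Phi = phi.evaluate(grid)            # (T, K)
    Psi = psi.evaluate(grid)            # (T, M)
    zpsi = Z.values @ (w[:, None] * Psi)   # (n, M): ∫ ψ_m Zᵢ
    # gᵢ(t) flattened over (k, m): gᵢ[t, k*M+m] = φ_k(t) · zpsiᵢ[m]
    # normal equations: A α = b with
    #   A[(k,m),(k',m')] = Σᵢ ∫ φ_k φ_k' · zpsiᵢ[m] zpsiᵢ[m']
    #   b[(k,m)]         = Σᵢ ∫ Wᵢ φ_k · zpsiᵢ[m]
    phigram = Phi.T @ (w[:, None] * Phi)          # (K, K)
    zz = zpsi.T @ zpsi                             # (M, M)
    A = np.kron(phigram, zz)
    wphi = W.values @ (w[:, None] * Phi)           # (n, K): ∫ Wᵢ φ_k
    b = (wphi.T @ zpsi).reshape(K * M)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > MAX_GRAM_CONDITION:
        raise np.linalg.LinAlgError(
            f"singular bivariate design (cond={cond:.2e}); K·M too large"
        )
    alpha = np.linalg.solve(A, b).reshape(K, M)
    vhat_vals = (zpsi @ alpha.T) @ Phi.T           # (n, T)
    return alpha, FunctionalSample(grid, vhat_vals)


class ConcurrentRegressor(TransformerMixin, BaseEstimator):
    """Concurrent functional regression Ŵ(t) = θ̂(t) Z(t), sklearn-style.

    fit(X, y) takes X = instrument curves and y = proxy curves, both as
    ``(n, T)`` arrays on ``grid`` (default 101 equispaced points on [0,1]).
    ``transform(X)`` calibrates new instrument curves to θ̂(t)·Z(t).

    Parameters
    ----------
    q : basis size for θ, or None to select by cross-validation.
    q_candidates : candidate sizes for CV.
    basis_kind : basis family for θ (default cubic B-splines).
    cv : number of CV folds.
    random_state : seed for the CV permutation.
    """

    def __init__(self, q=None, q_candidates=(4, 6, 8, 10), basis_kind="bspline",
                 cv=5, cv_repeats=3, one_se=True, random_state=0, grid=None):
        self.q = q
        self.q_candidates = q_candidates
        self.basis_kind = basis_kind
        self.cv = cv
        self.cv_repeats = cv_repeats
        self.one_se = one_se
        self.random_state = random_state
        self.grid = grid

    def _grid(self, X):
        from .fdata import make_grid

        return make_grid(X.shape[1]) if self.grid is None else np.asarray(self.grid)

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.atleast_2d(np.asarray(y, dtype=float))
        grid = self._grid(X)
        Z = FunctionalSample(grid, X)
        W = FunctionalSample(grid, y)
        q = self.q
        if q is None:
            q = select_q_cv(W, Z, self.q_candidates, folds=self.cv,
                            seed=self.random_state, basis_kind=self.basis_kind,
                            n_repeats=self.cv_repeats, one_se=self.one_se)
        fit = fit_concurrent(W, Z, make_basis(self.basis_kind, q))
        self.q_ = q
        self.basis_ = fit.theta_coefs.basis
        self.theta_coefs_ = fit.theta_coefs.coefs
        self.theta_fun_ = fit.theta_fun()
        self.gram_ = fit.gram
        self.fit_ = fit
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X * self.theta_fun_[None, :]


__all__ = [
    "ConcurrentFit",
    "ConcurrentRegressor",
    "fit_concurrent",
    "select_q_cv",
    "fit_bivariate",
    "MAX_GRAM_CONDITION",
]
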