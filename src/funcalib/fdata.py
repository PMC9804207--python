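"""Functional samples on a shared grid: quadrature, expansion, smoothing, FPCA.

Curves are stored as rows of an ``(n, T)`` matrix over a common evaluation
grid on [0, 1]; all integrals are trapezoid-rule quadratures on that grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import Basis, BSplineBasis, EmpiricalBasis, make_basis

DEFAULT_GRID_SIZE = 101

# GCV ladder for the roughness penalty in smooth_functional
_PENALTY_LADDER = np.logspace(-8, 2, 21)


def make_grid(num: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    """Equispaced grid of ``num`` points spanning [0, 1]."""
    if num < 2:
        raise ValueError("grid needs at least 2 points")
    return np.linspace(0.0, 1.0, num)


def check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("grid must be a 1-d array with at least 2 points")
    if grid[0] != 0.0 or grid[-1] != 1.0:
        raise ValueError("grid must start at 0 and end at 1")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    return grid


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    """Quadrature weights w with  Σ w_k f(t_k) ≈ ∫₀¹ f."""
    grid = np.asarray(grid, dtype=float)
    d = np.diff(grid)
    w = np.zeros_like(grid)
    w[:-1] += d / 2.0
    w[1:] += d / 2.0
    return w


@dataclass
class FunctionalSample:
    """n curves evaluated on a shared grid (row i = curve i)."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.grid = check_grid(self.grid)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.grid.size:
            raise ValueError("values row length must match grid length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values must be finite")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __len__(self) -> int:
        return self.n


@dataclass
class CoefVector:
    """Coefficients of a single curve in a basis expansion."""

    coefs: np.ndarray
    basis: Basis

    def __post_init__(self):
        self.coefs = np.asarray(self.coefs, dtype=float).ravel()
        if self.coefs.size != self.basis.size:
            raise ValueError("coefficient length must equal basis size")

    def reconstruct(self, grid: np.ndarray) -> np.ndarray:
        return self.basis.evaluate(grid) @ self.coefs


def inner_product(f: np.ndarray, g: np.ndarray, grid: np.ndarray) -> float:
    """Trapezoid approximation of ∫₀¹ f(t) g(t) dt on a shared grid."""
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape[-1] != grid.shape[0] or g.shape[-1] != grid.shape[0]:
        raise ValueError("curves and grid have mismatched lengths")
    w = trapezoid_weights(grid)
    return float(np.sum(w * f * g, axis=-1)) if f.ndim == 1 else np.sum(w * f * g, axis=-1)


def expand(curve: np.ndarray, basis: Basis, grid: np.ndarray) -> CoefVector:
    """Quadrature least-squares projection of a curve onto a basis.

    For an orthonormal basis this coincides with the inner-product
    coefficients ∫ f φ_j; for B-splines and monomials it is the weighted
    least-squares projection minimizing the quadrature L² distance.
    """
    coefs = expand_matrix(np.atleast_2d(curve), basis, grid)[0]
    return CoefVector(coefs, basis)


def expand_matrix(values: np.ndarray, basis: Basis, grid: np.ndarray) -> np.ndarray:
    """Project each row of ``values`` onto ``basis``; returns (n, size)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    B = basis.evaluate(grid)
    w = trapezoid_weights(grid)
    G = B.T @ (w[:, None] * B)
    rhs = B.T @ (w[:, None] * values.T)
    try:
        sol = np.linalg.solve(G, rhs)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular basis projection (basis size exceeds grid resolution?)"
        ) from err
    return sol.T


def reconstruct(coefs: np.ndarray, basis: Basis, grid: np.ndarray) -> np.ndarray:
    """Evaluate Σ_j c_j φ_j(t) on the grid (rows of ``coefs`` = curves)."""
    return np.asarray(coefs, dtype=float) @ basis.evaluate(grid).T


def smooth_functional(
    obs: pd.DataFrame,
    basis: BSplineBasis | None = None,
    penalty: float | None = None,
    grid: np.ndarray | None = None,
) -> FunctionalSample:
    """Penalized least-squares smoothing of discretely observed curves.

    Each subject's (time, value) pairs are fit by minimizing
    Σ_k {y_k − f(t_k)}² + λ ∫ (f″)², with f in a cubic B-spline basis.
    When ``penalty`` is None a single λ shared across subjects is chosen by
    generalized cross-validation over a log-spaced ladder 1e-8 … 1e2.

    Parameters
    ----------
    obs : DataFrame with columns ``id``, ``time``, ``value``; times in [0,1].
    basis : B-spline basis (default: cubic, 15 functions).
    penalty : roughness penalty λ ≥ 0, or None for GCV selection.
    grid : target evaluation grid (default 101 equispaced points).
    """
    required = {"id", "time", "value"}
    if not required.issubset(obs.columns):
        raise ValueError(f"observation table needs columns {sorted(required)}")
    if penalty is not None and penalty < 0:
        raise ValueError("penalty must be nonnegative")
    if grid is None:
        grid = make_grid()
    if basis is None:
        basis = BSplineBasis(15)

    fine = make_grid(401)
    D2 = basis.derivative_matrix(fine, order=2)
    wf = trapezoid_weights(fine)
    P = D2.T @ (wf[:, None] * D2)  # ∫ φ″φ″′

    groups = []
    for sid, sub in obs.groupby("id", sort=True):
        sub = sub.dropna(subset=["time", "value"])
        t = sub["time"].to_numpy(dtype=float)
        y = sub["value"].to_numpy(dtype=float)
        if t.size < 2:
            raise ValueError(f"subject {sid!r} has fewer than 2 observations")
        if t.min() < 0 or t.max() > 1:
            raise ValueError(f"subject {sid!r} has times outside [0, 1]")
        groups.append((sid, basis.evaluate(t), y))

    def _fit_all(lam):
        coefs, rss, tr = [], 0.0, 0.0
        for _, B, y in groups:
            A = B.T @ B + lam * P
            c = np.linalg.solve(A, B.T @ y)
            fitted = B @ c
            rss += float(np.sum((y - fitted) ** 2))
            # tr(H) = tr(B (B'B + λP)^{-1} B')
            tr += float(np.trace(np.linalg.solve(A, B.T @ B)))
            coefs.append(c)
        return np.array(coefs), rss, tr

    if penalty is None:
        n_obs = sum(len(y) for _, _, y in groups)
        best = (np.inf, None)
        for lam in _PENALTY_LADDER:
            try:
                _, rss, tr = _fit_all(lam)
            except np.linalg.LinAlgError:
                continue
            denom = max(n_obs - tr, 1e-8)
            gcv = n_obs * rss / denom**2
            if gcv < best[0]:
                best = (gcv, lam)
        penalty = best[1]
        if penalty is None:
            raise np.linalg.LinAlgError("GCV failed for every penalty on the ladder")

    coefs, _, _ = _fit_all(penalty)
    return FunctionalSample(grid, coefs @ basis.evaluate(grid).T)


def fpca(sample: FunctionalSample, n_components: int):
    """Functional PCA: eigenfunctions of the sample covariance operator.

    Curves are centered at the sample mean; eigenfunctions are orthonormal
    under trapezoid quadrature and eigenvalues are returned in nonincreasing
    order.

    Returns
    -------
    (EmpiricalBasis, eigenvalues)
    """
    n, T = sample.values.shape
    if n < 2:
        raise ValueError("FPCA needs at least 2 curves")
    if n_components < 1 or n_components > min(n, T):
        raise ValueError("n_components must be in [1, min(n, grid length)]")
    w = trapezoid_weights(sample.grid)
    centered = sample.values - sample.values.mean(axis=0)
    cov = centered.T @ centered / n
    sw = np.sqrt(w)
    sym = sw[:, None] * cov * sw[None, :]
    evals, evecs = np.linalg.eigh(sym)
    order = np.argsort(evals)[::-1][:n_components]
    evals = evals[order]
    eigenfuns = evecs[:, order] / sw[:, None]
    # sign convention: make each eigenfunction integrate to a nonnegative value
    signs = np.where(np.sum(w[:, None] * eigenfuns, axis=0) < 0, -1.0, 1.0)
    eigenfuns = eigenfuns * signs
    basis = EmpiricalBasis(sample.grid, eigenfuns)
    return basis, np.clip(evals, 0.0, None)


__all__ = [
    "DEFAULT_GRID_SIZE",
    "FunctionalSample",
    "CoefVector",
    "make_grid",
    "check_grid",
    "trapezoid_weights",
    "inner_product",
    "expand",
    "expand_matrix",
    "reconstruct",
    "smooth_functional",
    "fpca",
    "make_basis",
]
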