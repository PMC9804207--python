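"""Basis systems on the unit interval.

All functional objects in this package live on [0, 1].  A basis is an
ordered family of real functions evaluable on any grid; the four families
used throughout are monomials, the orthonormal Fourier system, cubic
B-splines with equispaced interior knots, and empirical (data-driven)
bases obtained from functional PCA.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline as _SciBSpline


class Basis:
    """Abstract ordered family of real functions on [0, 1]."""

    kind: str = "abstract"

    def __init__(self, size: int):
        size = int(size)
        if size < 1:
            raise ValueError(f"basis size must be >= 1, got {size}")
        self.size = size

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Evaluate all basis functions at ``points``.

        Returns an array of shape ``(len(points), size)``.
        """
        raise NotImplementedError

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.evaluate(points)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{type(self).__name__}(size={self.size})"


class MonomialBasis(Basis):
    """1, t, t², ... on [0, 1]."""

    kind = "monomial"

    def evaluate(self, points):
        t = np.asarray(points, dtype=float)
        return np.vander(t, N=self.size, increasing=True)


class FourierBasis(Basis):
    """Orthonormal Fourier system {1, √2 sin 2πt, √2 cos 2πt, √2 sin 4πt, ...}.

    The system is orthonormal with respect to the L²[0,1] inner product, so
    expansion coefficients are plain inner products.
    """

    kind = "fourier"

    def evaluate(self, points):
        t = np.asarray(points, dtype=float)
        out = np.empty((t.size, self.size))
        out[:, 0] = 1.0
        for j in range(1, self.size):
            k = (j + 1) // 2
            if j % 2 == 1:
                out[:, j] = np.sqrt(2.0) * np.sin(2 * np.pi * k * t)
            else:
                out[:, j] = np.sqrt(2.0) * np.cos(2 * np.pi * k * t)
        return out


class BSplineBasis(Basis):
    """Cubic B-splines with equispaced interior knots on [0, 1].

    ``size`` counts the basis functions; cubic splines require size >= 4
    (size - 4 interior knots).
    """

    kind = "bspline"
    degree = 3

    def __init__(self, size: int):
        super().__init__(size)
        if self.size < self.degree + 1:
            raise ValueError(
                f"cubic B-spline basis needs size >= {self.degree + 1}, got {self.size}"
            )
        n_interior = self.size - (self.degree + 1)
        interior = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
        self.knots = np.concatenate(
            [np.zeros(self.degree + 1), interior, np.ones(self.degree + 1)]
        )

    def evaluate(self, points):
        t = np.clip(np.asarray(points, dtype=float), 0.0, 1.0)
        mat = _SciBSpline.design_matrix(t, self.knots, self.degree,
                                        extrapolate=False).toarray()
        return mat

    def derivative_matrix(self, points, order: int = 2) -> np.ndarray:
        """Evaluate the ``order``-th derivative of each basis function."""
        t = np.clip(np.asarray(points, dtype=float), 0.0, 1.0)
        out = np.empty((t.size, self.size))
        for j in range(self.size):
            c = np.zeros(self.size)
            c[j] = 1.0
            out[:, j] = _SciBSpline(self.knots, c, self.degree)(t, nu=order)
        return out


class EmpiricalBasis(Basis):
    """Basis stored as values on a reference grid (e.g. FPCA eigenfunctions).

    Evaluation off the native grid uses linear interpolation; in practice the
    basis is used on the grid it was built on.
    """

    kind = "empirical"

    def __init__(self, grid: np.ndarray, values: np.ndarray):
        values = np.atleast_2d(np.asarray(values, dtype=float))
        super().__init__(values.shape[1])
        self.grid = np.asarray(grid, dtype=float)
        if self.grid.size != values.shape[0]:
            raise ValueError("grid length does not match stored basis values")
        self.values = values

    def evaluate(self, points):
        t = np.asarray(points, dtype=float)
        if t.size == self.grid.size and np.allclose(t, self.grid):
            return self.values
        return np.column_stack(
            [np.interp(t, self.grid, self.values[:, j]) for j in range(self.size)]
        )


_KINDS = {
    "monomial": MonomialBasis,
    "fourier": FourierBasis,
    "bspline": BSplineBasis,
}


def make_basis(kind: str, size: int, grid=None, values=None) -> Basis:
    """Construct a basis by name.

    Parameters
    ----------
    kind : {"monomial", "fourier", "bspline", "empirical"}
    size : number of basis functions.
    grid, values : required for ``kind="empirical"`` — the reference grid and
        the ``(len(grid), size)`` matrix of stored function values.
    """
    if kind == "empirical":
        if grid is None or values is None:
            raise ValueError("empirical basis requires grid and values")
        b = EmpiricalBasis(grid, values)
        if b.size != size:
            raise ValueError("size does not match provided values")
        return b
    try:
        cls = _KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown basis kind {kind!r}") from None
    return cls(size)
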