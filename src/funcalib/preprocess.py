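"""Data ingestion and pre-model adjustments for user-supplied curve data.

Curves arrive as long-format CSV tables (id, time, value) with time already
rescaled to [0, 1]; scalar responses and error-free covariates arrive as a
per-subject table (id, y, covariate...).  Raw device measurements are first
standardized by a constant so all values are below one in magnitude, and
scalar covariates are removed by regressing them out of the response and
carrying the residuals into the functional fit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .basis import BSplineBasis
from .fdata import FunctionalSample, make_grid, smooth_functional


def standardize(values, constant: float | None = None):
    """Divide by a positive constant so observations are bounded below one.

    If ``constant`` is None, uses max|values| · (1 + 1e-6), which makes every
    output strictly smaller than 1 in magnitude.

    Returns
    -------
    (scaled_values, constant)
    """
    arr = np.asarray(values, dtype=float)
    if constant is None:
        m = float(np.max(np.abs(arr)))
        constant = m * (1 + 1e-6) if m > 0 else 1.0
    if constant <= 0:
        raise ValueError("standardization constant must be positive")
    return arr / constant, float(constant)


def covariate_adjust(Y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residuals of Y after OLS on an intercept plus scalar covariates.

    With no covariates this centers Y.  The residuals, which carry the part
    of the response not explained by the error-free scalar covariates, are
    what the functional regression is fit to.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    n = Y.size
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        design = np.ones((n, 1))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        if covariates.shape[0] != n:
            raise ValueError("covariates do not match the response length")
        design = np.column_stack([np.ones(n), covariates])
    if n <= design.shape[1]:
        raise ValueError("need n > number of covariates + 1")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient covariate design")
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    return Y - design @ coef


def read_curves(
    path,
    grid: np.ndarray | None = None,
    smooth: str = "auto",
    basis_size: int = 15,
    penalty: float | None = None,
) -> tuple[FunctionalSample, np.ndarray]:
    """Read a long-format curve CSV (id, time, value) into a FunctionalSample.

    When every subject is observed exactly on the target grid and
    ``smooth != "always"``, values are pivoted directly; otherwise each
    subject is smoothed onto the grid with penalized B-splines
    (:func:`funcalib.fdata.smooth_functional`).

    Returns
    -------
    (sample, subject_ids) with ids in sorted order.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"id", "time", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"curve CSV {path} needs columns {sorted(required)}")
    if grid is None:
        grid = make_grid()
    ids = np.sort(df["id"].unique())
    if smooth not in {"auto", "always", "never"}:
        raise ValueError("smooth must be auto, always or never")

    def _on_grid() -> bool:
        counts = df.groupby("id")["time"].count()
        if not (counts == grid.size).all():
            return False
        times = df.sort_values(["id", "time"])["time"].to_numpy()
        return np.allclose(times.reshape(len(ids), grid.size), grid[None, :])

    if smooth != "always" and _on_grid():
        wide = df.pivot_table(index="id", columns="time", values="value")
        return FunctionalSample(grid, wide.loc[ids].to_numpy()), ids
    if smooth == "never":
        raise ValueError(
            f"curves in {path} are not on the target grid and smoothing is disabled"
        )
    sample = smooth_functional(df, BSplineBasis(basis_size), penalty, grid)
    return sample, ids


def write_curves(sample: FunctionalSample, path, ids=None) -> None:
    """Write a FunctionalSample as a long CSV at full (round-trip) precision."""
    curves_to_long(sample, ids).to_csv(path, index=False, float_format="%.17g")


def read_scalars(path) -> pd.DataFrame:
    """Read the per-subject scalar table (id, y, covariate...)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "id" not in df.columns or "y" not in df.columns:
        raise ValueError(f"scalar CSV {path} needs columns id and y")
    return df.sort_values("id").reset_index(drop=True)


def curves_to_long(sample: FunctionalSample, ids=None) -> pd.DataFrame:
    """Long-format (id, time, value) table for a FunctionalSample."""
    n, T = sample.values.shape
    if ids is None:
        ids = np.arange(n)
    return pd.DataFrame(
        {
            "id": np.repeat(ids, T),
            "time": np.tile(sample.grid, n),
            "value": sample.values.ravel(),
        }
    )


__all__ = [
    "standardize",
    "covariate_adjust",
    "read_curves",
    "read_scalars",
    "curves_to_long",
]
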