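"""Monte-Carlo data generators and study harness.

The generator follows the simulation design validating the two-step
calibration estimator:

* instruments   Zᵢ(t) = Σ_{j=1}^{k₀} z_{ij} φz_j(t), z_{ij} iid N(0,1),
  φz cubic B-splines, k₀ = 5;
* slope         θ̃(t) = Σ_{j=1}^{q₀} a_j φθ_j(t), a_j = j/q₀, monomials, q₀ = 3;
* coefficient   β̃(t) = Σ_{j=1}^{p₀} b_j φβ_j(t), b_j = 1/j, Fourier, p₀ = 3;
* truth         Xᵢ(t) = θ̃(t)Zᵢ(t) + Uᵢ(t), Uᵢ a standard Brownian motion;
* error process Ũᵢ a zero-mean Gaussian process with squared-exponential
  covariance — Scenario 1: 0.1·exp(−(s−t)²/(2l²)) varies the dependence
  range l; Scenario 2: σ·exp(−(s−t)²/(2·0.05²)) varies the error size σ;
* observed      Wᵢ(t) = Xᵢ(t) + Ũᵢ(t),  Yᵢ = δ∫β̃(t)Xᵢ(t)dt + eᵢ,
  eᵢ iid N(0, 0.1) (variance 0.1); δ = 1 in the estimation study, δ ≥ 0 is
  the effect size in the power study.

The instruments are deliberately unbounded Gaussians, a moderate violation
of the boundedness assumption the asymptotics use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .basis import BSplineBasis, FourierBasis, MonomialBasis
from .calibration import (
    compute_scores,
    fit_calibrated,
    fit_naive,
    select_p_cv,
    select_p_fve,
)
from .fdata import FunctionalSample, fpca, make_grid, trapezoid_weights
from .inference import gamma_hat, naive_test, test_statistic
from .instrument import fit_concurrent, select_q_cv

Q_CANDIDATES = (4, 6, 8, 10)
P_CANDIDATES = (2, 3, 4, 5, 6)
CV_FOLDS = 5
# Step-1 basis size: repeated CV with the one-standard-error parsimony rule
Q_CV_REPEATS = 3
# Step-2 truncation: FPCA components retained by fraction of variance explained
FVE_THRESHOLD = 0.99


@dataclass
class ScenarioConfig:
    """Full specification of one simulated dataset."""

    n: int = 500
    scenario: int = 1
    l: float = 0.05          # Scenario-1 dependence range
    sigma: float = 0.1       # Scenario-2 error variance scale
    delta: float = 1.0       # effect multiplier on ∫β̃X
    k0: int = 5
    q0: int = 3
    p0: int = 3
    e_var: float = 0.1
    grid_size: int = 101
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in (1, 2):
            raise ValueError("scenario must be 1 or 2")
        if self.l <= 0 or self.sigma <= 0 or self.e_var <= 0 or self.delta < 0:
            raise ValueError("l, sigma, e_var must be positive and delta >= 0")

    @property
    def kernel_params(self):
        """(amplitude, length-scale) of the error-process covariance."""
        if self.scenario == 1:
            return 0.1, self.l
        return self.sigma, 0.05


@dataclass
class SimDataset:
    """One simulated draw plus the generating truth."""

    Y: np.ndarray
    W: FunctionalSample
    Z: FunctionalSample
    X: FunctionalSample
    theta_true: np.ndarray
    beta_true: np.ndarray
    config: ScenarioConfig


class _GenCache:
    """Per-configuration fixed quantities shared across replicates."""

    def __init__(self):
        self._store = {}

    def get(self, cfg: ScenarioConfig):
        key = (cfg.grid_size, cfg.k0, cfg.q0, cfg.p0) + cfg.kernel_params
        if key not in self._store:
            grid = make_grid(cfg.grid_size)
            phi_z = BSplineBasis(cfg.k0).evaluate(grid)
            a = np.arange(1, cfg.q0 + 1) / cfg.q0
            theta = MonomialBasis(cfg.q0).evaluate(grid) @ a
            b = 1.0 / np.arange(1, cfg.p0 + 1)
            beta = FourierBasis(cfg.p0).evaluate(grid) @ b
            amp, ls = cfg.kernel_params
            d = grid[:, None] - grid[None, :]
            K = amp * np.exp(-(d**2) / (2.0 * ls**2))
            try:
                # amplitude-relative jitter keeps the σ→0 limit exact
                L = np.linalg.cholesky(K + 1e-9 * amp * np.eye(grid.size))
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    "error-process kernel not positive definite after jitter"
                ) from err
            self._store[key] = (grid, phi_z, theta, beta, L)
        return self._store[key]


_CACHE = _GenCache()


def gen_dataset(cfg: ScenarioConfig) -> SimDataset:
    """Draw one dataset; deterministic given ``cfg.seed``."""
    grid, phi_z, theta, beta, L = _CACHE.get(cfg)
    rng = np.random.default_rng(cfg.seed)
    T = grid.size
    h = np.diff(grid)

    z = rng.standard_normal((cfg.n, cfg.k0))
    Z = z @ phi_z.T
    # Brownian motion: U(0)=0, independent N(0, h) increments
    incr = rng.standard_normal((cfg.n, T - 1)) * np.sqrt(h)[None, :]
    U = np.concatenate([np.zeros((cfg.n, 1)), np.cumsum(incr, axis=1)], axis=1)
    X = theta[None, :] * Z + U
    Utilde = rng.standard_normal((cfg.n, T)) @ L.T
    # the proxy contaminates the systematic part: W = θ̃Z + Ũ; the
    # concurrent-model disturbance U reaches the response through X only
    W = theta[None, :] * Z + Utilde
    w = trapezoid_weights(grid)
    e = rng.standard_normal(cfg.n) * np.sqrt(cfg.e_var)
    Y = cfg.delta * (X @ (w * beta)) + e
    return SimDataset(
        Y=Y,
        W=FunctionalSample(grid, W),
        Z=FunctionalSample(grid, Z),
        X=FunctionalSample(grid, X),
        theta_true=theta,
        beta_true=beta,
        config=cfg,
    )


def estimation_error(est: np.ndarray, truth: np.ndarray, grid: np.ndarray) -> float:
    """Integrated squared error ∫ {â(t) − a(t)}² dt by quadrature."""
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape or est.shape[-1] != grid.shape[0]:
        raise ValueError("curves and grid have mismatched lengths")
    w = trapezoid_weights(grid)
    diff = est - truth
    return float(np.sum(w * diff * diff))


def run_replicate(
    ds: SimDataset,
    seed: int = 0,
    methods=("prop", "naive"),
    alpha: float = 0.05,
    q_candidates=Q_CANDIDATES,
    p_candidates=P_CANDIDATES,
    naive_candidates=None,
    folds: int = CV_FOLDS,
) -> dict:
    """Full pipeline on one dataset: Step 1 → FPCA → Step 2 (+ naive).

    Returns per-replicate ISEs, selected dimensions, and test results.
    """
    grid = ds.W.grid
    out: dict = {"n": ds.config.n}
    if "prop" in methods:
        q = select_q_cv(ds.W, ds.Z, q_candidates, folds=folds, seed=seed,
                        n_repeats=Q_CV_REPEATS, one_se=True)
        step1 = fit_concurrent(ds.W, ds.Z, q=q)
        out["q"] = q
        out["ise_theta"] = estimation_error(step1.theta_fun(), ds.theta_true, grid)
        psi, eigvals = fpca(step1.vhat, max(p_candidates))
        p = select_p_fve(eigvals, FVE_THRESHOLD, p_max=max(p_candidates))
        scores = compute_scores(step1.vhat, psi, p)
        fit = fit_calibrated(ds.Y, scores, psi, grid)
        out["p"] = p
        out["ise_prop"] = estimation_error(fit.beta_fun, ds.beta_true, grid)
        gamma = gamma_hat(scores, ds.Y)
        test = test_statistic(fit, gamma, ds.config.n)
        out["stat_prop"] = test.statistic
        out["reject_prop"] = test.p_value < alpha
        out["_fit_prop"] = fit
        out["_gamma"] = gamma
    if "naive" in methods:
        from .calibration import NAIVE_P_CANDIDATES

        if naive_candidates is None:
            naive_candidates = NAIVE_P_CANDIDATES
        nfit = fit_naive(ds.Y, ds.W, candidates=naive_candidates, folds=folds,
                         seed=seed)
        out["p_naive"] = nfit.p
        out["ise_naive"] = estimation_error(nfit.beta_fun, ds.beta_true, grid)
        ntest = naive_test(nfit, nfit.scores[:, 1:], ds.Y)
        out["stat_naive"] = ntest.statistic
        out["reject_naive"] = ntest.p_value < alpha
    return out


def _mc_se_mean(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def _mc_se_var(x: np.ndarray) -> float:
    """Standard error of the sample variance (moment-based, no normality)."""
    x = np.asarray(x, dtype=float)
    r = x.size
    m = x.mean()
    m4 = np.mean((x - m) ** 4)
    s2 = np.var(x, ddof=1)
    v = (m4 - s2**2 * (r - 3) / (r - 1)) / r
    return float(np.sqrt(max(v, 0.0)))


def _replicate_loop(cfg: ScenarioConfig, replicates: int, seed: int, methods,
                    **kw):
    rows, failures = [], 0
    for r in range(replicates):
        ds = gen_dataset(replace(cfg, seed=seed + r))
        try:
            res = run_replicate(ds, seed=seed + r, methods=methods, **kw)
        except np.linalg.LinAlgError:
            failures += 1
            continue
        res = {k: v for k, v in res.items() if not k.startswith("_")}
        rows.append(res)
    if failures > 0.01 * replicates:
        import warnings

        warnings.warn(f"{failures}/{replicates} replicates failed to fit")
    return pd.DataFrame(rows), failures


def run_estimation_study(
    settings,
    replicates: int = 100,
    seed: int = 0,
    methods=("prop", "naive"),
) -> pd.DataFrame:
    """Estimation-error study over a grid of scenario settings.

    ``settings`` is an iterable of :class:`ScenarioConfig`; replicate r of a
    setting uses seed ``seed + r``.  Returns one row per setting with mean
    and variance of the ISEs, mean selected dimensions, and Monte-Carlo
    standard errors.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    out = []
    for cfg in settings:
        df, failures = _replicate_loop(cfg, replicates, seed, methods)
        row = {
            "n": cfg.n,
            "scenario": cfg.scenario,
            "l": cfg.l,
            "sigma": cfg.sigma,
            "replicates": len(df),
            "failures": failures,
        }
        if "ise_theta" in df:
            row.update(
                theta_err=df["ise_theta"].mean(),
                theta_err_var=df["ise_theta"].var(ddof=1),
                theta_err_mc_se=_mc_se_mean(df["ise_theta"].to_numpy()),
            )
        if "ise_prop" in df:
            x = df["ise_prop"].to_numpy()
            row.update(
                prop=x.mean(), prop_var=np.var(x, ddof=1),
                prop_mc_se=_mc_se_mean(x), prop_var_mc_se=_mc_se_var(x),
                q_bar=df["q"].mean(), p_bar=df["p"].mean(),
            )
        if "ise_naive" in df:
            x = df["ise_naive"].to_numpy()
            row.update(naive=x.mean(), naive_var=np.var(x, ddof=1),
                       naive_mc_se=_mc_se_mean(x))
        out.append(row)
    return pd.DataFrame(out)


def run_power_study(
    n_list,
    delta_list,
    replicates: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    methods=("prop", "naive"),
) -> pd.DataFrame:
    """Rejection frequencies of the calibrated and naive tests at level α.

    Data use the inference-study error kernel 0.1·exp(−(s−t)²/(2·0.05²))
    and Y = δ∫β̃X dt + e; δ = 0 rows give empirical type-I error.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    rows = []
    for n in n_list:
        for delta in delta_list:
            cfg = ScenarioConfig(n=int(n), scenario=2, sigma=0.1, delta=float(delta))
            df, failures = _replicate_loop(cfg, replicates, seed, methods,
                                           alpha=alpha)
            row = {"n": int(n), "delta": float(delta), "alpha": alpha,
                   "replicates": len(df), "failures": failures}
            for m in methods:
                rej = df[f"reject_{m}"].to_numpy(dtype=float)
                row[f"power_{m}"] = rej.mean()
                row[f"power_{m}_mc_se"] = float(
                    np.sqrt(rej.mean() * (1 - rej.mean()) / rej.size)
                )
            rows.append(row)
    return pd.DataFrame(rows)


def run_dimension_study(
    dims,
    n_list,
    replicates: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Estimation error as the parameter dimensions p₀ = q₀ grow with n."""
    settings = [
        ScenarioConfig(n=int(n), scenario=1, l=0.05, sigma=0.1,
                       q0=int(d), p0=int(d))
        for d in dims
        for n in n_list
    ]
    res = run_estimation_study(settings, replicates=replicates, seed=seed,
                               methods=("prop",))
    res["dim"] = [int(d) for d in dims for _ in n_list]
    return res


__all__ = [
    "ScenarioConfig",
    "SimDataset",
    "gen_dataset",
    "estimation_error",
    "run_replicate",
    "run_estimation_study",
    "run_power_study",
    "run_dimension_study",
    "Q_CANDIDATES",
    "P_CANDIDATES",
]
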