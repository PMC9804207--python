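# Methods

## Model

A scalar outcome is linked to a square-integrable functional covariate on
the unit interval by the functional linear model

    Y = β₀ + ∫₀¹ β(t) X(t) dt + e,      E[e] = 0, var(e) = σ²ₑ.

`X(·)` is never observed.  Two functional measurements are available per
subject:

* a **proxy** `W(·)` contaminated by a measurement-error process `Ũ(·)`
  with arbitrary within-curve correlation, and
* an **instrument** `Z(·)` that is error-free, informative about `X(·)`
  through the concurrent model `X(t) = θ(t)Z(t) + U(t)`, and a surrogate
  (independent of `Y` given `X`, and independent of `e`, `U`, `Ũ`).

Under these conditions `E[Y | Z(·)] = β₀ + ∫ β(t) θ(t) Z(t) dt`, so the
unobservable regressor can be replaced by an estimate of its systematic
part `V(t) = θ(t)Z(t)` — classical regression calibration lifted to
function space.

## Two-step estimator

**Step 1 (instrument step).** Expand `θ` on a basis `φ` of size `q`
(cubic B-splines with equispaced interior knots by default) and minimize
`Σᵢ ∫ {Wᵢ(t) − θ′φ(t) Zᵢ(t)}² dt`.  The closed form is

    θ̂c = [ Σᵢ ∫ Zᵢ²(t) φ(t)φ′(t) dt ]⁻¹ Σᵢ ∫ Wᵢ(t) Zᵢ(t) φ(t) dt,

with all integrals by trapezoid quadrature on the shared grid.  The
calibrated regressor is `V̂ᵢ(t) = θ̂(t)Zᵢ(t)`.

**Step 2 (calibration step).** Build the empirical FPCA basis `ψ` of the
`V̂` sample (eigenfunctions of the sample covariance operator, orthonormal
under quadrature), form scores `V̂cᵢ = (1, ⟨V̂ᵢ,ψ₁⟩, …, ⟨V̂ᵢ,ψ_p⟩)′`, and
solve the ordinary least squares problem

    β̂c = ( Σᵢ V̂cᵢ V̂cᵢ′ )⁻¹ Σᵢ Yᵢ V̂cᵢ,      β̂(t) = Σ_{j≤p} β̂_j ψ_j(t).

Both steps are weakly consistent when the truncation dimensions grow
slowly with `n`; the test below additionally assumes the score Gram matrix
has bounded positive eigenvalues.

## Dimension selection

* `q` is chosen by repeated (3×) 5-fold cross-validation of the held-out
  quadrature prediction error `Σᵢ∫{Wᵢ − θ̂Zᵢ}²`, over candidates
  {4, 6, 8, 10}, with the one-standard-error parsimony rule.  Folds are
  contiguous blocks of a seeded permutation; ties break toward smaller q.
* `p` is chosen **response-independently** by truncating the FPCA spectrum
  at a fraction-of-variance-explained threshold (default 0.99, capped at
  6 components).  Selecting `p` by cross-validation on `Y` is available
  (`select_p_cv`, optionally with repeated partitions) but is not the
  default, for two reasons established during development and verified by
  the test suite: (i) when the instrument has finite rank `k₀`, the
  calibrated regressor's spectrum decays abruptly and CV selection between
  adjacent `p` is dominated by partition noise, inflating both the mean
  and the variance of the estimation error; (ii) any selection rule that
  consults the response correlates the retained subspace with the noise
  and visibly inflates the significance test's type-I error (measured at
  ≈0.12 versus the ≈0.05–0.07 obtained with a response-independent rule).
  A variance-explained cut keeps the frugal eigenbasis representation
  without touching the null calibration.
* The naive benchmark regresses `Y` on the orthonormal Fourier
  coefficients of `W` (intercept included) with `p` chosen by plain 5-fold
  CV over {2, …, 14}; the wider ladder reflects that the contaminated
  curves, unlike the finite-rank `V̂`, have a full spectrum.

## Significance test and confidence band

With `Γ̂ = Σᵢ V̂cᵢV̂cᵢ′ / (n · var̂(Y))` and `var̂(Y)` the sample variance of
the response, the statistic

    T̂ = { n β̂′ Γ̂ β̂ − (p+1) } / √{2(p+1)}

is, under `H₀: β = 0`, a normalized χ²₍p+1₎ random variable (the score
matrix whitens the quadratic form and `var(Y) = var(e)` under the null),
hence asymptotically standard normal as the dimension grows.  The p-value
is the upper normal tail: the quadratic form is stochastically larger
under alternatives, so the test is one-sided.  The variance normalization
is essential — without dividing by `var̂(Y)` the quadratic form is scaled
by σ²ₑ·var(Y) and the statistic never leaves the far-left tail.  The same
construction applied to the naive fit, `Tw = {nβ̂′naive Γw β̂naive − p}/√(2p)`
with `Γw = W′W/(n·var̂(Y))` over the coefficient matrix, has a null
distribution that is *not* χ²-calibrated once measurement error and
adaptive dimension selection enter — its type-I inflation is the point of
the comparison.

**Confidence band.** Inverting the normalized quadratic form gives the
ellipsoidal confidence region `(β̂−β)′Γ̂(β̂−β) ≤ c(α)` with
`c(α) = {(p+1) + √(2(p+1))·z₁₋α}/n`.  Applying Cauchy–Schwarz in the
Γ̂-norm to the linear functional `β(t) = ψ̃(t)′β` (with the extended basis
`ψ̃ = (1, ψ₁, …, ψ_p)`) yields the pointwise envelope

    half-width(t) = √{ c(α) · Σ_k ω_k(t)² / λ_k },
    ω_k(t) = Σ_l ψ̃_l(t) e_{kl},

where `(e_k, λ_k)` are the eigenpairs of `Γ̂`.  Because the envelope bounds
the whole ellipsoid direction-by-direction (a Scheffé-type construction),
its pointwise coverage is conservative: the coverage test in the suite
finds essentially full coverage at the 95% level rather than exactly 95%.

## Synthetic data generator

The generator (`funcalib.simulate`) reproduces the validation study's
conditions:

* instruments `Zᵢ(t) = Σ_{j≤k₀} z_{ij} φz_j(t)`, `z_{ij} ~ N(0,1)`, `φz`
  cubic B-splines, `k₀ = 5` — deliberately *unbounded* Gaussians, a
  moderate violation of the boundedness assumption used by the theory;
* slope `θ(t) = Σ_{j≤q₀} (j/q₀) t^{j−1}` (monomials, `q₀ = 3`);
* coefficient `β(t) = Σ_{j≤p₀} (1/j) φβ_j(t)` on the orthonormal Fourier
  system `{1, √2 sin 2πt, √2 cos 2πt, …}`, `p₀ = 3`;
* concurrent disturbance `U` a standard Brownian motion, entering the true
  covariate `X = θZ + U` and hence the response
  `Y = δ∫βX dt + e`, `e ~ N(0, 0.1)` (variance 0.1), `δ = 1` in the
  estimation study and the effect size in the power study;
* error process `Ũ` a zero-mean Gaussian process with squared-exponential
  covariance — Scenario 1: `0.1·exp(−(s−t)²/2l²)` (dependence range `l`),
  Scenario 2: `σ·exp(−(s−t)²/2·0.05²)` (error size σ) — sampled by
  Cholesky with an amplitude-relative jitter (`1e-9·σ`), so the σ→0 limit
  degenerates cleanly;
* proxy `W = θZ + Ũ`: the measurement error contaminates the systematic
  part of the covariate.  Consequently `W − X = Ũ − U`; the Step-1
  residual contains only `Ũ`, which makes the θ-estimation error scale
  linearly in the error amplitude across scenarios.

Everything is drawn on the default grid of 101 equispaced points;
replicate `r` of a study uses seed `base + r`, making studies
embarrassingly parallel and bitwise reproducible.  What the generator does
*not* emulate about real accelerometer data: nonnegativity and
zero-inflation of intensity counts, irregular wear-time and missingness,
survey weighting, and day-to-day within-subject correlation.  Passing the
simulation benchmarks therefore demonstrates correctness of the estimator
and test under the stated stochastic model, not robustness to those
device-data pathologies.

## Numerical choices

* All integrals are trapezoid quadratures (O(h²), exact for piecewise
  linear integrands); basis expansion uses weighted least-squares
  projection, which coincides with plain inner products for orthonormal
  bases.
* The Step-1 Gram matrix is rejected (LinAlgError) when its condition
  number exceeds 1e10 rather than silently regularized — a nearly singular
  Gram signals a degenerate instrument.
* Smoothing of discrete observations minimizes
  `Σ_k {y_k − f(t_k)}² + λ∫(f″)²` on cubic B-splines; a single λ shared
  across subjects is picked by GCV over the ladder 1e-8 … 1e2.
* FPCA solves the symmetrized weighted eigenproblem
  `W^{1/2} Ĉ W^{1/2}`; eigenfunction signs are fixed so each integrates to
  a nonnegative value.
* The intercept-only (`p = 0`) test degenerates to a variance-ratio
  statistic and is permitted.
* The band requires an orthonormal `ψ` and strictly positive `Γ̂`
  eigenvalues; both are checked.

## Known limitations

* **Finite-p null.** At the effective dimension retained here
  (`p + 1 = 5`) the null distribution of T̂ is a normalized χ²₅, which is
  right-skewed: the one-sided level at nominal 0.05 is ≈0.07 in closed
  form, and goodness-of-fit tests against the normal limit will reject at
  a few hundred replicates.  The normal approximation is an asymptotic
  statement in the dimension, not a finite-p identity.
* **Power saturation.** Under the default generator the test's
  noncentrality at moderate effect sizes is already far beyond the
  rejection threshold (e.g. ≈40 at n = 3000, δ = 0.1), so empirical power
  reaches 1.0 well before the theoretical power curve becomes informative.
* **Naive instability under long-range error.** When the error process is
  nearly constant in time (large `l`), the trailing Fourier coefficients
  of `W` have vanishing variance; least squares on them produces wildly
  variable coefficient functions, and cross-validation does not guard
  against this because a near-degenerate regressor costs only ~σ²/n in
  prediction while costing ~1/var(W_j) in function-estimation error.  The
  naive estimator's reported errors in that regime are orders of magnitude
  above the calibrated estimator's — which is the qualitative point, but
  their exact values are highly sensitive to the truncation rule.
* The confidence band is pointwise-conservative by construction (see
  above); it should be read as an envelope, not an exact pointwise
  interval.
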