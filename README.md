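# funcalib

Instrument-based regression calibration for scalar-on-function regression
when the functional covariate is observed with functional measurement error.

## The problem

Wearable devices record a subject's physical-activity intensity as a curve
over the day.  Relating a health outcome `Y` (say, log BMI) to the *true*
intensity profile `X(·)` calls for the functional linear model

    Y = β₀ + ∫₀¹ β(t) X(t) dt + e,

but the device measures only a contaminated curve `W(t) = X(t) + Ũ(t)`,
where the measurement-error process `Ũ(·)` may be correlated across the
whole day.  Regressing `Y` on `W` (the **naive** estimator) gives biased,
erratic estimates of `β(·)`.  Many devices, however, also record a second
functional variable that is essentially error-free and informative about
`X(·)` — step counts.  Treating that curve `Z(·)` as a **functional
instrumental variable** linked to the truth through the concurrent model

    X(t) = θ(t) Z(t) + U(t),

the package estimates `β(·)` by regression calibration in two steps:

1. **Instrument step** — fit `θ(·)` on a B-spline basis by the closed form
   `θ̂c = [Σᵢ ∫ Zᵢ² φφ′]⁻¹ Σᵢ ∫ Wᵢ Zᵢ φ`, and form the calibrated
   regressor `V̂ᵢ(t) = θ̂(t) Zᵢ(t)`.
2. **Calibration step** — regress `Y` by ordinary least squares on the
   leading functional-principal-component scores of `V̂`, and reconstruct
   `β̂(t)`.

Significance of the association is tested with the normalized quadratic
form

    T̂ = { n β̂′ Γ̂ β̂ − (p+1) } / √{2(p+1)},   Γ̂ = Σᵢ V̂cᵢV̂cᵢ′ / (n·var̂(Y)),

which is asymptotically standard normal under `H₀: β(·) = 0`, and an
eigen-decomposition of `Γ̂` yields an asymptotic confidence band for
`β̂(t)`.  A naive counterpart `Tw` built from the contaminated-curve
coefficients is provided as the benchmark whose type-I error inflates under
measurement error.

## Worked example

Simulate a cohort of n = 1000 subjects whose proxy curves carry a heavy,
smoothly-correlated error process (squared-exponential covariance with
variance 1), then fit the calibrated and naive estimators:

```python
import numpy as np
from funcalib import (ScenarioConfig, gen_dataset, estimation_error,
                      CalibratedFunctionalRegressor, NaiveFunctionalRegressor)

ds = gen_dataset(ScenarioConfig(n=1000, scenario=2, sigma=1.0, seed=7))
model = CalibratedFunctionalRegressor(random_state=7).fit(
    ds.W.values, ds.Y, instrument=ds.Z.values)
naive = NaiveFunctionalRegressor(random_state=7).fit(ds.W.values, ds.Y)

print(model.q_, model.p_)
print(estimation_error(model.beta_fun_, ds.beta_true, ds.W.grid))
print(estimation_error(naive.beta_fun_, ds.beta_true, ds.W.grid))
test = model.significance_test()
band = model.confidence_band(0.05)
```

This prints (formatted):

```
selected q = 4, retained FPCA components p = 4
ISE(theta) = 3.98e-04
ISE(beta)  = 0.0846  (calibrated)
ISE(beta)  = 0.4854  (naive)
T-hat = 82.10, p-value = 0.00e+00
beta(0.5): estimate 0.801, 95% band [0.099, 1.503], truth 0.529
```

The calibrated estimator's integrated squared error for `β(·)` is about
six times smaller than the naive one's: the instrument absorbs the
measurement error that biases the direct regression.  The test statistic
T̂ = 82.1 rejects `H₀: β = 0` overwhelmingly (the data were generated with
a real effect), and the pointwise 95% band at mid-day covers the true
coefficient value.

## Command line

The same pipeline runs from the shell on long-format CSV curve tables
(`id,time,value`, time rescaled to [0,1]) plus a per-subject scalar table
(`id,y,covariate…`):

```sh
funcalib simulate --n 1000 --scenario 2 --sigma 1 --seed 7 --out data/
funcalib fit --curves-w data/W.csv --curves-z data/Z.csv \
             --scalars data/scalars.csv --out-dir results/
funcalib study-estimation --scenario 1 --n 500 --n 3000 --l 0.05 --replicates 100
funcalib study-power --n 1000 --n 3000 --delta 0 --delta 0.3
```

`fit` writes `beta.csv` (the coefficient curve), `band.csv` (the confidence
band) and `test.json` (both tests, selected dimensions, config hash and
seed).  Raw measurements can be standardized (`--standardize-constant`) and
scalar covariates regressed out (`--covariate-cols age sex`) before the
functional fit, and off-grid observations are smoothed onto the analysis
grid with second-derivative-penalized B-splines (penalty chosen by GCV).

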