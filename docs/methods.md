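# Methods

Models, parameter defaults and numerical choices implemented in
`bbpcarbon`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## 1. Regression methods

For centered sums S<sub>xx</sub>, S<sub>yy</sub>, S<sub>xy</sub> over n
finite (x, y) pairs (non-finite rows are dropped and counted):

* **OLS (type I):** B = S<sub>xy</sub>/S<sub>xx</sub>, minimizing vertical
  squared residuals. Standard errors follow the classical formulas
  se(B) = √(s²/S<sub>xx</sub>), se(A) = √(s²(1/n + x̄²/S<sub>xx</sub>)) with
  s² = SSE/(n−2).
* **SMA (standardized major axis):** B = sign(r)·s<sub>y</sub>/s<sub>x</sub>,
  equivalently B<sub>SMA</sub> = B<sub>OLS</sub>/|r|. se(B) equals the OLS
  slope standard error; se(A)² = se(B)²·x̄² + s²<sub>res</sub>/n.
* **MA (major axis):** minimizer of perpendicular squared distance,
  B = [(S<sub>yy</sub>−S<sub>xx</sub>) +
  √((S<sub>yy</sub>−S<sub>xx</sub>)² + 4S<sub>xy</sub>²)]/(2S<sub>xy</sub>).
  Standard errors are reported as NaN (no closed form is exposed).
* **RMA (ranged major axis):** MA on range-normalized variables,
  back-transformed by range(y)/range(x); sensitive to outliers by
  construction (the tests verify this).

All four lines pass through the centroid (x̄, ȳ); r and r² are
method-independent. OLS and MA fits are verified against brute-force
Nelder–Mead minimization of their respective loss functions; the SMA/OLS
identity, axis-swap reciprocity (B<sub>SMA</sub>(y,x) =
1/B<sub>SMA</sub>(x,y)) and attenuation inequality
|B<sub>OLS</sub>| ≤ |B<sub>SMA</sub>| are tested exactly.

**Significance gate.** SMA is only meaningful when x and y are genuinely
correlated, so `fit_sma` refuses (raises `NotSignificantError`) when the
two-tailed t-test on r (t = r√(n−2)/√(1−r²), df = n−2, α = 0.05) is not
significant. The gate is on by default and can be disabled explicitly.
Datasets with |r| = 1 are significant but flagged degenerate for MA/RMA
variance formulas.

**Errors-in-variables attenuation.** With noise of variance σ<sub>x</sub>²
on the x axis, E[B<sub>OLS</sub>] = B·Var(x*)/(Var(x*)+σ<sub>x</sub>²).
The benchmark scenario (B = 2, Var(x*) = 1, σ<sub>x</sub> = 0.25,
σ<sub>y</sub> = 0.5) has closed-form attenuated slope 2/1.0625 = 1.8824;
the acceptance suite recovers 1.8824 (OLS) and 2.000 (SMA) to ±0.02 over 50
replicates of n = 10,000.

## 2. Carbon models

* **b<sub>bp,k</sub>** is the intercept of the TChl-a → b<sub>bp</sub>(λ)
  regression. Orientation is enforced (`derive_bbpk` refuses interchanged
  variables by inspecting labels): this is an asymmetric prediction problem,
  so OLS is the suitable method; SMA is computed for comparison. Negative
  intercepts are flagged and warned about, not silently clamped.
* **SF calibration.** SF is chosen so the mean Chl:C ratio,
  mean(TChla/((b<sub>bp</sub>−b<sub>bp,k</sub>)·SF)), equals the target
  0.010. The default statistic is the mean of per-sample ratios
  (SF = mean(TChla/(b<sub>bp</sub>−b<sub>bp,k</sub>))/0.010); ratio-of-means
  is available. Samples with b<sub>bp</sub> ≤ b<sub>bp,k</sub> are excluded
  and counted. One SF per wavelength is shared by both method branches, so
  the pointwise C<sub>phyto</sub> difference between branches is the
  constant Δb<sub>bp,k</sub>·SF — tested to 1e-10 and used for a closed-form
  RPD check to 1e-8.
* **C<sub>phyto</sub>** = (b<sub>bp</sub> − b<sub>bp,k</sub>)·SF; negative
  results can optionally be clamped to zero (off by default; negative-value
  masks are always returned).
* **POC** = B·b<sub>bp</sub> + A, with errors of comparable size on both
  axes; SMA is the suitable method, OLS the comparison.
* The original satellite scaling factor is 13,000 mg C m⁻² at 443 nm.
  Recalibration on match-ups carrying per-sample ratio
  TChla/(b<sub>bp</sub>−b<sub>bp,k</sub>) = 164.55 yields
  SF = 16,455 mg C m⁻² — a whole-percent increase of 26%.

## 3. Profile quality control

* **Despiking.** Residual = profile − running median (5-sample window,
  truncated at the profile ends); threshold = 2 × the 90th quantile
  (linear interpolation) of the signed residuals; points with residual
  above the threshold are removed. Negative excursions are never removed.
  Reference example: values (1,1,1,1,10,1,1,1)×10⁻³ give q90 = 2.7×10⁻³,
  threshold 5.4×10⁻³ and exactly one removal. A non-positive threshold
  (possible only when the majority of residuals are exactly zero, i.e. a
  noise-free record) is treated as a degenerate residual scale and nothing
  is flagged.
* **Binning:** mean of values within ±0.5 m (closed interval) of each
  nominal depth center; empty bins are omitted and counted; idempotent.
* **Dark offset:** uniform subtraction of an averaged dark reading;
  negative results flagged, not dropped.
* **Bottle matching:** nearest profile depth within 0.5 m of each discrete
  bottle depth (400, 200, 150, 80, 70, 60, 50, 40, 30, 20, 10, 5 m);
  ties break toward the shallower sample.

All operations preserve strictly increasing depth order.

## 4. Budgets

Depth integrals are trapezoidal over the requested z-range with **no
extrapolation**: only samples inside the range are used, the realized
bounds are reported, and partial coverage is flagged. Fewer than two
in-range samples gives NaN with a warning. Column budgets are accumulated
across casts by a second trapezoid over cast times (in days).
The comparison statistic is the relative percent difference
RPD = 100·(unsuitable − suitable)/suitable, with the suitable-method result
as the reference; RPD is asymmetric by construction
(rpd(a,b) = −rpd(b,a)·a/b).

## 5. Synthetic generators

All generators are seeded with `numpy.random.default_rng`; derived child
seeds come from `SeedSequence` masked to < 2³¹. The generators emulate the
statistical structure of three platforms, not any specific instrument:

* **Match-ups** (`gen_matchups`): latent x* from a lognormal (field-like
  skew) or normal distribution; independent Gaussian noise on both axes
  (σ<sub>x</sub>, σ<sub>y</sub>); optional positivity via reject-redraw
  (counted) and outlier inflation (counted). Canonical cruise scenario:
  TChl-a → b<sub>bp</sub>(700) with B = 6.1×10⁻³, A = 5.0×10⁻⁴ m⁻¹,
  n = 300. Canonical POC scenario: b<sub>bp</sub>(700) → POC with
  B = 4.0×10⁴ mg m⁻³/m⁻¹, A = 10 mg m⁻³.
* **Float cast series** (`gen_profile_series`): 87 casts at 5.4-day cadence
  on the acquisition grid 0.2 m (0–10 m), 1 m (10–250 m), 10 m (250–1000 m);
  smooth baseline (surface-enhanced decay plus a subsurface maximum at
  45 m, width 20 m) with seasonal modulation, Gaussian noise
  (σ = 5×10⁻⁵ m⁻¹) and positive spikes (rate 1%, amplitudes 5–50× σ,
  recorded in a truth table). The generator does **not** emulate sensor
  drift, missing casts or depth-dependent noise.
* **Gridded monthly series** (`gen_gridded_series`): 219 months of
  TChl-a/b<sub>bp</sub>(443) pairs whose realized r² is calibrated exactly
  to the target 0.56 by root-finding (`scipy.optimize.brentq`) on the noise
  scale; an infeasible target raises.

## 6. Determinism and reporting

One integer seed drives the whole pipeline through `SeedSequence` children.
Reports embed the seed and a SHA-256 hash of the configuration and never
contain wall-clock timestamps; figures are rendered with the Agg backend.
Rerunning the pipeline or `scripts/acceptance.py` with the same seed
reproduces every output file byte for byte (tested).

## 7. Limitations

* Synthetic scenarios are statistical stand-ins; absolute budget RPDs are
  scenario-dependent and should be read as orders of magnitude, not field
  values.
* MA/RMA standard errors are not provided.
* Despiking with truncated edge windows cannot distinguish a spike at the
  first or last sample from a steep gradient as reliably as in the interior.
* No netCDF reader is included; tabular CSV is the exchange format.
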