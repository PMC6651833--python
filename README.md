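# bbpcarbon

Quantifying how the choice of line-fitting method — ordinary least squares
(type I) versus symmetric "model II" regressions — propagates into
particulate-backscattering-based estimates of phytoplankton carbon
(C<sub>phyto</sub>) and particulate organic carbon (POC) in the ocean.

## The problem

Two standard bio-optical carbon models are built from linear regressions on
field match-ups of the particulate backscattering coefficient
b<sub>bp</sub>(λ):

* **C<sub>phyto</sub>** = (b<sub>bp</sub> − b<sub>bp,k</sub>) · SF, where the
  background coefficient b<sub>bp,k</sub> is the *intercept* of a
  TChl-a → b<sub>bp</sub> regression and SF (mg C m⁻²) is a scaling factor
  calibrated so that the implied mean Chl:C ratio equals a target value
  (0.010 by default);
* **POC** = B · b<sub>bp</sub> + A, with B and A taken from a
  b<sub>bp</sub> → POC regression.

Which regression is statistically suitable differs between the two:

* deriving b<sub>bp,k</sub> is an asymmetric prediction problem with a fixed
  dependent variable, for which **OLS** is appropriate;
* the b<sub>bp</sub>↔POC relation has comparable measurement error on both
  axes, for which a symmetric **type II** method (standardized major axis,
  SMA) is appropriate.

Because OLS slopes are attenuated by noise in the x variable
(E[B<sub>OLS</sub>] = B · Var(x*)/(Var(x*) + σ<sub>x</sub>²)) while SMA
slopes are not, swapping methods shifts intercepts, and hence
b<sub>bp,k</sub>, SF, and every downstream carbon budget. This package
implements the regressions, the carbon models, profile quality control,
depth/time budget integration, and synthetic data generators that emulate
the three observing platforms involved (ship casts, profiling floats,
monthly satellite-like series), so the method sensitivity can be measured
end to end.

## Worked example

```python
import numpy as np
from bbpcarbon import BivariateDataset, fit_ols, fit_sma

data = BivariateDataset([1, 2, 3, 4, 5], [2, 3, 5, 4, 6],
                        labels=("tchla", "bbp"))
ols = fit_ols(data)   # B=0.900, A=1.300, r=0.900
sma = fit_sma(data)   # B=1.000, A=1.000 (= B_OLS/|r|)
```

The same fit through the command line:

```bash
bbpcarbon fit --in pairs.csv --out fits.json        # all four methods
bbpcarbon calibrate --in matchups.csv --out params.json
bbpcarbon pipeline --seed 1 --out results/
```

`bbpcarbon pipeline` runs the full synthetic experiment — cruise match-ups →
b<sub>bp,k</sub> and SF under both methods, POC model, despiked float cast
series, 0–250 m and 0–400 m budget comparisons, and a 219-month
satellite-like series — and writes `report.json`, anomaly tables and
figures. Reruns with the same seed are byte-identical, figures included.

Representative quantities with `--seed 1` (synthetic data; values vary with
seed): cruise b<sub>bp,k</sub> = 6.07×10⁻⁴ m⁻¹ (OLS) vs 4.23×10⁻⁴ m⁻¹
(SMA); float-series C<sub>phyto</sub> budget differs by 71% between the two
parameterizations while the POC budget differs by only 0.9%; the
satellite-like C<sub>phyto</sub> series differ by 2.73 mg C m⁻³ on average
(34% of the mean) at r² = 0.56.

## Layout

| Module | Contents |
| --- | --- |
| `bbpcarbon.regression` | OLS, SMA, MA, RMA fits, standard errors, correlation-significance gate |
| `bbpcarbon.carbon` | b<sub>bp,k</sub> derivation, SF calibration, C<sub>phyto</sub>/POC models |
| `bbpcarbon.qc` | despiking, depth binning, dark offset, bottle matching |
| `bbpcarbon.budget` | depth/time trapezoidal integrals, anomaly fields, relative percent difference |
| `bbpcarbon.synthetic` | seeded generators for match-ups, float cast series, gridded monthly series |
| `bbpcarbon.pipeline`, `bbpcarbon.cli` | end-to-end experiment and the `bbpcarbon` command |

See `docs/methods.md` for model details, parameter defaults and numerical
choices.
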