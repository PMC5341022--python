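# tggpp — robustness and uncertainty analysis of the temperature-and-greenness GPP model

`tggpp` is a tested pipeline for probing how far a minimal remote-sensing
model of terrestrial gross primary production (GPP) can be pushed by
parameter calibration alone.  It is aimed at ecosystem modellers who work
with monthly flux-tower GPP and satellite vegetation/temperature products
and want a reproducible harness for sensitivity screening, Bayesian
calibration and skill attribution.

## The model

The temperature-and-greenness (TG) model predicts monthly GPP
(gC m⁻² day⁻¹) from only two satellite quantities — the enhanced vegetation
index (EVI) and land surface temperature (LST, °C):

```
GPP        = m · EVI_scaled · LST_scaled
EVI_scaled = max(EVI − 0.1, 0)
LST_scaled = max( min[ (LST − x_n)/(x_o − x_n), (x_m − LST)/(x_m − x_o) ], 0 )
```

`x_n`, `x_o`, `x_m` are the minimum, optimum and maximum LST for
photosynthesis (defaults 0, 30, 50 °C); the scalar `m` carries the flux
units and is profiled out by origin-constrained least squares.  The
pipeline asks, per plant functional type (PFT):

1. **Which parameters matter?** Morris elementary-effects screening
   (μ*, σ, ranks, interaction flags) of (x_n, x_o, x_m) against the RMSE of
   TG predictions.
2. **What are their posteriors?** Random-walk Metropolis–Hastings with
   uniform box priors (x_n −15–10, x_o 10–40, x_m 40–65 °C) and a Gaussian
   error likelihood, with split-R̂ / running-mean / prior-distance
   convergence verdicts — including an explicit "prior-dominated" verdict
   for parameters the data cannot constrain.
3. **Did calibration help?** Normalized Taylor statistics (R, STD′, RMSD′)
   of the default vs the calibrated model.
4. **What drives GPP where the TG model struggles?** Multiple linear
   regression of GPP on EVI, LST, precipitation and radiation with
   Johnson's relative-weight decomposition of R².

Inputs are monthly site series (CSV: `site_id, pft, date, gpp, evi, lst,
prc, rad, snow_flag`).  A QA screen masks snow-flagged months and months
with LST < −2 °C, and singular spectrum analysis (window 37 months, 6
leading components) smooths EVI and LST.  A seeded synthetic-cohort
generator for all 12 PFTs provides ground-truth data for every stage.

## Worked example

```python
import numpy as np
from tggpp import calibrate_pft, diagnose_convergence
from tggpp.synthdata import recovery_preset, simulate_site

preset = recovery_preset()                 # truth: x_n=-5, x_o=25, x_m=45 °C
site = simulate_site(preset, n_years=10, seed=1)     # 120 months, 15% noise
chain = calibrate_pft(site, n_iter=100_000, seed=2)
summary = diagnose_convergence(chain)
for name in ("x_n", "x_o", "x_m"):
    s = summary.params[name]
    print(f"{name}: mode {s.mode:6.2f}  95% CI ({s.ci_low:6.2f}, {s.ci_high:6.2f})  {s.verdict}")
```

prints

```
x_n: mode  -2.97  95% CI ( -6.16,  -1.23)  converged
x_o: mode  24.39  95% CI ( 23.56,  25.27)  converged
x_m: mode  44.51  95% CI ( 43.98,  45.12)  converged
```

The chain recovers all three generating temperatures (the optimum to within
about 1 °C) because the simulated LST cycle spans the whole response curve.
If LST never approaches the 40–65 °C prior box, the same call reports
`x_m: not-converged/prior-dominated` — the data simply contain no
information about the maximum temperature, and no optimized value should be
read off that posterior.

The full experiment is one command:

```
tggpp run-all --out results_dir --seed 1 --pft EBF --pft GRA --n-iter 50000
```

writing per-stage CSVs (`morris.csv`, `chain_<PFT>.csv`,
`posterior_summary.csv`, `convergence.csv`, `taylor.csv`,
`attribution.csv`, `parameter_table.csv`) into `results_dir`.

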