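# Methods

This note documents the modelling and numerical choices behind `tggpp`:
what each stage computes, the parameters that matter, what the synthetic
data do and do not emulate, and where the design was genuinely open.

## The TG forward model

GPP is modelled as `m · EVI_scaled · LST_scaled` with
`EVI_scaled = max(EVI − 0.1, 0)` and a piecewise-linear temperature
response rising from 0 at the minimum temperature `x_n` to 1 at the
optimum `x_o` and falling back to 0 at the maximum `x_m`
(defaults 0/30/50 °C; units °C throughout):

```
LST_scaled = max( min[ (LST − x_n)/(x_o − x_n), (x_m − LST)/(x_m − x_o) ], 0 )
```

Choices:

* **Lower clamps.** Both scalars are floored at 0 — negative greenness or
  temperature responses are biologically meaningless and GPP must be
  non-negative.  No upper clamp is needed on `LST_scaled`: under the strict
  ordering `x_n < x_o < x_m` the minimum of the two ramps cannot exceed 1.
  With the default parameters the response reduces exactly to
  `min(LST/30, 2.5 − 0.05·LST)` floored at 0, which the tests verify on a
  0.1 °C grid.
* **The scalar m is profiled, not sampled.**  The temperature parameters
  are the scientific unknowns; `m` is a flux-units slope that is
  re-estimated by origin-constrained least squares,
  `m = Σ pᵢgᵢ / Σ pᵢ²` over the scaled product `p`, truncated at 0, for
  every candidate temperature triple.  This keeps the calibration space
  4-dimensional (three temperatures + error scale) and makes every
  screening/calibration statistic a pure function of the temperatures.
  How the slope is set is a package choice; any monotone refit would do,
  and least squares is the one consistent with the Gaussian likelihood.
* **Degenerate orderings are rejected**, never repaired: constructing
  parameters with `x_n ≥ x_o` or `x_o ≥ x_m` raises, and the samplers
  treat such proposals as zero-probability states.

## Preprocessing

Order of operations per site: QA screen → long-gap exclusion → gap fill →
SSA smoothing.  The order is a documented package choice (smoothing after
screening, so contaminated months never leak into the reconstruction).

* **QA screen.** EVI is masked where the snow/ice flag is set or where
  LST < −2.0 °C (strict).  Masked months are excluded from every
  likelihood and statistic downstream; they are never imputed into a fit.
* **Gap handling.** SSA needs a complete series, so masked/missing EVI and
  LST values are bridged: internal gaps of ≤ 3 months linearly
  interpolated, edge gaps by nearest value.  Calendar years containing
  longer runs are masked wholesale and drop out of calibration — a
  pragmatic stand-in for the near-complete-site-year selection used with
  real tower records.
* **SSA.** Window 37 months, 6 leading components by default: the series
  is embedded in the L×K Hankel trajectory matrix, decomposed by SVD,
  truncated, and Hankelized back by anti-diagonal averaging.  With
  `n_components = window` the transform is the identity to numerical
  precision (a test), and a pure seasonal sinusoid occupies two
  eigentriples, so 6 components keep the annual cycle plus slow modulation
  while shedding high-frequency retrieval noise.  Series shorter than
  window + 1 months skip smoothing with a warning rather than failing.

## Morris screening

Parameter influence is ranked with r one-at-a-time trajectories on a
p-level grid over the unit cube (defaults r = 20, p = 8 — conventional
screening sizes, both configurable), mapped affinely onto the ranges
x_n ∈ [−15, 10], x_o ∈ [10, 40], x_m ∈ [40, 65] °C.  The screened output
is the RMSE of TG predictions (with m profiled) against observed GPP over
the pooled per-PFT months — a single fit-quality scalar consistent with
the calibration likelihood.  Conventions:

* grid step Δ = p/(2(p−1)); each parameter moves exactly once per
  trajectory;
* elementary effects are oriented as derivatives (Δf over the *signed*
  coordinate step), so μ* = mean |EE| and σ = SD of the signed EEs;
* an interaction flag marks σ > 2μ*;
* trajectories that would visit an ordering-violating triple in °C are
  rejection-resampled, so the model is never evaluated at invalid
  parameters;
* μ* ties break by declaration order (x_n, x_o, x_m), deterministically.

For additive linear functions μ* equals the absolute coefficient exactly
with σ = 0; the tests also check sampled (μ*, σ) against an exhaustive
enumeration of the finite design population at p = 4.

## Bayesian calibration

Unknowns: (x_n, x_o, x_m, log σ_ε).  Priors: the uniform screening boxes
for the temperatures with the ordering enforced through the prior (−∞
outside), and log σ_ε uniform on [ln 0.01, ln 100] — wide enough to be
uninformative on the flux scale.  Likelihood: independent Gaussian errors
on observed monthly GPP, with m profiled at every step.

Sampling is plain random-walk Metropolis–Hastings, 10⁵ iterations per PFT
by default.  Burn-in is the first 20%.  Proposal scales start at 5% of
each prior range; during burn-in only, per-coordinate scales are
re-estimated every 100 iterations as 2.38/√d times the recent sample
spread and a global factor is nudged to keep acceptance in 20–50%; scales
freeze at the end of burn-in so the retained chain satisfies detailed
balance.  A chain that accepts nothing after burn-in raises a stuck-chain
error.

Convergence verdicts replace the visual density/running-mean checks a
practitioner would apply:

* split-chain R̂ < 1.1 (4 sub-chains; cross-checked against arviz in the
  tests);
* running-mean drift over the last half of the chain < 5% of the prior
  range;
* **prior-dominated detection**: Kolmogorov–Smirnov distance between the
  post-burn-in draws and the uniform prior below 0.35, provided the chain
  is actually mixing (R̂ < 1.5).  The threshold uses a geometric margin: a
  posterior concentrated anywhere inside a uniform prior has KS ≥ 0.5
  from it, while a prior-shaped chain sits near 0; 0.35 therefore cannot
  misflag an identified parameter, yet catches the flat and "gamma-ish"
  near-flat shapes that arise when the data barely touch a parameter's
  range.  A prior-dominated parameter is reported as such — no optimized
  value is quoted for it, and the pipeline's parameter table falls back to
  the default value for that entry.

The "optimized value" is the posterior mode from a Gaussian KDE of the
post-burn-in draws (thinned to ≤ 5000 points, 512-point grid), with
median, mean and the central 95% credible interval alongside.

Identifiability structure worth knowing: when LST never exceeds `x_o`,
the optimum trades off exactly against the profiled `m` (only
`m/(x_o − x_n)` is identified) and `x_o` loses its meaning; when LST never
approaches the 40–65 °C box, `x_m` is prior-dominated.  The synthetic
experiments exploit both regimes deliberately.

## Evaluation

Skill is summarised by normalized Taylor statistics over pooled unmasked
months: Pearson R, model/observation SD ratio, and the *centered*
RMS difference divided by the observation SD.  Centered (bias-removed)
RMSD is required for the diagram identity
`RMSD′² = 1 + STD′² − 2·STD′·R` to hold; the mean bias is reported
separately in observation-SD units.  Per-PFT statistics pool all months
of all sites in the PFT; per-site breakdowns can be computed by passing
single sites.  Default-vs-calibrated comparisons additionally report the
Euclidean distance moved on the Taylor plane.

## Attribution

GPP is regressed on EVI, LST, precipitation and radiation (standardized,
OLS via statsmodels) and the explained variance is split by Johnson's
relative weights: eigendecompose the predictor correlation matrix
R = QΛQᵀ, form the orthogonal counterpart Z = XQΛ^(−1/2)Qᵀ, regress y on
Z, and accumulate squared loadings: ε_j = Σ_k (Λ*_jk)² β_k² with
Λ* = QΛ^(1/2)Qᵀ.  Σ ε_j = R² exactly (asserted to 1e-8), weights are
non-negative, and for orthogonal designs ε_j reduces to the squared
zero-order correlation.  Shares are reported as ε_j/R² × 100 (raw ε also
exported).  Significance per driver is quoted from the MLR t-tests, not
from the weights.  Attribution requires ≥ 30 pooled months.

## Synthetic data

The generator produces structurally realistic monthly site series with
known truth, not geographic realism: sinusoidal LST/EVI seasonal cycles
with mild AR(1) noise, radiation in phase with temperature, log-normal
monthly precipitation, GPP = TG(truth) + optional standardized-anomaly
co-drivers + i.i.d. Gaussian noise (SD = 15% of mean clean GPP by
default), truncated at 0, and snow flags in the three climatologically
coldest months.  Per-PFT presets use each type's published calibrated
temperature parameters as the generating truth (evergreen broadleaf
optimum 15 °C, evergreen needleleaf minimum −10 °C, maximum 50 °C
everywhere) with biome-plausible seasonal climates.

Because the noise is i.i.d. Gaussian — exactly the calibration
likelihood's assumption — parameter recovery is a fair test of the
sampler rather than of robustness to misspecification; an AR(1) noise
switch exists to stress that assumption.  What the generator does *not*
emulate: pixel-footprint mismatch, retrieval artefacts beyond white
noise, drought or disturbance anomalies, cross-site heterogeneity within
a PFT beyond seed variation.  Passing tests therefore demonstrate method
correctness and identifiability structure, not real-world skill.

## Problem sizes

Default experiment sizes were chosen so the full pipeline runs on a
single CPU in minutes: 120-month sites (10 years), 2–3 sites per PFT,
10⁵ MCMC iterations (≈ 4 s per chain), Morris r = 20.  The recovery
experiment uses 10 independent seeds × 10⁵ iterations; the end-to-end
determinism check uses a 2-PFT cohort at 2×10⁴ iterations.

## Known limitations

* Single-chain R̂ (split into sub-chains) can miss multimodality that
  parallel dispersed chains would reveal; `diagnose_convergence` accepts
  chain lists if that matters.
* The KDE mode is grid-resolution limited (range/512) and undefined
  aside from a fallback for degenerate point-mass chains.
* The prior-dominated verdict is binary; posteriors that are informed
  over only part of a parameter's range (KS ≈ 0.35–0.5) can land on
  either side depending on the noise realization.
* Site-year gap screening is a coarse whole-calendar-year mask, not the
  fractional-gap bookkeeping one would apply to real tower records.
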