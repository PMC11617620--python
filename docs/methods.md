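# Methods

This note documents the model implemented by `canopylna`, its
assumptions, the parameters that matter, the synthetic-data generator's
scope, and the numerical choices made where the design was open.

## The layered estimation model

### Agronomic quantities

Per plot and growth stage, the canopy is divided into three equal-height
layers counted from the top (1st upper, 2nd middle, 3rd lower). For each
layer *i*:

- LNC (leaf nitrogen concentration): N mass fraction of leaf dry matter
  (dimensionless; percent accepted on input and converted).
- LDW (leaf dry weight): leaf dry biomass per ground area, g/m².
  Sampled tillers are scaled to ground area by LDW = N·DW/n, where N is
  tiller density (tillers/m²), DW the dry weight of the n sampled
  tillers.
- LNA = LNC · LDW, g N/m².

Aggregates are defined by mass balance, not averaging: for any layer
combination, LDW and LNA add, and the aggregate LNC is LNA/LDW (an
LDW-weighted mean). The 4th stratum is 1st+2nd, the 5th is 2nd+3rd, and
canopy LNA = Σᵢ LNAᵢ exactly — this conservation identity is enforced by
construction and asserted in tests to 1e−9 relative.

### Spectral simulation

Hyperspectral reflectance (strictly increasing wavelength grid, nm) is
convolved with per-band spectral response functions (SRFs) into band
reflectance as the SRF-weighted mean ∫I·SRF / ∫SRF. Default SRFs are
Gaussians at 450/530/570/675/730/850 nm with 10 nm full width at half
maximum, truncated at ±3σ and sampled at 0.5 nm.

Quadrature: both curves are linearly interpolated onto the union of
their wavelength nodes; on each interval the product of the two linear
pieces is quadratic and is integrated in closed form
(h/6·(2I₀w₀ + I₀w₁ + I₁w₀ + 2I₁w₁)). The quadrature is therefore *exact*
for the interpolants, which is what lets the test suite hold it to 1e−6
relative against an independent dense trapezoid oracle; plain
trapezoidal integration of the product on the same grid misses that
tolerance by an order of magnitude or more. A single-node SRF
degenerates to point evaluation; zero overlap between SRF support and
spectrum grid is an error.

View zenith angle (VZA) is metadata: 0° nadir, negative values mark
backward (solar-aligned azimuth) viewing; the set used throughout is
{0°, −30°, −45°}. No bidirectional-reflectance modelling is attempted —
angular effects enter only through the data (or the generator's
visibility weights).

### Vegetation indices

Twelve indices (NDRE, gNDVI, mSR, RD_730, RD_850, RERI_730, CI_rededge,
CI_green, PSSRa, OSAVI, EVI, AIVI) are held in a registry of formula
strings over band symbols B450…B850, parsed once into ASTs and evaluated
by a restricted walker (arithmetic, unary minus, sqrt, numeric
constants; nothing else). Division by zero yields NaN, which downstream
tables flag and exclude with counts rather than silently dropping. The
AIVI implementation maps its two red-edge terms onto the single 730 nm
band available on the six-band sensor and is marked provisional in its
registry description.

### Estimators

All models follow scikit-learn estimator conventions.

- `LayerLinearRegressor`: OLS of layer LNA on one VI at one VZA
  (`slope_`, `intercept_`, `r_`); a zero-variance VI raises a degenerate-
  fit error rather than returning an arbitrary line.
- `LayerRandomForestRegressor`: random forest with ntree = 500,
  mtry = 1 (`max_features=1`), seed-controlled; a 10-fold
  cross-validation RRMSE diagnostic is computed at fit time
  (`cv_folds=0` skips the diagnostic; the fitted forest is identical).
  Forest predictions are means of training targets and hence bounded by
  the training-target range.
- `LayerCanopyLink`: OLS slope/intercept (k, c) relating one stratum's
  LNA to canopy LNA.
- `CompositeCanopyRegressor`: the layer-sum composition
  Σᵢ kᵢ·fᵢ(VIᵢ^(θᵢ)). For linear fᵢ it exposes a closed-form affine map
  (`as_affine()`). Records missing a required feature are skipped and
  counted; negative LNA predictions are flagged, not clipped.

Intercept rule: the composition propagates both the layer-model
intercepts (scaled by k) and the link intercepts c (`sum_links`, the
default), because that is the arithmetic under which single-stratum
canopy rows add consistently — the two-stratum composite intercepts
equal the sums of the corresponding single-stratum ones. A bare
`none` rule (slopes only) is available as a configuration option.

Screening: for a given layer, every (VI, VZA) pair is ranked by maximum
|Pearson R|, ties broken by minimum RRMSE, then lexicographic name
order, so the optimum is deterministic.

Two canopy estimators are compared:

- **LNA_Sum** (stratified): per-layer optimal (VI, VZA) models composed
  through identity links (k=1, c=0 — the three base layers already sum
  to the canopy), or a single multivariate random forest on the three
  selected features.
- **LNA_non** (unstratified baseline): one canopy regression on the best
  single (VI, VZA); the best single angle is reported alongside each
  per-angle fit.

Evaluation uses a 70/30 train/validation plot-stage split stratified by
growth stage × nitrogen treatment, with R² computed as 1 − SSE/SST on
the validation set (it can be negative), RRMSE = 100·RMSE/mean(observed),
and Pearson R.

A `published_registry()` bundles reference coefficients from a
multiangular UAV wheat field study — per-stratum links, canopy-composite
rows, and per-layer red-edge slopes — as ready-to-evaluate objects
tagged `published`, so those models can be run on new data without
refitting.

## The synthetic-data generator

The generator's defaults are the package's study conditions; every
statistical acceptance check runs against them unmodified.

### What it emulates

- Design: 36 plots × 6 growth stages (jointing → mid filling) × 2
  nitrogen treatments, matching a two-treatment field-trial scale.
- Vertical gradient: top-layer LNC 0.045 g/g decaying by factors
  (1, 0.85, 0.65) down the profile, with a stage-wise decline
  (slope 0.08 per stage step) and lognormal plot-level variability
  (`plot_sigma_lnc=0.06`).
- Biomass dynamics: canopy LDW follows a Gaussian-in-stage curve peaking
  at booting/heading (peak stage differs by N treatment), maximum
  220 g/m², split (0.40, 0.35, 0.25) across layers, with lognormal
  plot variability (`plot_sigma_ldw=0.25`). Together with the LNC
  settings this puts canopy LNA on a ~1–10 g/m² span — the working range
  of wheat field campaigns — and per-layer VI fits in the R ≈ 0.85–0.95
  regime. These two calibrations (`ldw_canopy_max`, `noise_sd`) were set
  once, on scale grounds, before the acceptance checks were frozen.
- Angular information: VI^θ = α_v + β_v·sat(Σᵢ wᵢ(θ)·LNAᵢ) + ε with
  visibility weights w(0°)=(0.70, 0.20, 0.10), w(−30°)=(0.25, 0.50,
  0.25), w(−45°)=(0.15, 0.35, 0.50): nadir is dominated by the upper
  layer, −45° by the lower — the premise that gives oblique views their
  value. A diagnostic one-hot visibility (each angle sees exactly one
  layer) makes the planted composite identifiable in closed form and is
  used by the recovery tests.
- Saturation: sat(x) = s·(1 − e^(−x/s)) with s = 8 g/m² applies a mild
  high-biomass compression, the canonical failure mode of ratio indices.
  `sat_scale=None` gives the strictly linear forward model that exact
  recovery requires.
- Noise: ε ~ N(0, noise_sd·β_v) with noise_sd = 0.3, i.e. noise scales
  with each VI's dynamic range.
- Reproducibility: one root seed feeds named substreams
  (profiles / vi / split) via `SeedSequence.spawn`, so each stage is
  independently reproducible and changing one stage's draws cannot
  perturb another's.
- Optionally, vegetation-like hyperspectral curves (chlorophyll-driven
  red edge at ~718 nm, green reflectance bump, LDW-driven NIR plateau)
  driven by the same profiles, to exercise the SRF-convolution path
  end to end.

### What it does not emulate

- No radiative transfer: the VI response is a planted statistical
  relation, not PROSAIL-style physics; visibility weights stand in for
  bidirectional reflectance effects.
- The hyperspectral path reproduces qualitative VI–nitrogen relations
  (signs, monotonicity), not the planted VI table values exactly: a
  smooth physical spectrum family cannot reproduce twelve planted affine
  index responses simultaneously.
- No soil background mixing, atmospheric effects, illumination drift,
  sensor miscalibration, or spatial autocorrelation between plots.
- Measurement error lives only in the VI channel; agronomic sampling
  (LNC, LDW) is treated as exact.

Consequently, passing tests demonstrate that the estimation machinery is
correct and that the layered composite recovers and exploits vertical
structure *when the angular data carry it* — they do not certify
coefficient transferability to real canopies, sensors, or sites.

## Numerical choices and degenerate inputs

- SRF convolution: exact union-grid quadrature (above); SRFs must have
  at least one positive weight; spectrum/SRF grids strictly increasing.
- VI evaluation: restricted AST, NaN on zero division; relative-change
  tables exclude zero-nadir rows and report exclusion counts.
- OLS: `numpy.polyfit` on centered data via the standard least-squares
  path; zero-variance predictors raise; constant targets flag R as
  undefined rather than returning 0.
- Screening tie-breaks: |R| desc → RRMSE asc → name asc (stable sorts).
- Cross-validation: fold count auto-reduces with a warning when n is
  small; a single-member stratum falls into the training split with a
  warning rather than breaking the stratified split.
- LNC plausibility: values outside (0, 0.10) g/g warn (likely
  percent/fraction confusion) but do not error.
- Rounding: composed published coefficients are reported to two decimals
  only at the reporting boundary; all internal arithmetic is double
  precision.

## Problem sizes used by the test suite

Chosen as the package's own working sizes: unit tests use 8–24 plots;
the planted-recovery coverage check runs 100 replicates of 34 plots
(≈200 plot-stage records each) against a 1500-plot large-sample
reference; the estimator-ordering check runs 50 seeded replicates of the
full 36-plot default design for both linear and random-forest variants.
The complete suite runs in a few minutes on one CPU.

## Known limitations

- The link coefficients kᵢ are study-specific regression slopes; on new
  data they should be re-estimated, and the identity-link sum is the
  safer default when all three base layers are modelled.
- Classical OLS standard errors mildly undercover the layer-to-canopy
  link slopes under the generator's lognormal plot heterogeneity
  (heteroskedastic residuals); the recovery tests therefore state
  coverage per quantity, which is the well-defined sampling-theory
  claim.
- The random-forest composite has no advantage over the linear composite
  on the generator's near-linear response surface; it is provided for
  parity and for data with real nonlinearity.
- AIVI's band mapping onto a single red-edge band is provisional
  (see its registry description).
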