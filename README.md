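# canopylna

Estimation of wheat canopy leaf nitrogen accumulation (LNA, g N per m²
ground) from multiangular multispectral reflectance, with explicit
treatment of the canopy's vertical nitrogen gradient.

## The problem

Leaf nitrogen in a wheat canopy is not vertically uniform: upper leaves
are younger and nitrogen-rich, lower leaves senesce first. A nadir-viewing
sensor sees mostly the upper third of the canopy, so a single nadir
vegetation-index (VI) regression systematically under-uses the information
that oblique views carry about the middle and lower strata. This package
implements a layered estimator for agronomists and remote-sensing
researchers working with multiangular UAV or field-spectrometer data:

1. Stratify the canopy into three equal-height layers (1st = upper,
   2nd = middle, 3rd = lower, counted from the top). Per-layer
   LNAᵢ = LNCᵢ · LDWᵢ (nitrogen mass fraction × leaf dry weight per
   ground area), and canopy LNA = Σᵢ LNAᵢ exactly.
2. For each layer, screen all (VI, view-zenith-angle) pairs and fit the
   per-layer regression LNAᵢ = aᵢ · VI^(θᵢ) + bᵢ at that layer's optimal
   angle θᵢ (nadir 0° for the upper layer; −30°/−45° backward-oblique
   views for the middle and lower layers).
3. Relate each layer to the whole canopy through a link
   LNA_canopy = kᵢ · LNAᵢ + cᵢ, and compose the canopy estimator

   LNA_Sum = Σᵢ kᵢ · fᵢ(VI^(θᵢ))  (+ propagated intercepts),

   which stays affine for linear fᵢ and is also available with a single
   multivariate random forest on the three selected (VI, θ) features.

The package covers the full chain: agronomic bookkeeping, spectral-
response-function (SRF) convolution of hyperspectral curves into the six
sensor bands (450/530/570/675/730/850 nm, 10 nm FWHM), a registry of 12
vegetation indices, screening, layered and unstratified estimators,
evaluation metrics (R², RRMSE, Pearson R), a synthetic-canopy generator
with planted vertical structure, and a `canopylna` command-line interface.
Estimators follow scikit-learn conventions (`fit`/`predict`,
`get_params`, fitted attributes with trailing underscores) and compose
with sklearn tooling.

## Worked example

Generate a synthetic multiangular dataset with a planted vertical
nitrogen gradient, then compare the layered composite (`LNA_Sum`) against
the best single-angle canopy regression (`LNA_non`) on a held-out 30%
validation split:

```python
from canopylna.synthetic import SynthConfig, generate_dataset
from canopylna.pipeline import run_comparison

config = SynthConfig(n_plots=24, seed=7, vi_names=("NDRE", "RERI_730", "EVI"))
frame, vi_table, truth = generate_dataset(config)
reports = run_comparison(frame, vi_table, split_seed=7, model_kinds=("linear",))
for label in ("LR-LNA_Sum", "LR-LNA_non"):
    r = reports[label]
    print(f"{label}:  R2 = {r.r2:.3f}   RRMSE = {r.rrmse_pct:.1f}%   (n = {r.n})")
```

Output:

```
LR-LNA_Sum:  R2 = 0.912   RRMSE = 16.3%   (n = 48)
LR-LNA_non:  R2 = 0.830   RRMSE = 22.7%   (n = 48)
```

`LR-LNA_Sum` is the composed three-layer linear model; `LR-LNA_non` is
the best single-angle unstratified regression. On data where oblique
angles carry middle/lower-layer information, the layered composite cuts
the relative RMSE (here 16.3% vs 22.7% of mean observed canopy LNA over
the 48 validation records). The same comparison runs from the shell:

```bash
canopylna simulate --seed 7 --n-plots 24 --out runs/sim
canopylna report --profiles runs/sim/profiles.csv \
    --vi-table runs/sim/vi_table.csv --seed 7 --out runs/report
```

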