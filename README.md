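# meatwhc

Chemometric prediction of pork water-holding capacity (WHC) from
T2-weighted MRI, with a synthetic phantom generator so the whole
modeling chain is testable end to end without scanner data.

## The problem

Repeated freeze–thaw cycles damage pork muscle microstructure: ice
crystals rupture cell membranes, bound and immobilized water migrate to
free water, and the meat's ability to hold water under pressure drops.
Pressing loss — the percentage of mass expelled when a meat cylinder is
pressed under constant load — is a standard destructive WHC assay. In
T2-weighted MRI, water-rich tissue gives high signal, so the pixel
intensities of a muscle cross-section carry the same information
nondestructively. This package models pressing loss (%) from the raw
pixel matrix of one selected slice per sample.

The modeling chain:

1. **Phantoms** (`meatwhc.phantom`): multi-slice scans of an elliptical
   muscle section whose expected interior intensity is
   `base_signal · max(0, 1 − signal_decay · ft_level)` for freeze–thaw
   severity `ft_level`, with additive Gaussian pixel noise clipped at 0,
   a smooth within-muscle intensity gradient, and some slices
   deliberately clipped by the field of view. The pressing-loss response
   is affine in the noise-free masked mean intensity plus noise.
   Group-level quality tables (texture profile, shear force, drip /
   cooking / pressing loss) are drawn around published group means.
2. **Slice selection** (`meatwhc.imaging`): DICOM slices are read
   losslessly; the foreground (≥ 20% of slice max) is labeled into
   8-connected components, slices whose largest component touches the
   border are rejected, and the largest complete slice is kept.
3. **Dataset** (`meatwhc.dataset`): selected slices are flattened
   row-major into an `n × p` matrix (`p = image_size²`), mean-centered,
   and split once 8:2 into calibration/validation.
4. **Models** (`meatwhc.chemometrics`): principal component regression
   (PCR) with the component count chosen at ≥ 95% cumulative explained
   variance, and NIPALS partial least squares regression (PLSR) with the
   number of latent variables chosen by Monte-Carlo cross-validation
   (8:2 splits repeated 1000 times; order with minimum mean held-out
   RMSE).
5. **Evaluation** (`meatwhc.evaluation`):
   `R² = 1 − Σ(y_act − y_pre)² / Σ(y_act − ȳ)²`,
   `RMSE = √(Σ(y_act − y_pre)²/N)` on each set (RMSEC / RMSEP),
   residuals `Res = y_act − y_pre` standardized by the
   calibration-residual standard deviation, and predictive-quality
   bands (high > 0.90, good 0.81–0.90, moderate 0.66–0.81, poor below).

## Worked example

```python
from meatwhc import RunConfig, run_study, relative_reduction

# pressing loss drops from 42.23% (fresh) to 28.99% (10 freeze-thaw cycles)
print(round(relative_reduction(42.23, 28.99), 2))   # 31.35  -> "about 31%"

cfg = RunConfig(seed=1, out_dir="study_out")        # 60 samples, 64x64 phantoms
res = run_study(cfg)
print(res.n_components, round(100 * res.cumulative_contribution, 2))
print(res.chosen_lv)
print(round(res.pls_metrics.r2_val, 4), round(res.pls_metrics.rmsep, 4))
```

prints

```
31.35
3 95.67
1
0.9591 1.1051
```

meaning: 3 principal components reach 95.67% cumulative variance,
Monte-Carlo cross-validation selects 1 latent variable (the phantom's
response is driven by a single latent factor — the freeze–thaw
intensity scale), and the PLSR model predicts held-out pressing loss
with R² = 0.9591 and RMSEP = 1.11 percentage points. `study_out/`
receives `metrics.json`, `manifest.json` (all seeds and parameters),
the RMSE-vs-order curve and the residual table; identical
configurations reproduce these files byte for byte.

The same study runs from the shell:

```sh
meatwhc run --seed 1 --out study_out
meatwhc generate --n-per-group 2 --ft-levels 0,10 --out cohort/   # DICOM phantoms
meatwhc select --in cohort/ --report selection.csv
```

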