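# Methods

## Phantom model

Each synthetic sample emulates one T2-weighted multi-slice scan of a
pork longissimus cross-section plus its pressing-loss measurement.

**Geometry.** The muscle is an ellipse (default semi-axes 0.36 and 0.28
of the image side, centered) on a zero background, `n_slices = 4`
slices per sample, default 256×256 pixels (the studies this package
targets use 64×64 in tests and the reference study for speed; the model
is resolution-independent). A configurable fraction of slices
(`clip_fraction`, default 0.25) is drawn with the ellipse shifted past
the top border, emulating slices whose contour is cut off by the field
of view; when `clip_fraction < 1` at least one slice is always
complete, so slice selection always has a valid candidate.

**Signal.** Freeze–thaw severity `ft_level` (0 = fresh) reduces the
expected interior intensity multiplicatively:

    E[interior] = base_signal · max(0, 1 − signal_decay · ft_level)

with `base_signal = 1000` intensity units and `signal_decay = 0.05`
per cycle, so 0/3/5/10 freeze–thaw cycles give interior means of
1000/850/750/500. This is phenomenological: no TR/TE relaxation
equation is modeled, only the monotone water-signal loss that
freeze–thaw damage produces. Additive Gaussian pixel noise
(`noise_sd`, default 30 ≈ 3% of base signal) is clipped at zero; a
clipped Gaussian rather than a Rician is used because the downstream
chemometrics is distribution-agnostic and the clipped model keeps
every closed form exact at `noise_sd = 0`.

**Texture.** A smooth low-order polynomial gradient (random per-sample
combination of the `u`, `v` and `u·v` fields, amplitude 5% of the
decayed base signal) is added inside the ellipse so the pixel matrix
has more than one informative principal direction. The gradient is
zero-meaned over the ellipse mask, which keeps the masked mean — and
hence the response coupling — exactly at its closed-form value.

**Response.** Pressing loss is affine in the *noise-free* masked mean
intensity µ:

    PL = response_intercept + response_slope · µ + N(0, response_noise_sd), clipped to [0, 100]

Defaults `intercept = 15.75`, `slope = 0.02648`, `response_noise_sd =
1.0` map the fresh and 10-cycle interior means (1000 and 500) onto
pressing losses of 42.23% and 28.99%, the published endpoints. The
slope is positive — lower signal (more freeze–thaw damage) means lower
pressing loss — matching the observed direction of the pressing-loss
assay. Because µ is noise-free, the signal-to-response coupling is
exactly linear and identifiable: with both noise terms at zero, a
two-parameter fit of response on µ has zero residual.

**Quality tables.** `simulate_quality_table` draws replicate records
around per-group means (moisture, drip/cooking/pressing loss, texture
profile, shear force) with standard deviation `cv · mean`. The texture
rows and the pressing-loss and shear-force endpoints are published
group means; intermediate moisture/drip/cooking/shear values are not
published numerically and were set once to follow the published trends
(moisture decreasing, drip increasing, cooking loss rising then
falling, shear force decreasing). Negative draws are clipped at zero
and counted in a warning.

**Seeding.** One master seed; per-sample seeds are
`(master · 1000003 + 7919 · i) mod 2³¹`, so cohorts are bit-reproducible
and extending a cohort never reshuffles existing samples.

## Slice selection

The field practice of picking "one clear, complete slice" per sample
is formalized: foreground = pixels at or above `threshold_fraction`
(default 0.2) of the slice maximum; 8-connected components are labeled;
a slice qualifies when its largest component does not meet the first or
last row/column; among qualifying slices the largest component wins,
ties to the lowest slice index. If no slice qualifies the highest
completeness score (largest component's share of all foreground pixels)
wins and the sample is flagged for manual review. The 0.2 threshold
separates the background noise floor from muscle signal at the default
noise level. DICOM reading preserves stored values exactly; a
non-identity rescale slope/intercept is applied with a warning.

## Preprocessing

Pixel columns and the response are mean-centered only. All pixels share
one intensity unit, so unit-variance autoscaling would inflate
background-noise pixels relative to tissue; it is deliberately not
offered as a default. Flattening is row-major so model coefficients can
be reshaped back into pixel maps for inspection.

## Models

**PCA** is computed by the economy SVD of the centered matrix — never
the p×p covariance, since p = image_size² ≫ n. Explained ratios are
σ²ⱼ/Σσ²; singular values below 1e−12 of the largest are treated as rank
deficiency and dropped. The PCR component count is the smallest k whose
cumulative ratio reaches the threshold (default 0.95); because scores
are orthogonal the regression on scores decouples into per-component
coefficients.

**PLSR** is classical univariate-response NIPALS with X- and
y-deflation: `w ∝ X'y`, `t = Xw`, `p = X't/(t't)`, `q = y't/(t't)`,
`X ← X − tp'`, `y ← y − qt`; the collapsed regression vector is
`β = W(P'W)⁻¹q`. For a single response the inner iteration converges in
one step, so `tol`/`max_iter` (1e−10, 500) only guard a future
multivariate extension. At full rank PCR, PLSR and ordinary least
squares coincide (verified to 1e−8), and NIPALS coefficients match an
independent SIMPLS implementation to 1e−6.

**Order selection** is Monte-Carlo cross-validation: 8:2 random splits
(default 1000), PLS fitted at every candidate order on the calibration
part, held-out RMSE averaged per order across splits (mean of per-split
RMSEs, not pooled residuals), argmin wins with ties to the smaller
order. Per-split seeds are master + fixed increment. Orders beyond a
split's extractable capacity reuse the largest extractable fit, with a
warning.

**Reported metrics** come from one fixed seeded 8:2 holdout (same ratio
as the cross-validation), not from pooled cross-validation predictions.
R² uses the evaluated set's own mean in the denominator. Validation
residuals are standardized by the calibration-residual standard
deviation (ddof = 1); the model is flagged reliable only if every
standardized residual is strictly below 1 in magnitude. Quality bands:
high for R² > 0.90, good for 0.81 ≤ R² ≤ 0.90, moderate for 0.66 ≤ R²
< 0.81 (the nominally undefined sliver (0.80, 0.81) is assigned to
moderate for continuity), poor below 0.66.

## Reference study scale

The packaged study runs 60 samples (15 per freeze–thaw level
0/3/5/10), 64×64 phantoms, 1000-split cross-validation with up to 15
latent variables. Cohort-level test suites use 50 master seeds with
200-split (recovery) or 100-split (model comparison) cross-validation.
These sizes keep a full run in seconds on one core while leaving the
calibration rank (47) well above every candidate model order.

## What the phantoms do and do not show

The phantom's response is driven by a single latent factor — the
freeze–thaw intensity scale. Tests passing on phantoms therefore
demonstrate that the pipeline recovers a known planted signal, selects
complete slices correctly, and that the from-scratch solvers agree with
independent references; they do not demonstrate performance on real
scans, where water-relevant variance is spread over many image
directions, muscle geometry varies between animals, and intensity is
not calibrated across sessions.

Two consequences are worth stating plainly:

- Because the response couples to the masked mean intensity, the
  response-relevant direction is essentially the first principal
  component. PCR at the 95% variance cut therefore already contains the
  full signal and performs on par with PLSR on phantoms — the clear
  PLSR-over-PCR advantage seen on real scans, where relevant variance
  is dispersed across many components, cannot emerge from this
  generator. The model-comparison suite measures roughly a 50/50 split
  between the two models rather than PLSR dominance.
- At low pixel noise the cross-validated RMSE curve is nearly flat in
  the model order: components beyond the first genuinely cancel
  projection noise in the leading score, so the RMSE-optimal order can
  exceed the structural dimension. Plain argmin order selection (no
  parsimony or one-standard-error rule, by design) then occasionally
  picks 3–6 latent variables for a rank-1 signal. This mirrors real
  chemometric practice, where optimal orders routinely exceed the
  number of chemically interpretable factors.

## Other limitations

- No physical relaxation modeling, no drip/cooking-loss time courses,
  no texture-feature engineering, no multivariate-response PLS2,
  no variable selection (VIP, sparsity), no susceptibility-artifact
  detection beyond contour completeness.
- ANOVA / multiple-range / correlation statistics on the quality tables
  are out of scope; the tables export as CSV for external tools.
- The DICOM writer emits minimal secondary-capture files (16-bit
  unsigned, no rescale); it is for phantoms and round-trip testing, not
  a general-purpose exporter.
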