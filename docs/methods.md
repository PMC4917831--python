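# Methods

## The measurement problem

Acute branch retinal vein occlusion produces retinal hemorrhages whose
shape carries diagnostic information: hemorrhage confined to the
nerve-fiber layer is striate ("flame-shaped") because blood tracks the
axon bundles, while hemorrhage in deeper layers is rounded ("dot/blot").
Flame-shaped hemorrhage at the posterior pole accompanies a perfused
macula; dot/blot hemorrhage frequently accompanies macular capillary
dropout, which otherwise requires fluorescein angiography to detect.
The package turns that qualitative impression into a bounded score on an
ordinary color fundus photograph and provides the cohort statistics used
to evaluate it as a diagnostic marker.

## Image chain

1. **Green channel.** Hemoglobin absorbs green light strongly, so the
   green plane of the RGB photograph carries the hemorrhage contrast.
   The plane is used as unchanged 8-bit values.
2. **ROI.** A 200 × 200 px window, supplied by the caller (on real
   photographs it is placed between the fovea and the affected arcade);
   automatic landmark detection is out of scope. Coordinates are 0-based,
   row-major, half-open; out-of-bounds ROIs raise rather than clamp.
3. **Band-pass 4–5 px.** Implemented as a difference of Gaussians whose
   FWHMs are the two scales (σ = FWHM / 2.3548), reflection padding.
   The filter is linear and exactly zero on constant input. The 4–5 px
   pass band selects streak-width texture and suppresses both pixel noise
   and slow illumination gradients.
4. **Otsu binarization, both polarities.** The real-valued response is
   min–max rescaled to 256 integer levels (Otsu's criterion operates on a
   histogram); pixels strictly above the between-class-variance-maximizing
   threshold are "on". The *negated* response yields the dark hemorrhage
   streaks, the positive response the bright hemorrhage-sparse
   (nerve-fiber) streaks. By linearity, inverting the ROI intensities
   swaps the two masks exactly. Constant planes raise a degenerate-
   histogram error.
5. **Skeletonization.** scikit-image's `skeletonize` (the Zhang–Suen
   two-subiteration family with staircase removal) thins each mask to
   unit-width curves; the algorithm is pinned here for reproducibility.
   Skeletons are idempotent fixed points and contain no solid 3 × 3
   block. No morphological cleanup is applied before or after thinning.

## The score

Every unordered pair of 8-adjacent skeleton pixels is assigned an
orientation from its connecting vector — 0°, 45°, 90°, 135° with respect
to the horizon (rows grow downward, so "up-right" is 45°). With counts
n₀, n₄₅, n₉₀, n₁₃₅,

P = √((n₀ − n₉₀)² + (n₄₅ − n₁₃₅)²) / Σn.

This is the orientation order parameter on the doubled angle, restricted
to four bins: the two differences are the components of the mean
resultant of 2θ over the pair population. P = 1 iff all pairs share one
orientation; P = 0 for equal counts. Diagonal pairs are *not* weighted by
√2 — raw pair counts are used. An empty skeleton raises an
undefined-score error rather than returning 0, because 0 asserts isotropy
of existing segments. The per-ROI score averages the hemorrhage and
hemorrhage-sparse skeleton scores, on the grounds that both the
hemorrhage itself and the spared nerve-fiber texture between streaks
carry the orientation signal.

The four-bin order parameter is the single largest modeling assumption in
the package; it is the unique standard statistic consistent with the
score's documented properties (range [0, 1], 1 for perfectly parallel
segments, built from exactly these four pair counts). It is isolated in
`parallelism_from_counts` so any refinement is a one-line change.

## Synthetic data

The generator emulates the two hemorrhage morphologies directly at ROI
scale on a fundus-colored background (8-bit RGB ≈ (185, 120, 45), with
hemorrhage attenuating green fully, blue moderately, red weakly, so the
green plane has maximal contrast):

* **Streak ROIs** (flame): `n_segments` = 70 dark capsules (width 3 px,
  length 70 ± 25 px) plus half as many brighter, slightly wider capsules
  (the nerve-fiber texture). Orientations are axial von Mises: 2θ ~
  vM(2·dominant, κ). κ = 0 is the isotropic control; κ ≈ 8 is a strongly
  oriented flame texture. Hemorrhage darkness multiplies green by 0.55;
  Gaussian pixel noise σ = 4.
* **Blob ROIs** (dot/blot): ellipses (radius 6 ± 2 px, eccentricity ≤
  0.6) with uniformly random orientation — no preferred direction by
  construction, which caps the attainable parallelism of blob textures.

Determinism: every image is a pure function of (params, size, seed). A
cohort derives the i-th eye's 31-bit image seed from the root seed's
`SeedSequence` state stream, so any single eye can be regenerated
without the rest.

**Calibration.** The pipeline's filters make a closed-form dial-to-score
map impractical, so a Monte-Carlo table (`data/calibration.json`, 100
replicates per grid point, built by `scripts/build_calibration.py`) maps
streak κ ∈ [0, 64] to mean pipeline score ≈ [0.05, 0.66] and blob count
∈ [3, 80] to ≈ [0.11, 0.03]. `generate_cohort` draws a per-eye target
score from the group's (mean, SD) — defaults 0.333 ± 0.110 for flame,
0.122 ± 0.067 for non-flame — and inverts the table by interpolation.
Because isotropic blobs cannot exceed ≈ 0.11 on average, non-flame
targets above that are clipped; realized blot group means land near
0.09–0.10, within ±0.05 of the 0.122 target, with the spread partly
supplied by per-image sampling noise.

**Cohort labels.** Defaults emulate a 58-eye cohort: 39/58 flame, zero
ischemic maculas among flame eyes, 13/19 ischemic among non-flame eyes.
`allocation="expected"` assigns the largest-remainder rounding of the
expected counts (reproducing a printed 2 × 2 table exactly);
`"random"` draws per-eye Bernoulli labels. Covariates (age 71.8 ± 12.5 y,
logMAR acuity 0.42 ± 0.36, foveal thickness 565 ± 196 µm, symptom
duration 1.7 ± 1.3 months) are independent clipped normals — the
simulator deliberately does *not* model covariate-perfusion correlations,
vessel trees, optic disc, fovea, illumination falloff or device optics.
Passing tests on this material therefore validates the computational
chain and its statistical behavior under known ground truth, not
performance on real photographs. No pixel scale (µm/px) is assumed;
everything is calibrated in pixels.

## Statistics layer

* Group comparisons: two-sided pooled-variance t test.
* 2 × 2 association: Pearson chi-squared without continuity correction
  (1 df); Fisher's exact test available behind a flag since the printed
  table's expected counts are borderline for the chi-squared conditions.
* ROC: empirical step-function curve; AUROC by the Mann–Whitney identity
  with midrank ties; variance, 95% CI and the p value against AUC = 0.5
  by DeLong's method (chosen over Hanley–McNeil; cross-checked against
  R's pROC in the test suite). With perfect separation the DeLong
  variance collapses to 0 and the CI degenerates to a point.
* Cutoff: the observed score maximizing Youden's J = sens + spec − 1,
  ties resolved toward higher specificity. For parallelism the ischemic
  macula is the positive class and the decision rule is *score ≤ cutoff*
  (ischemic eyes score lower).
* Sensitivity at 90%/95% specificity: best empirical sensitivity among
  operating points at or above the floor; no interpolation.
* Likelihood ratios: +LR = sens/(1 − spec), reported as undefined at
  100% specificity; −LR = (1 − sens)/spec, undefined at 0% specificity.
* Sample size (two means, normal approximation, allocation k = n₁/n₂):
  n₂ = (1 + 1/k)(z₁₋α/₂ + z₁₋β)² σ̄² / Δ², σ̄² = (s₁² + s₂²)/2, both
  groups rounded up. For the pilot inputs 0.33 ± 0.13 vs 0.20 ± 0.11,
  α = 0.05, β = 0.20, k = 0.75 this gives 12 + 16 = 28 eyes; published
  planning for the same inputs has quoted a total of 33, which this
  formula does not reproduce — the report carries the computed 28 as a
  planning note and makes no claim about the discrepant figure.
* Eyes with undeterminable perfusion (angiographic view blocked by dense
  hemorrhage) are excluded from every statistic.

## Problem sizes and numerical choices

The heavy validation checks use sizes chosen to balance statistical
resolution against a single-CPU run: the pattern-separation check runs
200 replicates of 200-eye cohorts (t-test p < 0.01 and pattern AUROC >
0.75 required in ≥ 90%); the κ-monotonicity check uses 100 replicates
per κ ∈ {0, 1, 2, 4, 8}, where adjacent-level mean gaps (≥ 0.02) exceed
Monte-Carlo error (SE ≈ 0.006) by an order of magnitude. Otsu, pair
counting and AUROC are validated against exhaustive/brute-force oracles
on 100 random small instances each. Per-image pipeline failures
(degenerate planes, unreadable files) are quarantined with a recorded
reason rather than aborting a cohort run.

## Known limitations

* The four-orientation binning cannot distinguish textures whose
  orientation content differs only within a 45° bin; finer binning and
  structure-tensor/Fourier anisotropy measures are out of scope.
* Blob textures' attainable score ceiling (~0.11 mean) sits below the
  non-flame group target mean, so the simulated non-flame distribution
  is mildly compressed relative to its nominal (mean, SD).
* The synthetic textures validate the pipeline, not clinical
  performance; no claim about real-photograph operating points (cutoffs,
  sensitivities) is made or tested.
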