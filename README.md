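# parafundus

Quantitative analysis of retinal hemorrhage patterns on color fundus
photographs in acute branch retinal vein occlusion (BRVO), for retina
researchers who want an objective alternative to visual grading.

In acute BRVO, hemorrhages in the nerve-fiber layer track the axon bundles
and look *flame-shaped* (parallel streaks), while deeper dot/blot
hemorrhages are rounded and isotropic. Flame-shaped hemorrhage goes with a
perfused (nonischemic) macula; dot/blot hemorrhage often accompanies
macular ischemia, normally diagnosed with invasive fluorescein
angiography. This package scores how "flame-like" a photograph is — its
**parallelism** — and provides the diagnostic statistics that relate the
score to macular perfusion status.

## The parallelism score

A 200 × 200 pixel region of interest is taken from the green channel of
the fundus photograph (hemorrhages absorb green light most strongly). A
4–5 px band-pass filter (difference of Gaussians, FWHM 4 and 5 px)
isolates streak-scale texture; each polarity of the response — dark
hemorrhage streaks and bright hemorrhage-sparse nerve-fiber streaks — is
binarized with Otsu's threshold and thinned to a unit-width skeleton.
With n₀, n₄₅, n₉₀, n₁₃₅ the counts of 8-adjacent on-pixel pairs at
0°, 45°, 90°, 135° to the horizon, each skeleton scores

    P = √((n₀ − n₉₀)² + (n₄₅ − n₁₃₅)²) / (n₀ + n₄₅ + n₉₀ + n₁₃₅)

the doubled-angle orientation order parameter: P = 1 when all pairs share
one orientation, P = 0 for equal counts (isotropy). The per-eye score is
the mean of the hemorrhage and hemorrhage-sparse skeleton scores.

Because no public image set accompanies this problem, the package ships a
synthetic fundus-texture generator (oriented streak fields with von Mises
axial orientation concentration κ; isotropic blob fields with a density
dial) and a cohort simulator calibrated so that pipeline scores of the
two pattern groups approximate 0.333 ± 0.110 (flame) and 0.122 ± 0.067
(non-flame). The statistics layer provides the pooled t test, 2 × 2
chi-squared/Fisher association, ROC analysis with DeLong confidence
intervals, Youden-index cutoffs, sensitivities at fixed specificity,
likelihood ratios, and a two-mean sample-size calculation.

## Worked example

```sh
python examples/score_single_roi.py
```

```
flame: hemorrhage=0.619 sparse=0.476 mean=0.547
blot : hemorrhage=0.038 sparse=0.017 mean=0.028
```

The flame texture's two skeletons are strongly oriented (region scores
0.619 and 0.476, mean 0.547); the blot texture is near-isotropic
(mean 0.028). `examples/run_cohort_pipeline.py` runs the full
simulate → score → analyze pipeline on a 30-eye cohort and prints the
cohort report, e.g.

```
parallelism by hemorrhage pattern (flame vs non-flame):
  0.333 +/- 0.135 (n=22) vs 0.115 +/- 0.037 (n=8), t=4.46, p=1.22e-04
pattern x perfusion table [[22, 0], [1, 7]]: chi2=25.11, p=5.42e-07
ROC for ischemic macula (low parallelism = positive):
  AUROC=0.901 (95% CI 0.781-1.000, p vs 0.5 = 5.37e-11)
```

Low parallelism flags the ischemic macula: flame eyes score high and are
nonischemic, blot eyes score low and are mostly ischemic.
`examples/diagnostic_statistics.py` exercises the statistics layer alone.

The same pipeline is available as a CLI:

```sh
parafundus simulate --out run --seed 7 --n-eyes 58
parafundus score    --out run
parafundus analyze  --out run --seed 7 --fisher
parafundus report   run/report.json
```

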