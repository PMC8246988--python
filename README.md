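# tractnorm

Normative univariate **and** multivariate analysis of white-matter tract
integrity for cross-sectional epilepsy cohorts.

Cross-sectional diffusion-MRI studies infer disease progression in temporal
lobe epilepsy (TLE) by correlating white-matter damage with epilepsy
duration. Tract-by-tract ("univariate") analyses are noisy, outlier-prone
and blind to the strong natural covariance between tracts — which matters
when different tracts are affected in different patients. `tractnorm`
implements both frameworks side by side for a cohort described only by a
demographics table and a table of mean fractional anisotropy (FA) for ten
limbic tracts (bilateral anterior thalamic radiation, cingulum gyrus,
cingulum hippocampus, fornix, uncinate fasciculus), plus a resampling
framework that quantifies how robust each result is. It is aimed at
researchers analysing tract-level summary measures; image reconstruction
and FA extraction happen upstream.

## The statistics at its core

1. **Covariate removal.** Sex and healthy-aging effects are removed per
   tract with a robust linear model (Huber M-estimator, IRLS, k = 1.345,
   MAD scale). The residuals FAr feed everything else.
2. **Robust univariate distance.** For subject *i* and tract *j*, draw
   1,000 random subsamples of 24 controls (leave-one-out for controls) and
   report the median of z = (FAr_ij − mean)/SD over subsamples.
3. **Robust multivariate distance.** Per hemisphere, the Mahalanobis
   distance of the five tract residuals,

       D_M = sqrt( (x − µ)ᵀ C⁻¹ (x − µ) ),

   with µ and C re-estimated per control subsample; C is a Ledoit–Wolf
   linearly shrunk covariance, so it stays well-conditioned at n = 24,
   p = 5. Each subject gets a left and a right distance, relabelled
   ipsi-/contralateral by seizure focus. 28 controls yield 2 × 28 = 56
   reference distances.
4. **Associations with duration.** One-tailed Spearman tests via
   t = ρ·sqrt(n−2)/sqrt(1−ρ²) with n−2 df, Bonferroni-corrected (h = 10
   tracts, h = 2 hemispheres); z-scores are hypothesised to fall, distances
   to rise with duration.
5. **Onset extrapolation.** Huber regression D_M = β0 + β1·duration on
   patients; log β0 is scored against the 56 log control distances by the
   same subsample-median protocol (1,000 subsamples of 54).
6. **Consistency κ.** Repeatedly subsample 30 of 33 patients per group and
   report the percentage of subsamples in which each corrected test is
   significant. κ near 0% or 100% = robust; intermediate = fragile.

A synthetic-cohort generator (`tractnorm.synthetic`) reproduces the
statistical structure of such a study (group sizes 28/33/33, correlated FA,
aging/sex effects, ipsilateral duration decline with per-patient
heterogeneity, optional outliers), so the whole pipeline is testable
without patient data.

## Worked example

```python
from tractnorm import (generate_cohort, residualize, compute_distance_set,
                       duration_associations, critical_rho)
from tractnorm.synthetic import GeneratorConfig

subjects, fa = generate_cohort(GeneratorConfig(), seed=1)
residuals, _ = residualize(fa, subjects)
distances = compute_distance_set(residuals, subjects, n_reps=1000, seed=1)
for r in duration_associations(distances, subjects, scope="combined"):
    print(r.measure_id, round(r.rho, 3), round(r.p_one_tailed, 4),
          r.significant_bonferroni)
```

prints

```
md_ipsi 0.277 0.0122 True
md_contra 0.105 0.2 False
```

i.e. pooling all 66 synthetic patients, the ipsilateral hemisphere distance
rises significantly with epilepsy duration (one-tailed p = 0.012 < α/h =
0.025) while the contralateral one does not — the generator's ipsilateral
effect is recovered with the hypothesised sign. The `examples/` scripts
walk through each stage (cohort generation, distances, associations, onset
extrapolation, robustness) and print a short interpretation with each
number.

A thin CLI drives the same pipeline from a YAML config:

```bash
tractnorm synth --out-dir cohort --seed 1
tractnorm run --config examples/pipeline.yaml
```

writing `distances.csv`, `associations.csv`, `onset.json`,
`cohort_tests.csv`, `outcome_tests.csv`, `consistency.csv` and a
`run_manifest.json` that records every seed needed to reproduce the run.

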