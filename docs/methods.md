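# Methods

This note documents the statistical procedures `tractnorm` implements, the
choices made where the design was genuinely open, what the synthetic
generator does and does not emulate, and known limitations.

## Pipeline model

The unit of analysis is a subject's vector of ten tract-mean FA values.
The pipeline assumes (i) FA is linear in age and sex within the healthy
range, (ii) control tract residuals are approximately multivariate normal
per hemisphere (checked by Lilliefors and Mardia gates), and (iii) disease
progression manifests as a monotone association between distance-from-
controls and epilepsy duration (duration = scan age − onset age; the I/O
layer enforces this identity to within 1 year of rounding slack).

### Covariate removal

Each tract is regressed on age and sex (F=0, M=1) with a Huber M-estimator
solved by IRLS: weight 1 for residuals within k·s, weight k·s/|r| beyond,
with k = 1.345 (the conventional 95%-efficiency constant) and the scale s
re-estimated each iteration as median(|r|)/0.6745. Convergence is declared
when no coefficient moves by more than 1e-8 (at most 100 iterations);
non-convergence is flagged on the result, not raised. A constant sex
column is dropped with a warning; constant age on top of that is a
rank-deficiency error.

`fit_population` chooses the rows the model is fitted on. The default is
`controls_only`, so patient pathology cannot be absorbed into the
healthy-aging estimate; `all_subjects` is exposed as a switch. This choice
has a real consequence discussed under *Calibration caveat* below.

### Robust distances

Both distance types score a subject against the control distribution using
the same resampling protocol: N = 1,000 random subsamples (without
replacement; distinct subsamples are not enforced across repetitions)
drawn from the reference controls — all 28 for patients, the other 27 for
a control — and the median of the per-subsample statistic is reported.
Subsample size defaults to 24, the largest size for which more than 1,000
distinct subsamples exist within 27.

* z-score: (value − subsample mean) / subsample SD, ddof = 1.
* Mahalanobis: sqrt((x−µ)ᵀC⁻¹(x−µ)) over the five same-hemisphere tract
  residuals, solved by Cholesky factorisation (never an explicit inverse),
  with µ the subsample mean and C a Ledoit–Wolf linearly shrunk covariance
  (shrinkage toward the scaled identity with the analytically optimal
  intensity). Shrinkage keeps C positive definite at n = 24, p = 5, which
  the sample covariance does not guarantee; the estimator name and
  intensity are recorded, and the sample covariance is available as an
  alternative. The shrunk matrix carries an n/(n−1) rescaling so that the
  p = 1 case reduces exactly to the unbiased variance — without it the
  univariate Mahalanobis distance and |z| would differ by a systematic
  factor sqrt(24/23).

Every subject's random stream is derived from (global seed, CRC32 of the
subject id), so results are independent of subject order and of which
subjects are scored. Zero-variance or singular subsamples are discarded
and logged; a fully degenerate reference raises.

### Inference

Spearman ρ (mean ranks on ties) is tested one-tailed through the
Student-t approximation t = ρ·sqrt(n−2)/sqrt(1−ρ²) with n−2 df.
Directions are fixed a priori: tract z-scores negative with duration,
hemisphere distances positive; a correlation opposing its direction is
never significant regardless of magnitude. Bonferroni uses h = 10 for the
tract family and h = 2 for the hemisphere pair; critical thresholds invert
the t quantile, ρ* = t*/sqrt(n−2+t*²). Against the exact permutation null
at n = 6 the approximation is accurate to < 0.03 for |ρ| < 0.8 (tested).

The onset extrapolation regresses patient distances on duration with the
same Huber engine and scores log β0 against the log of the 56 pooled
control distances via the subsample-median protocol (subsample size 54 of
56, mirroring the 24-of-27 rule). Natural log is used; the base cancels in
a z-score. The p-value is two-tailed normal — no direction is hypothesised
at onset. The distances are logged because they are positively skewed by
construction; scale invariance of the resulting z is exact and tested.

Surgical-outcome comparisons are one-tailed two-sample t-tests (pooled
variance by default, Welch available) of each tract z (seizure-free
hypothesised higher) and of each log hemisphere distance (seizure-free
hypothesised lower), Bonferroni-corrected within the same families.

Demographic 2×2 tables use Pearson χ² with the Yates continuity
correction; continuous demographics use two-tailed t-tests. Normality
gating of the control residuals uses a Lilliefors test per tract whose
p-value comes from a seeded Monte-Carlo simulation of the
estimated-parameter null (10,000 draws; the standard KS table would be
wrong with estimated mean/SD) and Mardia's skewness (χ² with
p(p+1)(p+2)/6 df) and kurtosis (normal approximation) per hemisphere,
with the usual large-sample reference distributions.

### Consistency κ

For each measure, κ is the percentage of N = 1,000 random m-of-n patient
subsamples (default m = 30 of 33) whose corrected one-tailed test is
significant, with the t threshold evaluated at n = m and the same h as the
headline analysis. Distances are *not* recomputed per subsample — only the
patients entering the correlation vary. κ is invariant to monotone
transforms of the measure (rank-based inner statistic), and its
Monte-Carlo SE is at most sqrt(0.25/N)·100 ≈ 1.6 points. Because the
subsamples of 33 patients overlap heavily, κ concentrates on the
exhaustive-enumeration value (tested at n = 6, m = 5) rather than
behaving like independent draws.

## Synthetic generator

FA of subject i, tract j:

    mean_j + age_slope·age_i + sex_offset·1[male]
    + slope_side(j)·duration_i·(1 + L_ij)        (patients)
    − outcome_deficit·1[contra, ILAE 2+]          (optional)
    + correlated Gaussian noise,

with L_ij ~ N(0, heterogeneity_sd) per patient and tract. Defaults: group
sizes 28/33/33 with the sex, outcome and hippocampal-sclerosis splits of a
typical surgical TLE cohort; tract means 0.35–0.50, SD 0.02; exchangeable
inter-tract correlation 0.4 within / 0.3 across hemispheres; age slope
−4e-4/yr, male offset +0.005; duration slopes −6e-4 (ipsi) and −2e-4
(contra) per year; heterogeneity SD 0.5. Ages are uniform on (18, 60) and
onset uniform on (1, 30), with rejection keeping duration ≥ 1 year, so the
duration identity holds exactly and duration is strongly age-correlated
(ρ ≈ 0.8), as in real chronic cohorts. Outliers, when requested, are
additive Gaussian shocks on random (subject, tract) cells. Draws leaving
(0, 1) are clipped with an explicit warning (at the default scales this
essentially never happens).

Named scenarios: `null_effects` (all systematic terms zero — groups
identical in law) and `strong_heterogeneous_ipsilateral` (ipsilateral
slope −6e-4 with heterogeneity SD 1.8). The latter encodes the regime the
multivariate analysis is designed for: per-patient loadings dilute every
single tract's correlation with duration (median best-tract κ ≈ 35%) while
the hemisphere-level distance keeps an essentially deterministic
association (κ ≈ 100%). A much stronger common slope would make the
univariate κ saturate too and erase the contrast.

What the generator does **not** emulate: longitudinal within-subject
trajectories, nonlinear aging, site/scanner effects, non-Gaussian FA
noise, spatial structure within tracts, or any real effect magnitudes —
studies of this design report rank correlations, not slopes, so generator
slopes are plausibility choices, never estimates of any real cohort.
Passing tests therefore demonstrate the statistical machinery is correct
and calibrated under these conditions, not that real cohorts will show
the same effect sizes.

## Calibration caveat: controls-only residualization

With `fit_population=controls_only`, the age-slope estimated from 28
controls carries sampling noise of ≈ 3e-4/yr per tract. Applied to
patients, this noise becomes a shared linear age trend in their residuals;
because duration is strongly age-correlated, it leaks into the duration
correlations with a random common sign, inflating the null family-wise
rate of the tract family roughly four-fold (measured: 0.15 vs nominal
0.05 over 600 null group-families). Fitting on all subjects makes
residuals in-sample orthogonal to age and restores nominal calibration
(0.022 univariate / 0.053 multivariate). The zero-effect calibration
study in the test suite therefore fits on all subjects — in a null cohort
there is no disease effect the covariate model could absorb — while the
pipeline default remains controls-only, protecting effect estimates in
real cohorts at a calibration cost users should be aware of.

## Numerical details and problem sizes

Ledoit–Wolf estimation is vectorised over subsamples (thousands of
24×5 problems per subject), and distances use batched Cholesky solves.
Degenerate cases: constant responses terminate the IRLS immediately with
unit weights; |ρ| = 1 returns p = 0 with a log note; ties receive mean
ranks. Monte-Carlo test sizes were chosen to keep the full suite around
five minutes on one core: the null-calibration study uses 1,000 replicate
cohorts with 200 subsample reps per distance, the robustness contrast 50
replicates at 100/200 reps, the onset null 500 replicates at 400 reps;
the acceptance script and examples use the full 1,000-rep protocol on a
single cohort.

## Limitations

Beyond the generator's idealisations: the Mahalanobis distance is not
decomposed into per-tract contributions (deliberately out of scope); only
FA is modelled, not multi-metric combinations; the Bonferroni correction
is the only multiplicity control offered; and Mardia p-values use
large-sample approximations without small-sample corrections.
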