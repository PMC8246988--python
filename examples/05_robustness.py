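"""Subsample-consistency (kappa) of the duration correlations.

Repeatedly subsample 30 of 33 patients per group, recompute each
Bonferroni-corrected one-tailed Spearman test and report the percentage of
subsamples that come out significant. Values near 0% or 100% are robust;
intermediate values flag associations that flip with the sample drawn.
"""

from tractnorm import (
    compute_distance_set, full_consistency_report, generate_cohort,
    residualize,
)
from tractnorm.synthetic import GeneratorConfig

# heterogeneous ipsilateral effect: different tracts hit in different
# patients - the regime where the hemisphere-level distance shines
cfg = GeneratorConfig.strong_heterogeneous_ipsilateral()
subjects, fa = generate_cohort(cfg, seed=1)
residuals, _ = residualize(fa, subjects)
distances = compute_distance_set(residuals, subjects, n_reps=1000, seed=1)

report = full_consistency_report(distances, subjects, m=30, n_reps=1000,
                                 seed=1)
for group in ("left_tle", "right_tle"):
    rows = {r.measure_id: r.kappa for r in report if r.group == group}
    uni = {k: v for k, v in rows.items() if k.startswith("z_")}
    print(f"{group}: kappa(md_ipsi) = {rows['md_ipsi']:5.1f}%   "
          f"kappa(md_contra) = {rows['md_contra']:5.1f}%   "
          f"best tract = {max(uni, key=uni.get)} ({max(uni.values()):.1f}%)")
# When per-tract effects are diluted across patients, only the multivariate
# hemisphere distance stays consistently significant across subsamples.
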