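# Full pipeline on a synthetic cohort drawn under the default study
# conditions. Replace the generator section with
#   input: {demographics: demographics.csv, tract_fa: tract_fa.csv}
# to analyse real tables (exactly one of the two may be present).
generator:
  n_control: 28
  n_left: 33
  n_right: 33
out_dir: tractnorm_out
seed: 1
covariates:
  fit_population: controls_only
distances:
  n_subsample: 24
  n_reps: 1000
robustness:
  m: 30
  n_reps: 1000
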