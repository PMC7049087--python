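# Demo end-to-end run: simulated summary statistics and cohort, reduced
# bootstrap replicates so the whole pipeline finishes in well under a minute.
seed: 1
n_bootstrap: 10000
bonferroni_n: 6
outcome_label: high parental life span
analyses:
  mr: true
  quartiles: true
  survival: true
  carriers: true
summary_stats:
  n_snps: 26
  causal_slope: -0.002
  pleiotropy_mean: 0.0
  pleiotropy_sd: 0.0
cohort:
  n_subjects: 6000
  log_hr_per_50mg: 0.157   # ln(1.17), the all-cause scale
  parental_longevity_log_or_per_50: -0.083   # ln(0.92): inject the MR signal
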