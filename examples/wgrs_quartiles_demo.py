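"""wGRS construction, quartiles and parental-lifespan associations.

Simulates a cohort whose parental longevity carries an injected log-odds
effect of ln(0.92) per 50 mg/dL of genetically predicted Lp(a), builds the
weighted genetic risk score from the instrument weights, and runs the
quartile and continuous logistic associations adjusted for age, sex and
10 ancestry principal components.
"""

import numpy as np

from lpamr import (CohortConfig, SummaryStatsConfig, assign_quartiles, build_wgrs,
                   call_phenotypes, continuous_association, generate_cohort,
                   generate_summary_stats, harmonize, quartile_association)

exposure, outcome = generate_summary_stats(SummaryStatsConfig(seed=7))
stat_set = harmonize(exposure, outcome)
weights = stat_set.snps[["rsid", "maf", "beta_exp"]].rename(columns={"beta_exp": "beta"})

cohort = generate_cohort(
    CohortConfig(n_subjects=20_000, parental_longevity_log_or_per_50=float(np.log(0.92)),
                 parental_missing_prob=0.0, seed=7),
    weights)

calls = call_phenotypes(cohort)
merged = cohort.merge(calls, on="subject_id")
print(f"subjects: {len(merged)}; high parental life span: "
      f"{int(merged['high_parental'].sum())} "
      f"({100 * merged['high_parental'].mean():.1f}%)")

grs = build_wgrs(merged[list(weights['rsid'])], stat_set, weight_source="demo")
quartiles = assign_quartiles(grs)
covs = merged[["age", "sex_male"] + [f"pc{i}" for i in range(1, 11)]]

print("\nOdds of a long-lived parent by wGRS quartile (Q1 = lowest score):")
for r in quartile_association(merged["high_parental"], quartiles, covs):
    print(f"  {r.label}: OR {r.odds_ratio:.2f} (95% CI {r.ci_low:.2f}-{r.ci_high:.2f})")

res = continuous_association(merged["high_parental"], grs, covs)
print(f"\ncontinuous wGRS: OR per 50 mg/dL {res.per_50.odds_ratio_per_50:.2f} "
      f"(95% CI {res.per_50.ci_low:.2f}-{res.per_50.ci_high:.2f}), p = {res.p:.3g}")
print("\nThe injected ln(0.92) per-50 signal is modest relative to this "
      "sample size, so expect the Q4 odds ratio below 1 and a continuous "
      "CI consistent with 0.92: genetically higher Lp(a), fewer long-lived "
      "parents.  Averaging over many replicates recovers 0.92 without bias "
      "(see the test suite).")
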