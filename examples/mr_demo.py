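"""Two-sample MR of genetically predicted Lp(a) on parental life span.

Builds a synthetic 26-SNP instrument (exposure effects in mg/dL per allele,
outcome effects in log-odds per allele with a true causal slope of -0.002
per mg/dL), harmonizes the two tables, and runs the full MR battery.
"""

import numpy as np

from lpamr import (SummaryStatsConfig, bonferroni_gate, bootstrap_pvalue,
                   egger_estimate, generate_summary_stats, harmonize,
                   ivw_estimate, scale_per_50)

exposure, outcome = generate_summary_stats(
    SummaryStatsConfig(n_snps=26, causal_slope=-0.002, seed=42))
stat_set = harmonize(exposure, outcome, outcome_label="high parental life span")

ivw = ivw_estimate(stat_set)
egger = egger_estimate(stat_set)
boot_p = bootstrap_pvalue(stat_set, "IVW", n_reps=100_000, seed=42)
per50 = scale_per_50(ivw)
flags, threshold = bonferroni_gate([ivw.slope_p], n_outcomes=6)

print(f"instrument SNPs after harmonization: {len(stat_set)}")
print(f"IVW slope (log-odds per mg/dL): {ivw.slope:.4f} (SD {ivw.slope_sd:.4f}), "
      f"p = {ivw.slope_p:.2e}")
print(f"Egger slope: {egger.slope:.4f} (SD {egger.slope_sd:.4f}); "
      f"intercept {egger.intercept:.4f}, intercept p = {egger.intercept_p:.2f}")
print(f"bootstrap p (100 000 parametric replicates): {boot_p:.2e}")
print(f"OR per 50 mg/dL: {per50.odds_ratio_per_50:.2f} "
      f"(95% CI {per50.ci_low:.2f}-{per50.ci_high:.2f})")
print(f"significant at the 6-outcome Bonferroni threshold "
      f"({threshold:.4f})? {flags[0]}")
print()
print("The IVW slope should sit near the injected -0.002; an OR per 50 mg/dL "
      "below 1 means genetically higher Lp(a) lowers the odds of having a "
      "long-lived parent.  A non-significant Egger intercept means no "
      "detectable directional pleiotropy, so the IVW reading stands.")
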