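# Methods

`lpamr` implements a two-part analysis of whether lifelong exposure to
elevated lipoprotein(a) — an LDL-like particle whose plasma level is largely
set by the *LPA* locus — shortens life: (i) two-sample Mendelian
randomization (MR) of genetically predicted Lp(a) against binary
parental-longevity phenotypes, and (ii) prospective cause-specific Cox
analyses of measured Lp(a) in a censored cohort.  Because the individual-level
biobank data behind such analyses cannot be shipped, the package includes a
seeded synthetic-data generator that reproduces the statistical structure the
analyses assume; every estimator is validated against that generator by
parameter recovery and null calibration.

## Two-sample MR

Inputs are per-SNP summary statistics: effects on Lp(a) in mg/dL per effect
allele (exposure) and effects on a longevity phenotype in log-odds or
log-hazard per allele (outcome), from non-overlapping samples.

**Harmonization.** Tables are inner-joined on rsid.  When the outcome row's
effect/other alleles are swapped relative to the exposure, the outcome beta's
sign is flipped and the allele frequency complemented.  Allele pairs that
cannot be reconciled are dropped with a warning, as are palindromic (A/T,
C/G) SNPs with effect-allele frequency in [0.42, 0.58], where strand cannot
be resolved (window configurable).  Finally every SNP is oriented so
`beta_exp >= 0` by flipping both betas together.  IVW is invariant to this
orientation; MR-Egger is not, and the positive-exposure convention is the
standard one for Egger regression.

**Estimators.** The per-SNP Wald ratio is `theta_j = beta_out_j / beta_exp_j`
with first-order delta-method SE `se_out_j / |beta_exp_j|`.  (One published
description inverts this ratio verbally; the implementation uses the standard
outcome-over-exposure orientation, which is the one consistent with odds
ratios per mg/dL.)  A SNP with `beta_exp = 0` is excluded with a warning
rather than raising a division error.  The IVW estimate is the fixed-effect
meta-analysis of the Wald ratios, weights `1/se_theta^2`; algebraically this
equals weighted least squares of `beta_out` on `beta_exp` through the origin
with weights `1/se_out^2`, and the test suite verifies that identity to
1e-12 relative against statsmodels WLS.  A fixed-effect (not multiplicative
random-effects) model is used: the analysis is a plain meta-analysis of Wald
ratios with no heterogeneity inflation.  MR-Egger is the same weighted
regression with a free intercept; the intercept estimates the average
directional pleiotropic effect and a two-tailed normal test of intercept = 0
flags unbalanced pleiotropy.  Standard errors for both estimators are the
known-variance (fixed-dispersion) forms — `slope_sd = Sxx^{-1/2}` — rather
than residual-scaled ones; this matches the fixed-effect IVW convention,
makes Egger reduce exactly to IVW when the intercept is constrained to zero,
and gives exactly uniform intercept p-values under the null (verified by a
Kolmogorov–Smirnov test over 500 simulated replicates).  No SIMEX correction
is applied.

**Bootstrap significance.** The slope's p-value can also be computed by a
parametric bootstrap: each of `n_reps` (default 100 000) replicates redraws
`beta_exp_j* ~ N(beta_exp_j, se_exp_j)` and `beta_out_j* ~ N(beta_out_j,
se_out_j)` independently and recomputes the slope; the reported p is the
two-tailed normal tail probability of `observed_slope / SD(resampled
slopes)`.  This reintroduces the exposure-side uncertainty the first-order
Wald SE ignores.  The one-sentence published description of this procedure
admits several readings; this z-from-simulations construction is the most
direct one and is fully seeded.  It is supported for both IVW and Egger.
Fewer than 100 replicates are refused (unstable SD).  In the limit
`se_exp -> 0` the bootstrap SD converges to the analytic IVW SD; the
acceptance suite checks agreement within 0.005 at 100 000 replicates.

**Scaling and significance gates.** Slopes in per-mg/dL units are rescaled
to odds ratios per 50-mg/dL increase, `OR = exp(50*slope)` with the Wald CI
transformed monotonically (hence symmetric on the log scale).  With six
longevity outcomes, the Bonferroni threshold is 0.05/6 = 0.0083 (strict
inequality).

## wGRS and parental-lifespan phenotypes

The weighted genetic risk score is `score_i = sum_j beta_exp_j * g_ij` in
mg/dL of genetically predicted Lp(a), over 0/1/2 effect-allele dosages.
Missing dosages are mean-imputed to `2*maf`; a subject with more than 10%
of SNPs missing (configurable) gets an absent score, never a silent zero.
Quartiles are cut at the empirical 25/50/75th percentiles with ties at a cut
point going to the lower quartile.  Three bundled example weight files
(filenames and docstrings marked *synthetic*) mimic the shape of the two
published instrument sources, including an isoform-adjusted variant; real
weight files with the same columns are drop-in replacements.

A father counts as long-lived when alive and *strictly* older than 90, or
deceased at age *at or above* 90; mothers analogously at 93.  The strict /
inclusive asymmetry is deliberate: a living 90-year-old may still die before
reaching the "died at 90+" condition.  "High parental life span" is the
Kleene OR of the two parents, so one long-lived parent decides the phenotype
even when the other parent is unknown, while missing data propagate as
missing, never as false.  Top-1% thresholds default to 96/98 years; these
defaults are placeholders for cohort-specific values and every output
records the thresholds used.  Ages outside [0, 120] reject the record with
its id logged.  Association analyses are maximum-likelihood logistic
regressions (statsmodels GLM/Binomial) of the phenotype on wGRS quartile
indicators (or the score entered linearly, rescaled per 50 mg/dL), adjusted
for age, sex and 10 ancestry principal components; quartiles with zero cases
are flagged non-estimable, and all-constant covariate columns are dropped
(making the zero-covariate fit identical to the unadjusted one).

## Prospective mortality analyses

Cox proportional-hazards models use lifelines' `CoxPHFitter`, which handles
tied event times with Efron's method — appropriate here because synthetic
event times generated at year-scale resolution tie frequently.  Cause-specific
hazards (all-cause, cardiovascular, noncardiovascular) are obtained by
recoding: deaths from competing causes are censored at their death time.
Model 1 adjusts for age and sex; Model 2 adds smoking, BMI, systolic blood
pressure, diabetes and a renal-function covariate.  The renal covariate is
configurable by column name (eGFR by default, serum creatinine as an
alternative) and the choice is recorded in the run report.  Lp(a) groupings:
a 50 mg/dL threshold (the threshold value itself belongs to the high group);
empirical percentile bands [0,P50), [P50,P80], (P80,P90], (P90,P95],
(P95,inf) computed on the full cohort (not sex-stratified); and a top-5% vs
bottom-50% contrast.  Event rates are `100*cases/denominator` rounded
half-up to one decimal, matching table conventions.  The age-equivalence
statistic divides the log-hazard of the high-vs-low Lp(a) contrast by the
per-year age log-hazard from the same Model-1 fit; no CI is attached by
default (a delta-method CI would require the covariance of the two
coefficients and is deliberately out of the default report).  Carrier
analyses contrast carriers (>= 1 raising allele) vs noncarriers at two
high-impact loci, plus combined allele-dose groups 0 / 1 / 2+; in synthetic
runs the two largest-weight instruments play that role.

## The synthetic generator

**Summary statistics.** Per SNP: `maf ~ U(0.05, 0.45)`; true exposure
effects `U(1, 16)` mg/dL per allele (heterogeneous magnitudes spanning the
range typical of *LPA* instruments); standard errors follow the single-SNP
regression scaling `se = sd_trait / sqrt(2*maf*(1-maf)*n)` with an exposure
trait SD of 30 mg/dL, n_exposure = 20 000 and n_outcome = 139 362 (the MR
study's sample size), giving strong instruments (F >> 10).  Observed
exposure betas carry sampling noise; outcome betas are
`N(causal_slope*beta_exp + alpha, se_out)` with per-SNP pleiotropy
`alpha ~ N(pleiotropy_mean, pleiotropy_sd)`.  30% of outcome rows (default)
are emitted on the opposite allele to force harmonization coverage in every
pipeline run.  Allele pairs are drawn non-palindromic by construction.

**Cohort.** Genotypes are independent `Binomial(2, maf)` dosages (no LD —
the MR estimators treat instruments as independent, so none is simulated).
Lp(a) is lognormal with a genotype contribution injected on the log scale:
the raw weighted dosage score is standardized and added with SD 0.46 on top
of an environmental log-SD of 1.0, so the total log-SD is 1.10 and, with
log-median ln(11.4), the 95th percentile sits near 6.1x the median —
reproducing the published percentile boundaries 11.4 and 69.7 mg/dL.  Those
two printed cut points are the only distributional facts available, so the
generator moment-matches them and exposes all shape parameters (including an
optional point mass of very low values) rather than fixing one "true"
distribution; the single-lognormal default compresses the mid-range slightly
(P80 ≈ 29 vs 35 mg/dL printed), which the ±20% calibration checks absorb.
Survival times are exponential with rate `0.011 * exp(lp)` per year, where
the linear predictor centres age (0.127 per year — the published all-cause
age coefficient), Lp(a) (ln(1.17) per 50 mg/dL by default, the published
threshold-contrast scale) and the Model-2 covariates at their sample means;
administrative censoring at 20 years yields roughly 30% all-cause mortality,
matching the source cohort's 5686/18 720.  Deaths are labelled
cardiovascular by a Bernoulli draw whose log-odds may rise with Lp(a)
(defaults give ≈ 42% cardiovascular deaths, matching 2412/5686) — a
conditional two-cause label, not a competing-risks hazard model, which
suffices because the analyses are cause-specific Cox models with competing
causes censored.  Parental ages are Normal(75, 9) for fathers and
Normal(80, 9) for mothers — chosen so that ≈ 12% of offspring have at least
one long-lived parent at the 90/93-year thresholds, matching the published
12.7% — independent of offspring genotype by default.  Setting
`parental_longevity_log_or_per_50` shifts each parent's probability of
surviving past the longevity threshold on the log-odds scale by the
offspring's genetically predicted Lp(a) (per 50 mg/dL) and draws ages from
the matching truncated normals: this injects an exact logistic MR signal
while preserving a realistic marginal age distribution, for end-to-end
recovery tests.  Ten ancestry PCs are standard normal noise.

What the generator does *not* emulate: linkage disequilibrium between
instruments, genotype imputation error, assay noise or isoform-dependent
measurement bias in Lp(a), secular trends in parental cohorts, and
non-proportional hazards.  Passing recovery tests therefore demonstrate that
the estimators are correct under the model's own assumptions, not that those
assumptions hold in any real cohort.

## Numerical and design choices

- All significance tests are two-tailed normal; p-values are clipped into
  (0, 1] (extreme z underflows the survival function to exactly 0).
- The bootstrap is vectorized (n_reps x n_snps Gaussian arrays) and seeded;
  the pipeline derives fixed per-stage child seeds from the global seed via
  `numpy.random.SeedSequence(entropy=seed, spawn_key=(stage,))`, so toggling
  one stage never perturbs another's stream.
- Egger requires >= 3 SNPs and oriented input; both violations raise.
  Quartile assignment requires >= 4 distinct scores; percentile banding
  requires >= 20 subjects and distinct cut points; degenerate inputs raise
  rather than returning silent defaults.
- Cox tie handling is Efron's method throughout (the lifelines
  implementation); Breslow approximation is not offered.
- Event rates round half-up (decimal arithmetic, not banker's rounding).
- Test problem sizes: MR calibration uses 26-SNP sets over 200–500
  replicates; Cox recovery uses 100 replicates at n = 18 720 with the fully
  adjusted model (omitting true covariates would attenuate the conditional
  HR by non-collapsibility); logistic recovery uses 15 replicates at
  n = 12 000.  These sizes put Monte-Carlo error well below the tested
  tolerances while keeping the default suite fast.

## Known limitations

- Weighted-median, mode-based, MR-PRESSO and multivariable MR estimators are
  out of scope, as are LD clumping, proxy-SNP lookup and build liftover.
- The per-allele → per-SD MAF rescaling (`2*maf*(1-maf)`) behind the
  published "adjusted for the minor allele frequency" phrase is exposed as an
  option on the wGRS but off by default, since the exact adjustment used is
  not documented.
- Fine–Gray competing-risks models, time-varying coefficients and formal
  proportionality diagnostics are not implemented.
- The synthetic parental-age model treats parents' vital status as
  independent of their age, which is unrealistic but immaterial to the
  phenotype-calling logic it exercises.
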