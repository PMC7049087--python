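"""Two-sample Mendelian randomization estimators.

Implements the per-SNP Wald ratio, the fixed-effect inverse-variance-weighted
(IVW) meta-analysis of Wald ratios, MR-Egger weighted regression with a free
intercept (whose deviation from zero indicates unbalanced horizontal
pleiotropy), a seeded parametric-bootstrap z-test for the slope, the
per-50-mg/dL odds-ratio rescaling, and the Bonferroni significance gate.

Conventions: the Wald ratio is theta_j = beta_out_j / beta_exp_j (outcome
units per mg/dL of Lp(a)) with first-order delta-method SE
se_out_j / |beta_exp_j|; IVW is the 1/se_theta^2-weighted mean of the
theta_j, algebraically identical to weighted least squares of beta_out on
beta_exp through the origin with weights 1/se_out^2; Egger is the same
weighted regression with a free intercept and requires every beta_exp >= 0
(Egger, unlike IVW, is not invariant to allele reorientation).
All tests are two-tailed normal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .instruments import HarmonizedSNP, SummaryStatSet

logger = logging.getLogger(__name__)

Method = Literal["IVW", "Egger"]


@dataclass
class WaldRatio:
    rsid: str
    theta: float      # outcome log-odds/log-hazard per mg/dL
    se_theta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.theta) and np.isfinite(self.se_theta)):
            raise ValueError("Wald ratio must be finite")
        if self.se_theta <= 0:
            raise ValueError("se_theta must be > 0")


@dataclass
class MREstimate:
    """Slope of the MR regression, in outcome units per mg/dL of Lp(a)."""

    method: Method
    slope: float
    slope_sd: float
    slope_p: float
    n_snps: int
    intercept: float | None = None
    intercept_sd: float | None = None
    intercept_p: float | None = None
    bootstrap_p: float | None = None

    def __post_init__(self) -> None:
        if (self.method == "Egger") != (self.intercept is not None):
            raise ValueError("intercept present iff method is Egger")
        if not 0 < self.slope_p <= 1:
            raise ValueError("slope_p must lie in (0, 1]")
        if self.slope_sd <= 0:
            raise ValueError("slope_sd must be > 0")


@dataclass
class ScaledEstimate:
    """Odds/hazard ratio per 50-mg/dL increase in Lp(a), with 95% CI."""

    odds_ratio_per_50: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.odds_ratio_per_50 <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")


def _two_tailed_p(z: float) -> float:
    # clip into (0, 1]: extreme z underflows sf() to exactly 0, and the
    # doubling can nudge past 1 at z = 0
    p = 2.0 * stats.norm.sf(abs(z))
    return float(min(1.0, max(p, 5e-324)))


def wald_ratio(snp: HarmonizedSNP) -> WaldRatio | None:
    """Per-SNP causal estimate beta_out/beta_exp with delta-method SE.

    Returns None (with a warning) when beta_exp == 0: such a SNP carries no
    instrument strength and is excluded rather than raising a division error.
    """
    if snp.beta_exp == 0:
        logger.warning("SNP %s has beta_exp = 0; excluded from Wald ratios", snp.rsid)
        return None
    return WaldRatio(snp.rsid, snp.beta_out / snp.beta_exp,
                     snp.se_out / abs(snp.beta_exp))


def wald_ratios(stat_set: SummaryStatSet) -> list[WaldRatio]:
    out = [wald_ratio(s) for s in stat_set]
    return [w for w in out if w is not None]


def _arrays(stat_set: SummaryStatSet):
    df = stat_set.snps
    return (df["beta_exp"].to_numpy(float), df["se_exp"].to_numpy(float),
            df["beta_out"].to_numpy(float), df["se_out"].to_numpy(float))


def ivw_estimate(stat_set: SummaryStatSet) -> MREstimate:
    """Fixed-effect IVW meta-analysis of the Wald ratios.

    slope = sum(w_j theta_j) / sum(w_j) with w_j = 1/se_theta_j^2;
    slope_sd = sum(w_j)^(-1/2).  Equivalent to weighted least squares of
    beta_out on beta_exp through the origin with weights 1/se_out^2.
    """
    ratios = wald_ratios(stat_set)
    if not ratios:
        raise ValueError("IVW requires at least one SNP with beta_exp != 0")
    theta = np.array([r.theta for r in ratios])
    w = np.array([1.0 / r.se_theta**2 for r in ratios])
    slope = float(np.sum(w * theta) / np.sum(w))
    sd = float(np.sum(w) ** -0.5)
    return MREstimate("IVW", slope, sd, _two_tailed_p(slope / sd), len(ratios))


def egger_estimate(stat_set: SummaryStatSet, *, _constrain_intercept: bool = False
                   ) -> MREstimate:
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    Weights 1/se_out^2 (simple Egger, no SIMEX).  The intercept estimates
    the average directional pleiotropic effect; intercept_p < .05 signals
    unbalanced pleiotropy.  Requires >= 3 SNPs and the beta_exp >= 0
    orientation.  ``_constrain_intercept`` forces the intercept to zero,
    an internal check mode under which Egger reduces exactly to IVW.
    """
    if len(stat_set) < 3:
        raise ValueError("MR-Egger requires at least 3 SNPs")
    if not stat_set.oriented:
        raise ValueError("MR-Egger requires the beta_exp >= 0 orientation; "
                         "harmonize() the inputs first")
    bx, _, by, se = _arrays(stat_set)
    w = 1.0 / se**2

    if _constrain_intercept:
        slope = float(np.sum(w * bx * by) / np.sum(w * bx**2))
        sd = float(np.sum(w * bx**2) ** -0.5)
        return MREstimate("IVW", slope, sd, _two_tailed_p(slope / sd), len(bx))

    sw = np.sum(w)
    mx, my = np.sum(w * bx) / sw, np.sum(w * by) / sw
    sxx = np.sum(w * (bx - mx) ** 2)
    if sxx == 0:
        raise ValueError("beta_exp has no weighted spread; Egger slope undefined")
    slope = float(np.sum(w * (bx - mx) * (by - my)) / sxx)
    intercept = float(my - slope * mx)
    slope_sd = float(sxx ** -0.5)
    intercept_sd = float((1.0 / sw + mx**2 / sxx) ** 0.5)
    return MREstimate(
        "Egger", slope, slope_sd, _two_tailed_p(slope / slope_sd), len(bx),
        intercept=intercept, intercept_sd=intercept_sd,
        intercept_p=_two_tailed_p(intercept / intercept_sd),
    )


def bootstrap_pvalue(
    stat_set: SummaryStatSet,
    estimator: Method = "IVW",
    n_reps: int = 100_000,
    seed: int = 0,
) -> float:
    """Parametric-bootstrap two-tailed z-test of the MR slope.

    Each replicate resamples beta_exp_j* ~ N(beta_exp_j, se_exp_j) and
    beta_out_j* ~ N(beta_out_j, se_out_j) independently and recomputes the
    slope; the p-value is the two-tailed normal tail probability of
    observed_slope / SD(resampled slopes).  Unlike the analytic IVW SE this
    propagates exposure-side uncertainty.  Fully vectorized and seeded.
    """
    if n_reps < 100:
        raise ValueError("n_reps < 100 gives an unstable bootstrap SD")
    if estimator not in ("IVW", "Egger"):
        raise ValueError(f"unknown estimator {estimator!r}")
    bx, sx, by, sy = _arrays(stat_set)
    observed = (ivw_estimate(stat_set) if estimator == "IVW"
                else egger_estimate(stat_set)).slope

    rng = np.random.default_rng(seed)
    bxs = bx[None, :] + rng.standard_normal((n_reps, bx.size)) * sx[None, :]
    bys = by[None, :] + rng.standard_normal((n_reps, by.size)) * sy[None, :]
    w = 1.0 / sy**2

    if estimator == "IVW":
        slopes = (bxs * bys * w).sum(axis=1) / (bxs**2 * w).sum(axis=1)
    else:
        sw = w.sum()
        mx = (bxs * w).sum(axis=1, keepdims=True) / sw
        my = (bys * w).sum(axis=1, keepdims=True) / sw
        dx, dy = bxs - mx, bys - my
        slopes = (w * dx * dy).sum(axis=1) / (w * dx**2).sum(axis=1)

    sd = float(np.std(slopes, ddof=1))
    if sd == 0:
        return 1.0 if observed == 0 else 0.0
    return _two_tailed_p(observed / sd)


def scale_per_50(est: MREstimate, *, z: float = 1.959963984540054) -> ScaledEstimate:
    """Rescale a per-mg/dL slope to an odds ratio per 50-mg/dL increase."""
    lo, hi = sorted((est.slope - z * est.slope_sd, est.slope + z * est.slope_sd))
    return ScaledEstimate(float(np.exp(50.0 * est.slope)),
                          float(np.exp(50.0 * lo)), float(np.exp(50.0 * hi)))


def bonferroni_gate(p_values: Sequence[float], n_outcomes: int = 6
                    ) -> tuple[list[bool], float]:
    """Strict Bonferroni flags: p < 0.05/n_outcomes.

    Returns (flags, threshold) with the threshold also reported rounded to
    4 decimals in logs (e.g. .0083 for six outcomes).
    """
    if n_outcomes < 1:
        raise ValueError("n_outcomes must be >= 1")
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    threshold = 0.05 / n_outcomes
    logger.info("Bonferroni threshold: %.4f (0.05/%d outcomes)", threshold, n_outcomes)
    return [bool(v) for v in (p < threshold)], threshold
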