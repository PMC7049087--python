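"""Parental-lifespan phenotypes and wGRS association analyses.

Offspring-reported parental ages are converted to binary longevity
phenotypes: a father counts as long-lived when still alive and older than
the paternal threshold (strictly), or deceased at or above it (inclusive);
analogously for mothers with a higher threshold.  "High parental life span"
means at least one long-lived parent, "top 1%" uses more extreme
thresholds.  Missing parental data propagate as missing phenotypes, never
as False.  Associations between the phenotypes and the Lp(a) wGRS (as
quartiles or as a continuous score) are logistic regressions adjusted for
age, sex and 10 ancestry principal components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .instruments import GRSVector
from .mr import MREstimate, ScaledEstimate, scale_per_50

logger = logging.getLogger(__name__)


@dataclass
class PhenotypeRuleSet:
    """Age thresholds (years) defining parental longevity phenotypes."""

    father_threshold: float = 90.0
    mother_threshold: float = 93.0
    top1_father_threshold: float = 96.0
    top1_mother_threshold: float = 98.0

    def __post_init__(self) -> None:
        if min(self.father_threshold, self.mother_threshold) <= 0:
            raise ValueError("thresholds must be positive")
        if (self.top1_father_threshold < self.father_threshold
                or self.top1_mother_threshold < self.mother_threshold):
            raise ValueError("top-1% thresholds must be >= base thresholds")


def _long_lived(age: pd.Series, alive: pd.Series, threshold: float) -> pd.Series:
    """Alive parents: strictly above threshold; deceased: at or above it."""
    age = pd.to_numeric(age, errors="coerce")
    alive = alive.astype("boolean")
    known = age.notna() & alive.notna()
    out = pd.array([pd.NA] * len(age), dtype="boolean")
    out[known] = np.where(alive[known].to_numpy(bool),
                          age[known] > threshold, age[known] >= threshold)
    return pd.Series(out, index=age.index)


def call_phenotypes(records: pd.DataFrame, rules: PhenotypeRuleSet | None = None
                    ) -> pd.DataFrame:
    """Derive binary longevity phenotypes from parental age/vital-status records.

    ``records`` needs columns subject_id, father_age, father_alive,
    mother_age, mother_alive (ages may be NaN, vital status NA).  Records
    with an out-of-range age (outside [0, 120]) are rejected and logged by
    subject id.  Returns one row per retained subject with nullable-boolean
    columns high_paternal, high_maternal, high_parental, top1_parental;
    high_parental is the Kleene OR of the parent-specific calls, so a
    single long-lived parent decides it even when the other is unknown.
    """
    rules = rules or PhenotypeRuleSet()
    rec = records.copy()
    bad = pd.Series(False, index=rec.index)
    for col in ("father_age", "mother_age"):
        age = pd.to_numeric(rec[col], errors="coerce")
        bad |= age.notna() & ((age < 0) | (age > 120))
    if bad.any():
        logger.warning("rejecting %d record(s) with out-of-range parental ages: %s",
                       int(bad.sum()), rec.loc[bad, "subject_id"].tolist())
        rec = rec[~bad]

    hp = _long_lived(rec["father_age"], rec["father_alive"], rules.father_threshold)
    hm = _long_lived(rec["mother_age"], rec["mother_alive"], rules.mother_threshold)
    tp = _long_lived(rec["father_age"], rec["father_alive"], rules.top1_father_threshold)
    tm = _long_lived(rec["mother_age"], rec["mother_alive"], rules.top1_mother_threshold)

    return pd.DataFrame({
        "subject_id": rec["subject_id"].to_numpy(),
        "high_paternal": hp.to_numpy(),
        "high_maternal": hm.to_numpy(),
        "high_parental": (hp | hm).to_numpy(),
        "top1_parental": (tp | tm).to_numpy(),
    }).astype({c: "boolean" for c in
               ("high_paternal", "high_maternal", "high_parental", "top1_parental")})


@dataclass
class LogisticContrast:
    """One logistic-regression contrast: OR with 95% Wald CI."""

    label: str
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p: float | None
    log_odds: float | None = None
    se: float | None = None
    estimable: bool = True
    note: str = ""


def _design(covariates: pd.DataFrame | None, index_len: int) -> pd.DataFrame:
    X = pd.DataFrame({"const": np.ones(index_len)})
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        # drop constant columns (all-zero covariates etc.) — they carry no
        # information and would make the design singular
        keep = [c for c in cov.columns if cov[c].nunique() > 1]
        X = pd.concat([X, cov[keep]], axis=1)
    return X


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    model = sm.GLM(y, X, family=sm.families.Binomial())
    return model.fit(maxiter=100)


def quartile_association(
    calls: pd.Series | np.ndarray,
    quartiles: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> list[LogisticContrast]:
    """Per-quartile odds ratios of a binary phenotype vs quartile 1.

    Maximum-likelihood logistic fit of phenotype on quartile indicators plus
    covariates (age, sex, 10 PCs in the standard analysis).  Subjects with a
    missing phenotype or unassigned quartile are excluded.  A quartile with
    zero cases or zero non-cases (complete separation for that indicator) is
    flagged non-estimable and excluded from the fit of the others.
    """
    y_all = pd.array(calls, dtype="boolean")
    q = np.asarray(quartiles)
    mask = ~pd.isna(y_all) & (q >= 1)
    if covariates is not None:
        covariates = covariates.reset_index(drop=True)
        mask &= ~covariates.isna().any(axis=1).to_numpy()
    y = y_all[mask].to_numpy(dtype=float)
    q = q[mask]
    cov = covariates[mask] if covariates is not None else None

    levels = sorted(np.unique(q))
    if len(levels) < 2:
        raise ValueError("need at least 2 populated quartiles")

    results: list[LogisticContrast] = []
    degenerate = set()
    for lv in levels[1:]:
        cases = y[q == lv].sum()
        noncases = (q == lv).sum() - cases
        ref_cases = y[q == levels[0]].sum()
        if cases == 0 or noncases == 0 or ref_cases == 0:
            degenerate.add(lv)
            results.append(LogisticContrast(
                f"Q{lv} vs Q{levels[0]}", None, None, None, None,
                estimable=False, note="zero cases in quartile or reference"))

    fit_mask = ~np.isin(q, list(degenerate))
    yf, qf = y[fit_mask], q[fit_mask]
    X = _design(cov[fit_mask].reset_index(drop=True) if cov is not None else None,
                int(fit_mask.sum()))
    for lv in levels[1:]:
        if lv not in degenerate:
            X[f"q{lv}"] = (qf == lv).astype(float)

    fit = _fit_logit(yf, X)
    for lv in levels[1:]:
        if lv in degenerate:
            continue
        name = f"q{lv}"
        beta = float(fit.params[name])
        se = float(fit.bse[name])
        results.append(LogisticContrast(
            f"Q{lv} vs Q{levels[0]}", float(np.exp(beta)),
            float(np.exp(beta - 1.959964 * se)), float(np.exp(beta + 1.959964 * se)),
            float(fit.pvalues[name]), log_odds=beta, se=se))
    results.sort(key=lambda r: r.label)
    return results


@dataclass
class ContinuousAssociation:
    """wGRS entered linearly: log-odds per mg/dL, rescaled per 50 mg/dL."""

    log_odds_per_mg: float | None
    se: float | None
    p: float | None
    per_50: ScaledEstimate | None
    estimable: bool = True
    note: str = ""


def continuous_association(
    calls: pd.Series | np.ndarray,
    wgrs: GRSVector,
    covariates: pd.DataFrame | None = None,
) -> ContinuousAssociation:
    """Logistic regression of a phenotype on the continuous wGRS.

    The score enters linearly (per mg/dL of genetically predicted Lp(a));
    the coefficient is rescaled to an odds ratio per 50 mg/dL.  A constant
    score is reported as non-estimable rather than fitted.
    """
    y_all = pd.array(calls, dtype="boolean")
    score = np.asarray(wgrs.score, dtype=float)
    mask = ~pd.isna(y_all) & np.isfinite(score)
    if covariates is not None:
        covariates = covariates.reset_index(drop=True)
        mask &= ~covariates.isna().any(axis=1).to_numpy()
    y = y_all[mask].to_numpy(dtype=float)
    s = score[mask]
    if np.unique(s).size < 2:
        return ContinuousAssociation(None, None, None, None, estimable=False,
                                     note="constant wGRS: association non-estimable")

    X = _design(covariates[mask] if covariates is not None else None, int(mask.sum()))
    X["wgrs"] = s
    fit = _fit_logit(y, X)
    beta, se = float(fit.params["wgrs"]), float(fit.bse["wgrs"])
    scaled = scale_per_50(_as_estimate(beta, se))
    return ContinuousAssociation(beta, se, float(fit.pvalues["wgrs"]), scaled)


def _as_estimate(beta: float, se: float) -> MREstimate:
    from scipy import stats
    p = min(1.0, 2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 1.0
    return MREstimate("IVW", beta, se, max(p, np.nextafter(0, 1)), 1)
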