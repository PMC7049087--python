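"""Prospective cause-specific mortality analyses of measured Lp(a).

Cox proportional-hazards models (Efron tie handling, via lifelines) relate
Lp(a) — as a 50-mg/dL threshold, empirical percentile bands, carrier status
at two Lp(a)-raising loci, or allele dose — to all-cause, cardiovascular
and noncardiovascular mortality.  Cause-specific hazards are obtained by
recoding: deaths from competing causes are treated as censored.  Covariate
sets follow the two standard models: Model 1 = age + sex; Model 2 adds
smoking, BMI, systolic blood pressure, diabetes and a renal-function
covariate.  The module also computes event rates and the age-equivalence
statistic (an exposure's log-hazard expressed as years of chronologic age).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

logger = logging.getLogger(__name__)

MODEL1_COVARIATES = ["age", "sex_male"]
MODEL2_COVARIATES = ["age", "sex_male", "smoking", "bmi", "sbp", "diabetes", "egfr"]

#: percentile bands of the Lp(a) distribution: <50, 50–80, 81–90, 91–95, >95
PERCENTILE_BAND_LABELS = ["<50", "50-80", "81-90", "91-95", ">95-100"]


@dataclass
class LpaGrouping:
    """Subject-level Lp(a) group labels under one grouping scheme."""

    scheme: str                      # threshold_50 | percentile_bands | top5_vs_bottom50
    cut_points: list[float]          # mg/dL boundaries actually used
    labels: pd.Series                # categorical label per subject (NaN = not in scheme)
    reference: str = ""


@dataclass
class SurvivalResult:
    """One Cox contrast: HR with 95% Wald CI plus event accounting."""

    contrast: str
    model: str
    hr: float
    ci_low: float
    ci_high: float
    beta: float
    beta_se: float
    p: float
    cases: int
    denominator: int
    event_rate_pct: float
    endpoint: str = "all-cause"
    estimable: bool = True
    note: str = ""


def event_rate(cases: int, denominator: int) -> float:
    """Percent event rate, half-up rounded to one decimal (table convention)."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if cases < 0:
        raise ValueError("cases must be >= 0")
    pct = Decimal(100 * cases) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def make_groups(lpa: pd.Series | np.ndarray, scheme: str = "threshold_50") -> LpaGrouping:
    """Group subjects by measured Lp(a) in mg/dL.

    ``threshold_50``: < 50 vs >= 50 mg/dL (the threshold value itself
    belongs to the high group).  ``percentile_bands``: [0,P50), [P50,P80],
    (P80,P90], (P90,P95], (P95,inf) computed from the empirical full-cohort
    distribution.  ``top5_vs_bottom50``: only the <50th and >=95th
    percentile groups, everyone else unlabelled.
    """
    x = pd.Series(np.asarray(lpa, dtype=float))
    if (x < 0).any():
        raise ValueError("Lp(a) must be >= 0 mg/dL")

    if scheme == "threshold_50":
        labels = pd.Series(np.where(x >= 50.0, ">=50 mg/dL", "<50 mg/dL"), index=x.index)
        return LpaGrouping(scheme, [50.0], labels, reference="<50 mg/dL")

    if scheme in ("percentile_bands", "top5_vs_bottom50"):
        if len(x) < 20:
            raise ValueError("percentile schemes need at least 20 subjects")
        p50, p80, p90, p95 = (float(v) for v in np.percentile(x, [50, 80, 90, 95]))
        if len({p50, p80, p90, p95}) < 4:
            raise ValueError("degenerate Lp(a) distribution: percentile cut "
                             "points are not distinct")
        lab = np.select(
            [x < p50, x <= p80, x <= p90, x <= p95],
            PERCENTILE_BAND_LABELS[:4], default=PERCENTILE_BAND_LABELS[4])
        labels = pd.Series(pd.Categorical(lab, categories=PERCENTILE_BAND_LABELS,
                                          ordered=True), index=x.index)
        if scheme == "top5_vs_bottom50":
            labels = labels.where(labels.isin(["<50", ">95-100"]))
        return LpaGrouping(scheme, [p50, p80, p90, p95], labels, reference="<50")

    raise ValueError(f"unknown grouping scheme {scheme!r}")


def cause_specific_events(event: pd.Series, cause: pd.Series, endpoint: str) -> pd.Series:
    """Recode the event indicator for a cause-specific Cox model.

    ``endpoint`` is 'all-cause', 'cvd' or 'non-cvd'; deaths from the
    competing cause count as censored.
    """
    ev = pd.Series(np.asarray(event, dtype=int))
    cz = pd.Series(np.asarray(cause, dtype=object))
    if endpoint == "all-cause":
        return ev
    if endpoint == "cvd":
        return ((ev == 1) & (cz == "cvd")).astype(int)
    if endpoint == "non-cvd":
        return ((ev == 1) & (cz != "cvd")).astype(int)
    raise ValueError(f"unknown endpoint {endpoint!r}")


def fit_cox(
    data: pd.DataFrame,
    exposure: str | LpaGrouping,
    *,
    covariates: list[str] = MODEL1_COVARIATES,
    duration_col: str = "time",
    event_col: str = "event",
    model: str = "Model 1",
    endpoint: str = "all-cause",
    report_covariates: list[str] | None = None,
) -> list[SurvivalResult]:
    """Cox proportional-hazards fit returning one result per exposure contrast.

    ``exposure`` is either the name of a numeric column (one result, HR per
    unit) or an :class:`LpaGrouping` (one result per non-reference group,
    indicator-coded against the grouping's reference).  Efron's method
    handles tied event times.  Non-convergence and monotone-likelihood
    (separation) problems are reported as non-estimable results, never
    silently dropped.
    """
    df = data.copy().reset_index(drop=True)
    if (df[duration_col] <= 0).any():
        raise ValueError("durations must be > 0")

    terms: list[tuple[str, str, pd.Series | None]] = []  # (column, contrast label, membership)
    if isinstance(exposure, LpaGrouping):
        labels = exposure.labels.reset_index(drop=True)
        df = df[labels.notna().to_numpy()].copy()
        labels = labels.dropna().reset_index(drop=True)
        ref = exposure.reference
        if isinstance(labels.dtype, pd.CategoricalDtype):
            present = set(labels.dropna())
            level_order = [l for l in labels.cat.categories if l in present]
            labels = labels.astype(object)
        else:
            level_order = list(pd.unique(labels))
        for lv in [l for l in level_order if l != ref]:
            col = f"grp[{lv}]"
            df[col] = (labels == lv).astype(float).to_numpy()
            terms.append((col, f"{lv} vs {ref}", labels == lv))
    else:
        terms.append((exposure, f"{exposure} (per unit)", None))
    for cov in report_covariates or []:
        terms.append((cov, f"{cov} (per unit)", None))

    fit_cols = list(dict.fromkeys(
        [c for c, _, _ in terms] + [c for c in covariates if df[c].nunique() > 1]))
    sub = df[[duration_col, event_col] + fit_cols]

    cph = CoxPHFitter()
    try:
        cph.fit(sub, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        logger.warning("Cox model did not converge: %s", err)
        return [_nonestimable(lbl, model, endpoint, f"non-convergence: {err}")
                for _, lbl, _ in terms]

    results = []
    total_events = int(sub[event_col].sum())
    for col, label, member in terms:
        beta = float(cph.params_[col])
        se = float(cph.standard_errors_[col])
        if member is not None:
            cases = int(sub.loc[member.to_numpy(), event_col].sum())
            denom = int(member.sum())
        else:
            cases, denom = total_events, len(sub)
        results.append(SurvivalResult(
            contrast=label, model=model,
            hr=float(np.exp(beta)),
            ci_low=float(np.exp(beta - 1.959964 * se)),
            ci_high=float(np.exp(beta + 1.959964 * se)),
            beta=beta, beta_se=se, p=float(cph.summary.loc[col, "p"]),
            cases=cases, denominator=denom,
            event_rate_pct=event_rate(cases, denom), endpoint=endpoint,
        ))
    return results


def _nonestimable(label: str, model: str, endpoint: str, note: str) -> SurvivalResult:
    return SurvivalResult(label, model, float("nan"), float("nan"), float("nan"),
                          float("nan"), float("nan"), float("nan"), 0, 0, 0.0,
                          endpoint=endpoint, estimable=False, note=note)


@dataclass
class AgeEquivalence:
    """Exposure log-hazard expressed as years of chronologic age."""

    beta_group: float
    beta_age_per_year: float
    years_equivalent: float = field(init=False)

    def __post_init__(self) -> None:
        if self.beta_age_per_year == 0:
            raise ValueError("beta_age_per_year must be nonzero")
        self.years_equivalent = self.beta_group / self.beta_age_per_year


def age_equivalence(beta_group: float, beta_age: float) -> AgeEquivalence:
    """Divide an exposure's mortality log-hazard by the per-year age log-hazard."""
    return AgeEquivalence(beta_group, beta_age)


def allele_dose_groups(dosage_a: np.ndarray, dosage_b: np.ndarray) -> pd.Series:
    """Combined raising-allele count over two loci, grouped 0 / 1 / 2+."""
    total = np.asarray(dosage_a) + np.asarray(dosage_b)
    lab = np.select([total == 0, total == 1], ["0", "1"], default="2+")
    return pd.Series(lab)


def carrier_analysis(
    data: pd.DataFrame,
    locus_a: str,
    locus_b: str,
    *,
    covariates: list[str] = MODEL1_COVARIATES,
    duration_col: str = "time",
    event_col: str = "event",
    endpoint: str = "all-cause",
    adjust_for_lpa: bool = False,
) -> dict[str, list[SurvivalResult]]:
    """Carrier and allele-dose mortality contrasts at two Lp(a)-raising loci.

    Per locus: carriers (>= 1 raising allele) vs noncarriers, Model-1
    covariates.  Combined: allele-dose groups 0 / 1 / 2+ summed over both
    loci, contrasted against 0.  ``adjust_for_lpa`` additionally conditions
    on measured Lp(a) (mediation check: the carrier HR should attenuate
    toward 1 when the effect acts through Lp(a) levels).  An empty carrier
    group is reported non-estimable.
    """
    covs = list(covariates) + (["lpa"] if adjust_for_lpa else [])
    out: dict[str, list[SurvivalResult]] = {}

    for locus in (locus_a, locus_b):
        carrier = (data[locus].to_numpy(float) >= 1).astype(float)
        if carrier.sum() == 0 or carrier.sum() == len(carrier):
            out[locus] = [_nonestimable(f"carrier vs noncarrier ({locus})", "Model 1",
                                        endpoint, "empty carrier or noncarrier group")]
            continue
        df = data.copy()
        grouping = LpaGrouping("carrier", [], pd.Series(
            np.where(carrier == 1, "carrier", "noncarrier"), index=df.index),
            reference="noncarrier")
        res = fit_cox(df, grouping, covariates=covs, duration_col=duration_col,
                      event_col=event_col, model="Model 1", endpoint=endpoint)
        for r in res:
            r.contrast = f"{locus}: {r.contrast}"
        out[locus] = res

    dose = allele_dose_groups(data[locus_a].to_numpy(float),
                              data[locus_b].to_numpy(float))
    grouping = LpaGrouping("allele_dose", [], dose.set_axis(data.index), reference="0")
    out["allele_dose"] = fit_cox(data, grouping, covariates=covs,
                                 duration_col=duration_col, event_col=event_col,
                                 model="Model 1", endpoint=endpoint)
    return out
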