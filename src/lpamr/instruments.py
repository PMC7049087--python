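"""Harmonization of GWAS summary statistics, weighted genetic risk scores, quartiles.

Two-sample MR combines per-SNP effects on the exposure (Lp(a), mg/dL per
effect allele) from one study with effects on the outcome (log-odds or
log-hazard per allele) from another.  Before any estimator runs, the two
tables must refer to the same effect allele at every SNP; this module
performs that alignment, builds the dosage-weighted genetic risk score
(wGRS, in mg/dL of genetically predicted Lp(a)) and assigns wGRS quartiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default effect-allele-frequency window inside which palindromic (A/T, C/G)
#: SNPs are considered strand-ambiguous and dropped.
PALINDROMIC_EAF_WINDOW = (0.42, 0.58)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

SUMMARY_STAT_COLUMNS = ["rsid", "effect_allele", "other_allele", "eaf", "beta", "se", "p"]


class HarmonizedSNP(NamedTuple):
    """One instrument SNP after allele alignment (beta_exp oriented >= 0)."""

    rsid: str
    effect_allele: str
    other_allele: str
    maf: float
    beta_exp: float   # mg/dL per effect allele
    se_exp: float
    beta_out: float   # log-odds / log-hazard per effect allele
    se_out: float


@dataclass
class SummaryStatSet:
    """Harmonized per-SNP exposure + outcome effects, the MR estimators' input.

    ``snps`` is a DataFrame with columns rsid, effect_allele, other_allele,
    maf, beta_exp, se_exp, beta_out, se_out; one row per SNP, rsids unique,
    every beta_exp >= 0 by the orientation convention.
    """

    snps: pd.DataFrame
    exposure_label: str = "Lp(a)"
    outcome_label: str = "outcome"

    def __post_init__(self) -> None:
        required = ["rsid", "effect_allele", "other_allele", "maf",
                    "beta_exp", "se_exp", "beta_out", "se_out"]
        missing = [c for c in required if c not in self.snps.columns]
        if missing:
            raise ValueError(f"SummaryStatSet missing columns: {missing}")
        if len(self.snps) == 0:
            raise ValueError("SummaryStatSet may not be empty")
        if self.snps["rsid"].duplicated().any():
            dup = self.snps.loc[self.snps["rsid"].duplicated(), "rsid"].tolist()
            raise ValueError(f"duplicate rsids in SummaryStatSet: {dup}")
        if (self.snps["se_exp"] <= 0).any() or (self.snps["se_out"] <= 0).any():
            raise ValueError("standard errors must be strictly positive")
        self.snps = self.snps.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self) -> Iterator[HarmonizedSNP]:
        for row in self.snps.itertuples(index=False):
            yield HarmonizedSNP(row.rsid, row.effect_allele, row.other_allele,
                                row.maf, row.beta_exp, row.se_exp,
                                row.beta_out, row.se_out)

    @property
    def oriented(self) -> bool:
        return bool((self.snps["beta_exp"] >= 0).all())

    def to_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Exposure and outcome tables in the on-disk summary-stat schema."""
        from scipy import stats

        def _table(beta_col: str, se_col: str) -> pd.DataFrame:
            beta = self.snps[beta_col].to_numpy(float)
            se = self.snps[se_col].to_numpy(float)
            return pd.DataFrame({
                "rsid": self.snps["rsid"],
                "effect_allele": self.snps["effect_allele"],
                "other_allele": self.snps["other_allele"],
                "eaf": self.snps["maf"],
                "beta": beta,
                "se": se,
                "p": 2.0 * stats.norm.sf(np.abs(beta) / se),
            })

        return _table("beta_exp", "se_exp"), _table("beta_out", "se_out")


@dataclass
class GRSVector:
    """Per-subject weighted genetic risk score, mg/dL of predicted Lp(a)."""

    subject_ids: np.ndarray
    score: np.ndarray
    weight_source: str = "unspecified"
    #: subjects whose score could not be computed (missingness cap exceeded)
    n_flagged: int = 0

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.score = np.asarray(self.score, dtype=float)
        if self.subject_ids.shape[0] != self.score.shape[0]:
            raise ValueError("one score per subject required")

    def __len__(self) -> int:
        return len(self.score)


#: bundled synthetic example weight files (schema: summary-stat columns with
#: beta in mg/dL per allele); real weight files are drop-in replacements
EXAMPLE_WEIGHT_SOURCES = {
    "burgess-style": "burgess_style_weights_synthetic.tsv",
    "mack-style": "mack_style_weights_synthetic.tsv",
    "mack-style-isoform-adjusted": "mack_style_isoform_adjusted_weights_synthetic.tsv",
}


def load_example_weights(source: str = "burgess-style") -> pd.DataFrame:
    """Load one of the bundled synthetic instrument weight tables.

    These mimic the shape of published Lp(a) instrument sets (26 and 22 SNPs
    including two high-impact variants) but the numbers are synthetic.
    """
    from importlib.resources import files

    if source not in EXAMPLE_WEIGHT_SOURCES:
        raise ValueError(f"unknown weight source {source!r}; "
                         f"choose from {sorted(EXAMPLE_WEIGHT_SOURCES)}")
    path = files("lpamr") / "data" / EXAMPLE_WEIGHT_SOURCES[source]
    return pd.read_csv(path, sep="\t")


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    *,
    exposure_label: str = "Lp(a)",
    outcome_label: str = "outcome",
    palindromic_eaf_window: tuple[float, float] = PALINDROMIC_EAF_WINDOW,
) -> SummaryStatSet:
    """Align exposure and outcome summary statistics onto shared effect alleles.

    Inner-joins on rsid; outcome rows whose effect/other alleles are swapped
    relative to the exposure get their beta sign flipped and eaf complemented;
    rows whose allele sets cannot be reconciled, and palindromic SNPs with
    eaf inside ``palindromic_eaf_window`` (strand-ambiguous), are dropped with
    a warning.  Finally every SNP is oriented so beta_exp >= 0, flipping both
    betas together — the convention MR-Egger presupposes.
    """
    for name, tab in (("exposure", exposure), ("outcome", outcome)):
        missing = [c for c in ("rsid", "effect_allele", "other_allele", "beta", "se")
                   if c not in tab.columns]
        if missing:
            raise ValueError(f"{name} table missing columns: {missing}")

    merged = exposure.merge(outcome, on="rsid", suffixes=("_exp", "_out"), how="inner")
    if len(merged) == 0:
        raise ValueError(
            f"no overlapping rsids between exposure {exposure_label!r} "
            f"and outcome {outcome_label!r} tables"
        )

    same = (merged["effect_allele_exp"] == merged["effect_allele_out"]) & (
        merged["other_allele_exp"] == merged["other_allele_out"])
    swapped = (merged["effect_allele_exp"] == merged["other_allele_out"]) & (
        merged["other_allele_exp"] == merged["effect_allele_out"])
    irreconcilable = ~(same | swapped)
    if irreconcilable.any():
        dropped = merged.loc[irreconcilable, "rsid"].tolist()
        logger.warning("dropping %d SNP(s) with irreconcilable alleles: %s",
                       len(dropped), dropped)
        merged = merged[~irreconcilable].copy()
        same, swapped = same[~irreconcilable], swapped[~irreconcilable]

    # align outcome to exposure's effect allele
    beta_out = np.where(swapped, -merged["beta_out"], merged["beta_out"])
    if "eaf_exp" in merged.columns:
        eaf = merged["eaf_exp"].to_numpy(float)
    else:
        eaf = np.where(swapped, 1.0 - merged["eaf_out"], merged["eaf_out"])

    palindromic = merged.apply(
        lambda r: _is_palindromic(r["effect_allele_exp"], r["other_allele_exp"]), axis=1
    ).to_numpy(bool)
    lo, hi = palindromic_eaf_window
    ambiguous = palindromic & (eaf >= lo) & (eaf <= hi)
    if ambiguous.any():
        dropped = merged.loc[ambiguous, "rsid"].tolist()
        logger.warning("dropping %d strand-ambiguous palindromic SNP(s): %s",
                       len(dropped), dropped)

    keep = ~ambiguous
    merged, beta_out, eaf = merged[keep], beta_out[keep], eaf[keep]
    if len(merged) == 0:
        raise ValueError("all overlapping SNPs were dropped during harmonization")

    beta_exp = merged["beta_exp"].to_numpy(float)
    effect = merged["effect_allele_exp"].to_numpy(object)
    other = merged["other_allele_exp"].to_numpy(object)

    # orient to beta_exp >= 0: flip both betas, swap alleles, complement eaf
    flip = beta_exp < 0
    beta_exp = np.where(flip, -beta_exp, beta_exp)
    beta_out = np.where(flip, -beta_out, beta_out)
    effect, other = np.where(flip, other, effect), np.where(flip, effect, other)
    eaf = np.where(flip, 1.0 - eaf, eaf)

    snps = pd.DataFrame({
        "rsid": merged["rsid"].to_numpy(),
        "effect_allele": effect,
        "other_allele": other,
        "maf": np.minimum(eaf, 1.0 - eaf),
        "beta_exp": beta_exp,
        "se_exp": merged["se_exp"].to_numpy(float),
        "beta_out": beta_out,
        "se_out": merged["se_out"].to_numpy(float),
    })
    return SummaryStatSet(snps, exposure_label=exposure_label, outcome_label=outcome_label)


def build_wgrs(
    dosages: pd.DataFrame,
    stat_set: SummaryStatSet | pd.DataFrame,
    *,
    max_missing_frac: float = 0.10,
    weight_source: str = "unspecified",
    maf_standardize: bool = False,
) -> GRSVector:
    """Dosage-weighted genetic risk score: score_i = sum_j beta_exp_j * g_ij.

    ``dosages`` is subjects x SNPs (columns named by rsid, values in [0, 2],
    NaN for missing).  Missing dosages are mean-imputed to 2*maf; a subject
    with more than ``max_missing_frac`` of SNPs missing gets a NaN score
    (flagged absent, never silently zero).

    ``maf_standardize`` rescales each weight by sqrt(2*maf*(1-maf)) — a
    per-allele to per-genotype-SD conversion sometimes described as adjusting
    for minor allele frequency.  Off by default; when on, the score is no
    longer in mg/dL and a warning says so.
    """
    if isinstance(stat_set, SummaryStatSet):
        weights = stat_set.snps[["rsid", "maf", "beta_exp"]].rename(
            columns={"beta_exp": "beta"})
    else:
        weights = stat_set.rename(columns={"eaf": "maf"}) if "eaf" in stat_set.columns \
            else stat_set
        weights = weights[["rsid", "maf", "beta"]]

    missing_cols = [r for r in weights["rsid"] if r not in dosages.columns]
    if missing_cols:
        raise ValueError(f"dosage matrix lacks columns for rsids: {missing_cols}")

    G = dosages[list(weights["rsid"])].to_numpy(float)
    if np.nanmin(G, initial=0.0) < 0 or np.nanmax(G, initial=0.0) > 2:
        raise ValueError("dosages must lie in [0, 2]")

    w = weights["beta"].to_numpy(float)
    maf = weights["maf"].to_numpy(float)
    if maf_standardize:
        logger.warning("maf_standardize: weights rescaled by sqrt(2*maf*(1-maf)); "
                       "scores are per genotype SD, not mg/dL")
        w = w * np.sqrt(2.0 * maf * (1.0 - maf))
    miss = np.isnan(G)
    G_imp = np.where(miss, 2.0 * maf[None, :], G)
    score = G_imp @ w

    over_cap = miss.mean(axis=1) > max_missing_frac
    score[over_cap] = np.nan
    if over_cap.any():
        logger.warning("%d subject(s) exceed the %.0f%% dosage-missingness cap; "
                       "scores flagged absent", int(over_cap.sum()),
                       100 * max_missing_frac)

    ids = dosages.index.to_numpy()
    return GRSVector(ids, score, weight_source=weight_source,
                     n_flagged=int(over_cap.sum()))


def assign_quartiles(scores: GRSVector | np.ndarray | pd.Series) -> np.ndarray:
    """Quartile labels 1–4 from the empirical 25/50/75th percentiles.

    Ties exactly at a cut point go to the lower quartile.  Requires at least
    four distinct finite score values; NaN scores get quartile 0 (unassigned).
    """
    x = scores.score if isinstance(scores, GRSVector) else np.asarray(scores, float)
    finite = np.isfinite(x)
    vals = x[finite]
    if np.unique(vals).size < 4:
        raise ValueError("need at least 4 distinct score values to form quartiles")
    cuts = np.percentile(vals, [25, 50, 75])
    q = np.zeros(x.shape, dtype=int)
    q[finite] = 1 + np.searchsorted(cuts, vals, side="left")
    return q
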