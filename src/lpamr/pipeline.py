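"""End-to-end orchestration: simulate -> harmonize -> MR -> phenotypes -> survival.

A :class:`RunConfig` (built in code or loaded from YAML) names either input
files or simulation blocks for the summary statistics and the cohort, plus
analysis toggles and a single global seed.  The seed fans out to fixed
per-stage child seeds, so toggling one stage never perturbs another's
random stream and identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .instruments import GRSVector, SummaryStatSet, assign_quartiles, build_wgrs, harmonize
from .mr import bonferroni_gate, bootstrap_pvalue, egger_estimate, ivw_estimate, scale_per_50
from .phenotypes import (ContinuousAssociation, LogisticContrast, PhenotypeRuleSet,
                         call_phenotypes, continuous_association, quartile_association)
from .report import (MRRecord, render_age_equivalence, render_forest_rows,
                     render_mr_table, render_survival_table)
from .survival import (MODEL1_COVARIATES, MODEL2_COVARIATES, AgeEquivalence,
                       SurvivalResult, age_equivalence, carrier_analysis,
                       cause_specific_events, fit_cox, make_groups)
from .synthetic import CohortConfig, SummaryStatsConfig, generate_cohort, generate_summary_stats

logger = logging.getLogger(__name__)

_STAGE_KEYS = {"summary_stats": 0, "cohort": 1, "bootstrap": 2}


def stage_seed(seed: int, stage: str) -> int:
    """Fixed per-stage child seed derived from the global seed."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_KEYS[stage],))
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Each input is either a file path or a simulate block, never both.
    ``renal_covariate`` names the renal-function column used in Model 2
    (recorded in the report).
    """

    seed: int = 0
    output_dir: str | None = None
    n_bootstrap: int = 100_000
    bonferroni_n: int = 6
    outcome_label: str = "high parental life span"
    analyses: dict[str, bool] = field(default_factory=lambda: {
        "mr": True, "quartiles": True, "survival": True, "carriers": True})
    summary_stats: SummaryStatsConfig | None = None
    cohort: CohortConfig | None = None
    exposure_path: str | None = None
    outcome_path: str | None = None
    cohort_path: str | None = None
    weights_path: str | None = None
    phenotype_rules: PhenotypeRuleSet = field(default_factory=PhenotypeRuleSet)
    renal_covariate: str = "egfr"
    #: optional offspring recruitment-age window applied before phenotype calling
    offspring_age_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.summary_stats is not None and (self.exposure_path or self.outcome_path):
            raise ValueError("give either a summary-stats simulate block or file "
                             "paths, never both")
        if self.cohort is not None and self.cohort_path:
            raise ValueError("give either a cohort simulate block or a cohort_path, "
                             "never both")
        if self.summary_stats is None and not (self.exposure_path and self.outcome_path):
            self.summary_stats = SummaryStatsConfig()
        if self.cohort is None and not self.cohort_path:
            self.cohort = CohortConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = dict(raw)
        if "summary_stats" in kw and kw["summary_stats"] is not None:
            blk = dict(kw["summary_stats"])
            for key in ("exposure_effect_range", "maf_range"):
                if key in blk:
                    blk[key] = tuple(blk[key])
            kw["summary_stats"] = SummaryStatsConfig(**blk)
        if "cohort" in kw and kw["cohort"] is not None:
            blk = dict(kw["cohort"])
            for key in ("low_value_range", "age_range", "parental_thresholds"):
                if key in blk:
                    blk[key] = tuple(blk[key])
            kw["cohort"] = CohortConfig(**blk)
        if "phenotype_rules" in kw and kw["phenotype_rules"] is not None:
            kw["phenotype_rules"] = PhenotypeRuleSet(**kw["phenotype_rules"])
        if "offspring_age_range" in kw and kw["offspring_age_range"] is not None:
            kw["offspring_age_range"] = tuple(kw["offspring_age_range"])
        return cls(**kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything one run computed, plus provenance and surfaced warnings."""

    provenance: dict
    mr_records: list[MRRecord] = field(default_factory=list)
    mr_disabled_reason: str | None = None
    bonferroni_threshold: float | None = None
    phenotype_counts: dict[str, int] = field(default_factory=dict)
    quartile_ors: list[LogisticContrast] = field(default_factory=list)
    continuous: ContinuousAssociation | None = None
    survival_results: list[SurvivalResult] = field(default_factory=list)
    carrier_results: dict[str, list[SurvivalResult]] = field(default_factory=dict)
    age_equiv: AgeEquivalence | None = None
    lpa_band_cut_points: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def run(config: RunConfig) -> RunReport:
    """Execute the enabled stages in dependency order and collect the report."""
    collector = _WarningCollector()
    logging.getLogger("lpamr").addHandler(collector)
    try:
        return _run(config, collector)
    finally:
        logging.getLogger("lpamr").removeHandler(collector)


def _run(config: RunConfig, collector: _WarningCollector) -> RunReport:
    report = RunReport(provenance={
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "lpamr_version": __version__,
    })

    # --- inputs: summary statistics -------------------------------------
    if config.summary_stats is not None:
        ss_cfg = dataclasses.replace(
            config.summary_stats, seed=stage_seed(config.seed, "summary_stats"))
        exposure, outcome = generate_summary_stats(ss_cfg)
    else:
        exposure = _read_table(config.exposure_path)
        outcome = _read_table(config.outcome_path)
    stat_set = harmonize(exposure, outcome, outcome_label=config.outcome_label)

    # --- MR --------------------------------------------------------------
    if config.analyses.get("mr", True):
        ivw = ivw_estimate(stat_set)
        egger = egger_estimate(stat_set)
        boot_p = bootstrap_pvalue(stat_set, "IVW", n_reps=config.n_bootstrap,
                                  seed=stage_seed(config.seed, "bootstrap"))
        flags, thr = bonferroni_gate([ivw.slope_p], n_outcomes=config.bonferroni_n)
        report.mr_records.append(MRRecord(
            outcome=config.outcome_label, ivw=ivw, egger=egger,
            ivw_per_50=scale_per_50(ivw), bootstrap_p=boot_p, significant=flags[0]))
        report.bonferroni_threshold = thr
    else:
        report.mr_disabled_reason = "MR stage disabled in config (analyses.mr = false)"

    # --- cohort ----------------------------------------------------------
    if config.cohort is not None:
        co_cfg = dataclasses.replace(config.cohort,
                                     seed=stage_seed(config.seed, "cohort"))
        weights = stat_set.snps[["rsid", "maf", "beta_exp"]].rename(
            columns={"beta_exp": "beta"})
        cohort = generate_cohort(co_cfg, weights)
    else:
        cohort = _read_table(config.cohort_path)
    if config.weights_path:
        weights = _read_table(config.weights_path).rename(columns={"eaf": "maf"})
    else:
        weights = stat_set.snps[["rsid", "maf", "beta_exp"]].rename(
            columns={"beta_exp": "beta"})

    pheno_cohort = cohort
    if config.offspring_age_range is not None:
        lo, hi = config.offspring_age_range
        pheno_cohort = cohort[(cohort["age"] >= lo) & (cohort["age"] <= hi)]

    # --- phenotypes + wGRS associations ----------------------------------
    if config.analyses.get("quartiles", True):
        calls = call_phenotypes(pheno_cohort, config.phenotype_rules)
        merged = pheno_cohort.merge(calls, on="subject_id")
        for col in ("high_parental", "top1_parental", "high_paternal", "high_maternal"):
            report.phenotype_counts[col] = int(merged[col].sum())
        geno = merged.set_index("subject_id")[list(weights["rsid"])]
        grs = build_wgrs(geno, weights, weight_source="run")
        quartiles = assign_quartiles(grs)
        covs = merged[["age", "sex_male"] + [f"pc{i}" for i in range(1, 11)]]
        y = merged["high_parental"]
        report.quartile_ors = quartile_association(y, quartiles, covs)
        report.continuous = continuous_association(y, grs, covs)

    # --- survival --------------------------------------------------------
    model2 = [c if c != "egfr" else config.renal_covariate for c in MODEL2_COVARIATES]
    if config.analyses.get("survival", True):
        for scheme in ("threshold_50", "percentile_bands"):
            grouping = make_groups(cohort["lpa"], scheme)
            if scheme == "percentile_bands":
                report.lpa_band_cut_points = grouping.cut_points
            for endpoint in ("all-cause", "cvd"):
                ev = cause_specific_events(cohort["event"], cohort["cause"], endpoint)
                df = cohort.assign(event=ev.to_numpy())
                for model, covs in (("Model 1", MODEL1_COVARIATES), ("Model 2", model2)):
                    report.survival_results.extend(fit_cox(
                        df, grouping, covariates=covs, model=model, endpoint=endpoint))
        # age equivalence: top-5% vs bottom-50% and per-year age from one Model-1 fit
        grouping = make_groups(cohort["lpa"], "top5_vs_bottom50")
        res = fit_cox(cohort, grouping, covariates=MODEL1_COVARIATES,
                      model="Model 1", endpoint="all-cause",
                      report_covariates=["age"])
        group_res = next(r for r in res if r.contrast.startswith(">95"))
        age_res = next(r for r in res if r.contrast.startswith("age"))
        report.age_equiv = age_equivalence(group_res.beta, age_res.beta)
        report.survival_results.extend(res)

    if config.analyses.get("carriers", True):
        # the two largest-weight instruments play the role of the two
        # high-impact Lp(a)-raising loci
        top2 = weights.nlargest(2, "beta")["rsid"].tolist()
        for endpoint in ("all-cause", "cvd"):
            ev = cause_specific_events(cohort["event"], cohort["cause"], endpoint)
            df = cohort.assign(event=ev.to_numpy())
            res = carrier_analysis(df, top2[0], top2[1], endpoint=endpoint)
            for key, value in res.items():
                report.carrier_results[f"{key} ({endpoint})"] = value

    report.warnings = list(collector.messages)
    if config.output_dir:
        write_outputs(report, config.output_dir)
    return report


def render_tables(report: RunReport) -> str:
    """Render the full run report as concatenated text tables."""
    blocks = [render_mr_table(report.mr_records)]
    if report.mr_disabled_reason:
        blocks.append(f"# note: {report.mr_disabled_reason}")
    if report.quartile_ors:
        est = [r for r in report.quartile_ors if r.estimable]
        blocks.append(render_forest_rows(
            [r.label for r in est], [r.odds_ratio for r in est],
            [r.ci_low for r in est], [r.ci_high for r in est]))
    blocks.append(render_survival_table(report.survival_results,
                                        "Survival analyses (measured Lp(a))"))
    for key, value in report.carrier_results.items():
        blocks.append(render_survival_table(value, f"Carrier analyses: {key}"))
    blocks.append(render_age_equivalence(report.age_equiv))
    if report.warnings:
        blocks.append("# warnings\n" + "\n".join(f"# - {w}" for w in report.warnings))
    return "\n\n".join(blocks) + "\n"


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, pd.Series):
        return obj.tolist()
    return obj


def report_to_dict(report: RunReport) -> dict:
    return _to_jsonable(dataclasses.asdict(report))


def write_outputs(report: RunReport, output_dir: str | Path) -> None:
    """Write report.json (machine-readable) and tables.txt (rendered)."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = report_to_dict(report)
    (out / "report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True, allow_nan=False) + "\n")
    (out / "tables.txt").write_text(
        f"# config {report.provenance['config_hash']} seed {report.provenance['seed']}\n\n"
        + render_tables(report))
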