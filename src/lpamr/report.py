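"""Text-table rendering of run results, mirroring the standard report layout.

Three blocks: an MR-estimates table (one row per exposure-outcome pair with
IVW and Egger slopes, SDs, p-values, the Egger intercept and its p), Cox
survival blocks (contrast, model, HR with CI, cases/denominator and event
rate), and forest-plot-ready rows (label, OR/HR, CI).  Rendered values are
pipe-delimited at fixed printed precision so that a rendered table can be
parsed back into its machine-readable values exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from .mr import MREstimate, ScaledEstimate
from .survival import AgeEquivalence, SurvivalResult


@dataclass
class MRRecord:
    """All MR outputs for one exposure-outcome pair."""

    outcome: str
    ivw: MREstimate
    egger: MREstimate
    ivw_per_50: ScaledEstimate
    bootstrap_p: float | None = None
    significant: bool | None = None


def _fmt(x: float | None, nd: int = 4) -> str:
    return "NA" if x is None else f"{x:.{nd}f}"


def render_mr_table(records: list[MRRecord]) -> str:
    """MR summary block: slope (SD), p, Egger intercept and intercept p."""
    header = ("outcome | ivw_slope | ivw_sd | ivw_p | egger_slope | egger_sd | "
              "egger_p | intercept | intercept_p | n_snps | bootstrap_p | or_per_50 "
              "| ci_low | ci_high")
    lines = ["# MR estimates (slope in outcome units per mg/dL Lp(a))", header]
    for r in records:
        lines.append(" | ".join([
            r.outcome,
            _fmt(r.ivw.slope), _fmt(r.ivw.slope_sd), f"{r.ivw.slope_p:.3e}",
            _fmt(r.egger.slope), _fmt(r.egger.slope_sd), f"{r.egger.slope_p:.3e}",
            _fmt(r.egger.intercept), _fmt(r.egger.intercept_p),
            str(r.ivw.n_snps),
            "NA" if r.bootstrap_p is None else f"{r.bootstrap_p:.3e}",
            _fmt(r.ivw_per_50.odds_ratio_per_50, 2),
            _fmt(r.ivw_per_50.ci_low, 2), _fmt(r.ivw_per_50.ci_high, 2),
        ]))
    return "\n".join(lines)


def parse_mr_table(text: str) -> pd.DataFrame:
    """Inverse of :func:`render_mr_table` at printed precision."""
    lines = [l for l in text.splitlines() if l and not l.startswith("#")]
    cols = [c.strip() for c in lines[0].split("|")]
    rows = []
    for line in lines[1:]:
        vals = [v.strip() for v in line.split("|")]
        row: dict[str, Any] = {"outcome": vals[0]}
        for c, v in zip(cols[1:], vals[1:]):
            row[c] = None if v == "NA" else (int(v) if c == "n_snps" else float(v))
        rows.append(row)
    return pd.DataFrame(rows)


def render_survival_table(results: list[SurvivalResult], title: str) -> str:
    """Survival block: one row per contrast with HR (95% CI) and event rate."""
    header = ("contrast | endpoint | model | hr | ci_low | ci_high | beta | beta_se "
              "| cases | denominator | event_rate_pct")
    lines = [f"# {title}", header]
    for r in results:
        if not r.estimable:
            lines.append(f"{r.contrast} | {r.endpoint} | {r.model} | NA | NA | NA | "
                         f"NA | NA | {r.cases} | {r.denominator} | NA  # {r.note}")
            continue
        lines.append(" | ".join([
            r.contrast, r.endpoint, r.model,
            f"{r.hr:.2f}", f"{r.ci_low:.2f}", f"{r.ci_high:.2f}",
            f"{r.beta:.4f}", f"{r.beta_se:.4f}",
            str(r.cases), str(r.denominator), f"{r.event_rate_pct:.1f}",
        ]))
    return "\n".join(lines)


def parse_survival_table(text: str) -> pd.DataFrame:
    """Inverse of :func:`render_survival_table` at printed precision."""
    lines = [l for l in text.splitlines() if l and not l.startswith("#")]
    cols = [c.strip() for c in lines[0].split("|")]
    rows = []
    for line in lines[1:]:
        line = line.split("  #")[0]
        vals = [v.strip() for v in line.split("|")]
        row: dict[str, Any] = {}
        for c, v in zip(cols, vals):
            if c in ("contrast", "endpoint", "model"):
                row[c] = v
            elif c in ("cases", "denominator"):
                row[c] = int(v)
            else:
                row[c] = None if v == "NA" else float(v)
        rows.append(row)
    return pd.DataFrame(rows)


def render_forest_rows(labels: list[str], estimates: list[float],
                       ci_lows: list[float], ci_highs: list[float]) -> str:
    """Forest-plot-ready rows: label, ratio estimate, 95% CI bounds."""
    lines = ["# forest rows", "label | estimate | ci_low | ci_high"]
    for lab, est, lo, hi in zip(labels, estimates, ci_lows, ci_highs):
        lines.append(f"{lab} | {est:.2f} | {lo:.2f} | {hi:.2f}")
    return "\n".join(lines)


def render_age_equivalence(eq: AgeEquivalence | None) -> str:
    lines = ["# age equivalence (all-cause mortality)",
             "beta_group | beta_age_per_year | years_equivalent"]
    if eq is not None:
        lines.append(f"{eq.beta_group:.4f} | {eq.beta_age_per_year:.4f} | "
                     f"{eq.years_equivalent:.2f}")
    return "\n".join(lines)
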