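"""Orchestrate the two association analyses per drug-class cohort.

Analysis 1 (``adr_adr``): mine ADR-only transactions and report the top
rules with a single ADR consequent, ranked by descending support.

Analysis 2 (``demo_gender``): mine ADR + demographic transactions with the
consequent constrained to a single gender item (antecedent gender-free) and
report, per gender, the top rules by descending support.

Ranking ties break by descending confidence, then descending lift, then
lexicographic antecedent and consequent labels, so top-k output is fully
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .apriori import AssociationRule, MinerConfig, frequent_itemsets, generate_rules
from .jader_io import Case, Gender
from .rule_stats import round_half_up
from .transactions import build_adr_transactions, build_demo_transactions

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSummary",
    "AnalysisReport",
    "Rounding",
    "run_adr_analysis",
    "run_demo_analysis",
    "summarize_cohort",
    "write_report",
]


@dataclass(frozen=True)
class CohortSummary:
    """Case and (per-case deduplicated) ADR counts, overall and by gender."""

    n_cases: int
    n_adr: int
    cases_by_gender: Dict[str, int]
    adr_by_gender: Dict[str, int]
    adr_counting: str = "deduplicated per case"


@dataclass(frozen=True)
class AnalysisReport:
    class_name: str
    analysis_kind: str  # "adr_adr" or "demo_gender"
    rows: Tuple[AssociationRule, ...]  # ranked, reported subset
    all_rules: Tuple[AssociationRule, ...]
    cohort_summary: CohortSummary
    t: int


@dataclass(frozen=True)
class Rounding:
    """Decimal places used in the rounded report columns."""

    support: int = 4
    confidence: int = 2
    lift: int = 1
    conviction: int = 2


def summarize_cohort(cohort: Sequence[Case]) -> CohortSummary:
    cases_by_gender = {"female": 0, "male": 0, "unknown": 0}
    adr_by_gender = {"female": 0, "male": 0, "unknown": 0}
    n_adr = 0
    for case in cohort:
        g = case.gender.value
        cases_by_gender[g] += 1
        adr_by_gender[g] += len(case.adr_terms)
        n_adr += len(case.adr_terms)
    return CohortSummary(len(cohort), n_adr, cases_by_gender, adr_by_gender)


def _ranked(rules: Sequence[AssociationRule]) -> List[AssociationRule]:
    return sorted(
        rules,
        key=lambda r: (
            -r.support,
            -r.confidence,
            -r.lift,
            [(i.kind, i.label) for i in r.antecedent],
            [(i.kind, i.label) for i in r.consequent],
        ),
    )


def run_adr_analysis(
    cohort: Sequence[Case],
    config: Optional[MinerConfig] = None,
    top_k: int = 5,
    single_consequent_only: bool = True,
    class_name: str = "",
) -> AnalysisReport:
    """Mine ADR <-> ADR rules on a cohort and rank the top_k by support.

    Only rules with a single ADR consequent are reported by default (the
    display convention of the published tables); the complete rule list is
    retained on the report.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    if config is None:
        config = MinerConfig()
    ts = build_adr_transactions(cohort)
    rules = generate_rules(frequent_itemsets(ts, config), ts, config)
    reported = [r for r in rules if len(r.consequent) == 1] if single_consequent_only else list(rules)
    reported = _ranked(reported)[:top_k]
    return AnalysisReport(
        class_name=class_name,
        analysis_kind="adr_adr",
        rows=tuple(reported),
        all_rules=tuple(rules),
        cohort_summary=summarize_cohort(cohort),
        t=ts.t,
    )


def run_demo_analysis(
    cohort: Sequence[Case],
    config: Optional[MinerConfig] = None,
    top_k_per_gender: int = 3,
    class_name: str = "",
) -> AnalysisReport:
    """Mine (ADR, age-decade) -> gender rules; report top_k per gender.

    Gender-unknown cases stay in the transaction set, so t — and with it
    every marginal support — covers the whole cohort.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    if config is None:
        config = MinerConfig()
    config = replace(config, consequent_constraint="gender")
    summary = summarize_cohort(cohort)
    if summary.cases_by_gender["female"] + summary.cases_by_gender["male"] == 0:
        logger.warning("cohort has no gender-known cases; no gender rules can exist")
        ts = build_demo_transactions(cohort)
        return AnalysisReport(class_name, "demo_gender", (), (), summary, ts.t)
    ts = build_demo_transactions(cohort)
    rules = generate_rules(frequent_itemsets(ts, config), ts, config)
    reported: List[AssociationRule] = []
    for gender in ("female", "male"):
        per_gender = [r for r in rules if r.consequent[0].label == gender]
        reported.extend(_ranked(per_gender)[:top_k_per_gender])
    return AnalysisReport(class_name, "demo_gender", tuple(reported), tuple(rules), summary, ts.t)


def _labels(items) -> str:
    return ", ".join(i.label for i in items)


def _format_rows(report: AnalysisReport, rounding: Rounding, full_precision: bool) -> str:
    lines = ["Type,X,Y,Support,Confidence,Lift,Conviction"]
    for r in report.rows:
        if full_precision:
            sup, conf, lift = repr(r.support), repr(r.confidence), repr(r.lift)
            conv = "NA" if r.conviction is None else repr(r.conviction)
        else:
            sup = f"{round_half_up(r.support, rounding.support):.{rounding.support}f}"
            conf = f"{round_half_up(r.confidence, rounding.confidence):.{rounding.confidence}f}"
            lift = f"{round_half_up(r.lift, rounding.lift):.{rounding.lift}f}"
            conv = (
                "NA"
                if r.conviction is None
                else f"{round_half_up(r.conviction, rounding.conviction):.{rounding.conviction}f}"
            )
        x = _labels(r.antecedent)
        y = _labels(r.consequent)
        fields = [report.class_name, x, y, sup, conf, lift, conv]
        quoted = [f'"{f}"' if "," in f else f for f in fields]
        lines.append(",".join(quoted))
    return "\n".join(lines) + "\n"


def write_report(
    report: AnalysisReport, path, rounding: Optional[Rounding] = None
) -> None:
    """Write the ranked rows as CSV (rounded columns, NA token for absent
    conviction) plus a ``*_full.csv`` companion with full-precision values.
    Byte output is deterministic for a fixed report."""
    if rounding is None:
        rounding = Rounding()
    path = Path(path)
    path.write_text(_format_rows(report, rounding, full_precision=False), encoding="utf-8")
    full = path.with_name(path.stem + "_full" + path.suffix)
    full.write_text(_format_rows(report, rounding, full_precision=True), encoding="utf-8")
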