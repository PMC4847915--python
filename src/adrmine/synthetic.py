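"""Synthetic JADER-schema data with known ground truth.

Generates DEMO/DRUG/REAC CSV fixtures that emulate the relational structure
of a spontaneous-reporting database — per-case REAC multiplicity,
decade-coded age strings, a gender field with missing values — with
*planted* associations whose population statistics are known in closed
form, so the whole mining pipeline can be validated without any download.

Per case the generative model samples, independently across cases:

* gender (female / male / unknown) and an age decade (or unknown);
* one drug class, then one member drug, recorded with causality
  ``suspected``;
* background ADRs: each non-planted vocabulary term independently with the
  background rate;
* planted pairs (X, Y, P(X), P(Y|X)): X is added with probability P(X);
  Y is added with probability P(Y|X) when X was added and with the
  background rate otherwise — so Y's marginal is contaminated by background
  occurrences while confidence of X -> Y stays P(Y|X) exactly, and setting
  P(Y|X) equal to the background rate yields exact independence (lift 1);
* planted gender effects (term, P(term|female), P(term|male)): the term is
  added with the rate of the case's gender, or the background rate when
  gender is unknown.

Background sampling is independent per term — a deliberate simplification;
real report data have correlated noise (syndromes, duplicated reports) that
this generator does not emulate.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .rule_stats import RuleStatistics

__all__ = [
    "GeneratorSpec",
    "GroundTruthManifest",
    "CaseTruth",
    "default_spec",
    "generate",
    "analytic_rule_statistics",
]

_DECADES = (
    "10代", "20代", "30代", "40代", "50代", "60代", "70代", "80代", "90代",
)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the generative model; see the module docstring."""

    n_cases: int = 20000
    gender_probs: Tuple[float, float, float] = (0.585, 0.385, 0.03)  # F, M, unknown
    age_decade_probs: Optional[Dict[str, float]] = None  # raw string -> prob; "" = unknown
    drug_classes: Tuple[Tuple[str, Tuple[str, ...], float], ...] = (
        ("SSRI", ("fluvoxamine", "paroxetine", "sertraline", "escitalopram"), 0.73),
        ("SNRI", ("milnacipran", "duloxetine"), 0.156),
        ("NaSSA", ("mirtazapine",), 0.114),
    )
    adr_vocabulary: Tuple[str, ...] = (
        "nausea", "vomiting", "dizziness", "somnolence", "headache",
        "insomnia", "serotonin syndrome", "hyponatraemia", "rash",
        "hepatic function abnormal", "qt prolonged", "tremor",
        "agitation", "constipation", "weight increased",
        "aspartate aminotransferase increased",
        "alanine aminotransferase increased",
        "suicidal ideation", "rhabdomyolysis", "akathisia",
    )
    background_rate: float = 0.02
    planted_pairs: Tuple[Tuple[str, str, float, float], ...] = (
        # (X term, Y term, P(X), P(Y|X)) — a strong laboratory-test pair
        ("aspartate aminotransferase increased",
         "alanine aminotransferase increased", 0.02, 0.9),
    )
    planted_gender_effects: Tuple[Tuple[str, float, float], ...] = (
        # (term, P(term|female), P(term|male))
        ("suicidal ideation", 0.10, 0.01),
        ("rhabdomyolysis", 0.01, 0.08),
    )

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        if abs(sum(self.gender_probs) - 1.0) > 1e-9 or min(self.gender_probs) < 0:
            raise ValueError("gender_probs must be non-negative and sum to 1")
        ages = self.age_decade_probs
        if ages is not None:
            if abs(sum(ages.values()) - 1.0) > 1e-9 or min(ages.values()) < 0:
                raise ValueError("age_decade_probs must be non-negative and sum to 1")
        if not self.drug_classes:
            raise ValueError("at least one drug class is required")
        class_p = [p for _, _, p in self.drug_classes]
        if abs(sum(class_p) - 1.0) > 1e-9 or min(class_p) < 0:
            raise ValueError("drug class probabilities must be non-negative and sum to 1")
        if not 0 <= self.background_rate <= 1:
            raise ValueError("background_rate must be in [0, 1]")
        vocab = set(self.adr_vocabulary)
        planted_terms: List[str] = []
        for x, y, px, pyx in self.planted_pairs:
            if x not in vocab or y not in vocab:
                raise ValueError(f"planted pair ({x!r}, {y!r}) uses terms outside the vocabulary")
            if not (0 <= px <= 1 and 0 <= pyx <= 1):
                raise ValueError("planted pair probabilities must be in [0, 1]")
            planted_terms += [x, y]
        for term, pf, pm in self.planted_gender_effects:
            if term not in vocab:
                raise ValueError(f"gender-effect term {term!r} outside the vocabulary")
            if not (0 <= pf <= 1 and 0 <= pm <= 1):
                raise ValueError("gender-effect probabilities must be in [0, 1]")
            planted_terms.append(term)
        if len(planted_terms) != len(set(planted_terms)):
            raise ValueError("a term may appear in at most one planted mechanism")

    @property
    def ages(self) -> Dict[str, float]:
        if self.age_decade_probs is not None:
            return self.age_decade_probs
        # adult-heavy default with 5% age-unknown
        probs = {"": 0.05, "10代": 0.05, "20代": 0.14, "30代": 0.16, "40代": 0.15,
                 "50代": 0.13, "60代": 0.12, "70代": 0.11, "80代": 0.07, "90代": 0.02}
        return probs


@dataclass(frozen=True)
class CaseTruth:
    case_id: str
    gender: str  # "female" / "male" / ""
    age_raw: str
    drug_class: str
    drug_name: str
    adr_terms: Tuple[str, ...]  # sorted, deduplicated


@dataclass(frozen=True)
class GroundTruthManifest:
    """What was actually generated, plus population-level rule statistics
    for every planted mechanism."""

    spec: GeneratorSpec
    seed: int
    cases: Tuple[CaseTruth, ...]
    analytic: Dict[Tuple[str, str], RuleStatistics]

    def class_cohort_ids(self, class_name: str) -> List[str]:
        return [c.case_id for c in self.cases if c.drug_class == class_name]


def _stats_from_probs(p_x: float, p_y: float, p_xy: float) -> RuleStatistics:
    support = p_xy
    confidence = p_xy / p_x
    lift = confidence / p_y
    if confidence >= 1.0 - 1e-15:
        conviction = None
    else:
        conviction = (1.0 - p_y) / (1.0 - confidence)
    return RuleStatistics(support, confidence, lift, conviction)


def analytic_rule_statistics(spec: GeneratorSpec, pair: Tuple[str, str]) -> RuleStatistics:
    """Closed-form population statistics of a planted rule X -> Y.

    For a planted ADR pair with r the background rate, pX = P(X) and
    q = P(Y|X):

        P(X)     = pX
        P(Y)     = pX q + (1 - pX) r      (background contaminates Y's marginal)
        P(X & Y) = pX q

    so confidence is exactly q and lift is q / P(Y); q = r gives lift 1.
    For a gender effect (term -> female/male) the consequent marginal is the
    gender probability and the term marginal mixes the per-gender rates
    (background rate for gender-unknown cases).
    Raises ``ValueError`` for a pair that was not planted.
    """
    x, y = pair
    r = spec.background_rate
    for px_term, py_term, p_x_raw, p_y_given_x in spec.planted_pairs:
        if (x, y) == (px_term, py_term):
            p_x = p_x_raw
            p_y = p_x_raw * p_y_given_x + (1 - p_x_raw) * r
            p_xy = p_x_raw * p_y_given_x
            return _stats_from_probs(p_x, p_y, p_xy)
    p_f, p_m, p_u = spec.gender_probs
    for term, p_f_rate, p_m_rate in spec.planted_gender_effects:
        if x != term or y not in ("female", "male"):
            continue
        rate_f = p_f_rate
        rate_m = p_m_rate
        p_term = p_f * rate_f + p_m * rate_m + p_u * r
        if y == "female":
            p_gender, p_term_and_gender = p_f, p_f * rate_f
        else:
            p_gender, p_term_and_gender = p_m, p_m * rate_m
        return _stats_from_probs(p_term, p_gender, p_term_and_gender)
    raise ValueError(f"pair {pair!r} was not planted in this spec")


def default_spec(**overrides) -> GeneratorSpec:
    """The study-scale default specification, optionally overridden."""
    return GeneratorSpec(**overrides)


def _simulate(spec: GeneratorSpec, seed: int) -> List[CaseTruth]:
    rng = np.random.default_rng(seed)
    genders = ("female", "male", "")
    age_labels = list(spec.ages.keys())
    age_p = np.array([spec.ages[k] for k in age_labels])
    class_names = [name for name, _, _ in spec.drug_classes]
    class_p = np.array([p for _, _, p in spec.drug_classes])
    members = {name: drugs for name, drugs, _ in spec.drug_classes}
    pair_terms = {x for x, _, _, _ in spec.planted_pairs} | {
        y for _, y, _, _ in spec.planted_pairs
    }
    effect_terms = {t for t, _, _ in spec.planted_gender_effects}
    background_terms = [
        t for t in spec.adr_vocabulary if t not in pair_terms and t not in effect_terms
    ]
    cases: List[CaseTruth] = []
    width = max(6, len(str(max(spec.n_cases, 1))))
    for i in range(spec.n_cases):
        case_id = f"C{i + 1:0{width}d}"
        gender = genders[rng.choice(3, p=spec.gender_probs)]
        age = age_labels[rng.choice(len(age_labels), p=age_p)]
        cls = class_names[rng.choice(len(class_names), p=class_p)]
        drug = members[cls][rng.integers(len(members[cls]))]
        adrs = set()
        for term in background_terms:
            if rng.random() < spec.background_rate:
                adrs.add(term)
        for x, y, p_x, p_y_given_x in spec.planted_pairs:
            if rng.random() < p_x:
                adrs.add(x)
                p_y_here = p_y_given_x
            else:
                p_y_here = spec.background_rate
            if rng.random() < p_y_here:
                adrs.add(y)
        for term, p_f_rate, p_m_rate in spec.planted_gender_effects:
            rate = (
                p_f_rate if gender == "female"
                else p_m_rate if gender == "male"
                else spec.background_rate
            )
            if rng.random() < rate:
                adrs.add(term)
        cases.append(CaseTruth(case_id, gender, age, cls, drug, tuple(sorted(adrs))))
    return cases


def _csv_text(header: Sequence[str], rows: Sequence[Sequence[str]]) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(header)
    w.writerows(rows)
    return buf.getvalue()


def generate(
    spec: GeneratorSpec,
    seed: int,
    out_dir: Optional[Path] = None,
    encoding: str = "utf-8",
) -> Tuple[str, str, str, GroundTruthManifest]:
    """Generate DEMO/DRUG/REAC CSV text and the ground-truth manifest.

    With ``out_dir`` set, also writes ``DEMO.csv``, ``DRUG.csv`` and
    ``REAC.csv`` there (``encoding="cp932"`` exercises real-release
    encoding handling).  Output is byte-identical for a fixed seed.
    """
    cases = _simulate(spec, seed)
    demo_rows = [[c.case_id, c.gender, c.age_raw, ""] for c in cases]
    drug_rows = [[c.case_id, c.drug_name, "suspected"] for c in cases]
    reac_rows = [[c.case_id, term, ""] for c in cases for term in c.adr_terms]
    demo_csv = _csv_text(["case_id", "gender", "age", "weight"], demo_rows)
    drug_csv = _csv_text(["case_id", "drug_name", "causality"], drug_rows)
    reac_csv = _csv_text(["case_id", "adr_term", "outcome"], reac_rows)
    analytic: Dict[Tuple[str, str], RuleStatistics] = {}
    for x, y, _, _ in spec.planted_pairs:
        analytic[(x, y)] = analytic_rule_statistics(spec, (x, y))
    for term, p_f_rate, p_m_rate in spec.planted_gender_effects:
        for g in ("female", "male"):
            analytic[(term, g)] = analytic_rule_statistics(spec, (term, g))
    manifest = GroundTruthManifest(spec, seed, tuple(cases), analytic)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, text in (
            ("DEMO.csv", demo_csv), ("DRUG.csv", drug_csv), ("REAC.csv", reac_csv)
        ):
            (out_dir / name).write_bytes(text.encode(encoding))
    return demo_csv, drug_csv, reac_csv, manifest
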