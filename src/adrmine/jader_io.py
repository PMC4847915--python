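"""Read and join JADER-schema spontaneous-report tables.

JADER (the Japanese Adverse Drug Event Report database) ships as relational
CSV tables keyed by a case identifier; this module covers the three used
here:

* DEMO — one row per case: gender, age category (decade-coded strings such
  as ``"20代"``), weight;
* DRUG — one row per reported drug per case: drug name and causality role
  (suspected / concomitant / interacting);
* REAC — one row per reported adverse reaction per case: preferred term and
  outcome.

Real JADER files are CP932-encoded with Japanese headers; the reader takes
an encoding and a column-name mapping so both real downloads and UTF-8
fixtures parse.  Rows are joined into per-case :class:`Case` records — the
unit of analysis — and cohorts are selected by drug-class membership.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Gender",
    "Causality",
    "DemoRecord",
    "ReacRecord",
    "DrugRecord",
    "Case",
    "DrugClassConfig",
    "ColumnMapping",
    "DEFAULT_COLUMNS",
    "JADER_COLUMNS",
    "GENDER_VALUES",
    "CAUSALITY_VALUES",
    "ANTIDEPRESSANT_CLASSES",
    "read_table",
    "assemble_cases",
    "filter_cohort",
]


class Gender(enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class Causality(enum.Enum):
    SUSPECTED = "suspected"
    CONCOMITANT = "concomitant"
    INTERACTING = "interacting"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class DemoRecord:
    case_id: str
    gender: Gender
    age_raw: str
    weight_raw: str = ""


@dataclass(frozen=True)
class ReacRecord:
    case_id: str
    adr_term: str
    outcome_raw: str = ""


@dataclass(frozen=True)
class DrugRecord:
    case_id: str
    drug_name: str
    causality: Causality


@dataclass(frozen=True)
class Case:
    """One spontaneous report: the patient-level transaction unit."""

    case_id: str
    gender: Gender
    age_raw: str
    adr_terms: FrozenSet[str]
    drugs: FrozenSet[Tuple[str, Causality]]


@dataclass(frozen=True)
class DrugClassConfig:
    """A drug class (e.g. SSRI) as a set of name-match strings.

    ``match_mode="substring"`` is the practical default because JADER drug
    names carry salt and formulation suffixes; ``causality_filter``
    defaults to suspected-only, the conservative pharmacovigilance
    convention.
    """

    class_name: str
    member_names: Tuple[str, ...]
    match_mode: str = "substring"
    causality_filter: FrozenSet[Causality] = frozenset({Causality.SUSPECTED})

    def __post_init__(self) -> None:
        if not self.member_names:
            raise ValueError(f"drug class {self.class_name!r} has an empty member list")
        if self.match_mode not in ("substring", "exact"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")

    def matches(self, drug_name: str) -> bool:
        if self.match_mode == "exact":
            return any(drug_name == m for m in self.member_names)
        return any(m in drug_name for m in self.member_names)


#: The three antidepressant classes studied, as generic-name match strings.
ANTIDEPRESSANT_CLASSES: Tuple[DrugClassConfig, ...] = (
    DrugClassConfig(
        "SSRI", ("fluvoxamine", "paroxetine", "sertraline", "escitalopram")
    ),
    DrugClassConfig("SNRI", ("milnacipran", "duloxetine")),
    DrugClassConfig("NaSSA", ("mirtazapine",)),
)


@dataclass(frozen=True)
class ColumnMapping:
    """Header names for each schema, plus value maps for coded fields."""

    demo: Dict[str, str]
    reac: Dict[str, str]
    drug: Dict[str, str]
    gender_values: Dict[str, Gender] = field(default_factory=lambda: dict(GENDER_VALUES))
    causality_values: Dict[str, Causality] = field(
        default_factory=lambda: dict(CAUSALITY_VALUES)
    )


GENDER_VALUES: Dict[str, Gender] = {
    "female": Gender.FEMALE,
    "male": Gender.MALE,
    "f": Gender.FEMALE,
    "m": Gender.MALE,
    "女性": Gender.FEMALE,
    "男性": Gender.MALE,
}

CAUSALITY_VALUES: Dict[str, Causality] = {
    "suspected": Causality.SUSPECTED,
    "concomitant": Causality.CONCOMITANT,
    "interacting": Causality.INTERACTING,
    "被疑薬": Causality.SUSPECTED,
    "併用薬": Causality.CONCOMITANT,
    "相互作用": Causality.INTERACTING,
}

#: Canonical (fixture) column names, written by the synthetic generator.
DEFAULT_COLUMNS = ColumnMapping(
    demo={"case_id": "case_id", "gender": "gender", "age": "age", "weight": "weight"},
    reac={"case_id": "case_id", "adr_term": "adr_term", "outcome": "outcome"},
    drug={"case_id": "case_id", "drug_name": "drug_name", "causality": "causality"},
)

#: Header names of the real JADER release (CP932-encoded files).
JADER_COLUMNS = ColumnMapping(
    demo={"case_id": "識別番号", "gender": "性別", "age": "年齢", "weight": "体重"},
    reac={"case_id": "識別番号", "adr_term": "有害事象", "outcome": "転帰"},
    drug={"case_id": "識別番号", "drug_name": "医薬品（一般名）", "causality": "医薬品の関与"},
)


class SchemaError(ValueError):
    """A required column is missing or a row violates a field invariant."""


def _read_csv(path, columns: Dict[str, str], encoding: str, schema: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding=encoding)
    missing = [col for col in columns.values() if col not in df.columns]
    if missing:
        raise SchemaError(
            f"{schema} file {path} is missing required column(s): {', '.join(missing)}"
        )
    logger.info("read %d %s rows from %s", len(df), schema, path)
    return df


def read_table(
    path,
    schema: str,
    encoding: str = "utf-8",
    columns: Optional[ColumnMapping] = None,
):
    """Read one JADER-schema CSV into typed records.

    Parameters
    ----------
    path
        CSV file with a header row; quoted fields allowed; extra columns
        are ignored.
    schema
        ``"DEMO"``, ``"REAC"`` or ``"DRUG"``.
    encoding
        Text encoding; real JADER downloads are ``"cp932"``.
    columns
        Header-name mapping; defaults to the canonical fixture names
        (:data:`DEFAULT_COLUMNS`).  Use :data:`JADER_COLUMNS` for real files.

    Returns a list of ``DemoRecord`` / ``ReacRecord`` / ``DrugRecord`` in
    row order.  Unrecognised gender or causality strings map to the UNKNOWN
    member rather than erroring; an empty ADR term is a validation error.
    """
    if columns is None:
        columns = DEFAULT_COLUMNS
    schema = schema.upper()
    if schema == "DEMO":
        cols = columns.demo
        df = _read_csv(path, cols, encoding, schema)
        out_demo: List[DemoRecord] = []
        for i, row in enumerate(df.itertuples(index=False)):
            r = dict(zip(df.columns, row))
            case_id = r[cols["case_id"]].strip()
            if not case_id:
                raise SchemaError(f"{path}: DEMO row {i + 2} has an empty case_id")
            gender = columns.gender_values.get(r[cols["gender"]].strip().lower())
            if gender is None:
                gender = columns.gender_values.get(r[cols["gender"]].strip(), Gender.UNKNOWN)
            out_demo.append(
                DemoRecord(case_id, gender, r[cols["age"]].strip(), r[cols["weight"]].strip())
            )
        return out_demo
    if schema == "REAC":
        cols = columns.reac
        df = _read_csv(path, cols, encoding, schema)
        out_reac: List[ReacRecord] = []
        for i, row in enumerate(df.itertuples(index=False)):
            r = dict(zip(df.columns, row))
            case_id = r[cols["case_id"]].strip()
            term = r[cols["adr_term"]].strip()
            if not case_id:
                raise SchemaError(f"{path}: REAC row {i + 2} has an empty case_id")
            if not term:
                raise SchemaError(f"{path}: REAC row {i + 2} has an empty adr_term")
            out_reac.append(ReacRecord(case_id, term, r[cols["outcome"]].strip()))
        return out_reac
    if schema == "DRUG":
        cols = columns.drug
        df = _read_csv(path, cols, encoding, schema)
        out_drug: List[DrugRecord] = []
        for i, row in enumerate(df.itertuples(index=False)):
            r = dict(zip(df.columns, row))
            case_id = r[cols["case_id"]].strip()
            name = r[cols["drug_name"]].strip()
            if not case_id:
                raise SchemaError(f"{path}: DRUG row {i + 2} has an empty case_id")
            if not name:
                raise SchemaError(f"{path}: DRUG row {i + 2} has an empty drug_name")
            caus = columns.causality_values.get(r[cols["causality"]].strip().lower())
            if caus is None:
                caus = columns.causality_values.get(
                    r[cols["causality"]].strip(), Causality.UNKNOWN
                )
            out_drug.append(DrugRecord(case_id, name, caus))
        return out_drug
    raise ValueError(f"unknown schema {schema!r}; expected DEMO, REAC or DRUG")


def assemble_cases(
    demo: Sequence[DemoRecord],
    reac: Sequence[ReacRecord],
    drug: Sequence[DrugRecord],
) -> List[Case]:
    """Join the three tables into one :class:`Case` per DEMO row.

    REAC/DRUG rows whose case_id is absent from DEMO are dropped (their
    count is logged); ADR terms are deduplicated per case.  A duplicate
    case_id within DEMO is an error.
    """
    seen: Set[str] = set()
    adrs: Dict[str, Set[str]] = {}
    drugs: Dict[str, Set[Tuple[str, Causality]]] = {}
    for rec in demo:
        if rec.case_id in seen:
            raise SchemaError(f"duplicate case_id {rec.case_id!r} in DEMO")
        seen.add(rec.case_id)
        adrs[rec.case_id] = set()
        drugs[rec.case_id] = set()
    dropped = 0
    for r in reac:
        if r.case_id in adrs:
            adrs[r.case_id].add(r.adr_term)
        else:
            dropped += 1
    for g in drug:
        if g.case_id in drugs:
            drugs[g.case_id].add((g.drug_name, g.causality))
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d REAC/DRUG rows with case_ids absent from DEMO", dropped)
    return [
        Case(
            rec.case_id,
            rec.gender,
            rec.age_raw,
            frozenset(adrs[rec.case_id]),
            frozenset(drugs[rec.case_id]),
        )
        for rec in demo
    ]


def filter_cohort(cases: Sequence[Case], config: DrugClassConfig) -> List[Case]:
    """Cases with at least one drug entry matching the class under its match
    mode and causality filter.  A case on drugs of several classes can appear
    in several cohorts."""
    cohort = [
        case
        for case in cases
        if any(
            config.matches(name) and caus in config.causality_filter
            for name, caus in case.drugs
        )
    ]
    logger.info("cohort %s: %d of %d cases", config.class_name, len(cohort), len(cases))
    return cohort
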