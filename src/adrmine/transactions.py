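"""Build per-case transactions for itemset mining.

Two representations are used downstream:

* ADR-only transactions — each case contributes the set of its deduplicated
  adverse-reaction preferred terms (analysis of ADR <-> ADR associations);
* demographic transactions — the ADR items plus, where known, one age-decade
  item and one gender item (analysis of ADR/age -> gender associations).

Cases with unknown gender or unmappable age stay in the transaction set with
those items simply absent: they still contribute to the denominator t, which
is what makes marginal supports (and hence lift) come out on the full cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence

from .jader_io import Case, Gender

__all__ = [
    "Item",
    "TransactionSet",
    "DEFAULT_AGE_DECADE_MAP",
    "age_to_decade_item",
    "build_adr_transactions",
    "build_demo_transactions",
    "write_basket_file",
]

ITEM_KINDS = ("adr", "age_decade", "gender")


@dataclass(frozen=True, order=True)
class Item:
    """A transaction member: an ADR term, an age-decade label or a gender.

    Ordering is lexicographic on (kind, label); this is the canonical item
    order used for candidate generation and all deterministic output.
    """

    kind: str
    label: str

    def __post_init__(self) -> None:
        if self.kind not in ITEM_KINDS:
            raise ValueError(f"unknown item kind {self.kind!r}")
        if not self.label:
            raise ValueError("item label must be non-empty")


@dataclass(frozen=True)
class TransactionSet:
    """An ordered collection of item sets over a finite vocabulary."""

    transactions: tuple
    vocabulary: FrozenSet[Item]

    def __post_init__(self) -> None:
        for i, txn in enumerate(self.transactions):
            extra = txn - self.vocabulary
            if extra:
                raise ValueError(f"transaction {i} has items outside the vocabulary: {sorted(extra)}")

    @property
    def t(self) -> int:
        """Total number of transactions (the paper's denominator t)."""
        return len(self.transactions)

    @classmethod
    def from_iterable(cls, transactions: Iterable[Iterable[Item]]) -> "TransactionSet":
        txns = tuple(frozenset(txn) for txn in transactions)
        vocab = frozenset().union(*txns) if txns else frozenset()
        return cls(txns, vocab)


# Decade-coded JADER age strings -> canonical English decade labels.
# Non-decade strings ("10歳未満", "高齢者", free text) deliberately map to
# nothing: the case then carries no age item.
DEFAULT_AGE_DECADE_MAP: Dict[str, str] = {
    "10代": "tens",
    "20代": "twenties",
    "30代": "thirties",
    "40代": "forties",
    "50代": "fifties",
    "60代": "sixties",
    "70代": "seventies",
    "80代": "eighties",
    "90代": "nineties+",
    "100代": "nineties+",
}


def age_to_decade_item(
    age_raw: str, age_map: Optional[Dict[str, str]] = None
) -> Optional[Item]:
    """Map a decade-coded age string (e.g. ``"20代"``) to an age item.

    Returns ``None`` for empty or unmapped strings; the mapping is
    configurable to absorb dialect variants in real data.
    """
    if age_map is None:
        age_map = DEFAULT_AGE_DECADE_MAP
    label = age_map.get(age_raw.strip())
    if label is None:
        return None
    return Item("age_decade", label)


def build_adr_transactions(cohort: Sequence[Case]) -> TransactionSet:
    """One transaction per case holding its deduplicated ADR items.

    Cases without any ADR yield empty transactions and still count in t.
    """
    txns = [
        frozenset(Item("adr", term) for term in case.adr_terms) for case in cohort
    ]
    return TransactionSet.from_iterable(txns)


def build_demo_transactions(
    cohort: Sequence[Case], age_map: Optional[Dict[str, str]] = None
) -> TransactionSet:
    """ADR items plus at most one age-decade item and one gender item per case.

    Gender items are added only for female/male; unknown-gender cases keep
    their ADR items and remain in the denominator t.
    """
    txns: List[FrozenSet[Item]] = []
    for case in cohort:
        items = {Item("adr", term) for term in case.adr_terms}
        age_item = age_to_decade_item(case.age_raw, age_map)
        if age_item is not None:
            items.add(age_item)
        if case.gender in (Gender.FEMALE, Gender.MALE):
            items.add(Item("gender", case.gender.value))
        txns.append(frozenset(items))
    return TransactionSet.from_iterable(txns)


def write_basket_file(ts: TransactionSet, path) -> None:
    """Export one transaction per line, tab-separated item labels, for
    cross-checking with external miners.  Empty transactions export as empty
    lines so line count equals t."""
    lines = []
    for txn in ts.transactions:
        labels = sorted(item.label for item in txn)
        lines.append("\t".join(labels))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
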