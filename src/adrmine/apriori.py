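"""Level-wise apriori frequent-itemset mining and rule generation.

The classic algorithm: frequent 1-itemsets first, then candidates of size k
are formed by joining frequent (k-1)-itemsets that share a (k-2)-prefix
under the canonical item order, pruned by downward closure (any candidate
with an infrequent subset is discarded) and counted by intersecting
per-itemset transaction-id sets.

Rule generation partitions each frequent itemset of size >= 2 into a
non-empty antecedent X and consequent Y and keeps partitions meeting the
confidence threshold.  An optional consequent constraint restricts Y to a
single item of a given kind with X free of that kind — used for the
demographics -> gender analysis.

Thresholds are inclusive (support >= min_support, confidence >=
min_confidence), matching the usual convention of association-rule miners.
Output order is deterministic and independent of transaction order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Tuple

from .rule_stats import ContingencyTable, RuleStatistics, compute_rule_statistics
from .transactions import Item, TransactionSet

__all__ = [
    "MinerConfig",
    "FrequentItemset",
    "AssociationRule",
    "frequent_itemsets",
    "generate_rules",
    "mine",
]


@dataclass(frozen=True)
class MinerConfig:
    """Mining thresholds; the defaults are the study's (support 0.001,
    confidence 0.8)."""

    min_support: float = 0.001
    min_confidence: float = 0.8
    max_len: int = 10
    consequent_constraint: Optional[str] = None  # an item kind, e.g. "gender"
    conviction_formula: str = "standard"

    def __post_init__(self) -> None:
        if not 0 < self.min_support <= 1:
            raise ValueError("min_support must be in (0, 1]")
        if not 0 < self.min_confidence <= 1:
            raise ValueError("min_confidence must be in (0, 1]")
        if self.max_len < 2:
            raise ValueError("max_len must be >= 2")


@dataclass(frozen=True)
class FrequentItemset:
    items: Tuple[Item, ...]  # canonically sorted
    count: int
    support: float


@dataclass(frozen=True)
class AssociationRule:
    antecedent: Tuple[Item, ...]
    consequent: Tuple[Item, ...]
    table: ContingencyTable
    stats: RuleStatistics

    @property
    def support(self) -> float:
        return self.stats.support

    @property
    def confidence(self) -> float:
        return self.stats.confidence

    @property
    def lift(self) -> float:
        return self.stats.lift

    @property
    def conviction(self) -> Optional[float]:
        return self.stats.conviction


def frequent_itemsets(ts: TransactionSet, config: MinerConfig) -> List[FrequentItemset]:
    """All itemsets of size 1..max_len with support >= min_support.

    Raises ``ValueError`` on an empty transaction set.  Result is sorted by
    (size, canonical item order).
    """
    t = ts.t
    if t == 0:
        raise ValueError("cannot mine an empty transaction set (t = 0)")
    tidsets: Dict[Tuple[Item, ...], FrozenSet[int]] = {}
    for item in sorted(ts.vocabulary):
        tids = frozenset(i for i, txn in enumerate(ts.transactions) if item in txn)
        if len(tids) / t >= config.min_support:
            tidsets[(item,)] = tids
    out: List[FrequentItemset] = [
        FrequentItemset(items, len(tids), len(tids) / t)
        for items, tids in sorted(tidsets.items())
    ]
    level = sorted(tidsets)
    k = 2
    while level and k <= config.max_len:
        prev_frequent = set(level)
        next_tidsets: Dict[Tuple[Item, ...], FrozenSet[int]] = {}
        for i, p in enumerate(level):
            for q in level[i + 1 :]:
                if p[:-1] != q[:-1]:
                    break  # sorted level: no later q shares the prefix
                candidate = p + (q[-1],)
                # downward closure: all (k-1)-subsets must be frequent
                if any(
                    candidate[:j] + candidate[j + 1 :] not in prev_frequent
                    for j in range(len(candidate) - 2)
                ):
                    continue
                tids = tidsets[p] & tidsets[q]
                if len(tids) / t >= config.min_support:
                    next_tidsets[candidate] = tids
        level = sorted(next_tidsets)
        tidsets.update(next_tidsets)
        out.extend(
            FrequentItemset(items, len(next_tidsets[items]), len(next_tidsets[items]) / t)
            for items in level
        )
        k += 1
    out.sort(key=lambda fi: (len(fi.items), fi.items))
    return out


def _rule_table(
    count_xy: int, count_x: int, count_y: int, t: int
) -> ContingencyTable:
    return ContingencyTable(
        a=count_xy,
        b=count_x - count_xy,
        c=count_y - count_xy,
        d=t - count_x - count_y + count_xy,
    )


def generate_rules(
    itemsets: List[FrequentItemset], ts: TransactionSet, config: MinerConfig
) -> List[AssociationRule]:
    """Emit every partition X -> Y of each frequent itemset (size >= 2) whose
    confidence meets the threshold.

    With ``consequent_constraint`` set, Y must be exactly one item of that
    kind and X must contain none of it.  Counts for X and Y come from the
    frequent-itemset table itself (both are frequent by downward closure),
    so each rule's contingency table is exact.
    """
    counts = {fi.items: fi.count for fi in itemsets}
    t = ts.t
    rules: List[AssociationRule] = []
    for fi in itemsets:
        n = len(fi.items)
        if n < 2:
            continue
        for x_size in range(1, n):
            for x_combo in itertools.combinations(fi.items, x_size):
                y_combo = tuple(it for it in fi.items if it not in x_combo)
                if config.consequent_constraint is not None:
                    if len(y_combo) != 1 or y_combo[0].kind != config.consequent_constraint:
                        continue
                    if any(it.kind == config.consequent_constraint for it in x_combo):
                        continue
                count_x = counts[x_combo]
                if fi.count / count_x < config.min_confidence:
                    continue
                table = _rule_table(fi.count, count_x, counts[y_combo], t)
                stats = compute_rule_statistics(
                    table, conviction_formula=config.conviction_formula
                )
                rules.append(AssociationRule(x_combo, y_combo, table, stats))
    rules.sort(
        key=lambda r: (
            -r.support,
            -r.confidence,
            -r.lift,
            [(i.kind, i.label) for i in r.antecedent],
            [(i.kind, i.label) for i in r.consequent],
        )
    )
    return rules


def mine(ts: TransactionSet, config: Optional[MinerConfig] = None) -> List[AssociationRule]:
    """Convenience wrapper: frequent itemsets then rules."""
    if config is None:
        config = MinerConfig()
    return generate_rules(frequent_itemsets(ts, config), ts, config)
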