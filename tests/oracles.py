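"""Independent brute-force oracles for the miner.

Deliberately naive: exhaustive enumeration over the power set of the
vocabulary with direct per-transaction subset counting, and exhaustive
antecedent/consequent partitioning for rules.  No shared code with the
level-wise miner.
"""

import itertools
from typing import Dict, FrozenSet, List, Optional, Tuple


def brute_frequent_itemsets(
    transactions: List[frozenset], min_support: float, max_len: Optional[int] = None
) -> Dict[Tuple, int]:
    """Counts of every itemset (size 1..max_len) with support >= min_support,
    found by checking all subsets of the vocabulary against all transactions."""
    t = len(transactions)
    vocab = sorted(set().union(*transactions)) if transactions else []
    if max_len is None:
        max_len = len(vocab)
    out: Dict[Tuple, int] = {}
    for k in range(1, min(max_len, len(vocab)) + 1):
        for combo in itertools.combinations(vocab, k):
            s = frozenset(combo)
            count = sum(1 for txn in transactions if s <= txn)
            if t and count / t >= min_support:
                out[combo] = count
    return out


def brute_rules(
    frequent: Dict[Tuple, int],
    min_confidence: float,
    consequent_kind: Optional[str] = None,
) -> Dict[Tuple[FrozenSet, FrozenSet], float]:
    """Every X -> Y partition of every frequent itemset meeting the
    confidence threshold; maps (X, Y) to confidence."""
    out: Dict[Tuple[FrozenSet, FrozenSet], float] = {}
    for itemset, count in frequent.items():
        if len(itemset) < 2:
            continue
        for x_size in range(1, len(itemset)):
            for x in itertools.combinations(itemset, x_size):
                y = tuple(i for i in itemset if i not in x)
                if consequent_kind is not None:
                    if len(y) != 1 or y[0].kind != consequent_kind:
                        continue
                    if any(i.kind == consequent_kind for i in x):
                        continue
                conf = count / frequent[x]
                if conf >= min_confidence:
                    out[(frozenset(x), frozenset(y))] = conf
    return out


def tally_contingency(transactions: List[frozenset], X: frozenset, Y: frozenset):
    """(a, b, c, d) by a per-transaction tally, independent of the package."""
    a = b = c = d = 0
    for txn in transactions:
        x_in, y_in = X <= txn, Y <= txn
        a += x_in and y_in
        b += x_in and not y_in
        c += y_in and not x_in
        d += not x_in and not y_in
    return a, b, c, d


def random_transactions(rng, n: int, vocab) -> List[frozenset]:
    """n random transactions; each vocabulary item included independently
    with a random per-item rate in [0.05, 0.6]."""
    rates = {item: 0.05 + 0.55 * rng.random() for item in vocab}
    return [
        frozenset(item for item in vocab if rng.random() < rates[item])
        for _ in range(n)
    ]
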