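"""Contingency tables and association indicators for rules over transaction sets.

A rule X -> Y over t patient-level transactions is summarised by the 2x2
table

    =====================  =========  =========
    .                      Y present  Y absent
    =====================  =========  =========
    X present              a          b
    X absent               c          d
    =====================  =========  =========

and by four indicators:

    support    = a / t
    confidence = a / (a + b)
    lift       = confidence / ((a + c) / t)
    conviction = (1 - supp(Y)) / (1 - confidence)
               = ((b + d) / t) / (b / (a + b))

Conviction is undefined when confidence = 1 (b = 0); it is reported as an
explicit NA, never as infinity.  An alternative conviction variant with a
(c + d)/t numerator is available for comparison with sources that print
that form (see :func:`compute_rule_statistics`).

The module also supports the inverse problem: given indicator values that
were *published rounded* (as in a journal table), recover the unique integer
contingency table consistent with all of them simultaneously
(:func:`reconstruct_table`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import FrozenSet, Iterable, Optional

__all__ = [
    "ContingencyTable",
    "RuleStatistics",
    "PrintedRule",
    "contingency",
    "compute_rule_statistics",
    "reconstruct_table",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero (the convention of printed tables),
    avoiding Python's banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """Counts a, b, c, d for a rule X -> Y; t = a + b + c + d."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def t(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RuleStatistics:
    """Support, confidence, lift and conviction; conviction is None (NA)
    exactly when confidence = 1."""

    support: float
    confidence: float
    lift: float
    conviction: Optional[float]

    @property
    def conviction_is_na(self) -> bool:
        return self.conviction is None


def contingency(transactions: Iterable[FrozenSet], X: frozenset, Y: frozenset) -> ContingencyTable:
    """Tally the 2x2 presence/absence table of item sets X and Y.

    A transaction counts as "X present" iff it contains *every* item of X
    (likewise Y).  X and Y must be non-empty and disjoint.
    """
    X = frozenset(X)
    Y = frozenset(Y)
    if not X or not Y:
        raise ValueError("X and Y must be non-empty")
    if X & Y:
        raise ValueError(f"X and Y must be disjoint, share {sorted(X & Y)!r}")
    a = b = c = d = 0
    for txn in transactions:
        has_x = X <= txn
        has_y = Y <= txn
        if has_x and has_y:
            a += 1
        elif has_x:
            b += 1
        elif has_y:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def compute_rule_statistics(
    ct: ContingencyTable, conviction_formula: str = "standard"
) -> RuleStatistics:
    """Compute the four indicators from a contingency table at full precision.

    Parameters
    ----------
    ct
        Contingency table with t >= 1 and an observed antecedent (a + b >= 1).
    conviction_formula
        ``"standard"`` uses the (b + d)/t numerator, algebraically equal to
        (1 - supp(Y)) / (1 - confidence); ``"as_printed"`` uses (c + d)/t,
        a variant some published tables print.

    Raises
    ------
    ValueError
        If t = 0, the antecedent is never observed (confidence undefined) or
        the consequent is never observed (lift undefined).
    """
    if conviction_formula not in ("standard", "as_printed"):
        raise ValueError(f"unknown conviction_formula {conviction_formula!r}")
    a, b, c, d, t = ct.a, ct.b, ct.c, ct.d, ct.t
    if t < 1:
        raise ValueError("empty transaction set: t = 0")
    if a + b == 0:
        raise ValueError("antecedent never observed (a + b = 0): confidence undefined")
    if a + c == 0:
        raise ValueError("consequent never observed (a + c = 0): lift undefined")
    support = a / t
    confidence = a / (a + b)
    lift = confidence / ((a + c) / t)
    if b == 0:
        conviction: Optional[float] = None
    elif conviction_formula == "standard":
        conviction = ((b + d) / t) / (b / (a + b))
    else:
        conviction = ((c + d) / t) / (b / (a + b))
    return RuleStatistics(support, confidence, lift, conviction)


@dataclass(frozen=True)
class PrintedRule:
    """Rounded indicator values as printed in a published table.

    ``conviction=None`` means the table printed the NA token.  The ``*_dp``
    fields give the number of decimal places each value was printed with
    (published tables are not always consistent about this).
    """

    t: int
    support: float
    confidence: float
    lift: float
    conviction: Optional[float]
    support_dp: int = 4
    confidence_dp: int = 2
    lift_dp: int = 1
    conviction_dp: int = 1


def _rounds_to(value: float, printed: float, dp: int) -> bool:
    return math.isclose(round_half_up(value, dp), printed, abs_tol=1e-12)


def reconstruct_table(
    printed: PrintedRule,
    consequent_count: Optional[int] = None,
    conviction_formula: str = "standard",
) -> ContingencyTable:
    """Recover the integer contingency table behind published rounded values.

    Searches exhaustively over integer (a, b, c) with d = t - a - b - c for
    tables whose full-precision indicators round (half-up, at the printed
    precision) to every printed value simultaneously.  When the consequent's
    marginal count a + c is known independently — e.g. a published per-gender
    case count — pass it as ``consequent_count`` to pin c.

    Returns the unique solution; raises ``ValueError`` if none or several
    tables are consistent (the published row is then under-determined).
    """
    t = printed.t
    if t < 1:
        raise ValueError("t must be >= 1")
    half_s = 0.5 * 10 ** (-printed.support_dp)
    a_lo = max(0, math.ceil((printed.support - half_s) * t))
    a_hi = min(t, math.floor((printed.support + half_s) * t))
    solutions = []
    for a in range(a_lo, a_hi + 1):
        if not _rounds_to(a / t, printed.support, printed.support_dp):
            continue
        # antecedent totals compatible with the printed confidence
        half_c = 0.5 * 10 ** (-printed.confidence_dp)
        conf_lo = max(printed.confidence - half_c, 1e-9)
        ab_hi = min(t, math.floor(a / conf_lo)) if a > 0 else t
        for ab in range(max(a, 1), ab_hi + 1):
            if t - ab < 0:
                continue
            if not _rounds_to(a / ab, printed.confidence, printed.confidence_dp):
                continue
            b = ab - a
            if printed.conviction is None and b != 0:
                continue
            if printed.conviction is not None and b == 0:
                continue
            if consequent_count is not None:
                ac_candidates = [consequent_count]
            else:
                ac_candidates = range(max(a, 1), t - b + 1)
            for ac in ac_candidates:
                c = ac - a
                d = t - a - b - c
                if c < 0 or d < 0:
                    continue
                ct = ContingencyTable(a, b, c, d)
                stats = compute_rule_statistics(ct, conviction_formula=conviction_formula)
                if not _rounds_to(stats.lift, printed.lift, printed.lift_dp):
                    continue
                if printed.conviction is not None and not _rounds_to(
                    stats.conviction, printed.conviction, printed.conviction_dp
                ):
                    continue
                solutions.append(ct)
    if not solutions:
        raise ValueError("no integer contingency table matches the printed values")
    if len(set(solutions)) > 1:
        raise ValueError(
            f"printed values are under-determined: {len(set(solutions))} consistent tables"
        )
    return solutions[0]
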