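# adrmine

Association-rule mining for pharmacovigilance signal screening on
spontaneous adverse-drug-reaction (ADR) report databases with the JADER
table layout (the PMDA's Japanese Adverse Drug Event Report database:
relational CSV tables DEMO / DRUG / REAC keyed by a case identifier).

It is aimed at drug-safety analysts who want to go beyond one-drug /
one-event disproportionality and ask two questions about drugs sharing an
indication (the shipped configuration covers the SSRI, SNRI and NaSSA
antidepressant classes):

1. which adverse reactions co-occur within the same patient reports
   (ADR ↔ ADR rules), and
2. which reactions and age groups are associated with reporter gender
   (ADR, age-decade → gender rules).

## The method

Each case (one spontaneous report) becomes a transaction: the set of its
deduplicated ADR preferred terms, optionally plus one age-decade item and
one gender item. Frequent itemsets are mined with a level-wise **apriori**
algorithm (candidate join on the (k−2)-prefix, downward-closure pruning,
transaction-id-set counting), and every antecedent/consequent partition
X → Y meeting the confidence threshold is scored from its 2×2 contingency
table (a = cases with X and Y, b = X only, c = Y only, d = neither,
t = a+b+c+d):

    support    = a/t
    confidence = a/(a+b)
    lift       = [a/(a+b)] / [(a+c)/t]
    conviction = (1 − supp(Y)) / (1 − confidence)   (NA when confidence = 1)

Default thresholds are support ≥ 0.001 and confidence ≥ 0.8. A conviction
variant with a (c+d)/t numerator, printed by some sources, is available as
`conviction_formula="as_printed"`; see `docs/methods.md` for why the
standard form is the default.

A synthetic-data module generates JADER-schema CSVs with *planted*
associations whose population statistics are known in closed form, so the
entire pipeline — CSV parsing, case assembly, cohort selection,
transaction building, mining, reporting — is testable without downloading
the real database. The package also solves the inverse problem: from a
*published rounded* table row (support/confidence/lift/conviction plus t),
`reconstruct_table` recovers the unique integer contingency table behind
it by exhaustive search.

## Worked example

```python
from adrmine import ContingencyTable, compute_rule_statistics, round_half_up

# top SSRI rule: AST increased -> ALT increased over t = 4377 cases
s = compute_rule_statistics(ContingencyTable(a=26, b=2, c=4, d=4345))
print(round_half_up(s.support, 4),      # 0.0059  — 26/4377 cases report both
      round_half_up(s.confidence, 2),   # 0.93    — 26 of 28 AST cases also have ALT
      round_half_up(s.lift, 1),         # 135.5   — 135-fold over independence
      round_half_up(s.conviction, 1))   # 13.9    — X-without-Y 14x rarer than chance
```

prints `0.0059 0.93 135.5 13.9`: the two transaminase elevations are
reported together far more often than chance — a classic co-reported
laboratory pair. The scripts in `examples/` run this, a toy mining
session, and the full synthetic pipeline end to end:

```
python examples/01_rule_statistics.py
python examples/02_apriori_basics.py
python examples/03_synthetic_pipeline.py
```

A thin CLI mirrors the library for shell use:

```
adrmine synth --seed 42 --n 20000 --out data/
adrmine run --demo data/DEMO.csv --drug data/DRUG.csv --reac data/REAC.csv \
            --analysis both --out reports/
```

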