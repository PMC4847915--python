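"""Mine a toy transaction set with the level-wise apriori algorithm.

Five patients with small sets of adverse reactions; thresholds are set
loosely so the handful of frequent itemsets and rules is easy to verify by
eye.
"""

from adrmine import Item, MinerConfig, TransactionSet, frequent_itemsets, generate_rules


def adr(label):
    return Item("adr", label)


ts = TransactionSet.from_iterable([
    {adr("nausea"), adr("vomiting")},
    {adr("nausea"), adr("vomiting"), adr("dizziness")},
    {adr("nausea")},
    {adr("dizziness")},
    {adr("vomiting"), adr("nausea")},
])

cfg = MinerConfig(min_support=0.4, min_confidence=0.8)
itemsets = frequent_itemsets(ts, cfg)
print(f"{len(itemsets)} frequent itemsets at support >= {cfg.min_support}:")
for fi in itemsets:
    print(f"  {{{', '.join(i.label for i in fi.items)}}}  "
          f"count={fi.count}  support={fi.support:.2f}")

rules = generate_rules(itemsets, ts, cfg)
print(f"\n{len(rules)} rules at confidence >= {cfg.min_confidence}:")
for r in rules:
    conv = "NA" if r.conviction is None else f"{r.conviction:.2f}"
    print(f"  {', '.join(i.label for i in r.antecedent)} -> "
          f"{', '.join(i.label for i in r.consequent)}  "
          f"supp={r.support:.2f} conf={r.confidence:.2f} "
          f"lift={r.lift:.2f} conv={conv}")
print("\nvomiting -> nausea has confidence 1.00 (every vomiting case also "
      "reported nausea), so its conviction is NA.")
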