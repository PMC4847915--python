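"""Score a rule from its contingency table, and recover a table from
published rounded statistics.

The top SSRI rule (aspartate aminotransferase increased -> alanine
aminotransferase increased) has the table a=26, b=2, c=4, d=4345 over
t=4377 reported cases: 26 patients reported both laboratory abnormalities,
2 only the antecedent, 4 only the consequent.
"""

from adrmine import (
    ContingencyTable,
    PrintedRule,
    compute_rule_statistics,
    reconstruct_table,
    round_half_up,
)

ct = ContingencyTable(a=26, b=2, c=4, d=4345)
s = compute_rule_statistics(ct)
print(f"support    = {round_half_up(s.support, 4)}   (rule seen in a/t of all cases)")
print(f"confidence = {round_half_up(s.confidence, 2)}     (P(Y | X): how often X implies Y)")
print(f"lift       = {round_half_up(s.lift, 1)}    (x-fold enrichment over independence)")
print(f"conviction = {round_half_up(s.conviction, 1)}     (>1 means X without Y is rarer than chance)")

# The inverse: given only the rounded values a journal table prints, the
# integer table is often uniquely determined.
printed = PrintedRule(t=4377, support=0.0059, confidence=0.93, lift=135.5,
                      conviction=13.9)
recovered = reconstruct_table(printed)
print(f"\nrecovered from rounded values: a={recovered.a}, b={recovered.b}, "
      f"c={recovered.c}, d={recovered.d}")
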