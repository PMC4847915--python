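# Methods

## Data model and unit of analysis

The unit of analysis is the *case* — one spontaneous report, identified by
a case id shared across the DEMO (gender, age category, weight), DRUG
(drug name, causality role) and REAC (ADR preferred term, outcome) tables.
Assembly keeps one `Case` per DEMO row; REAC/DRUG rows whose case id does
not appear in DEMO are dropped with a logged count, and ADR terms are
deduplicated per case. Cases with no REAC rows are kept with an empty ADR
set: they still belong to the cohort and therefore to the denominator t,
which is what the d cell of every contingency table counts.

Cohorts are selected by drug-class membership. Matching defaults to
substring (JADER drug names carry salt and brand suffixes, e.g.
"パロキセチン塩酸塩" for paroxetine hydrochloride) and the causality filter
defaults to suspected-only — the conservative pharmacovigilance
convention; both are configurable, since report databases do not record
which convention a given published analysis used. A case on drugs of
several classes appears in every matching cohort.

## Transactions

Analysis 1 uses ADR-only transactions. Analysis 2 adds at most one
age-decade item (canonical labels `tens` … `nineties+`, mapped from
decade-coded strings like "20代"; non-decade strings such as "高齢者" map
to no item) and at most one gender item (female/male). Gender-unknown and
age-unknown cases *remain in the transaction set* with those items absent.
This is deliberate and matters numerically: marginal supports — and hence
lift and conviction — are taken over the whole cohort, not over the
gender-known subset. The published gender-rule values are only consistent
with the full-cohort denominator (e.g. a female marginal of 392/686, not
392/678), and it is also how itemset miners conventionally treat missing
items.

## Mining

Level-wise apriori: frequent 1-itemsets, then size-k candidates joined
from (k−1)-itemsets sharing a (k−2)-prefix under the canonical item order
(lexicographic on (kind, label)), pruned by downward closure and counted
by intersecting per-itemset transaction-id sets. Thresholds are inclusive;
defaults are the study settings, support ≥ 0.001 and confidence ≥ 0.8,
with `max_len = 10` (the reference miner's default; published rules reach
only 2-item antecedents). Rule generation emits every partition of every
frequent itemset, including multi-item consequents — reporting filters to
single-item consequents by default, mirroring the published tables. For
the gender analysis the consequent is constrained to exactly one gender
item with a gender-free antecedent. Output ordering — descending support,
then confidence, then lift, then lexicographic antecedent and consequent
labels — is an invented but fixed tie-break chain so top-k reports are
byte-reproducible. Correctness is checked against an independent
exhaustive power-set oracle (up to 12-item vocabularies) rather than a
second mining library.

## Indicators and the conviction discrepancy

Statistics are computed at full precision from integer tables and rounded
only at report time (default: support 4 dp, confidence 2, lift 1,
conviction 2 — published rounding is not internally consistent, so a
full-precision companion file is always written). Ties round away from
zero. Conviction is NA exactly when confidence = 1; it is represented as
an absent value, never infinity, and serialized as the token `NA`.

Two conviction variants exist because the printed formula in the source
material, conviction = [(c+d)/t] / [b/(a+b)], contradicts the values the
same source prints: for the anxiety → irritability table (a=4, b=1, c=7,
d=674, t=686) it yields 4.96 (rounds to 5.0) whereas the published value
4.9 matches the standard form [(b+d)/t] / [b/(a+b)] ≡
(1 − supp(Y))/(1 − confidence), which gives 4.92. The gender rules confirm
the same. The standard form is therefore the default; the printed variant
is kept as `conviction_formula="as_printed"` for comparison, and the test
suite asserts both roundings.

## Reconstructing tables from published rounded rows

Published headline rows cannot be re-derived end to end without the exact
database release, but each row over-determines its integer contingency
table: `reconstruct_table` searches all (a, b, c) at the given t for
tables whose exact indicators round (half-up, at the printed precisions)
to every printed value simultaneously, optionally pinning the consequent
marginal a+c to a published count (the per-gender case totals). It errors
rather than guessing when zero or several tables qualify. All reference
rows used in the acceptance checks reconstruct uniquely.

## Synthetic generator

The generator emulates the three-table relational structure at the study
scale: default 20 000 cases; gender 58.5% female / 38.5% male / 3%
missing (chosen to match the published cohort composition, with the
missing fraction present specifically to exercise the denominator
decision above); an adult-heavy decade distribution with 5% age-unknown;
class probabilities 0.73/0.156/0.114 proportional to the published SSRI/
SNRI/NaSSA cohort sizes; a 20-term ADR vocabulary with a 2% independent
background rate per term.

Planted mechanisms have closed-form statistics. For a pair
(X, Y, pX, q=P(Y|X)): X occurs with probability pX; Y with probability q
when X occurred, else with the background rate r. Hence P(X)=pX,
P(X∧Y)=pX·q, P(Y)=pX·q+(1−pX)·r — confidence is exactly q, the background
contaminates only Y's marginal, and q=r gives exact independence
(lift 1). For a gender effect (term, p_f, p_m) the term occurs at the
rate of the case's gender (background rate when gender is unknown).
Defaults plant one strong laboratory pair (pX=0.02, q=0.9) and two
opposite-skew gender effects (0.10/0.01 female-skewed, 0.01/0.08
male-skewed), i.e. one recoverable rule per gender plus one planting per
gender that correctly *fails* the confidence threshold.

What the generator does not emulate: correlated background noise
(syndromes), MedDRA term hierarchies, duplicate reports, temporal
dynamics, and any drug–ADR dependence (ADRs are sampled independently of
class). Passing recovery tests therefore demonstrates correctness of the
pipeline's counting and thresholding under a known sampling model, not
robustness to real reporting biases.

## Test scale and numerical choices

Statistical recovery tests run at n = 20 000 with 3-standard-error
acceptance bands derived from the planted parameters (binomial SE for
support and confidence; the lift band propagates both the confidence and
consequent-marginal SEs). Oracle-equivalence checks use 500 random
transaction sets of 60 transactions over 4–12 item vocabularies, a size
at which exhaustive enumeration is itself cheap and trustworthy. Monte
Carlo validation of the closed forms uses 10^6 vectorised draws of the
planted mechanism alone. All randomness is seeded; reports and generated
CSVs are byte-identical across runs for a fixed seed.

## Known limitations

- No disproportionality statistics (PRR/ROR/IC/EBGM), confidence
  intervals or multiple-testing control — the method ranks rules by raw
  support and applies none.
- ADR labels are used verbatim; no MedDRA normalisation or translation.
- Real-release headline counts (total cases per class, per-gender totals)
  depend on the specific database revision and are out of scope; only the
  per-rule statistics are reproduced, via integer reconstruction.
- The ambiguity of "patients taking" a drug class (causality role,
  multi-class overlap) is resolved by explicit configuration rather than
  a single hard-coded convention.
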