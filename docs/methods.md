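# Methods

## Model and procedure

`comorbmine` treats each patient as one market-basket transaction: the set
of all three-character ICD-10 categories coded across every hospitalization
of that patient. Mining proceeds in the classic two Apriori steps —
(1) level-wise enumeration of all itemsets whose support meets an inclusive
minimum, using prefix-join candidate generation with downward-closure
pruning and exact per-item transaction-id-set counting; (2) generation of
every ordered antecedent/consequent partition of each frequent itemset of
size ≥ 2, scored by support, confidence, and lift from exact integer
counts. A rule is a statement of co-occurrence only; no temporal or causal
ordering is claimed or used.

Preprocessing encodes the cohort-selection assumptions:

- **Category truncation.** Codes are uppercased, whitespace-stripped, and
  truncated to the first three characters (letter + two digits). Fourth
  characters are discarded: categories are the unit of analysis. Chapters
  are the leading letter only; the universe runs A00–U99, so chapter-U
  codes are retained.
- **Code exclusion.** Chapters V/W/X/Y/Z denote external causes and
  health-status contacts, not diseases, and are dropped. Codes whose
  description contains "other" as a standalone, case-insensitive word are
  dropped because residual ("other ...") categories pool heterogeneous
  conditions. Word-boundary matching is a deliberate design choice — plain
  substring matching would false-positive on words like "mother" — and
  both the token and case sensitivity are configurable, since the rule is
  inherently language-dependent and the matching granularity of the
  original cohort is not documented.
- **Patient selection.** Patients with a single distinct admission are
  dropped. The admission count is assessed on the *raw* input, before code
  exclusion: the criterion concerns hospitalizations, not retainable
  codes, so a patient whose second admission carried only excluded codes
  remains eligible. Patients whose retained category set is empty are then
  dropped, because an all-false row can contribute to no itemset and would
  silently deflate every support; the drop is counted in the run log.
- **Malformed codes** fail loudly in strict mode; the default lenient mode
  skips them with a count, the faithful behavior for records with
  incomplete data.

All support denominators use the number of retained patients. Duplicate
codes within or across admissions collapse to one binary item.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_support` | 0.001 | inclusive floor on joint prevalence |
| `min_confidence` | 0.60 | inclusive floor on P(consequent \| antecedent) |
| `min_lift` | 1.0 (strict >) | positive-dependence requirement |
| `max_antecedent_size` | 2 | at most two antecedent categories |
| `consequent_size` | 1 | exactly one consequent category |
| `max_len` | 3 | largest itemset mined (= 2 + 1) |

The asymmetry of the comparisons — inclusive for support and confidence,
strict for lift — is intentional and tested: a rule at confidence exactly
0.60 passes, a rule at lift exactly 1.0 (exact independence) does not.
Rules are sorted by confidence descending with deterministic tie-breaks
(lift, then support, both descending, then lexicographic itemsets).

An optional redundancy heuristic (`prune_redundant`, off by default) drops
a rule when a proper sub-antecedent rule with the same consequent has
confidence at least as high. It is a crude automated stand-in for manual
expert de-duplication of nested rules and is clearly labelled as such; the
pipeline never applies it unless asked.

## Synthetic cohorts

The generator emulates the *structure* of a hospital discharge extract:
one row per coded diagnosis per admission; 2–4 admissions per eligible
patient with items scattered uniformly across them (plus one item re-coded
in a second admission, as chronic conditions are at each stay, so every
eligible patient materializes ≥ 2 admissions); four-character codes (random
fourth digit) to exercise truncation; 10% single-admission decoy patients;
and a 5% per-admission rate of injected excluded codes (V/W/X/Y/Z chapters
and "other"-description categories disjoint from the analysis items).

Dependencies are planted as triples (p_antecedent, p_conditional,
p_background): the patient carries the full antecedent with probability
p_antecedent; the consequent appears with probability p_conditional given
the antecedent, p_background otherwise; noise items are independent
Bernoulli draws. The closed forms

```
support    = p_antecedent · p_conditional
confidence = p_conditional
lift       = p_conditional / (p_antecedent·p_conditional + (1−p_antecedent)·p_background)
```

are exact provided the transaction denominator equals the eligible-patient
count, which the generator guarantees by assigning a generic symptomatic
filler code (R69) to eligible patients whose draws produced no condition.
The default study condition plants I63 → I10 at (0.3, 0.8, 0.1) — expected
support 0.24, confidence 0.80, lift 2.5806 — over background prevalences
(E11 0.20, K29 0.12, C34 0.10, J18 0.08, N18 0.05) chosen to resemble
common hospital diagnoses. Planted rules act independently per patient;
overlapping categories across rules are OR-ed and trigger a validation
warning because the closed forms then no longer hold exactly.

For the null-cohort check the planted dependency is set to independence at
p_conditional = p_background = 0.3: all conditional probabilities then sit
far below the 0.60 confidence floor, and essentially no rule survives
filtering at 50,000 patients.

What the generator does **not** model: age/sex structure, calendar time,
admission ordering, realistic disease correlation beyond the planted
rules, or ICD-10 dictionary descriptions beyond a small built-in set.
Passing recovery tests therefore demonstrate correctness of the pipeline's
counting and filtering under known dependence — not that mined rules from
real data are clinically valid, which requires expert review.

## Numerical choices

- Support counting is exact integer arithmetic on transaction-id sets; no
  sampling. Oracle-equivalence tests require set equality and equal integer
  counts against exhaustive enumeration.
- Threshold comparisons happen on raw floats exactly as configured; the
  miner and the brute-force oracle apply the identical comparison, so
  boundary cases cannot diverge between them.
- Rendered tables round half-even to 2 decimal places (percentages for
  support/confidence, plain for lift); JSON and library objects always
  carry full-precision fractions.
- All randomness flows through one named `numpy.random.Generator`; a fixed
  seed gives byte-identical output files.
- Single-threaded execution is the semantic contract; any parallel variant
  must be bit-identical to the serial result.

## Problem sizes used in validation

Oracle equivalence runs on 100 random databases of ≤ 12 items × ≤ 200
transactions, where exhaustive enumeration is exact and cheap. Parameter
recovery uses 20 cohorts of 50,000 patients each, accepting support and
confidence within 3 binomial standard errors of their closed forms and
lift within 5% relative error, requiring ≥ 95% of seeds to pass. The
worked-sample checks use the published 11-patient TRUE/FALSE matrix; its
six unnamed placeholder columns are re-entered under synthetic in-range
names, and all asserted counts touch only named columns.

## Known limitations

- Chapters are classified by first letter only; true ICD-10 chapter ranges
  (e.g. neoplasms spanning C00–D48) are out of scope by design.
- The "other"-description rule operates on whatever description strings
  the input carries; cohorts coded in other languages need a different
  token.
- Full-scale published rule sets from undeposited hospital EMRs are not
  reproducible at desk scale; validation rests on analytic identities
  among published metrics, oracle equivalence, and synthetic recovery.
- Statistical significance, multiple-testing control, and causal ordering
  of rules are out of scope.
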