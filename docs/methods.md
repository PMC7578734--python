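# Methods

## Data model

A *prescription* is the set of acupoints one clinical trial stimulated;
a dataset is an ordered list of N prescriptions over a universe of
acupoint codes. Set semantics are enforced at load time: duplicate
(study, acupoint) rows collapse, codes are trimmed and case-folded to
the registry's canonical form (standard `meridian+number` codes are
upper-cased; registered experience-point names such as `Xiongtong` are
kept verbatim). The universe is ordered by descending prescription
frequency with lexicographic tie-break, so every tabular output is
deterministic. The 0/1 incidence matrix (prescriptions × acupoints) is
the bridge to all matrix computations; its row sums are prescription
sizes and its column sums acupoint frequencies.

The built-in registry covers the 37 CSAP acupoints: 36 map to the ten
meridians (PC, LU, HT, ST, BL, RN, LI, LR, SP, KI) and one experience
point belongs to none. Strict mode rejects unknown codes with the
offending code and row; permissive mode auto-registers them with no
meridian and a warning, for reuse on new datasets.

## Frequency tables

`acupoint_frequency` counts prescriptions containing each code and
reports shares against **total usages** (Σ prescription sizes), the
convention under which an acupoint in 25 of 27 prescriptions carries
25/130 = 19.2%. `meridian_frequency` aggregates per meridian under two
explicit semantics — `usage_sum` (sum of member-acupoint counts, which
conserves total usages) and `prescription_count` (prescriptions using ≥1
member, bounded by N) — because published per-meridian counts for the
CSAP study follow neither recipe when recomputed from the per-acupoint
table, and the derivation used there is not stated. The package
therefore exposes both transparent definitions (default `usage_sum`)
and asserts only the internal share arithmetic of such tables (e.g. a
frequency of 16 against a column total of 80 prints as 20.0%). Shares
are rounded half-up at 1 decimal.

## Association rules

Frequent itemsets are mined level-wise (Apriori): size-k candidates are
joined from frequent (k−1)-itemsets and pruned unless every (k−1)-subset
is frequent, then counted against the data. Support thresholds are
compared on exact rationals (a count qualifies iff count·100/N ≥ the
threshold), so 4/27 = 14.8% correctly falls below a 15% floor while
5/27 = 18.5% clears it.

Rules have a single-item consequent (the behaviour of Modeler-style
Apriori, and the shape of every published CSAP rule row): for each
frequent antecedent A and each universe item b ∉ A with |A|+1 ≤
`max_rule_size`, the rule is emitted iff σ(A∪{b})/σ(A) ≥ the confidence
floor. Defaults reproduce the CSAP study settings: support 15%,
confidence 80%, `max_rule_size` 3 (the published table contains no
larger rule, although larger antecedents would pass the thresholds —
the default reproduces that reporting scope).

Two support conventions are exposed because the published rule table and
the stated formula disagree: the table's leading row prints 59.26% =
σ(antecedent)/N, while the textbook rule-support formula gives
σ(A∪{b})/N = 55.56% for the same rule. `antecedent` (default) matches
the published numbers; `joint` implements the formula. Confidence and
lift are unaffected. All statistics are carried as `fractions.Fraction`
and rounded half-up at 2 decimals only for presentation (so an exact
lift of 1.0125 prints as 1.01 — the half-digit is in the fourth
decimal — and 27/16 = 1.6875 prints as 1.69).

Published rule tables list each rule's items without marking which side
is the antecedent, and the listing order is inconsistent (some rows are
antecedent-first, others consequent-first). Rules are therefore keyed by
(antecedent set, consequent), and the reference comparison resolves each
published row to its statistic-consistent orientation. One published row
({LU6}→HT5) is orientation-symmetric — both directions have antecedent
frequency 5 and identical statistics — so its mirror {HT5}→LU6 is mined
as well. In total the reconstructed data force three rules through the
published thresholds that the published table omits ({HT5}→LU6,
{LU6,PC6}→LU9, {HT5,PC6}→LU6); the miner reports them and the fixture
verifier tracks them explicitly as companions rather than suppressing
them.

A brute-force oracle (`brute_force_rules`) enumerates every antecedent
subset and consequent directly, guarded to ≤ 20 items unless overridden;
tests assert exact rule-set equality (including statistics) between the
Apriori path and the oracle on the shipped dataset and on 100 seeded
random datasets.

## Co-occurrence and network

The co-occurrence matrix is MᵀM for incidence matrix M: symmetric, with
single-acupoint frequencies on the diagonal. Normalisation divides by N
only (15 joint uses in 27 prescriptions → 55.6%); no usage-based
alternative is offered, keeping one unambiguous meaning. Pair ranking is
by count descending with lexicographic tie-break. Heat-map rendering is
deliberately out of scope: the matrix file is the deliverable.

The co-usage graph is **undirected** — joint usage is symmetric, and
per-node degree in published network summaries reads as a single
undirected degree — with edge weight equal to the raw co-occurrence
count and an edge iff that count ≥ `min_weight` (default 1). Global
statistics: average degree 2E/V; average path length and diameter from
unweighted BFS shortest paths, computed on the largest connected
component and flagged with the component size and convention. A
single-node component reports path statistics as undefined (`None`)
rather than raising. k-cores come from standard iterative peeling (a
node's core number is the largest k it survives); peeling order does not
affect the result, which tests confirm against a from-scratch fixed-point
oracle. The Fruchterman–Reingold layout is seed-deterministic and scaled
to the square frame of the requested area.

The published network figures for the CSAP study (36 nodes, 277 edges,
average degree 23.3, path length 1.62, diameter 2, the k ≥ 13 core) are
mutually inconsistent (2·277/36 ≈ 15.4 ≠ 23.3) and depend on an
edge-construction step that cannot be reconstructed from printed data,
so no exact network figure is asserted; tests check structural
properties instead (the hub acupoint has maximum degree, the largest
component's diameter is ≤ 3, and all oracle equivalences).

## The reconstructed CSAP dataset

The study deposited no raw prescriptions, but its printed summaries
over-determine the data: the 37 acupoint marginals (summing to 130
usages over N = 27) are printed outright, and each published rule's
antecedent frequency × confidence fixes an exact joint count — e.g.
confidence 93.75% at antecedent frequency 16 fixes σ(LU9∩PC6) = 15.
Three 100%-confidence rows at full antecedent frequency are containment
statements (LU6 ⊆ LU9, LU6 ⊆ PC6, HT5 ⊆ PC6), which propagate the pair
counts to the triples.

The shipped dataset is a hand-curated satisfying assignment, frozen as
version-controlled long-format text rather than solved at runtime (the
feasibility analysis was done once; determinism and fast tests follow).
Its skeleton: four prescriptions {LU6,LU9,HT5,PC6}, one {LU6,LU9,PC6},
one {HT5,PC6}, eleven further LU9 prescriptions (one lacking PC6), an
ST36 block disjoint from LU9, and BL15/HT7 blocks split across the LU9
and ST36 sides. Low-frequency acupoints are spread so that every
acupoint pair outside the published joints co-occurs ≤ 4 times (below
the 15% antecedent floor) and every pair touching a frequency-5 acupoint
≤ 3 times (below the 80% confidence trigger), while roughly balancing
prescription sizes around the 130/27 ≈ 4.8 average. `verify_fixture`
re-checks every marginal, exact joint and guard bound, then re-mines the
dataset and demands the rule set equal the 13 published rows plus the
three documented companions.

What the reconstruction does and does not show: it is
constraint-equivalent to the real data for every statistic the printed
tables pin down (marginals, the rule table, the top co-occurrence), so
reproducing those tables from it validates the *pipeline arithmetic*
exactly. Joint structure beyond the printed constraints (and hence exact
heat-map cells or network figures) is unknowable from the publication,
and nothing here claims to recover the historical prescriptions.

## Random-transaction generator

`random_dataset` draws each item into each transaction as an independent
Bernoulli trial, re-drawing empty transactions, with a seeded generator.
One subtlety matters for calibration tests: re-drawing conditions the
sample on non-emptiness, which makes a bare pair of items negatively
dependent — for inclusion probabilities 0.6 and 0.5 the conditional lift
is 0.375/(0.75·0.625) = 0.8, not 1. Lift-sanity tests therefore include
an always-present filler item, eliminating re-draws so the tested pair
is exactly independent; at n = 2000 the empirical lift then sits within
binomial sampling error (±0.1) of 1.

## Problem sizes and numerical choices

The shipped analyses run on the 27×37 dataset in well under a second.
Property tests use 100 seeded 20-transaction/8-item datasets for the
miner-vs-oracle check, 25–30-node random graphs for the network oracles,
and n = 2000 for the lift calibration; the full suite completes in a few
seconds. Thresholds are compared as exact rationals; presentation
rounding is half-up (away from zero on ties) at 1 decimal for shares and
2 decimals for rule statistics; ordering of every output table is fully
specified (frequency descending then code; rules by antecedent size,
support, confidence, lexicographic; exports by degree then code).

## Known limitations

- Per-meridian counts as published for the CSAP study cannot be
  recomputed from the per-acupoint table; both implemented semantics are
  documented alternatives, not reproductions.
- Exact network-level figures are not reproducible from printed data and
  are not attempted.
- The generator models item independence only; it does not emulate the
  syndrome-driven correlation structure of real prescriptions, so
  passing calibration tests validates the statistics' implementation,
  not any clinical claim.
- Interestingness measures beyond support/confidence/lift (conviction,
  leverage), negative rules, and community detection are out of scope.
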