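# acumine

Data-mining toolkit for **acupoint prescription data**: the sets of
acupuncture points (acupoints) that clinical trials of a condition
stimulate. Each trial contributes one *prescription* — a set of acupoint
codes such as `PC6` (Neiguan) or `LU9` (Taiyuan) — and the collection of
prescriptions is analysed as a market-basket transaction dataset.

The package was built around the published evidence synthesis of
acupuncture for chronic stable angina pectoris (CSAP): 27 trial
prescriptions over 37 acupoints (36 meridian points plus one
extra-meridian experience point), 130 acupoint usages in total. It is
aimed at evidence-synthesis and traditional-medicine informatics
researchers who want those prescription-mining analyses to be scripted,
tested and reproducible rather than assembled by hand in GUI tools.

## What it computes

Over a transaction dataset of N prescriptions with σ(A) the number of
prescriptions containing itemset A:

- **Frequency tables** — per-acupoint usage counts with shares of total
  usages, and per-meridian aggregates (usage-sum or prescription-count
  semantics).
- **Association rules** (Apriori, level-wise with downward-closure
  pruning), with single-item consequents and the classic statistics
  - support s(A) = σ(A)/N,
  - confidence c(A→b) = σ(A∪{b})/σ(A),
  - lift = c(A→b)/s(b), lift > 1 marking positive association.

  Two rule-support conventions are exposed: `antecedent` (σ(A)/N, the
  SPSS-Modeler convention used in published rule tables) and `joint`
  (σ(A∪{b})/N, the textbook formula). All ratios are computed on exact
  rationals and rounded half-up at the displayed precision. An
  exhaustive `brute_force_rules` oracle backs the miner in the tests.
- **Co-occurrence matrix** — symmetric acupoint×acupoint joint
  prescription counts (the Gram matrix of the 0/1 incidence matrix),
  normalised by N.
- **Co-usage network** — an undirected graph linking acupoints that
  appear together, weighted by co-occurrence count, with degree
  statistics, BFS path length/diameter, k-core decomposition,
  seed-deterministic Fruchterman–Reingold layout, and Gephi-style
  node/edge list export.
- **Reconstructed CSAP dataset** — the study deposited no raw data, but
  its printed summary tables over-determine the joint structure; the
  package ships a 27-prescription synthetic dataset satisfying every
  printed marginal and rule-implied joint count, plus a verifier
  (`verify_fixture`) that re-checks all of them and re-mines the rules.

## Worked example

```python
import acumine as am

ds = am.build_csap_fixture()          # 27 prescriptions, 37 acupoints
print(ds.N, ds.total_usages)          # 27 130

table = am.acupoint_frequency(ds)
print(table.rows.head(3).to_string(index=False))
#  label  frequency  share_pct
#    PC6         25       19.2
#    LU9         16       12.3
#   ST36          9        6.9

rules = am.mine_rules(ds, min_support_pct=15, min_confidence_pct=80)
top = rules[0]
print(sorted(top.antecedent), "->", top.consequent,
      top.support_pct, top.confidence_pct, top.lift)
# ['LU9'] -> PC6 59.26 93.75 1.01

matrix = am.cooccurrence_matrix(ds)
print(am.top_pairs(matrix, k=1))
# [('LU9', 'PC6', 15, 55.6)]
```

The first rule reads: LU9 appears in 16/27 prescriptions (support
59.26% under the antecedent convention); when it does, PC6 co-appears
15/16 times (confidence 93.75%); lift 1.01 means the pair is used
together almost exactly as often as independence would predict —
unsurprising, since PC6 is in 25 of the 27 prescriptions. The top
co-occurring pair, LU9–PC6, appears jointly in 55.6% of prescriptions.

The same analyses are available from a shell:

```bash
acumine freq   --input prescriptions.csv
acumine rules  --input prescriptions.csv --min-support 15 --min-confidence 80
acumine cooc   --input prescriptions.csv --normalized
acumine network --input prescriptions.csv --out-dir out/
acumine report  --input prescriptions.csv --out-dir out/   # full bundle
acumine fixtures verify                                    # shipped dataset
```

Input is delimited text, either *long* (`study_id,acupoint`, one row per
usage) or *wide* (0/1 incidence table). A 37-acupoint registry mapping
codes to their ten meridians ships with the package; unknown codes are
rejected in strict mode or auto-registered with `--permissive`.

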