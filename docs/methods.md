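# Methods

## Problem setting

The unit of analysis is one hospital discharge of an adult inpatient
whose principal diagnosis is a mood disorder (ICD-10 F30–F39). Each
discharge carries up to 20 additional diagnoses; these comorbidities,
mapped to ICD-10 middle-classification blocks, form the transaction
over which co-occurrence patterns are mined. One record is one
transaction — discharge abstracts carry no patient identity across
admissions, so no patient-level deduplication is attempted, and no
temporal ordering or present-on-admission logic is modelled.

## Block mapping and comorbidity classes

Diagnosis codes are reduced to their 3-character category (letter + two
digits); 4th characters and dots are subcategory detail below block
granularity and are dropped. The packaged block table is the WHO ICD-10
(2016) middle classification, shipped as CSV and validated at load time
(ordered, non-overlapping ranges; block ranges may cross letters, e.g.
X85–Y09). Categories not covered by the table — gaps in the
classification, or local KCD-7 extensions outside listed ranges — are
governed by a policy flag: `error` (library default, keeps tests
strict) or `skip` with a logged warning (pipeline default, matching how
real dumps with local codes are handled in practice).

A block is classified *psychiatric* exactly when it lies entirely
within F00–F69, otherwise *physical*. This is applied literally, so
F70–F99 blocks (mental retardation, developmental and childhood-onset
disorders, F99) count as physical comorbidity.

## Transactions

Records are filtered to a principal-diagnosis subgroup (F30, F31, F32,
F33, F34, F38, F39, or the pooled cohort), and each record's additional
codes are mapped to a deduplicated block set. Two deliberate choices:

- **Empty transactions stay in the denominator.** Support is a fraction
  of *all* discharges in the subgroup, not of those with ≥ 1
  comorbidity. This is forced by the arithmetic of per-subgroup support
  values in published tables (e.g. 262/7709 = 0.034) and is the
  epidemiologically meaningful denominator.
- **Same-block comorbidities are kept.** The additional code equal to
  the principal's own category is never an item, but other codes that
  map into the principal's block are retained by default (an F31
  additional diagnosis on an F33 discharge is a genuine mood-block
  comorbidity; subgroup frequency profiles do show F30–F39 among
  comorbidities). `same_block_policy="drop_block"` excludes the whole
  principal block instead, for sensitivity analyses.

## Rule mining

Apriori is implemented directly (the item universe is ~130 blocks at
most, and tens in practice): level-wise sorted-prefix candidate
joining, downward-closure pruning, support counting by scanning each
transaction's k-subsets against the hashed candidate set. Rules have a
single consequent; antecedents up to size 2 by default (sufficient for
every published row while keeping the rule space interpretable).

Metrics are computed from unrounded integer counts; rounding to 3
decimals happens only at report time. This matters: several published
IS values are only reproducible from unrounded support (e.g.
IS = √((38/2414) · 6.970) = 0.331, whereas the rounded support 0.016
gives 0.334).

Filters default to support ≥ 0.01 and confidence ≥ 0.10 (inclusive
minima, the convention of standard miners — no published rule sits on
the boundary, so inclusivity is unobservable there) and lift > 1
(strict: positive association only). Ranking is by descending IS, ties
broken by descending support and then lexicographic rule label so runs
are deterministic. Bidirectional pairs are defined on single-antecedent
rules only; lift and IS symmetry across the pair is an algebraic
identity and asserted to 1e-12 in tests.

`AprioriMiner` wraps the whole mine–filter–rank path as a scikit-learn
estimator (`fit`, fitted attributes `itemsets_`, `rules_`,
`n_transactions_`), with `BlockTransactionizer` as the records →
transactions transformer in front of it; the module-level functions
(`apriori`, `generate_rules`, `filter_rules`, `rank_rules`, …) are the
same steps as plain calls. `brute_force_itemsets` is an independent
enumeration oracle (≤ 12 items, ≤ 200 transactions) used only for
validation.

## Prevalence and χ²

Prevalence tables count records whose transaction contains ≥ 1
psychiatric / physical / any block, per stratum of a demographic field
or per subgroup, with percentages of the stratum size. Independence is
tested with Pearson's χ² without continuity correction — the choice is
verifiable: the sex × psychiatric table reconstructed from published
stratum counts reproduces the published statistic 12.466 only without
Yates' correction. Tables with an all-zero marginal raise by default;
with `allow_degenerate=True` zero-expected cells are skipped and the
result is flagged `valid=False`, mirroring the "N/A" convention of
published tables (whose exact rule for N/A cells is not stated; ours is
a documented choice). Display rounding is 2 dp for percentages and 3 dp
for statistics, with p-values below 0.001 rendered `<0.001`;
computation is always on unrounded values.

## Synthetic cohorts

### Exact mode

`generate_exact_cohort` turns target block marginals and joint
co-occurrence counts into a concrete cohort: joint itemsets are placed
largest-first as records carrying exactly that itemset (minus records
already covering them), remaining marginal mass becomes single-block
records, and the rest of the n records carry no comorbidities. A final
recount raises if the greedy layout cannot realise the spec. Output
ordering is canonical (sorted by content), so identical specs produce
byte-identical files. Joint itemsets of any size are supported — a
published rule with a two-block antecedent implies a triple
co-occurrence that pairwise cells cannot express.

Published rows state N, support, confidence(s) and lift but not the
marginal counts. `marginals_from_rule_row` recovers them as the
integers inside the printed confidence's rounding interval whose
recomputed lift matches the printed lift at 3 dp; recovered marginals
are cross-consistent between rows sharing a block (the hypertension
block recovers as 838 from three independent pooled rows).

### Stochastic mode

`generate_random_cohort` draws, per record, independent Bernoulli base
blocks and then lets each planted association inject its pair with
probability `p_pair` (a latent Bernoulli factor). The induced
quantities have closed forms used as test oracles:

```
P(A)      = 1 − (1 − p_A)(1 − p_pair)
P(A ∧ B)  = p_pair + (1 − p_pair) · p_A · p_B
lift      = P(A ∧ B) / (P(A) · P(B))
```

Recovery is tested at n = 50,000 with the empirical lift required to
fall within 3 Monte-Carlo standard errors (batch-means estimate, 25
batches) of the closed form; without planting, pairwise lift converges
to 1. All randomness flows through one `numpy` generator seeded from
the mandatory config seed, so identical configs give identical cohorts.

Default study conditions mirror the emulated national cohort: subgroup
sizes 45 / 2414 / 4245 / 827 / 117 / 7 / 54 (total 7709) and
demographic strata (e.g. 2362 male / 5347 female) reconstructed from
the published count-and-percentage cells, which determine the stratum
sizes uniquely. Base block prevalences follow the leading comorbidity
profile (hypertensive diseases ≈ 0.10 > neurotic disorders 0.08 >
diabetes ≈ 0.06 > upper-GI diseases 0.05, plus rarer blocks), with two
planted pairs (diabetes–hypertension, metabolic–hypertension) supplying
realistic positive association. Demographics are independent of
diagnosis content: no joint demographic–diagnosis model is claimed by
the source material, so none is invented. Passing tests on these
cohorts therefore validate the *pipeline arithmetic and recovery
behaviour*, not clinical structure — real discharge data has correlated
comorbidity burdens by age, coding-depth artefacts and survey design
effects that the generator deliberately does not emulate.

## Rule networks

The top rules (≤ 20 by default, matching what is legible in a drawn
network) form a directed graph: block nodes carry `node_support` (the
maximum support of incident rules, the "node size" channel), edges
carry support, lift and IS (lift being the "edge darkness" channel).
Multi-block antecedents are rendered through an auxiliary junction node
— the bipartite convention of basket-analysis visualisers — because
plain graph formats cannot express hyperedges. GraphML export is typed
(doubles) and round-trips all attributes; DOT is written by a minimal
local writer; layout is presentation, not contract.

## Pipeline determinism and problem sizes

`run_pipeline` writes a fixed-layout bundle (records, prevalence
tables, per-subgroup transactions, frequency profiles, 3-dp report
rule tables plus full-precision raw tables, GraphML networks, manifest)
and reruns byte-identically for deterministic inputs; the manifest
embeds the resolved config and seed. Report floats are fixed at 3 dp;
raw CSVs keep full precision. The test suite and acceptance script run
at the cohort sizes above (7709-record exact reconstructions; one
50,000-record stochastic cohort for recovery), which is the scale at
which every published quantity is determined.

## Known limitations

- Survey design (two-stage cluster sampling, weights) is out of scope;
  all statistics are unweighted, as in the emulated analysis.
- The χ² validity flag is a documented convention, not an inference of
  the original table's N/A rule.
- The unknown-code policy cannot recover what a local KCD code *meant*;
  skipped codes simply vanish from transactions.
- Exact-mode layouts place at most one joint itemset per record beyond
  the specified overlaps; specs requiring overlapping joint structure
  not expressible that way are rejected by the recount check rather
  than approximated.
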