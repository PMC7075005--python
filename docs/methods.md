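# Methods

## The model

`herbnet` ranks candidate protein targets of a multi-component herbal
formula by how much the integrity of a pathway-derived target network
degrades when a single target is assumed undruggable.

The input is a bipartite target-pathway membership relation (in practice,
the retained rows of a pathway over-representation analysis of the
formula's predicted targets). Its one-mode projection is the
**targets-pathways-targets (TPT) network**: nodes are targets belonging to
at least one retained pathway, and two targets are joined iff they share a
pathway; the edge stores the exact set of shared pathways. Baseline edges
have length 1 — shared-pathway multiplicity does not weight edges at
baseline; it only matters under perturbation.

**Knockout perturbation.** Each target contributes an equal share to every
pathway it belongs to (the equal-share assumption is hard-coded; there is
no per-target weighting hook). Setting off target *i* reduces every pathway
*j* containing it, with *N_j* members, to pathway efficacy

    PE_j = (N_j − 1) / N_j,

while unrelated pathways keep efficacy 1. An edge carrying *t* affected
pathways has edge efficacy equal to the product of their PEs,

    EE = ∏ (N_k − 1)/N_k   over the t affected pathways,

and its length stretches from 1 to L = 1/EE. The knocked node is **not**
deleted: its incident pairs still count, only lengths change.

**Network efficiency and the score.** With d_mn the weighted
shortest-path length between targets m and n,

    NE = Σ_{unordered pairs {m,n}} 1 / d_mn,

with unreachable pairs contributing 0, and the score of target *i* is the
network-efficiency decrease

    NED_i = NE_0 − NE_i ≥ 0.

The sum runs over *unordered* pairs: on the worked example below this
yields the published NE_0 = 13.83, whereas an ordered sum would double it.
Targets are ranked by descending NED (ties broken by ascending target id),
and the top ⌈0.10·n⌉ are selected as main targets — at n = 279 that is 28.

**Exact arithmetic.** PE, EE and L are kept as exact rationals
(`fractions.Fraction`), so L·(N−1)/N = 1 holds exactly for single-pathway
edges; lengths are converted to floats only inside the shortest-path
solver. Displayed efficacies round to integer percent (2/3 → 67%).

## Worked example

The demonstration network (`herbnet.sample_network()`) has 7 targets A–G
and 6 pathways: a = {A,B,C}, b = {B,C,E}, c = {B,E}, d = {C,D},
e = {C,F}, f = {F,G} — 14 membership pairs projecting to 8 edges. At unit
lengths NE_0 = 83/6 ≈ 13.8333. Knocking out the hub C gives PE = 2/3 for
the two size-3 pathways and 1/2 for the two size-2 pathways, hence edge
lengths AB = AC = BE = CE = 1.5, BC = 9/4 = 2.25 (two affected pathways,
EE = 4/9), CD = CF = 2, FG = 1, and NE_C = 8.476144, NED_C = 5.357190.

**Documented discrepancy.** The published account of this same example
prints NE = 8.60 and NED = 5.23 for the C knockout, but Dijkstra over its
own printed edge-length matrix (identical to the lengths above) gives
8.476144 / 5.357190. The printed matrix is taken as normative here; the
implementation is deliberately not adjusted to emit 8.60, and the source
of the 0.12 gap is not guessed at.

## Numerical and algorithmic choices

- **Shortest paths:** standard Dijkstra (scipy's sparse-graph
  implementation) per source over the symmetric length matrix. It
  reproduces the worked example's distance matrix; no modified or
  approximate variant is used.
- **Ranking determinism:** NE_0 is computed once per ranking; knockouts
  are independent, and results are sorted (−NED, target id) regardless of
  evaluation order.
- **Degenerate inputs:** an empty map projects to an empty graph (NE = 0);
  a pathway with one member contributes no edges, and a target in no
  edge-bearing pathway has NED exactly 0; a zero edge efficacy (impossible
  for edges built by projection, whose pathways have ≥ 2 members) is
  guarded by treating the edge as absent.
- **Top-k rounding:** ceiling, so 10% of 279 targets selects 28.

## Surrounding stages

- **Oral-bioavailability screen:** Veber's rule — rotatable bonds ≤ 10 and
  topological polar surface area ≤ 140 Å², both boundaries inclusive.
  Descriptors come from the input table; compounds with missing or
  negative descriptors raise an error rather than being silently dropped
  or passed. No molecular-weight cut is applied; curating the input table
  is the caller's responsibility.
- **Enrichment:** one-sided hypergeometric upper-tail test per pathway
  with Benjamini–Hochberg FDR control and retention at q < 0.05. This is a
  transparent local substitute for the web-service enrichment used in the
  original study, whose annotation release and gene universe are not
  recoverable; by default the universe is every target appearing in the
  annotation table, and pathway sets are intersected with the universe
  before testing. A pre-enriched target-pathway table may bypass this
  stage entirely.
- **Baselines:** degree centrality is reported as the raw degree and
  betweenness as unnormalized Brandes betweenness with fractional credit
  for tied shortest paths. The downstream comparison is rank-based, so
  normalization could not change it; raw values are simpler to verify.
- **TPD network:** a directed three-layer DAG, main target → pathway →
  ICD-11 disease class, built from the main-target set, the annotation and
  a pathway-disease input table. Duplicate pathway-disease rows collapse
  to a single edge. Main pathways have indegree strictly greater than 10
  (distinct main targets), main disease classes strictly greater than 20
  (distinct pathways); both thresholds are overridable.
- **Validation:** Spearman rank correlation of each score (NED, DC, BC)
  against full-text and abstract literature co-occurrence counts. rho is
  the Pearson correlation of mid-ranks; the two-tailed p-value uses the
  t approximation with n − 2 degrees of freedom (the common
  statistical-package default — the original analysis does not state its
  tie handling, so this is a documented choice). An exact permutation
  p-value is available for n ≤ 8. Constant inputs yield a flagged result
  with NaN statistics instead of an exception. Published correlation
  coefficients from the original study depend on proprietary literature
  queries and are not reproduction targets.

## Synthetic data

The generators exist so every stage is testable without downloads:

- `sample_network()` — the fixed worked-example map above.
- `random_bipartite(spec)` — each (target, pathway) pair is included
  independently with `membership_prob`; pathways falling below
  `min_pathway_size` (default 2, since smaller pathways are invisible to
  the projection) are redrawn, or dropped if configured. The study-scale
  conditions used in the acceptance checks are 279 targets, 155 pathways
  and membership probability 0.035, chosen to match the reported scale of
  the real analysis (279 relevant targets, 155 pathways, ≈6.5k TPT edges).
- `synthetic_cooccurrence(scores, beta, baseline, seed)` — Poisson counts
  with log-mean `baseline + beta · standardized(score)`: the simplest
  monotone count model, giving an exact independence null at `beta = 0`.

What the generators do **not** emulate: the real compound/target
distributions of any particular formula, correlated pathway membership
(real pathways overlap non-independently), and the heavy-tailed, highly
zero-inflated character of real literature counts. Passing tests therefore
demonstrate correctness of the algorithms under controlled conditions, not
recovery of any particular published ranking.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale by design: the
7-target worked example exercises every formula exactly; property checks
use 100 random maps of ≤ 30 targets and 50 graphs of ≤ 12 nodes against a
Floyd–Warshall oracle; the validation calibration uses 1000 null and 100
alternative replicates at n = 279. All generators are bit-reproducible
given their seed, and re-running the pipeline with the same config and
seed reproduces every artifact byte-for-byte.

## Known limitations

- Equal-share pathway contribution is an assumption, not an estimate;
  targets with very different within-pathway importance are not
  distinguished.
- Single-target knockouts only; no simultaneous multi-target restraint.
- The full-scale published network (279 nodes, 6549 edges) can only be
  reproduced from the original supplementary annotation table, which is an
  input, not part of this package.
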