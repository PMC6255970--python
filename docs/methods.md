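# Methods

This note documents the statistical models, algorithmic choices and
simulation design behind `crosstalkkit`, and what the test suite does and
does not establish.

## Over-representation testing

The enrichment stage treats gene sets as flat (no ontology-graph
propagation) and tests each term one-sidedly for over-representation: with
background size `N`, term size `K`, query size `n` and overlap `k`, the
p-value is the hypergeometric upper tail `P(X >= k)`. Two numerical routes
implement the same quantity:

* for `N <= 200`, exact integer summation of the pmf numerators followed by
  one big-integer division, which is correctly rounded to double precision;
* for larger `N`, log-space summation with `lgamma` log-binomials
  (relative error ~1e-13), which keeps magnitudes like 1e-44 finite.

Benjamini–Hochberg is the plain step-up procedure with an optional family
size `m_total` larger than the number of supplied p-values; the enrichment
driver uses it to count zero-overlap terms (which are not emitted as
records) in the correction, keeping the FDR conservative. Correction is
stratified by ontology/functional-class label: published GO enrichment
columns back-calculate to distinct per-ontology family sizes (the bundled
reference table implies 256 / 87 / 45 for the P / F / C strata), so a
single pooled correction would not reproduce practice.

Exact tests are discrete: `P(p < alpha)` is at most, and generally below,
`alpha`. The null-calibration fixture therefore uses large gene sets
(2 000–8 000 of 20 000, query 5 000) where the attainable significance
levels are dense and the conservatism bias is an order of magnitude smaller
than the Monte-Carlo standard error; with study-sized sets (3–28 genes) the
same test is structurally conservative and no implementation can sit at the
nominal rate.

## Cross-talk network

Filters and thresholds (all exposed as configuration):

| parameter | default | meaning |
|---|---|---|
| `min_genes` | 3 | minimum candidate genes for a pathway to enter |
| `min_shared` | 3 | minimum shared genes for a pair to be tested |
| `pair_fdr` | 0.01 | BH-FDR cut-off for selecting edges |
| `top_fraction` | off | optional truncation of the ranked edge list |
| `module_min_nodes` | 4 | functional-class size that counts as a major module |

Design choices where the procedure was genuinely open:

* **Pair-test universe.** The Fisher universe for pathway pairs is the set
  of candidate genes covered by at least one valid pathway: the cross-talk
  analysis operates entirely inside the candidate list, so the genome-wide
  background would overstate significance. A `background_size` override is
  available.
* **Rank score.** Pairs are ranked "by JC and OC"; the combination rule is
  the arithmetic mean `(JC + OC) / 2` (symmetric, order-preserving when the
  two agree), selectable as `mean | jc | oc`.
* **Selection rule.** The unambiguous rule — FDR < 0.01 plus the
  shared-gene floor — is the default; `top_fraction` (with `ceil` so the
  selection is never smaller than the stated fraction) is provided for
  workflows that truncate the ranking instead. Both behaviours are
  implemented because published descriptions of this step are not mutually
  consistent; neither is asserted as ground truth.
* **Modules.** Major modules are functional classes with at least 4
  surviving pathways — the smallest module reported in practice has 4
  members; graph clustering is deliberately not used because the grouping
  is class-driven.
* Average local clustering uses the standard convention that nodes of
  degree < 2 contribute 0.

## BUM scoring and subnetwork extraction

The p-value mixture `f(x) = lambda + (1 - lambda) a x^(a-1)` is fitted by
bounded L-BFGS-B from five fixed starting points; fits whose signal mass
`(1 - lambda)(1 - a)` falls below 1e-3 are flagged `no_signal`. The FDR
target is converted to a threshold via `estFDR(x) = pi0 x / F(x)` with
`pi0 = lambda + (1 - lambda) a` (the conservative null bound) and solved by
log-space bisection; a closed form exists and is used as a cross-check in
the tests, the bisection being the implementation.

Node scores `s(p) = (a - 1)(ln p - ln tau)` follow the standard
signal-to-noise log-ratio form for BUM models (up to a positive factor),
and are positive exactly when `p < tau`. Edge "distances" are the summed
score deficits of the endpoints from the maximum node score — nonnegative,
and decreasing in endpoint scores — so minimum spanning trees run through
high-scoring corridors.

Exact maximum-weight connected-subgraph solving (an NP-hard Steiner-type
problem) is out of scope; the implementation is the MST projection followed
by exact tree dynamic programming and greedy augmentation with
positive-scoring neighbours. Guarantees come from cross-checks rather than
theory: two independently implemented MST algorithms must agree in weight;
the tree DP must equal exhaustive enumeration on small trees; and the full
heuristic is bounded by (and in ~97% of random small instances equal to)
the exhaustive oracle. Ties everywhere resolve by smallest node name;
disconnected inputs are solved per component and the best component wins.

## Synthetic data

The generator reproduces the *shape* of the study inputs, not their
content: ~10^4 genes with sorghum-style locus IDs, 69 pathways with 3–28
members and KEGG-style `ko` identifiers and functional-class labels drawn
with class frequencies matching the published cross-talk table, a 133-gene
candidate set, and a 266-node PPI graph (uniform-random or
preferential-attachment edges, mean degree 4) with a 15-node planted
module.

Key design points:

* **Pathway gene pool.** Pathway members are drawn from a 250-gene
  drought-associated subpool of the universe by default
  (`pathway_pool_size`; `None` disables). Published per-pathway gene
  counts are counts of *candidate* genes, i.e. pathway membership in such
  studies is concentrated on the candidate list; without a subpool,
  pathways drawn from the full universe would share essentially no
  candidate genes and the cross-talk stage would be vacuously empty.
* **Controlled overlap.** Designated pathway pairs (consecutive indices)
  share a core of `round(overlap_rate * min sizes)` genes; the remainders
  are drawn independently, so at `overlap_rate = 0` pairwise overlap sits
  exactly at the hypergeometric chance level.
* **Candidate enrichment.** Candidates are sampled without replacement
  with per-gene weights (`enrichment_odds` inside designated pathways, 1
  elsewhere) via Gumbel-key weighted sampling; odds of 1 reduce to a
  uniform draw. The default odds of 100 reflect that the emulated list is
  a *prioritized* candidate set, not a mild association signal.
* **Planted module.** Module nodes receive `p ~ Beta(a, 1)` (default
  `a = 0.2`), background nodes `p ~ Uniform(0, 1]`; a random tree over the
  module guarantees its connectivity, and disconnected graph components
  are bridged deterministically through their smallest node IDs.
* **Determinism.** One integer seed feeds three spawned `SeedSequence`
  streams (pathways, candidates, graph); serialized outputs are
  byte-identical across runs of the same configuration.

What the simulations do *not* emulate: read-level expression data and the
processing that produces per-gene p-values, KEGG topology, annotation
pipelines, and correlated real-world pathway hierarchies. Passing the
recovery tests therefore shows the algorithms behave correctly under the
assumed statistical model, not that any particular biological claim is
reproduced.

## Problem sizes and known limitations

The validation suites run at sizes chosen to make each check exact or
well-powered: the hypergeometric tail is verified against
rational-arithmetic enumeration for *every* margin with `N <= 60`
(~1.2 million values); calibration uses 200 null replicates; algorithm
cross-checks use 100 random instances each; BUM recovery uses 20 replicates
of 10^4 p-values.

Planted-module recovery depends sharply on the signal shape `a`: at
`a = 0.05` nearly every planted p-value clears the FDR-0.01 threshold and
median F1 exceeds 0.8, while at `a = 0.2` only ~17% of planted nodes can
score positive at that threshold and even an oracle p-value threshold tops
out near expected F1 0.54 — weak-signal modules are not recoverable by any
method at this FDR, a property of the model rather than of the heuristic.
Both regimes are measured and reported by the acceptance script.

Other limitations: no exact integer-programming subnetwork solver; no
edge-confidence weighting of the PPI graph; gene IDs are case-sensitive
and never normalized; the bundled reference tables carry printed counts
and p-values only, not gene memberships, so membership-dependent quantities
cannot be recomputed from them.
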