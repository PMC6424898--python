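# Methods

## Graphs, degrees, and quality measures

Networks are simple undirected weighted graphs; weights are positive
confidence or correlation scores. The weighted degree is
`d_i = Σ_j A_ij`, the total edge weight `e = ½ Σ_i d_i`. Directed
inputs are folded to undirected form by keeping the maximum weight per
unordered pair, since every downstream formula assumes a symmetric
adjacency. Ingestion rejects self-loops, non-positive weights, and
conflicting duplicate edges.

Sparsification removes edges below a threshold computed from the edge
weight sample of the network at hand: the default keeps
`w ≥ μ − kσ` with `k = 2` (population standard deviation, each edge
one observation); `μ + kσ` and a plain quantile rule are also
available. Thresholds are computed per network, never pooled.

**Modularity.** The community score
`Q(c) = (1/2e) Σ_{i≠j∈c} (A_ij − γ d_i d_j/2e)` deliberately excludes
the diagonal pair `i = j`. Relative to the standard Newman form this
adds `γ Σ_{i∈c} d_i²/(2e)²` per community; summed over a *total*
partition the correction is a constant of the graph, so partition
rankings — and therefore Louvain optima — are unchanged, while
single-community scores differ (e.g. a d-regular graph scored as one
community gives `1/n`, not 0). Single-community scores always
normalize by `2e` of the *whole* graph, including during seed
expansion; normalizing by the induced subgraph would make every prefix
score incomparable across sizes.

**Conductance** uses the community volume (sum of member degrees) in
the denominator: `φ(c) = cut(c)/min(vol(c), vol(c̄))`, 0 for an
uncut community, undefined (error) for a module of isolated nodes.
**CEIL** instead uses the intra-community edge weight `W_int`:
internal score `W_int/C(n_c,2)` (0 for singletons), external score
`W_int/(W_int + cut)`, CEIL = product. Using volume in CEIL would
push clique scores above 1. The per-node **core score** is
outgoing/internal edge weight; a node with internal weight 0 scores
+∞ so that core extraction prunes it first.

All four measures are verified against an independent double-loop
evaluation on every module of every graph with at most 7 nodes (the
graph atlas, ~142 000 modules) to 1e-12.

## Partitioners

*Louvain* delegates to `networkx.community.louvain_communities`; the
"resistance" parameter is its resolution multiplier γ on the null
term, the only standard one-parameter family matching the documented
range [0.1, 1] and its module-size effect. Runs are deterministic
given the seed.

*MCL* adds self-loops of weight 1, column-normalizes, and alternates
expansion (matrix squaring) with inflation (elementwise power,
pruning of entries < 1e-8, renormalization) until the matrix change
drops below 1e-8 or 200 iterations. Clusters are the connected
components of the converged nonzero pattern; overlapping attractors
resolve to the lowest cluster id. Columns remain stochastic to 1e-9
after every inflation.

*CEIL clustering* greedily maximizes the size-weighted network score
`Σ_c (n_c/n)·CEIL(c)` by single-node moves from a singleton start,
sweeping nodes in sorted order until no move improves the objective;
it has no hyperparameter. On two disjoint K4s the greedy optimum
matches exhaustive search over all 4140 partitions of 8 nodes. No
aggregation phase is used; at the scales this package targets the
local-moving pass suffices, and determinism is preserved.

## Core-module frameworks

**Consensus.** Each node carries a vector of r community labels, one
per base clustering. With `a` agreements, the default similarity is
the matching fraction `a/r`; linking pairs with similarity > 0.5 then
implements a majority vote over base clusterings, the standard
consensus-clustering rule. The stricter Jaccard form `a/(2r−a)` on
clustering-index-qualified labels is available as an option, but it
lets a single dissenting fine-grained base clustering veto every link
when r ≤ 3 (a = r−1 gives at most 0.5, excluded by the strict
threshold), which in practice collapses the consensus graph whenever
MCL or CEIL fragments a sparse community; the majority form is
therefore the default. Both forms equal 1 iff two nodes co-occur in
every base clustering. Consensus edges are weighted by the similarity
and clustered with Louvain at resistance 1.0; nodes isolated in the
consensus network stay singletons.

**Ensemble** runs a set of base clusterers (default: Louvain at
resistances 0.1–1.0, MCL at inflations 2–9, CEIL) and clusters their
consensus. **Perturbation** clusters 100 copies of the network, each
with ⌊1% of edges⌋ dropped uniformly at random, using Louvain at
resistance 0.1 per copy, and takes the same consensus. Edge drops
ignore weights.

**Reclustering** repeatedly splits any module above 100 nodes by
running Louvain on its induced subgraph; a module the sub-clusterer
returns whole is marked unsplittable and kept. The procedure only
refines — nodes from different input modules are never merged.
**Min-outgoing cores** leave modules of ≤ 100 nodes untouched and
otherwise keep the 60 nodes of lowest core score (ties: higher
internal weight, then node id); 60 matches the empirically typical
disease-module size, and both counts are configurable.

## Seed selection and PPR expansion

Disease seeds are genes below a GWAS p-value cutoff (1e-4 by default,
1e-6 as the strict variant) in *any* trait, intersected with the
graph. Unsupervised alternatives: top-k HITS hub scores (power
iteration to 1e-10; on an undirected graph hubs equal authorities),
and spread hubs — greedily take the highest-weighted-degree unmarked
node and mark its closed neighborhood, yielding high-degree seeds
with disjoint neighborhoods.

Personalized PageRank is computed by the local push procedure: unit
residual mass starts at the seed; a push at `u` moves `α·r_u` to the
score and spreads `(1−α)·r_u` over neighbors proportionally to edge
weight, until every residual satisfies `r_u < ε·d_u`. The invariant
`Σ scores + Σ residuals = 1` holds throughout, and converged scores
are push-order independent (checked FIFO vs LIFO to 1e-6, and against
dense personalized PageRank). The teleport α = 0.85 and ε = 1e-5 are
conventional defaults — neither is dictated by the method — and are
echoed in run configs.

Expansion ranks candidates by degree-normalized PPR score (`p_u/d_u`,
the sweep-cut ordering; raw scores optional), grows the module one
node at a time to at most 100 members, records the single-community
modularity of every prefix, and returns the best prefix of at least
3 members (the DREAM module-size floor). Seeds whose reachable
neighborhood cannot form a 3-node module are rejected and logged.
Identical modules from different seeds are deduplicated.

## Overlap resolution

A cover's single-assignment nodes form the base communities; nodes
with ≥ 2 labels form the overlap. Three assignment rules:

- *random*: uniform among the node's own candidate modules (restricting
  to candidates keeps modules local; a global-random variant exists);
- *conductance*: each overlap node independently joins the candidate
  whose conductance **after inclusion** is smallest (before-inclusion
  scores would not depend on the node at all);
- *iterative*: sequential assignment in lexicographic order with
  community updates after every placement, followed by reassignment
  phases (extract each overlap node, re-place it by the same rule)
  until a phase moves nothing, or 50 phases.

On the default overlapping benchmark the iterative rule converges in
2–3 phases and convergence implies 1-stability (a full no-move pass is
exactly the stability check). A caveat: minimum-conductance
best-response is not a potential game, and joint placements with no
fixed point exist — observed on one 4×20 draw, where enumerating all
placements of the six overlap nodes shows *no* 1-stable configuration,
so the phase loop cycles and returns its current state with a
non-convergence warning. There is no convergence guarantee, only
typical behavior.

## Enrichment

Module-trait enrichment combines member-gene p-values by Fisher's
method: `−2 Σ ln p` referred to χ² with 2k degrees of freedom, where
k counts *all* module members — genes missing from the score table
are imputed p = 1 (conservative: they contribute degrees of freedom
but no signal). Benjamini-Hochberg runs across all (module, trait)
pairs; pairs with q ≤ FDR (default 5%) are flagged, and a module is
enriched if any trait flags it. This scorer is a deliberate
lightweight substitute for SNP-level pathway tools (no LD correction,
no gene fusion); externally computed calls can be wrapped in
`EnrichmentResult` instead. Under a uniform null (200 modules × 5
traits) the flag rate stays within 0.05 + 2 binomial SE; a module of
20 genes with Beta(0.1, 1) p-values is detected with power ≥ 0.9.

The comorbidity network increments a trait-pair count for every
module enriched in both traits, then keeps the top ⌈f·|edges|⌉ edges
by count (default f = 0.5), retaining all edges tied with the cutoff.

## Synthetic benchmarks

`planted_partition(sizes, p_in, p_out, seed)` draws independent
Bernoulli edges (within-block `p_in = 0.3`, between `p_out = 0.01` by
default) with confidence-like weights: Uniform(0.6, 1) within blocks,
Uniform(0.1, 0.5) between. Weighted edges are the default so the
weighted code paths (degrees, cuts, volumes) are always exercised.
`overlapping_benchmark` additionally wires the last `n` nodes of each
block into the next block at `p_in`, making them true members of both
modules. The default benchmark is 4 blocks of 25; the clustering
recovery experiments use 4 blocks of 20.

`synth_gwas` assigns each trait a set of causal truth modules (default:
trait t → block t); causal genes draw p ~ Beta(a, 1) with a = 0.1
(CDF `x^a`, so P(p < 1e-4) ≈ 0.40 — roughly 10 seeds per causal
25-node block), all other cells Uniform(0, 1). Beta(a, 1) was chosen
for its closed-form calibration; `a` is the single effect-size knob.

What the generator does *not* emulate: scale-free degree structure,
degree-corrected blocks, correlated traits, LD structure between gene
scores, and the million-edge scale of real interactomes. Passing
recovery tests therefore demonstrates correctness of the machinery
under clean planted structure, not performance on real networks.

## Experiment sizes and numerical choices

Recovery experiments use 20 replicate benchmark draws (clustering) or
10 (seed expansion and subsampling); enrichment calibration uses 200
modules × 5 traits and 30 power replicates. These sizes give binomial
standard errors small enough for the stated thresholds while keeping
each experiment in seconds. Tie-breaks are deterministic everywhere
(lexicographic node order, lowest community label); every stochastic
component takes an explicit seed, and identical configs reproduce
byte-identical outputs.

Known limitations, measured on the default conditions: Louvain at
resistance 0.1 prefers to merge a weakly separated block pair in
roughly a quarter of 4×20 benchmark draws (the between-block weight
exceeds the γ = 0.1 null penalty); since the merge then persists in
nearly all edge-dropped copies, perturbation consensus — which uses
resistance 0.1 per copy by design — inherits it, recovering the
planted partition at ARI ≥ 0.9 in about 15 of 20 draws. It does
rescue draws where the merge is fragile under edge deletion. At
resistances ≥ 0.5 the same graphs are recovered exactly.
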