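# coremod

Core disease-module identification in weighted biological networks.

Complex-disease genes cluster in the interactome: groups of densely
interacting genes ("modules") tend to share function, and a module whose
genes carry strong GWAS association signal for a trait is a candidate
*disease module*. Off-the-shelf non-overlapping community detection
finds a few giant communities in protein-interaction, co-expression, or
homology networks; these are too large and too unspecific to be
disease-relevant. `coremod` implements a toolkit for extracting small,
structurally strong **core modules** instead, and for growing
overlapping modules around disease-associated **seed genes**.

## What is in the box

**Quality measures** (`coremod.quality`) for a community *c* in a
weighted graph with adjacency *A*, weighted degrees *d_i* and total edge
weight *e*:

- modularity `Q(c) = (1/2e) Σ_{i≠j∈c} (A_ij − γ d_i d_j / 2e)` (the
  diagonal pair *i = j* is excluded; γ is the resolution/"resistance"),
- conductance `φ(c) = cut(c) / min(vol(c), vol(c̄))` — lower is better,
- the CEIL score: internal density `W_int / C(n_c, 2)` times
  separability `W_int / (W_int + cut)`,
- per-node core score `outgoing(n) / internal(n)` — lower ranks better.

**Baseline partitioners** (`coremod.partitioners`), as scikit-learn
style clusterers over `networkx` graphs: `LouvainClustering`
(modularity maximization with a resistance parameter),
`MCLClustering` (Markov clustering: expansion/inflation of the flow
matrix), `CEILClustering` (local moving on the size-weighted CEIL
objective).

**Core-module frameworks** (`coremod.coremods`):
`EnsembleClustering` (majority consensus across heterogeneous base
clusterings), `PerturbationClustering` (consensus across randomly
edge-dropped network copies), `recluster_large` (iterative splitting of
oversized modules), and `min_outgoing_core` (keep the 60 best
core-scored nodes of a module larger than 100).

**Seed expansion** (`coremod.seedexp`): disease seeds from GWAS
gene-score tables (p < 1e-4 or 1e-6 in any trait), unsupervised seeds
by HITS or spread hubs, approximate personalized PageRank by local
push, and `PPRSeedExpander`, which grows each seed's PPR-ranked
neighborhood one node at a time (up to 100) and keeps the prefix of
maximal single-community modularity.

**Overlap resolution and evaluation** (`coremod.overlaps`):
overlapping-to-non-overlapping assignment (random, one-shot minimum
conductance, or iterative minimum conductance with reassignment
phases), LCC clusterability scoring, module-trait enrichment (Fisher's
method + Benjamini-Hochberg at 5% FDR — a lightweight stand-in for
SNP-level pathway scorers), hit ratios and method scores, and
comorbidity networks linking traits co-enriched in the same modules.

**Synthetic benchmarks** (`coremod.synthgen`): weighted planted
partitions (optionally with designated overlap nodes between adjacent
blocks) and synthetic GWAS tables whose causal genes draw
p ~ Beta(a, 1), so the full pipeline is testable without any download.

## Worked example

```python
from coremod import synthgen, seedexp, overlaps, metrics

bench = synthgen.planted_partition([25]*4, p_in=0.3, p_out=0.01, seed=7)
cfg = synthgen.SynthGWASConfig(n_traits=3, seed=7)
scores = synthgen.synth_gwas(bench, cfg)            # gene x trait p-values

seeds = seedexp.disease_seeds(scores, bench.graph, cutoff=1e-4)
cover, seed_map = seedexp.expand_all(bench.graph, seeds.nodes)
enr = overlaps.enrich_modules(cover, scores, fdr=0.05)
part, phases, converged = overlaps.assign_iterative(bench.graph, cover)
```

Output for this run:

```
seeds: 34 genes below 1e-4 in some trait
expanded modules: 25 (deduplicated)
enriched modules: 25 of 25
overlap resolution: converged=True in 4 phases
recovered causal modules (F1>=0.8): 1.00
module 0: size 27, modularity 0.140, conductance 0.173
```

34 of the 100 genes pass the genome-wide threshold in at least one of
the three traits (the causal blocks plant Beta(0.1, 1) p-values, so
roughly 40% of causal genes pass). Expanding each seed and
deduplicating identical modules leaves 25 overlapping modules; all are
enriched at 5% FDR, and every planted causal block is recovered at
F1 ≥ 0.8. Iterative conductance assignment turns the cover into a
partition in a handful of phases.

The same pipeline is available from the shell:

```sh
coremod synth --blocks 4 --block-size 25 --traits 3 --seed 7 --out bench/
coremod expand --graph bench/network.tsv --seeds-from pvalues \
    --gene-scores bench/gene_scores.tsv --pvalue-cutoff 1e-4 --out mods.tsv
coremod eval --graph bench/network.tsv --modules mods.tsv \
    --gene-scores bench/gene_scores.tsv --out report.tsv
```

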