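"""Synthetic planted-partition benchmarks and synthetic GWAS gene scores.

The generator emulates, at toy scale, the heterogeneity of weighted
biological interaction networks: blocks of densely wired nodes
(within-block edge probability ``p_in``, confidence-like weights drawn
high) sparsely connected to the rest (``p_out``, low weights), with an
optional designated overlap between adjacent blocks.  Gene-score tables
mirror GWAS gene p-values: genes in a trait's causal modules draw
p ~ Beta(a, 1) (CDF x^a, stochastically small for a < 1); everything
else is Uniform(0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PlantedBenchmark",
    "SynthGWASConfig",
    "planted_partition",
    "overlapping_benchmark",
    "synth_gwas",
]


@dataclass
class PlantedBenchmark:
    """A generated network with its ground truth.

    truth is a cover (label -> member set); for non-overlapping
    benchmarks every node carries exactly one label and
    ``truth_partition`` gives the node -> label view.
    """

    graph: nx.Graph
    truth: dict[int, set[str]]
    config: dict

    @property
    def truth_partition(self) -> dict[str, int]:
        part: dict[str, int] = {}
        for label, members in self.truth.items():
            for v in members:
                if v in part:
                    raise ValueError("truth is a cover, not a partition")
                part[v] = label
        return part


@dataclass
class SynthGWASConfig:
    """Synthetic GWAS settings.

    n_traits: number of trait columns; causal_modules maps trait name ->
    truth-module labels (default: trait t is causal for block t modulo
    the number of blocks); a: Beta(a, 1) shape of causal p-values
    (smaller = stronger signal); background cells are Uniform(0, 1).
    """

    n_traits: int = 3
    causal_modules: dict[str, list[int]] | None = None
    a: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_traits < 1:
            raise ValueError("need at least one trait")
        if not 0 < self.a < 1:
            raise ValueError("a must lie in (0, 1) so causal p-values are small")

    def resolve_causal(self, labels: Sequence[int]) -> dict[str, list[int]]:
        if self.causal_modules is not None:
            return self.causal_modules
        labels = sorted(labels)
        return {f"trait_{t}": [labels[t % len(labels)]] for t in range(self.n_traits)}


def _default_weights(rng: np.random.Generator, n: int, within: bool) -> np.ndarray:
    # confidence-score semantics: strong within-block, weak between
    return rng.uniform(0.6, 1.0, n) if within else rng.uniform(0.1, 0.5, n)


def planted_partition(sizes: Sequence[int], p_in: float = 0.3, p_out: float = 0.01,
                      weight_law: Callable | None = None, seed: int = 0
                      ) -> PlantedBenchmark:
    """Weighted planted-partition graph with independent Bernoulli edges.

    ``sizes`` are the block sizes (each >= 3); node ids are zero-padded
    strings ``g000, g001, ...`` assigned block by block.  Edges appear
    with probability ``p_in`` within a block and ``p_out`` between;
    weights come from ``weight_law(rng, n, within)`` (default:
    Uniform(0.6, 1) within, Uniform(0.1, 0.5) between).
    """
    if p_in <= p_out:
        raise ValueError("planting requires p_in > p_out")
    if p_out < 0:
        raise ValueError("p_out must be >= 0")
    if any(s < 3 for s in sizes):
        raise ValueError("block sizes must be >= 3")
    weight_law = weight_law or _default_weights
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    width = max(3, len(str(n - 1)))
    names = [f"g{i:0{width}d}" for i in range(n)]
    block_of = np.repeat(np.arange(len(sizes)), sizes)
    g = nx.Graph()
    g.add_nodes_from(names)
    iu, ju = np.triu_indices(n, k=1)
    within = block_of[iu] == block_of[ju]
    p = np.where(within, p_in, p_out)
    keep = rng.random(len(iu)) < p
    w = np.empty(keep.sum())
    kw = within[keep]
    w[kw] = weight_law(rng, int(kw.sum()), True)
    w[~kw] = weight_law(rng, int((~kw).sum()), False)
    for (i, j, wt) in zip(iu[keep], ju[keep], w):
        g.add_edge(names[i], names[j], weight=float(wt))
    truth = {b: {names[i] for i in range(n) if block_of[i] == b}
             for b in range(len(sizes))}
    config = dict(sizes=list(sizes), p_in=p_in, p_out=p_out, seed=seed,
                  overlap=0)
    return PlantedBenchmark(g, truth, config)


def overlapping_benchmark(sizes: Sequence[int], p_in: float = 0.3,
                          p_out: float = 0.01, n_overlap_per_pair: int = 2,
                          weight_law: Callable | None = None, seed: int = 0
                          ) -> PlantedBenchmark:
    """Planted blocks where adjacent block pairs share designated nodes.

    The last ``n_overlap_per_pair`` nodes of block b additionally join
    block b+1: they are wired into block b+1 with probability ``p_in``
    (within-style weights) and appear in both truth modules.
    """
    if n_overlap_per_pair < 0:
        raise ValueError("n_overlap_per_pair must be >= 0")
    if n_overlap_per_pair > min(sizes):
        raise ValueError("overlap exceeds the smallest block size")
    bench = planted_partition(sizes, p_in, p_out, weight_law, seed)
    if n_overlap_per_pair == 0:
        return bench
    weight_law = weight_law or _default_weights
    rng = np.random.default_rng(seed + 1)
    g = bench.graph
    truth = {b: set(m) for b, m in bench.truth.items()}
    blocks = sorted(truth)
    for b in blocks[:-1]:
        shared = sorted(bench.truth[b])[-n_overlap_per_pair:]
        targets = sorted(bench.truth[b + 1])
        for v in shared:
            truth[b + 1].add(v)
            hit = rng.random(len(targets)) < p_in
            w = weight_law(rng, int(hit.sum()), True)
            for t, wt in zip(np.array(targets)[hit], w):
                if not g.has_edge(v, t):
                    g.add_edge(v, str(t), weight=float(wt))
    config = dict(bench.config, overlap=n_overlap_per_pair)
    return PlantedBenchmark(g, truth, config)


def synth_gwas(bench: PlantedBenchmark, cfg: SynthGWASConfig | None = None
               ) -> pd.DataFrame:
    """Gene x trait p-value table with planted causal modules.

    Genes in a trait's causal truth modules draw p ~ Beta(a, 1); all
    other cells are Uniform(0, 1).  Fully reproducible from cfg.seed.
    """
    cfg = cfg or SynthGWASConfig()
    causal = cfg.resolve_causal(list(bench.truth))
    unknown = {m for mods in causal.values() for m in mods} - set(bench.truth)
    if unknown:
        raise ValueError(f"causal modules not in truth: {sorted(unknown)}")
    rng = np.random.default_rng(cfg.seed)
    genes = sorted(bench.graph.nodes)
    traits = list(causal)
    table = pd.DataFrame(rng.uniform(0.0, 1.0, (len(genes), len(traits))),
                         index=genes, columns=traits)
    for trait, mods in causal.items():
        members = sorted(set().union(*(bench.truth[m] for m in mods)))
        # Beta(a, 1) via inverse CDF x^a: U^(1/a)
        table.loc[members, trait] = rng.uniform(0.0, 1.0, len(members)) ** (1.0 / cfg.a)
    return table.clip(lower=np.nextafter(0.0, 1.0))  # p-values in (0, 1]
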