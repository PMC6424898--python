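"""Core-module identification frameworks.

Four refinement strategies for extracting small, structurally strong
("core") modules from weighted biological networks:

* **Ensemble clustering** — run several base partitioners (Louvain at
  multiple resistances, MCL at multiple inflations, CEIL), build a
  consensus network from pairwise Jaccard similarity of per-node
  assignment vectors, and cluster the consensus with Louvain.
* **Perturbation clustering** — cluster many randomly edge-dropped
  copies of the network and take the same consensus, keeping only
  modules persistent under noise.
* **Large-module reclustering** — iteratively re-partition any module
  larger than a size cap by running Louvain on its induced subgraph.
* **Min-outgoing cores** — inside an oversized module, rank nodes by
  core score (outgoing/internal edge-weight ratio) and keep the
  best-ranked fixed-size core.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from . import quality
from .partitioners import (
    CEILClustering,
    LouvainClustering,
    MCLClustering,
    _GraphClusterer,
    louvain_modularity,
)

logger = logging.getLogger(__name__)

__all__ = [
    "consensus_network",
    "default_base_estimators",
    "EnsembleClustering",
    "PerturbationClustering",
    "ensemble_cluster",
    "perturbation_cluster",
    "recluster_large",
    "min_outgoing_core",
]


def consensus_network(partitions: Sequence[Mapping[str, int]],
                      threshold: float = 0.5,
                      similarity: str = "simple") -> nx.Graph:
    """Consensus graph from the pairwise Jaccard similarity of assignments.

    Each node carries a vector of r community labels, one per base
    clustering.  With ``a`` agreements out of r clusterings,
    ``similarity="simple"`` (the default) scores the matching fraction
    a / r, so the 0.5 threshold implements a majority vote over base
    clusterings — the standard consensus-clustering rule.
    ``similarity="qualified"`` scores the Jaccard form a / (2r - a) on
    the clustering-index-qualified label sets (labels from different
    clusterings share no namespace); it is stricter — at small r a
    single dissenting clustering can veto a pair.  Either form equals 1
    iff the two nodes co-occur in every clustering.  Node pairs with
    similarity strictly above ``threshold`` are linked, weighted by the
    similarity.
    """
    r = len(partitions)
    if r == 0:
        raise ValueError("need at least one base partition")
    if similarity not in {"qualified", "simple"}:
        raise ValueError(f"unknown similarity form: {similarity!r}")
    nodes = set().union(*(set(p) for p in partitions))
    agreements: dict[tuple[str, str], int] = {}
    for p in partitions:
        groups: dict[int, list[str]] = {}
        for node, label in p.items():
            groups.setdefault(label, []).append(node)
        for members in groups.values():
            members.sort()
            for u, v in itertools.combinations(members, 2):
                agreements[(u, v)] = agreements.get((u, v), 0) + 1
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for (u, v), a in agreements.items():
        sim = a / (2 * r - a) if similarity == "qualified" else a / r
        if sim > threshold:
            g.add_edge(u, v, weight=sim)
    return g


def default_base_estimators() -> list[_GraphClusterer]:
    """The full baseline grid: Louvain R in 0.1..1.0, MCL I in 2..9, CEIL."""
    louvains = [LouvainClustering(resistance=round(0.1 * i, 1)) for i in range(1, 11)]
    mcls = [MCLClustering(inflation=float(i)) for i in range(2, 10)]
    return [*louvains, *mcls, CEILClustering()]


class EnsembleClustering(_GraphClusterer):
    """Consensus over heterogeneous base partitioners.

    Runs every base estimator on the graph, links node pairs whose
    assignment vectors are Jaccard-similar above ``threshold`` into a
    consensus network, and clusters the (similarity-weighted) consensus
    with Louvain.  Nodes isolated in the consensus network stay
    singletons.

    Parameters
    ----------
    base_estimators : list of clusterers or None
        Defaults to the full baseline grid (Louvain at ten resistances,
        MCL at eight inflations, CEIL).
    threshold : float, default 0.5
        Similarity cutoff for consensus edges (strict).
    similarity : {"simple", "qualified"}
        Majority-vote agreement fraction (default) or the stricter
        Jaccard form on clustering-index-qualified labels.
    consensus_resistance : float, default 1.0
        Louvain resistance used on the consensus network.
    """

    def __init__(self, base_estimators=None, threshold: float = 0.5,
                 similarity: str = "simple", consensus_resistance: float = 1.0,
                 random_state: int = 0):
        self.base_estimators = base_estimators
        self.threshold = threshold
        self.similarity = similarity
        self.consensus_resistance = consensus_resistance
        self.random_state = random_state

    def _base(self):
        if self.base_estimators is None:
            return default_base_estimators()
        if not self.base_estimators:
            raise ValueError("base_estimators must be non-empty")
        return self.base_estimators

    def _cluster(self, g: nx.Graph) -> list[set[str]]:
        from sklearn.base import clone

        base_partitions = [clone(est).fit(g).partition_ for est in self._base()]
        consensus = consensus_network(base_partitions, self.threshold, self.similarity)
        self.consensus_network_ = consensus
        return _louvain_with_singletons(consensus, self.consensus_resistance,
                                        self.random_state)


def _louvain_with_singletons(consensus: nx.Graph, resistance: float,
                             random_state: int) -> list[set[str]]:
    """Louvain on the non-isolated part of a consensus graph; isolates
    become singleton communities."""
    isolates = [v for v in consensus.nodes if consensus.degree(v) == 0]
    core = consensus.subgraph([v for v in consensus.nodes if consensus.degree(v) > 0])
    modules: list[set[str]] = []
    if core.number_of_nodes() > 0:
        part = louvain_modularity(core, resistance=resistance, random_state=random_state)
        modules.extend(quality.partition_to_modules(part))
    modules.extend({v} for v in isolates)
    return modules


class PerturbationClustering(_GraphClusterer):
    """Modules persistent across randomly perturbed copies of the network.

    Each of ``n_iter`` perturbed copies drops ``floor(drop_frac * |E|)``
    edges uniformly at random and is clustered with Louvain at the given
    resistance.  The per-copy partitions are combined through the same
    Jaccard consensus as the ensemble, and the consensus network is
    clustered with Louvain.
    """

    def __init__(self, drop_frac: float = 0.01, n_iter: int = 100,
                 resistance: float = 0.1, threshold: float = 0.5,
                 similarity: str = "simple", consensus_resistance: float = 1.0,
                 random_state: int = 0):
        self.drop_frac = drop_frac
        self.n_iter = n_iter
        self.resistance = resistance
        self.threshold = threshold
        self.similarity = similarity
        self.consensus_resistance = consensus_resistance
        self.random_state = random_state

    def _cluster(self, g: nx.Graph) -> list[set[str]]:
        if not 0 <= self.drop_frac < 1:
            raise ValueError("drop_frac must lie in [0, 1)")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        edges = sorted(g.edges)
        if not edges:
            raise ValueError("perturbation clustering needs at least one edge")
        n_drop = math.floor(self.drop_frac * len(edges))
        if n_drop >= len(edges):
            raise ValueError("drop count equals the edge count")
        rng = np.random.default_rng(self.random_state)
        partitions = []
        for i in range(self.n_iter):
            h = g.copy()
            if n_drop:
                drop_idx = rng.choice(len(edges), size=n_drop, replace=False)
                h.remove_edges_from(edges[j] for j in drop_idx)
            seed = int(rng.integers(0, 2**31 - 1))
            partitions.append(louvain_modularity(h, resistance=self.resistance,
                                                 random_state=seed))
        if self.n_iter == 1:
            return quality.partition_to_modules(partitions[0])
        consensus = consensus_network(partitions, self.threshold, self.similarity)
        self.consensus_network_ = consensus
        return _louvain_with_singletons(consensus, self.consensus_resistance,
                                        self.random_state)


def ensemble_cluster(g: nx.Graph, base_estimators=None, **kwargs) -> dict[str, int]:
    """Ensemble-consensus partition of ``g``; node -> label mapping."""
    return EnsembleClustering(base_estimators=base_estimators, **kwargs).fit(g).partition_


def perturbation_cluster(g: nx.Graph, **kwargs) -> dict[str, int]:
    """Perturbation-consensus partition of ``g``; node -> label mapping."""
    return PerturbationClustering(**kwargs).fit(g).partition_


def recluster_large(g: nx.Graph, p: Mapping[str, int], max_size: int = 100,
                    resistance: float = 1.0, random_state: int = 0) -> dict[str, int]:
    """Iteratively split modules larger than ``max_size``.

    Oversized modules are re-clustered with Louvain on their induced
    subgraph; a module the sub-clusterer refuses to split (one community
    returned) is kept and marked unsplittable.  Never merges nodes from
    different input modules.  Labels are recompacted on return.
    """
    modules = [set(m) for m in quality.partition_to_modules(p)]
    unsplittable: set[frozenset] = set()
    while True:
        oversized = [m for m in modules
                     if len(m) > max_size and frozenset(m) not in unsplittable]
        if not oversized:
            break
        target = oversized[0]
        sub = g.subgraph(target)
        sub_part = louvain_modularity(sub, resistance=resistance,
                                      random_state=random_state)
        pieces = quality.partition_to_modules(sub_part)
        if len(pieces) <= 1:
            unsplittable.add(frozenset(target))
            logger.info("recluster_large: module of size %d is unsplittable", len(target))
            continue
        modules.remove(target)
        modules.extend(pieces)
    modules.sort(key=lambda m: min(m))
    return {node: label for label, m in enumerate(modules) for node in m}


def min_outgoing_core(g: nx.Graph, module: Iterable[str], core_size: int = 60,
                      size_trigger: int = 100) -> set[str]:
    """Core of an oversized module: the ``core_size`` best-ranked nodes.

    Modules of at most ``size_trigger`` nodes are returned unchanged.
    Nodes are ranked by core score ascending (lower = more internal);
    ties go to higher internal edge weight, then lexicographic node id.
    """
    members = set(module)
    if len(members) <= size_trigger:
        return members

    def internal_weight(v: str) -> float:
        return sum(d["weight"] for u, d in g[v].items() if u in members)

    ranked = sorted(members,
                    key=lambda v: (quality.core_score(g, members, v),
                                   -internal_weight(v), v))
    return set(ranked[:core_size])
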