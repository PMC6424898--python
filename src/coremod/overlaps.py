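"""Overlap resolution, clusterability, enrichment, and comorbidity.

A *cover* (label -> member set, overlaps permitted) is converted to a
partition by first forming the base communities (nodes with a single
assignment) and then placing each overlap node by one of three rules:
random among its own candidate modules, one-shot minimum conductance, or
iterative minimum conductance with reassignment phases until no node
moves.

Module-trait enrichment uses Fisher's method over member-gene GWAS
p-values with Benjamini-Hochberg correction across all (module, trait)
pairs — a deliberately simple stand-in for SNP-level pathway scorers
such as PASCAL; externally computed enrichment calls can be supplied
instead through :class:`EnrichmentResult`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from . import netio, quality

logger = logging.getLogger(__name__)

__all__ = [
    "base_communities",
    "assign_random",
    "assign_conductance",
    "assign_iterative",
    "OverlapResolver",
    "lcc_clusterability",
    "EnrichmentResult",
    "enrich_modules",
    "hit_ratio",
    "method_score",
    "overlap_counts",
    "comorbidity_network",
]

Cover = Mapping[int, set]


def _membership(cover: Cover) -> dict[str, set[int]]:
    member: dict[str, set[int]] = {}
    for label, nodes in cover.items():
        if not nodes:
            raise ValueError(f"module {label} is empty")
        for v in nodes:
            member.setdefault(v, set()).add(label)
    return member


def base_communities(cover: Cover) -> tuple[dict[str, int], set[str]]:
    """Split a cover into base partition (single-assignment nodes) and
    the overlap node set (>= 2 assignments)."""
    if not cover:
        raise ValueError("cover is empty")
    member = _membership(cover)
    base = {v: next(iter(labels)) for v, labels in member.items() if len(labels) == 1}
    overlap = {v for v, labels in member.items() if len(labels) >= 2}
    if not base:
        raise ValueError("every node overlaps; no base community to assign into")
    return base, overlap


def _base_sets(cover: Cover) -> tuple[dict[int, set[str]], dict[str, set[int]], set[str]]:
    base, overlap = base_communities(cover)
    sets: dict[int, set[str]] = {label: set() for label in cover}
    for v, label in base.items():
        sets[label].add(v)
    member = _membership(cover)
    return sets, member, overlap


def assign_random(g: nx.Graph, cover: Cover, random_state: int = 0) -> dict[str, int]:
    """Assign each overlap node uniformly among its own candidate modules."""
    sets, member, overlap = _base_sets(cover)
    rng = np.random.default_rng(random_state)
    out = {v: next(iter(member[v])) for v in member if len(member[v]) == 1}
    for v in sorted(overlap):
        candidates = sorted(member[v])
        out[v] = int(candidates[rng.integers(len(candidates))])
    return out


def _placement_conductance(g: nx.Graph, community: set[str], node: str) -> float:
    return quality.conductance(g, community | {node})


def assign_conductance(g: nx.Graph, cover: Cover) -> dict[str, int]:
    """One-shot assignment: each overlap node goes, independently, to the
    candidate base community whose conductance after inclusion is lowest
    (ties to the lowest label).  Placements do not see each other."""
    sets, member, overlap = _base_sets(cover)
    out = {v: next(iter(member[v])) for v in member if len(member[v]) == 1}
    for v in sorted(overlap):
        best = min(sorted(member[v]),
                   key=lambda c: (_placement_conductance(g, sets[c], v), c))
        out[v] = best
    return out


def assign_iterative(g: nx.Graph, cover: Cover, max_phases: int = 50
                     ) -> tuple[dict[str, int], int, bool]:
    """Sequential minimum-conductance assignment with reassignment phases.

    Phase 1 places overlap nodes one after another (lexicographic
    order), each into the candidate community minimizing conductance
    after inclusion, updating the community before the next placement.
    Each later phase extracts every overlap node in turn and re-places
    it the same way; phases repeat until none moves or ``max_phases`` is
    reached.  Returns (partition, phases used, converged flag).
    """
    sets, member, overlap = _base_sets(cover)
    order = sorted(overlap)
    placed: dict[str, int] = {}
    # phase 1: initial sequential placement
    for v in order:
        best = min(sorted(member[v]),
                   key=lambda c: (_placement_conductance(g, sets[c], v), c))
        sets[best].add(v)
        placed[v] = best
    phases = 1
    converged = False
    while phases < max_phases:
        moved = 0
        for v in order:
            cur = placed[v]
            sets[cur].discard(v)
            best = min(sorted(member[v]),
                       key=lambda c: (_placement_conductance(g, sets[c], v), c))
            sets[best].add(v)
            if best != cur:
                moved += 1
                placed[v] = best
        phases += 1
        if moved == 0:
            converged = True
            break
    if not converged:
        logger.warning("assign_iterative: no convergence in %d phases", max_phases)
    out = {v: label for label, nodes in sets.items() for v in nodes}
    return out, phases, converged


class OverlapResolver(BaseEstimator):
    """Overlap-to-partition resolution as an estimator.

    ``fit(X, cover)`` resolves the cover on graph ``X`` with the chosen
    ``mode`` ("random", "conductance", or "iterative") and stores the
    resulting ``partition_`` plus, for the iterative mode, ``n_phases_``
    and ``converged_``.
    """

    def __init__(self, mode: str = "iterative", max_phases: int = 50,
                 random_state: int = 0):
        self.mode = mode
        self.max_phases = max_phases
        self.random_state = random_state

    def fit(self, X: nx.Graph, cover: Cover):
        if self.mode == "random":
            self.partition_ = assign_random(X, cover, self.random_state)
        elif self.mode == "conductance":
            self.partition_ = assign_conductance(X, cover)
        elif self.mode == "iterative":
            self.partition_, self.n_phases_, self.converged_ = assign_iterative(
                X, cover, self.max_phases)
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        return self

    def fit_transform(self, X: nx.Graph, cover: Cover) -> dict[str, int]:
        return self.fit(X, cover).partition_


def lcc_clusterability(g: nx.Graph, genes: Iterable[str]) -> tuple[float, float]:
    """(modularity, conductance) of the LCC of a gene set's induced subgraph.

    The LCC is scored as a single community against the whole graph.
    Raises for a single-node LCC, where conductance is not meaningful.
    """
    lcc = netio.largest_connected_component(g, genes)
    if len(lcc) < 2:
        raise ValueError("LCC has a single node; conductance undefined")
    return quality.modularity(g, lcc), quality.conductance(g, lcc)


@dataclass
class EnrichmentResult:
    """Per-(module, trait) enrichment calls at a stated FDR.

    ``table`` has columns module, trait, pvalue, qvalue, enriched.
    """

    table: pd.DataFrame
    fdr: float

    @property
    def enriched_pairs(self) -> set[tuple[int, str]]:
        sub = self.table[self.table["enriched"]]
        return set(zip(sub["module"], sub["trait"]))

    def module_enriched(self) -> dict[int, bool]:
        """Any-trait enrichment flag per module."""
        return self.table.groupby("module")["enriched"].any().to_dict()

    def traits_per_module(self) -> dict[int, set[str]]:
        sub = self.table[self.table["enriched"]]
        out: dict[int, set[str]] = {}
        for m, t in zip(sub["module"], sub["trait"]):
            out.setdefault(m, set()).add(t)
        return out

    def n_enriched(self) -> int:
        return sum(self.module_enriched().values())


def _as_cover(modules) -> dict[int, set[str]]:
    if isinstance(modules, Mapping):
        first = next(iter(modules.values()), None)
        if first is not None and isinstance(first, (set, frozenset, list, tuple)):
            return {int(k): set(v) for k, v in modules.items()}
        # node -> label partition
        cover: dict[int, set[str]] = {}
        for node, label in modules.items():
            cover.setdefault(int(label), set()).add(node)
        return cover
    return {i: set(m) for i, m in enumerate(modules)}


def enrich_modules(modules, scores: pd.DataFrame, fdr: float = 0.05) -> EnrichmentResult:
    """Fisher's-method enrichment of modules in GWAS gene scores.

    For each module and trait, member-gene p-values (genes absent from
    the table imputed p = 1) are combined as -2 sum(ln p), referred to a
    chi-square with 2k degrees of freedom; Benjamini-Hochberg is applied
    across all (module, trait) pairs and pairs with q <= fdr are flagged.
    Modules containing no scored gene are excluded with a warning.
    """
    if not 0 < fdr < 1:
        raise ValueError("fdr must lie in (0, 1)")
    cover = _as_cover(modules)
    rows = []
    scored_genes = set(scores.index)
    for label in sorted(cover):
        genes = sorted(cover[label])
        present = [gx for gx in genes if gx in scored_genes]
        if not present:
            logger.warning("enrich_modules: module %d has no scored gene; skipped",
                           label)
            continue
        sub = scores.loc[present]
        for trait in scores.columns:
            p = sub[trait].to_numpy(dtype=float)
            p = np.where(np.isnan(p), 1.0, p)
            k = len(genes)  # unscored members count as p = 1
            stat = -2.0 * np.log(np.clip(p, 1e-300, 1.0)).sum()
            pval = float(stats.chi2.sf(stat, 2 * k))
            rows.append((label, trait, pval))
    if not rows:
        raise ValueError("no module has scored genes")
    table = pd.DataFrame(rows, columns=["module", "trait", "pvalue"])
    reject, qvals, _, _ = multipletests(table["pvalue"], alpha=fdr, method="fdr_bh")
    table["qvalue"] = np.maximum(qvals, table["pvalue"])
    table["enriched"] = reject
    return EnrichmentResult(table, fdr)


def hit_ratio(n_enriched: int, n_predicted: int) -> float:
    """Fraction of predicted modules that are enriched."""
    if n_predicted <= 0:
        raise ValueError("n_predicted must be > 0")
    if not 0 <= n_enriched <= n_predicted:
        raise ValueError("need 0 <= n_enriched <= n_predicted")
    return n_enriched / n_predicted


def method_score(per_network_enriched: Iterable[int]) -> int:
    """Total enriched-module count across networks (a method's score)."""
    counts = list(per_network_enriched)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    return sum(counts)


def overlap_counts(cover: Cover) -> dict[str, int]:
    """Number of modules each node belongs to."""
    counts: dict[str, int] = {}
    for nodes in cover.values():
        for v in nodes:
            counts[v] = counts.get(v, 0) + 1
    return counts


def comorbidity_network(enr: EnrichmentResult, top_frac: float = 0.5) -> nx.Graph:
    """Trait-trait network from modules enriched for multiple traits.

    Every module enriched for >= 2 traits increments the count of each
    enriched-trait pair; the top ``ceil(top_frac * |edges|)`` edges by
    count are retained, keeping all edges tied with the cutoff count.
    Edge counts live in the ``count`` attribute.
    """
    counts: dict[tuple[str, str], int] = {}
    for traits in enr.traits_per_module().values():
        if len(traits) < 2:
            continue
        for a, b in itertools.combinations(sorted(traits), 2):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    g = nx.Graph()
    if not counts:
        logger.warning("comorbidity_network: no module enriched for >= 2 traits")
        return g
    n_keep = int(np.ceil(top_frac * len(counts)))
    ordered = sorted(counts.values(), reverse=True)
    cutoff = ordered[n_keep - 1]
    for (a, b), c in counts.items():
        if c >= cutoff:
            g.add_edge(a, b, count=c)
    return g
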