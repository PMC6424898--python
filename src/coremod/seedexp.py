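"""Seed selection and personalized-PageRank seed expansion.

Overlapping disease modules are grown around seed nodes.  Seeds come
from three sources: genes passing a GWAS p-value threshold in any trait
(disease seeds), HITS hub scores, or "spread hubs" (greedy high-degree
nodes with non-overlapping neighborhoods).  Expansion ranks the
neighborhood of a seed by approximate personalized PageRank (computed
with the local push procedure), grows a nested family of candidate
modules one node at a time, and keeps the prefix with maximal
single-community modularity.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import quality

logger = logging.getLogger(__name__)

__all__ = [
    "SeedSet",
    "ExpansionConfig",
    "disease_seeds",
    "hits_seeds",
    "spread_hub_seeds",
    "ppr",
    "expand_seed",
    "expand_all",
    "PPRSeedExpander",
]


@dataclass
class SeedSet:
    """A set of seed nodes with provenance."""

    nodes: set[str]
    provenance: str
    scores: dict[str, float] = field(default_factory=dict)

    def __iter__(self):
        return iter(sorted(self.nodes))

    def __len__(self):
        return len(self.nodes)


@dataclass
class ExpansionConfig:
    """PPR seed-expansion settings.

    alpha: teleport probability of the push recursion (mass retained at
    the current node per push); eps: residual tolerance relative to
    degree; module sizes bracket the accepted prefix.
    """

    alpha: float = 0.85
    eps: float = 1e-5
    max_size: int = 100
    min_size: int = 3
    degree_normalize: bool = True

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if not 3 <= self.min_size <= self.max_size:
            raise ValueError("need 3 <= min_size <= max_size")


def disease_seeds(scores: pd.DataFrame, g: nx.Graph, cutoff: float = 1e-4) -> SeedSet:
    """Genes present in ``g`` with p < cutoff in at least one trait.

    ``scores`` is a gene x trait table of p-values in (0, 1]; missing
    cells are ignored.  Union semantics over traits.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    passing = scores.index[(scores < cutoff).any(axis=1)]
    nodes = set(passing) & set(g.nodes)
    best = scores.min(axis=1)
    if not nodes:
        logger.warning("disease_seeds: no gene passes cutoff %g", cutoff)
    return SeedSet(nodes, f"pvalue_{cutoff:g}",
                   {n: float(best[n]) for n in nodes})


def hits_seeds(g: nx.Graph, k: int) -> SeedSet:
    """Top-k nodes by HITS hub score (power iteration to 1e-10).

    On an undirected graph hub and authority scores coincide with the
    principal eigenvector of the weighted adjacency.  Ties broken by
    lexicographically smallest node id.
    """
    nodes = sorted(g.nodes)
    if not 1 <= k <= len(nodes):
        raise ValueError(f"k must lie in [1, {len(nodes)}]")
    a = nx.to_scipy_sparse_array(g, nodelist=nodes, weight="weight", format="csr")
    x = np.ones(len(nodes)) / len(nodes)
    for _ in range(10_000):
        y = a @ x
        norm = np.abs(y).sum()
        if norm == 0:
            y = x  # edgeless graph: uniform scores
            break
        y = y / norm
        if np.abs(y - x).max() < 1e-10:
            x = y
            break
        x = y
    else:  # pragma: no cover
        x = y
    scores = dict(zip(nodes, x))
    top = sorted(nodes, key=lambda v: (-scores[v], v))[:k]
    return SeedSet(set(top), "hits", {v: float(scores[v]) for v in top})


def spread_hub_seeds(g: nx.Graph, k: int) -> SeedSet:
    """Greedy high-degree seeds with mutually disjoint neighborhoods.

    Repeatedly take the highest weighted-degree unmarked node, then mark
    it and its neighbors.  Stops at k seeds or when every node is marked
    (fewer seeds, with a warning).  Ties by lexicographic id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(g.nodes, key=lambda v: (-g.degree(v, weight="weight"), v))
    marked: set[str] = set()
    seeds: list[str] = []
    for v in order:
        if len(seeds) == k:
            break
        if v in marked:
            continue
        seeds.append(v)
        marked.add(v)
        marked.update(g[v])
    if len(seeds) < k:
        logger.warning("spread_hub_seeds: only %d of %d seeds attainable",
                       len(seeds), k)
    return SeedSet(set(seeds), "spread_hub",
                   {v: float(g.degree(v, weight="weight")) for v in seeds})


@dataclass
class PPRVector:
    """Approximate personalized PageRank from a single seed.

    scores: per-node PPR mass; residual: unpushed mass; the push
    procedure maintains sum(scores) + sum(residual) = 1 and terminates
    when every residual_u < eps * d_u.
    """

    scores: dict[str, float]
    residual: dict[str, float]
    alpha: float
    eps: float


def ppr(g: nx.Graph, seed: str, alpha: float = 0.85, eps: float = 1e-5,
        schedule: str = "fifo") -> PPRVector:
    """Approximate PPR by repeated local push operations.

    Starting from unit residual mass at ``seed``, a push at u moves
    ``alpha * r_u`` into u's score and spreads ``(1 - alpha) * r_u``
    over u's neighbors proportionally to edge weight, until every
    residual is below ``eps`` times the node's weighted degree.  The
    converged scores are independent of the push order; ``schedule``
    ("fifo" or "lifo") only changes the processing order.
    """
    if seed not in g:
        raise ValueError(f"seed {seed!r} not in graph")
    degree = {seed: g.degree(seed, weight="weight")}
    p: dict[str, float] = {}
    r: dict[str, float] = {seed: 1.0}
    queue: deque[str] = deque([seed])
    in_queue = {seed}

    def pushable(u: str) -> bool:
        d = degree.setdefault(u, g.degree(u, weight="weight"))
        return r.get(u, 0.0) >= eps * d and r.get(u, 0.0) > 0

    while queue:
        u = queue.popleft() if schedule == "fifo" else queue.pop()
        in_queue.discard(u)
        ru = r.get(u, 0.0)
        du = degree.setdefault(u, g.degree(u, weight="weight"))
        if du == 0:
            # isolated node: all mass stays put
            p[u] = p.get(u, 0.0) + ru
            r[u] = 0.0
            continue
        if ru < eps * du:
            continue
        p[u] = p.get(u, 0.0) + alpha * ru
        r[u] = 0.0
        spread = (1.0 - alpha) * ru
        for v, data in g[u].items():
            r[v] = r.get(v, 0.0) + spread * data["weight"] / du
            if v not in in_queue and pushable(v):
                queue.append(v)
                in_queue.add(v)
        if pushable(u) and u not in in_queue:  # pragma: no cover
            queue.append(u)
            in_queue.add(u)
    return PPRVector(p, {k: v for k, v in r.items() if v > 0}, alpha, eps)


@dataclass
class ExpandedModule:
    """Result of one seed expansion."""

    seed: str
    members: frozenset[str]
    modularity: float


def expand_seed(g: nx.Graph, seed: str, cfg: ExpansionConfig | None = None
                ) -> ExpandedModule | None:
    """Grow a module around ``seed`` to the modularity-maximal PPR prefix.

    Non-seed nodes with positive PPR score are ranked descending by
    (optionally degree-normalized) score and appended one at a time up
    to ``max_size`` members; the prefix of size >= ``min_size`` with the
    highest single-community modularity is returned.  Returns ``None``
    (rejected) when no prefix reaches the minimum size.
    """
    cfg = cfg or ExpansionConfig()
    vec = ppr(g, seed, alpha=cfg.alpha, eps=cfg.eps)
    candidates = [v for v in vec.scores if v != seed]

    def rank_key(v: str) -> tuple[float, str]:
        s = vec.scores[v]
        if cfg.degree_normalize:
            d = g.degree(v, weight="weight")
            s = s / d if d > 0 else 0.0
        return (-s, v)

    candidates.sort(key=rank_key)
    candidates = candidates[: cfg.max_size - 1]
    if len(candidates) + 1 < cfg.min_size:
        logger.info("expand_seed: seed %r rejected (neighborhood too small)", seed)
        return None

    two_e = 2.0 * g.size(weight="weight")
    members = [seed]
    member_set = {seed}
    d_seed = g.degree(seed, weight="weight")
    w_int = 0.0
    vol = d_seed
    sum_sq = d_seed * d_seed
    best = None
    for v in candidates:
        dv = g.degree(v, weight="weight")
        w_int += sum(d["weight"] for u, d in g[v].items() if u in member_set)
        vol += dv
        sum_sq += dv * dv
        members.append(v)
        member_set.add(v)
        if len(members) >= cfg.min_size:
            q = (2.0 * w_int - (vol * vol - sum_sq) / two_e) / two_e
            if best is None or q > best[0] + 1e-15:
                best = (q, len(members))
    if best is None:  # pragma: no cover
        return None
    q, size = best
    return ExpandedModule(seed, frozenset(members[:size]), q)


def expand_all(g: nx.Graph, seeds: Iterable[str], cfg: ExpansionConfig | None = None
               ) -> tuple[dict[int, set[str]], dict[str, int | None]]:
    """Expand every seed; return a cover and the seed -> module-label map.

    Modules with identical node sets are deduplicated.  Rejected seeds
    map to ``None``.
    """
    cfg = cfg or ExpansionConfig()
    seed_list = sorted(set(seeds))
    if not seed_list:
        raise ValueError("seeds must be non-empty")
    cover: dict[int, set[str]] = {}
    label_of: dict[frozenset[str], int] = {}
    seed_map: dict[str, int | None] = {}
    for seed in seed_list:
        res = expand_seed(g, seed, cfg)
        if res is None:
            seed_map[seed] = None
            continue
        if res.members not in label_of:
            label = len(label_of)
            label_of[res.members] = label
            cover[label] = set(res.members)
        seed_map[seed] = label_of[res.members]
    if not cover:
        logger.warning("expand_all: every seed was rejected")
    return cover, seed_map


class PPRSeedExpander(BaseEstimator):
    """Overlapping module detection by PPR seed expansion.

    ``fit(X, seeds)`` expands every seed on the graph ``X`` and stores
    the deduplicated cover.  Follows the scikit-learn estimator
    protocol for parameter handling; the fitted attributes are
    ``cover_`` (label -> member set), ``modules_`` (list of member
    sets), ``seed_modules_`` (seed -> label or None) and
    ``rejected_seeds_``.
    """

    def __init__(self, alpha: float = 0.85, eps: float = 1e-5,
                 max_size: int = 100, min_size: int = 3,
                 degree_normalize: bool = True):
        self.alpha = alpha
        self.eps = eps
        self.max_size = max_size
        self.min_size = min_size
        self.degree_normalize = degree_normalize

    def _config(self) -> ExpansionConfig:
        return ExpansionConfig(alpha=self.alpha, eps=self.eps,
                               max_size=self.max_size, min_size=self.min_size,
                               degree_normalize=self.degree_normalize)

    def fit(self, X: nx.Graph, seeds: Iterable[str]):
        if isinstance(seeds, SeedSet):
            seeds = seeds.nodes
        cover, seed_map = expand_all(X, seeds, self._config())
        self.cover_ = cover
        self.modules_ = [cover[k] for k in sorted(cover)]
        self.seed_modules_ = seed_map
        self.rejected_seeds_ = sorted(s for s, m in seed_map.items() if m is None)
        return self

    def fit_transform(self, X: nx.Graph, seeds: Iterable[str]) -> list[set[str]]:
        return self.fit(X, seeds).modules_
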