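"""Baseline non-overlapping partitioners as sklearn-style estimators.

Each clusterer follows the scikit-learn clustering protocol: ``fit(X)``
takes a :class:`networkx.Graph` (in place of a feature matrix), and the
fitted object exposes ``labels_`` aligned with ``nodes_`` (nodes in
sorted order), plus a ``partition_`` dict and ``modules_`` list.
Module-level functions (:func:`louvain_modularity`, :func:`mcl`,
:func:`ceil_cluster`) are thin wrappers returning the partition dict.
"""

from __future__ import annotations

import logging
from typing import Iterable

import networkx as nx
import numpy as np
import scipy.sparse as sp
from networkx.algorithms.community import louvain_communities
from sklearn.base import BaseEstimator, ClusterMixin

from . import quality

logger = logging.getLogger(__name__)

__all__ = [
    "LouvainClustering",
    "MCLClustering",
    "CEILClustering",
    "louvain_modularity",
    "mcl",
    "ceil_cluster",
]


def _canonical_partition(modules: Iterable[Iterable[str]]) -> dict[str, int]:
    """Relabel communities 0..k-1, ordered by smallest member node."""
    mods = sorted((sorted(m) for m in modules), key=lambda m: m[0])
    return {node: label for label, members in enumerate(mods) for node in members}


class _GraphClusterer(BaseEstimator, ClusterMixin):
    """Shared fit plumbing for clusterers over networkx graphs."""

    def _cluster(self, g: nx.Graph) -> list[set[str]]:  # pragma: no cover
        raise NotImplementedError

    def fit(self, X: nx.Graph, y=None):
        if not isinstance(X, nx.Graph):
            raise TypeError("X must be a networkx.Graph")
        if X.number_of_nodes() == 0:
            raise ValueError("cannot cluster an empty graph")
        modules = self._cluster(X)
        self.partition_ = _canonical_partition(modules)
        self.nodes_ = sorted(X.nodes)
        self.labels_ = np.array([self.partition_[n] for n in self.nodes_])
        self.modules_ = quality.partition_to_modules(self.partition_)
        return self

    def fit_predict(self, X: nx.Graph, y=None) -> np.ndarray:
        return self.fit(X).labels_


class LouvainClustering(_GraphClusterer):
    """Greedy multilevel modularity maximization (Louvain).

    The ``resistance`` parameter acts as the resolution multiplier on the
    degree-null term; smaller values yield larger communities.  Runs to
    convergence (no modularity change); deterministic for a fixed
    ``random_state`` (node visit order is the only randomness).

    Parameters
    ----------
    resistance : float, default 0.1
        Resolution multiplier R in (0, 1] on the null-model term.
    random_state : int, default 0
        Seed for the node-shuffling RNG.
    max_level : int or None
        Optional cap on aggregation levels.
    """

    def __init__(self, resistance: float = 0.1, random_state: int = 0,
                 max_level: int | None = None):
        self.resistance = resistance
        self.random_state = random_state
        self.max_level = max_level

    def _cluster(self, g: nx.Graph) -> list[set[str]]:
        if self.resistance <= 0:
            raise ValueError("resistance must be > 0")
        comms = louvain_communities(
            g, weight="weight", resolution=self.resistance,
            max_level=self.max_level, seed=self.random_state,
        )
        return [set(c) for c in comms]


class MCLClustering(_GraphClusterer):
    """Markov clustering: alternate expansion and inflation of the flow matrix.

    A column-stochastic transition matrix (self-loops of weight 1 added)
    is repeatedly squared (expansion) and elementwise-powered with column
    renormalization (inflation I) until the matrix stops changing.
    Clusters are read from the attractor structure: connected components
    of the nonzero pattern of the converged matrix.
    """

    def __init__(self, inflation: float = 2.0, expansion: int = 2,
                 max_iter: int = 200, tol: float = 1e-8, prune: float = 1e-8):
        self.inflation = inflation
        self.expansion = expansion
        self.max_iter = max_iter
        self.tol = tol
        self.prune = prune

    @staticmethod
    def _normalize_columns(m: sp.csr_matrix) -> sp.csr_matrix:
        col_sums = np.asarray(m.sum(axis=0)).ravel()
        col_sums[col_sums == 0] = 1.0
        return (m @ sp.diags(1.0 / col_sums)).tocsr()

    def _cluster(self, g: nx.Graph) -> list[set[str]]:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")
        nodes = sorted(g.nodes)
        a = nx.to_scipy_sparse_array(g, nodelist=nodes, weight="weight", format="csr")
        a = sp.csr_matrix(a, dtype=float)
        a = a + sp.identity(len(nodes), format="csr")  # self-loops weight 1
        m = self._normalize_columns(a)
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            prev = m
            for _ in range(self.expansion - 1):  # expansion: matrix power
                m = m @ prev
            m = m.tocsr()
            m.data = np.power(m.data, self.inflation)  # inflation
            m.data[m.data < self.prune] = 0.0
            m.eliminate_zeros()
            m = self._normalize_columns(m)
            diff = abs(m - prev)
            if diff.nnz == 0 or diff.max() < self.tol:
                converged = True
                break
        if not converged:
            logger.warning("MCL did not converge in %d iterations; "
                           "interpreting current matrix", self.max_iter)
        self.n_iter_ = n_iter
        pattern = m + m.T
        n_comp, comp = sp.csgraph.connected_components(pattern, directed=False)
        modules: dict[int, set[str]] = {}
        for idx, c in enumerate(comp):
            modules.setdefault(int(c), set()).add(nodes[idx])
        return list(modules.values())


class CEILClustering(_GraphClusterer):
    """Louvain-style local moving on the size-weighted CEIL objective.

    Maximizes sum_c (n_c / n) * CEIL(c) by greedy single-node moves from
    a singleton start, sweeping nodes in sorted order until no move
    improves the objective.  The method has no hyperparameter.
    """

    def __init__(self):
        pass

    def _cluster(self, g: nx.Graph) -> list[set[str]]:
        nodes = sorted(g.nodes)
        n = len(nodes)
        comm_of = {v: i for i, v in enumerate(nodes)}
        members: dict[int, set[str]] = {i: {v} for i, v in enumerate(nodes)}
        # per-community cached stats: internal weight, cut weight
        internal = {i: 0.0 for i in members}
        cut = {i: g.degree(v, weight="weight") for i, v in enumerate(nodes)}
        degree = {v: g.degree(v, weight="weight") for v in nodes}

        def contribution(c: int) -> float:
            nc = len(members[c])
            w_int = internal[c]
            if nc <= 1 or w_int == 0:
                return 0.0
            int_score = w_int / (nc * (nc - 1) / 2)
            ext_score = w_int / (w_int + cut[c])
            return (nc / n) * int_score * ext_score

        improved = True
        self.n_passes_ = 0
        while improved:
            improved = False
            self.n_passes_ += 1
            for v in nodes:
                cur = comm_of[v]
                # weight of v's edges into each neighboring community
                w_to: dict[int, float] = {}
                for u, data in g[v].items():
                    w_to[comm_of[u]] = w_to.get(comm_of[u], 0.0) + data["weight"]
                candidates = set(w_to) - {cur}
                if not candidates:
                    continue
                base = contribution(cur)
                w_cur = w_to.get(cur, 0.0)
                # stats of cur after removing v
                best_gain = 0.0
                best_c = None
                for c in sorted(candidates):
                    before = base + contribution(c)
                    self._move(v, cur, c, w_cur, w_to.get(c, 0.0),
                               members, internal, cut, comm_of, degree)
                    after = contribution(cur) + contribution(c)
                    gain = after - before
                    # revert
                    self._move(v, c, cur, w_to.get(c, 0.0), w_cur,
                               members, internal, cut, comm_of, degree)
                    if gain > best_gain + 1e-12:
                        best_gain = gain
                        best_c = c
                if best_c is not None:
                    self._move(v, cur, best_c, w_cur, w_to.get(best_c, 0.0),
                               members, internal, cut, comm_of, degree)
                    improved = True
        return [m for m in members.values() if m]

    @staticmethod
    def _move(v, src, dst, w_src, w_dst, members, internal, cut, comm_of, degree):
        """Move v from community src to dst, updating cached stats.

        w_src / w_dst: weight of v's edges into src-minus-v / dst.
        """
        members[src].discard(v)
        internal[src] -= w_src
        cut[src] = cut[src] - degree[v] + 2 * w_src
        members[dst].add(v)
        internal[dst] += w_dst
        cut[dst] = cut[dst] + degree[v] - 2 * w_dst
        comm_of[v] = dst


def louvain_modularity(g: nx.Graph, resistance: float = 0.1,
                       random_state: int = 0) -> dict[str, int]:
    """Louvain partition of ``g``; returns a node -> label mapping."""
    return LouvainClustering(resistance=resistance, random_state=random_state).fit(g).partition_


def mcl(g: nx.Graph, inflation: float = 2.0, **kwargs) -> dict[str, int]:
    """Markov clustering of ``g``; returns a node -> label mapping."""
    return MCLClustering(inflation=inflation, **kwargs).fit(g).partition_


def ceil_cluster(g: nx.Graph) -> dict[str, int]:
    """CEIL-objective clustering of ``g``; returns a node -> label mapping."""
    return CEILClustering().fit(g).partition_
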