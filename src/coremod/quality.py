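"""Community quality measures: modularity, conductance, CEIL, core score.

All measures are weighted: A_ij is the edge weight, the degree d_i is the
sum of incident edge weights, and e is the total edge weight.  On
unweighted simple graphs they reduce to the usual counting definitions.

Modularity here excludes the diagonal (self-pair) terms: for a community
c it is (1/2e) * sum over ordered pairs i != j in c of
(A_ij - gamma * d_i d_j / 2e).  Relative to the standard Newman form this
adds gamma * sum_{i in c} d_i^2 / (2e)^2; the correction is constant
across total partitions, so partition rankings are unaffected.

A note on symbols: the conductance denominator is the community *volume*
(sum of member degrees over the whole graph); the CEIL internal score by
contrast uses the intra-community edge weight.  Both are cached on
:class:`ModuleStats`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "ModuleStats",
    "module_stats",
    "modularity",
    "conductance",
    "ceil_score",
    "core_score",
    "partition_to_modules",
    "modules_to_partition",
]


@dataclass(frozen=True)
class ModuleStats:
    """Cached edge statistics of a node set within a graph.

    internal: total weight of edges with both endpoints inside.
    cut: total weight of edges with exactly one endpoint inside.
    volume: sum of member (weighted) degrees; volume = 2*internal + cut.
    sum_sq_degree: sum of squared member degrees (modularity diagonal term).
    """

    n_nodes: int
    internal: float
    cut: float
    volume: float
    sum_sq_degree: float


def module_stats(g: nx.Graph, members: Iterable[str]) -> ModuleStats:
    members = set(members)
    if not members:
        raise ValueError("module must be non-empty")
    missing = members - set(g.nodes)
    if missing:
        raise ValueError(f"module members not in graph: {sorted(missing)[:5]}")
    internal = 0.0
    cut = 0.0
    volume = 0.0
    sum_sq = 0.0
    for u in members:
        du = g.degree(u, weight="weight")
        volume += du
        sum_sq += du * du
        for v, data in g[u].items():
            w = data["weight"]
            if v in members:
                internal += w  # counted from both endpoints -> halve below
            else:
                cut += w
    return ModuleStats(len(members), internal / 2.0, cut, volume, sum_sq)


def partition_to_modules(p: Mapping[str, int]) -> list[set[str]]:
    """Group a node->label mapping into member sets, ordered by label."""
    out: dict[int, set[str]] = {}
    for node, label in p.items():
        out.setdefault(label, set()).add(node)
    return [out[k] for k in sorted(out)]


def modules_to_partition(modules: Iterable[Iterable[str]]) -> dict[str, int]:
    """Inverse of :func:`partition_to_modules` (modules must be disjoint)."""
    p: dict[str, int] = {}
    for label, module in enumerate(modules):
        for node in module:
            if node in p:
                raise ValueError(f"node {node!r} appears in multiple modules")
            p[node] = label
    return p


def _single_modularity(g: nx.Graph, members: set[str], two_e: float, gamma: float) -> float:
    st = module_stats(g, members)
    null = gamma * (st.volume * st.volume - st.sum_sq_degree) / two_e
    return (2.0 * st.internal - null) / two_e


def modularity(g: nx.Graph, p: Mapping[str, int] | Iterable[str], gamma: float = 1.0) -> float:
    """Modularity of a partition, or of a single community.

    ``p`` may be a node->label mapping (the per-community scores are
    summed) or a bare node set scored as one community.  Normalization
    is always by 2e of the whole graph.
    """
    two_e = 2.0 * g.size(weight="weight")
    if two_e == 0:
        raise ValueError("modularity undefined on a graph with no edge weight")
    if isinstance(p, Mapping):
        return sum(
            _single_modularity(g, mod, two_e, gamma) for mod in partition_to_modules(p)
        )
    return _single_modularity(g, set(p), two_e, gamma)


def conductance(g: nx.Graph, members: Iterable[str]) -> float:
    """cut(c) / min(vol(c), vol(complement)); 0 when the cut is empty."""
    members = set(members)
    st = module_stats(g, members)
    if st.volume == 0:
        raise ValueError("conductance undefined: module of isolated nodes")
    if st.cut == 0:
        return 0.0
    total_vol = 2.0 * g.size(weight="weight")
    return st.cut / min(st.volume, total_vol - st.volume)


def ceil_score(g: nx.Graph, members: Iterable[str]) -> float:
    """CEIL community score: internal density x separability.

    internal = W_int / C(n_c, 2) for n_c > 1 (0 otherwise);
    external = W_int / (W_int + cut); the score is their product.
    Singleton or edgeless modules score 0.
    """
    st = module_stats(g, set(members))
    if st.n_nodes <= 1 or st.internal == 0:
        return 0.0
    internal_score = st.internal / math.comb(st.n_nodes, 2)
    external_score = st.internal / (st.internal + st.cut)
    return internal_score * external_score


def core_score(g: nx.Graph, members: Iterable[str], node: str) -> float:
    """Per-node ratio of outgoing to internal edge weight within a module.

    0 when the node has no outgoing weight; +inf when it has outgoing
    weight but no internal weight (such nodes rank last, i.e. are pruned
    first when extracting a core).
    """
    members = set(members)
    if node not in members:
        raise ValueError(f"node {node!r} is not a member of the module")
    inside = 0.0
    outside = 0.0
    for v, data in g[node].items():
        if v in members:
            inside += data["weight"]
        else:
            outside += data["weight"]
    if outside == 0:
        return 0.0
    if inside == 0:
        return math.inf
    return outside / inside
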