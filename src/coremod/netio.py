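"""Graph and module-file I/O plus network preprocessing.

Networks are held as :class:`networkx.Graph` objects with a ``weight``
attribute on every edge.  Node identifiers are opaque strings (typically
gene or protein symbols); no identifier translation is performed.
Ingestion enforces the invariants the rest of the package relies on:
no self-loops, no duplicate edges, strictly positive weights.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SparsifyConfig",
    "read_weighted_edgelist",
    "validate_graph",
    "sparsify",
    "graph_density",
    "write_modules",
    "read_modules",
    "largest_connected_component",
    "weighted_degree",
    "total_edge_weight",
]


class EdgeListParseError(ValueError):
    """Raised for malformed or inconsistent edge-list input."""


@dataclass
class SparsifyConfig:
    """Edge-weight thresholding rule.

    mode
        ``mean_minus_ksd`` keeps edges with w >= mu - k*sigma (literal
        reading of "removing edges lesser than two standard deviations
        from the mean"); ``mean_plus_ksd`` keeps w >= mu + k*sigma;
        ``quantile`` keeps w >= the q-th weight quantile.
    k
        Number of standard deviations (population sigma), default 2.
    q
        Quantile in (0, 1) for ``quantile`` mode.
    """

    mode: str = "mean_minus_ksd"
    k: float = 2.0
    q: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in {"mean_minus_ksd", "mean_plus_ksd", "quantile"}:
            raise ValueError(f"unknown sparsify mode: {self.mode!r}")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.mode == "quantile" and not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")


def weighted_degree(g: nx.Graph, node: str) -> float:
    """Weighted degree d_i = sum of incident edge weights."""
    return g.degree(node, weight="weight")


def total_edge_weight(g: nx.Graph) -> float:
    """Total edge weight e; sum of degrees equals 2e."""
    return g.size(weight="weight")


def validate_graph(g: nx.Graph) -> nx.Graph:
    """Check the ingestion invariants; returns the graph unchanged."""
    for u, v, w in g.edges(data="weight"):
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        if w is None or w <= 0:
            raise ValueError(f"non-positive or missing weight on edge {u!r}-{v!r}")
    return g


def read_weighted_edgelist(path: str | Path, symmetrize: bool = False) -> nx.Graph:
    """Read a whitespace/TAB-delimited weighted edge list.

    Each non-comment line must carry at least three columns:
    ``node_a node_b weight``.  Lines starting with ``#`` are ignored.
    Self-loops are dropped with a warning.  A duplicate unordered pair
    with conflicting weights is an error unless ``symmetrize`` is set,
    in which case the maximum weight per pair is kept (used to fold
    directed inputs such as signaling networks into undirected form).
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected >=3 columns, got {len(parts)}"
                )
            a, b = parts[0], parts[1]
            try:
                w = float(parts[2])
            except ValueError as exc:
                raise EdgeListParseError(
                    f"{path}:{lineno}: non-numeric weight {parts[2]!r}"
                ) from exc
            if w <= 0:
                raise EdgeListParseError(f"{path}:{lineno}: non-positive weight {w}")
            if a == b:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, a)
                continue
            if g.has_edge(a, b):
                prev = g[a][b]["weight"]
                if symmetrize:
                    g[a][b]["weight"] = max(prev, w)
                elif not math.isclose(prev, w, rel_tol=1e-12):
                    raise EdgeListParseError(
                        f"{path}:{lineno}: duplicate edge {a!r}-{b!r} with "
                        f"conflicting weights {prev} and {w}"
                    )
                continue
            g.add_edge(a, b, weight=w)
    return validate_graph(g)


def sparsify(g: nx.Graph, cfg: SparsifyConfig | None = None) -> nx.Graph:
    """Drop low-weight edges; the node set (isolates included) is kept.

    Thresholds use the mean and *population* standard deviation of the
    edge-weight sample, each edge counted once.
    """
    cfg = cfg or SparsifyConfig()
    out = nx.Graph()
    out.add_nodes_from(g.nodes)
    weights = np.array([w for _, _, w in g.edges(data="weight")], dtype=float)
    if weights.size == 0:
        return out
    if cfg.mode == "quantile":
        thresh = float(np.quantile(weights, cfg.q))
    else:
        mu = float(weights.mean())
        sigma = float(weights.std())  # population sd (ddof=0)
        thresh = mu - cfg.k * sigma if cfg.mode == "mean_minus_ksd" else mu + cfg.k * sigma
    kept = [(u, v, w) for u, v, w in g.edges(data="weight") if w >= thresh]
    out.add_weighted_edges_from(kept)
    frac_removed = 1.0 - len(kept) / weights.size
    logger.info("sparsify: removed %.1f%% of %d edges (threshold %.4g)",
                100 * frac_removed, weights.size, thresh)
    return out


def graph_density(n_nodes: int, n_edges: int) -> float:
    """Density 2m / (n (n-1)) of a simple undirected graph."""
    if n_nodes < 2:
        raise ValueError("density requires at least 2 nodes")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def write_modules(modules: Sequence[Iterable[str]], path: str | Path) -> None:
    """Write modules as TSV: integer id, TAB, TAB-separated member ids."""
    with open(path, "w") as fh:
        for i, module in enumerate(modules, start=1):
            members = sorted(module)
            if not members:
                raise ValueError(f"module {i} is empty")
            fh.write(f"{i}\t" + "\t".join(members) + "\n")


def read_modules(path: str | Path) -> list[set[str]]:
    """Inverse of :func:`write_modules`; returns member sets in file order."""
    modules: list[set[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: module line with no members")
            modules.append(set(parts[1:]))
    return modules


def largest_connected_component(g: nx.Graph, genes: Iterable[str]) -> set[str]:
    """LCC of the subgraph induced by ``genes``.

    Genes absent from the graph are dropped with a warning.  Ties on
    component size are broken by the lexicographically smallest member.
    """
    genes = set(genes)
    known = genes & set(g.nodes)
    if len(known) < len(genes):
        logger.warning("largest_connected_component: dropped %d unknown genes",
                       len(genes) - len(known))
    if not known:
        raise ValueError("no requested genes are present in the graph")
    sub = g.subgraph(known)
    components = sorted(nx.connected_components(sub), key=lambda c: (-len(c), min(c)))
    return set(components[0])
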