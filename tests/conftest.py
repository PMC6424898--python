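import itertools

import networkx as nx
import pytest


def wgraph(edges):
    """Build a weighted graph from (u, v, w) triples."""
    g = nx.Graph()
    g.add_weighted_edges_from(edges)
    return g


def unit_graph(edges):
    """Unweighted-as-weighted graph: every edge has weight 1."""
    return wgraph([(u, v, 1.0) for u, v in edges])


@pytest.fixture
def two_triangles():
    """Two disjoint triangles a-b-c and x-y-z."""
    return unit_graph([("a", "b"), ("b", "c"), ("a", "c"),
                       ("x", "y"), ("y", "z"), ("x", "z")])


@pytest.fixture
def four_cycle():
    return unit_graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])


@pytest.fixture
def two_k5_bridged():
    """Two K5 cliques joined by a single edge."""
    left = [f"a{i}" for i in range(5)]
    right = [f"b{i}" for i in range(5)]
    edges = list(itertools.combinations(left, 2)) + list(itertools.combinations(right, 2))
    edges.append((left[0], right[0]))
    return unit_graph(edges), set(left), set(right)


def clique(names):
    return list(itertools.combinations(names, 2))
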