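import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coremod import metrics, seedexp, synthgen
from coremod.seedexp import (
    ExpansionConfig,
    PPRSeedExpander,
    disease_seeds,
    expand_all,
    expand_seed,
    hits_seeds,
    ppr,
    spread_hub_seeds,
)
from conftest import clique, unit_graph, wgraph


def star(center, leaves):
    return [(center, leaf) for leaf in leaves]


class TestDiseaseSeeds:
    def table(self):
        return pd.DataFrame({"traitA": [1e-5, 1e-3, 0.5],
                             "traitB": [0.9, 0.8, 1e-6]},
                            index=["g1", "g2", "g3"])

    def test_threshold_and_union_semantics(self):
        g = unit_graph([("g1", "g2"), ("g2", "g3")])
        seeds = disease_seeds(self.table(), g, cutoff=1e-4)
        # g1 passes in traitA, g3 in traitB only; g2 nowhere
        assert seeds.nodes == {"g1", "g3"}
        assert seeds.provenance.startswith("pvalue")

    def test_genes_absent_from_graph_excluded(self):
        g = unit_graph([("g2", "g3")])
        seeds = disease_seeds(self.table(), g, cutoff=1e-4)
        assert seeds.nodes == {"g3"}

    def test_no_passing_gene_warns_and_is_empty(self, caplog):
        g = unit_graph([("g1", "g2")])
        with caplog.at_level("WARNING"):
            seeds = disease_seeds(self.table(), g, cutoff=1e-9)
        assert len(seeds) == 0
        assert "no gene passes" in caplog.text


class TestHitsSeeds:
    def test_star_center_wins(self):
        g = unit_graph(star("hub", [f"l{i}" for i in range(6)]))
        assert hits_seeds(g, 1).nodes == {"hub"}

    def test_clique_ties_broken_lexicographically(self):
        g = unit_graph(clique("dcba"))
        assert hits_seeds(g, 2).nodes == {"a", "b"}

    def test_k_equals_n_returns_all(self, two_triangles):
        assert hits_seeds(two_triangles, 6).nodes == set(two_triangles.nodes)

    def test_k_too_large_is_error(self, two_triangles):
        with pytest.raises(ValueError):
            hits_seeds(two_triangles, 7)


class TestSpreadHubSeeds:
    def test_star_center(self):
        g = unit_graph(star("hub", list("abc")))
        assert spread_hub_seeds(g, 1).nodes == {"hub"}

    def test_two_disjoint_stars_both_centers(self):
        g = unit_graph(star("h1", [f"a{i}" for i in range(5)]) +
                       star("h2", [f"b{i}" for i in range(4)]))
        assert spread_hub_seeds(g, 2).nodes == {"h1", "h2"}

    def test_neighborhood_marking_blocks_adjacent_hubs(self):
        # second-highest degree node is adjacent to the first: skipped
        g = unit_graph(star("h1", ["h2", "a", "b", "c"]) + star("h2", ["d", "e"]))
        seeds = spread_hub_seeds(g, 2)
        assert "h1" in seeds.nodes and "h2" not in seeds.nodes

    def test_unattainable_k_warns(self, caplog):
        g = unit_graph(star("hub", list("ab")))
        with caplog.at_level("WARNING"):
            seeds = spread_hub_seeds(g, 5)
        assert len(seeds) == 1
        assert "attainable" in caplog.text


class TestPPR:
    def conservation(self, vec):
        return sum(vec.scores.values()) + sum(vec.residual.values())

    def test_isolated_seed_keeps_all_mass(self):
        g = nx.Graph()
        g.add_nodes_from(["s", "t"])
        g.add_edge("t", "u", weight=1.0)
        vec = ppr(g, "s")
        assert vec.scores["s"] == pytest.approx(1.0)

    def test_mass_conserved_and_residuals_below_tolerance(self):
        bench = synthgen.planted_partition([15] * 3, 0.4, 0.02, seed=0)
        g = bench.graph
        seed = sorted(g.nodes)[0]
        vec = ppr(g, seed, eps=1e-6)
        assert self.conservation(vec) == pytest.approx(1.0, abs=1e-9)
        for u, r in vec.residual.items():
            assert r < 1e-6 * g.degree(u, weight="weight")

    def test_clique_symmetry(self):
        g = unit_graph(clique("abcde"))
        vec = ppr(g, "a", eps=1e-8)
        others = [vec.scores[v] for v in "bcde"]
        assert max(others) - min(others) < 1e-8

    def test_push_schedule_independence(self):
        bench = synthgen.planted_partition([20] * 2, 0.3, 0.02, seed=1)
        g = bench.graph
        seed = sorted(g.nodes)[5]
        a = ppr(g, seed, eps=1e-8, schedule="fifo").scores
        b = ppr(g, seed, eps=1e-8, schedule="lifo").scores
        for v in set(a) | set(b):
            assert abs(a.get(v, 0) - b.get(v, 0)) < 1e-6

    def test_agrees_with_networkx_personalized_pagerank(self):
        # our teleport alpha corresponds to damping 1 - alpha in the
        # usual PageRank recursion p = (1-d) s + d p W
        g = unit_graph(clique("abcd") + [("d", "e"), ("e", "f")])
        seed = "a"
        vec = ppr(g, seed, alpha=0.5, eps=1e-10)
        exact = nx.pagerank(g, alpha=0.5, personalization={seed: 1.0},
                            tol=1e-14, max_iter=1000, weight="weight")
        for v in g.nodes:
            assert vec.scores.get(v, 0.0) == pytest.approx(exact[v], abs=1e-6)


class TestExpandSeed:
    def test_disjoint_clique_fully_recovered(self):
        g = unit_graph(clique("abcdef") + clique("uvwxyz"))
        res = expand_seed(g, "a")
        assert set(res.members) == set("abcdef")

    def test_seed_always_member_and_size_bounds(self):
        bench = synthgen.planted_partition([25] * 4, 0.3, 0.01, seed=2)
        g = bench.graph
        cfg = ExpansionConfig()
        for seed in sorted(g.nodes)[:10]:
            res = expand_seed(g, seed, cfg)
            if res is None:
                continue
            assert seed in res.members
            assert cfg.min_size <= len(res.members) <= cfg.max_size

    def test_deterministic(self):
        bench = synthgen.planted_partition([20] * 3, 0.3, 0.02, seed=4)
        seed = sorted(bench.graph.nodes)[0]
        a = expand_seed(bench.graph, seed)
        b = expand_seed(bench.graph, seed)
        assert a.members == b.members

    def test_isolated_seed_rejected(self):
        g = unit_graph(clique("abcd"))
        g.add_node("lonely")
        assert expand_seed(g, "lonely") is None


class TestExpandAll:
    def test_same_clique_seeds_deduplicated(self):
        g = unit_graph(clique("abcdef") + clique("uvwxyz"))
        cover, seed_map = expand_all(g, ["a", "b"])
        assert len(cover) == 1
        assert seed_map["a"] == seed_map["b"]

    def test_seeds_in_different_components_give_disjoint_modules(self):
        g = unit_graph(clique("abcdef") + clique("uvwxyz"))
        cover, _ = expand_all(g, ["a", "u"])
        mods = list(cover.values())
        assert len(mods) == 2
        assert not (mods[0] & mods[1])

    def test_estimator_interface(self):
        bench = synthgen.planted_partition([25] * 4, 0.3, 0.01, seed=0)
        table = synthgen.synth_gwas(bench, synthgen.SynthGWASConfig(seed=0))
        seeds = disease_seeds(table, bench.graph, 1e-4)
        est = PPRSeedExpander().fit(bench.graph, seeds)
        assert est.modules_
        assert est.get_params()["alpha"] == 0.85
        for module in est.modules_:
            assert 3 <= len(module) <= 100


class TestSeedFractionMonotonicity:
    def test_recovered_modules_non_decreasing_in_seed_fraction(self):
        fractions = (0.1, 0.5, 1.0)
        totals = {f: 0.0 for f in fractions}
        for s in range(10):
            bench = synthgen.planted_partition([25] * 4, 0.3, 0.01, seed=s)
            cfg = synthgen.SynthGWASConfig(n_traits=3, seed=s)
            table = synthgen.synth_gwas(bench, cfg)
            seeds = sorted(disease_seeds(table, bench.graph, 1e-4).nodes)
            causal = [bench.truth[m] for mods in
                      cfg.resolve_causal(sorted(bench.truth)).values() for m in mods]
            rng = np.random.default_rng(s)
            for f in fractions:
                k = max(1, int(round(f * len(seeds))))
                sub = list(rng.choice(seeds, size=k, replace=False))
                cover, _ = expand_all(bench.graph, sub)
                totals[f] += metrics.recovered_fraction(causal, cover.values(), 0.8)
        means = [totals[f] / 10 for f in fractions]
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))
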