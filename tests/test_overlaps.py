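import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coremod import overlaps, quality, synthgen
from coremod.overlaps import (
    EnrichmentResult,
    OverlapResolver,
    assign_conductance,
    assign_iterative,
    assign_random,
    base_communities,
    comorbidity_network,
    enrich_modules,
    hit_ratio,
    lcc_clusterability,
    method_score,
    overlap_counts,
)
from conftest import clique, unit_graph


def bridged_cover():
    """K6 and K3 sharing node 'o': o belongs to both modules."""
    k6 = ["a", "b", "c", "d", "e", "o"]
    k3 = ["x", "y", "o"]
    g = unit_graph(clique(k6) + clique(k3))
    cover = {0: set(k6), 1: set(k3)}
    return g, cover


class TestBaseCommunities:
    def test_no_overlap_identity(self):
        cover = {0: {"a", "b"}, 1: {"c"}}
        base, overlap = base_communities(cover)
        assert base == {"a": 0, "b": 0, "c": 1}
        assert overlap == set()

    def test_overlap_node_detected(self):
        g, cover = bridged_cover()
        base, overlap = base_communities(cover)
        assert overlap == {"o"}
        assert "o" not in base

    def test_all_overlapping_is_error(self):
        with pytest.raises(ValueError):
            base_communities({0: {"a"}, 1: {"a"}})


class TestAssignment:
    def test_no_overlap_all_modes_return_base(self):
        g = unit_graph(clique("abc") + clique("xyz"))
        cover = {0: set("abc"), 1: set("xyz")}
        expected = {**{v: 0 for v in "abc"}, **{v: 1 for v in "xyz"}}
        assert assign_random(g, cover, 0) == expected
        assert assign_conductance(g, cover) == expected
        part, _, conv = assign_iterative(g, cover)
        assert part == expected and conv

    def test_random_restricted_to_candidates(self):
        g, cover = bridged_cover()
        for s in range(10):
            part = assign_random(g, cover, s)
            assert part["o"] in (0, 1)

    def test_conductance_prefers_larger_clique(self):
        g, cover = bridged_cover()
        base = {0: set("abcde"), 1: set("xy")}
        # enumerate both placements of 'o' directly
        with_k6 = quality.conductance(g, base[0] | {"o"})
        with_k3 = quality.conductance(g, base[1] | {"o"})
        best = 0 if with_k6 < with_k3 else 1
        assert assign_conductance(g, cover)["o"] == best
        part, phases, conv = assign_iterative(g, cover)
        assert part["o"] == best and conv

    def test_iterative_one_stable_on_overlapping_benchmark(self):
        bench = synthgen.overlapping_benchmark([25] * 4, 0.3, 0.01,
                                               n_overlap_per_pair=2, seed=0)
        part, phases, conv = assign_iterative(bench.graph, bench.truth)
        assert conv and phases <= 5
        # 1-stability: no overlap node can find a better placement
        _, overlap = base_communities(bench.truth)
        member = {v: {c for c, m in bench.truth.items() if v in m} for v in overlap}
        sets = {}
        for v, label in part.items():
            sets.setdefault(label, set()).add(v)
        for v in overlap:
            cur = part[v]
            sets[cur].discard(v)
            scores = {c: quality.conductance(bench.graph, sets[c] | {v})
                      for c in member[v]}
            sets[cur].add(v)
            assert scores[cur] == min(scores.values())

    def test_resolver_estimator_modes(self):
        g, cover = bridged_cover()
        for mode in ("random", "conductance", "iterative"):
            r = OverlapResolver(mode=mode).fit(g, cover)
            assert set(r.partition_) == set(g.nodes)
            assert set(r.partition_.values()) <= set(cover)


class TestLCCClusterability:
    def test_disjoint_clique_zero_conductance(self):
        g = unit_graph(clique("abcd") + clique("wxyz"))
        mod, cond = lcc_clusterability(g, set("abcd"))
        assert cond == 0.0
        assert mod > 0

    def test_random_gene_sample_poorly_clusterable(self):
        bench = synthgen.planted_partition([40] * 5, 0.2, 0.05, seed=0)
        rng = np.random.default_rng(0)
        conds = []
        for _ in range(10):
            genes = set(rng.choice(sorted(bench.graph.nodes), 10, replace=False))
            try:
                _, cond = lcc_clusterability(bench.graph, genes)
            except ValueError:
                continue
            conds.append(cond)
        assert np.mean(conds) > 0.8

    def test_single_node_lcc_is_error(self):
        g = unit_graph(clique("abc"))
        g.add_edge("p", "q", weight=1.0)
        g.add_node("z")
        with pytest.raises(ValueError):
            lcc_clusterability(g, {"z"})


class TestEnrichment:
    def test_all_p_one_not_enriched(self):
        genes = [f"g{i}" for i in range(10)]
        scores = pd.DataFrame({"t1": np.ones(10)}, index=genes)
        enr = enrich_modules([set(genes[:5])], scores)
        assert not enr.table["enriched"].any()

    def test_planted_signal_flagged(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(100)]
        scores = pd.DataFrame(rng.uniform(size=(100, 3)), index=genes,
                              columns=["t1", "t2", "t3"])
        scores.loc[genes[:20], "t2"] = rng.uniform(size=20) ** 10  # Beta(0.1, 1)
        modules = [set(genes[i * 20:(i + 1) * 20]) for i in range(5)]
        enr = enrich_modules(modules, scores)
        assert (0, "t2") in enr.enriched_pairs

    def test_qvalues_dominate_pvalues_and_flags_match_bh(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(60)]
        scores = pd.DataFrame(rng.uniform(size=(60, 2)) ** 3, index=genes,
                              columns=["t1", "t2"])
        modules = [set(genes[i * 10:(i + 1) * 10]) for i in range(6)]
        enr = enrich_modules(modules, scores, fdr=0.1)
        t = enr.table
        assert (t["qvalue"] >= t["pvalue"] - 1e-15).all()
        # direct BH step-up oracle
        p = np.sort(t["pvalue"].to_numpy())
        m = len(p)
        below = np.nonzero(p <= 0.1 * np.arange(1, m + 1) / m)[0]
        k = 0 if below.size == 0 else below[-1] + 1
        assert int(t["enriched"].sum()) == k

    def test_module_without_scored_genes_excluded(self, caplog):
        scores = pd.DataFrame({"t1": [0.5]}, index=["g0"])
        with caplog.at_level("WARNING"):
            enr = enrich_modules([{"g0"}, {"unknown"}], scores)
        assert set(enr.table["module"]) == {0}
        assert "no scored gene" in caplog.text


class TestReportingArithmetic:
    @pytest.mark.parametrize("e,n,expect", [
        (16, 872, 0.0183),
        (9, 209, 0.0431),
        (0, 7, 0.0),
    ])
    def test_hit_ratio(self, e, n, expect):
        assert hit_ratio(e, n) == pytest.approx(expect, abs=5e-5)

    def test_hit_ratio_zero_denominator(self):
        with pytest.raises(ValueError):
            hit_ratio(0, 0)

    @pytest.mark.parametrize("counts,expect", [
        ([16, 18, 9, 9, 4, 8], 64),
        ([22, 21, 14, 20, 9, 10], 96),
        ([], 0),
    ])
    def test_method_score(self, counts, expect):
        assert method_score(counts) == expect

    def test_overlap_counts_double_counting_identity(self):
        cover = {0: {"a", "b", "o"}, 1: {"o", "c"}, 2: {"o", "b"}}
        counts = overlap_counts(cover)
        assert counts["o"] == 3
        assert counts.get("z", 0) == 0
        assert sum(counts.values()) == sum(len(m) for m in cover.values())


class TestComorbidity:
    @staticmethod
    def from_pairs(pairs):
        """EnrichmentResult stub from explicit enriched (module, trait) pairs."""
        rows = [(m, t, 0.001, 0.01, True) for m, t in pairs]
        table = pd.DataFrame(rows, columns=["module", "trait", "pvalue",
                                            "qvalue", "enriched"])
        return EnrichmentResult(table, 0.05)

    def test_single_multi_trait_module(self):
        net = comorbidity_network(self.from_pairs([(0, "X"), (0, "Y")]))
        assert net["X"]["Y"]["count"] == 1

    def test_counts_accumulate(self):
        net = comorbidity_network(self.from_pairs(
            [(0, "X"), (0, "Y"), (1, "X"), (1, "Y")]))
        assert net["X"]["Y"]["count"] == 2

    def test_top_fraction_tie_rule(self):
        # counts {AB:3, AC:2, AD:2, AE:1}; top 50% -> cutoff count 2, ties kept
        pairs = []
        for i in range(3):
            pairs += [(i, "A"), (i, "B")]
        for i in range(3, 5):
            pairs += [(i, "A"), (i, "C")]
        for i in range(5, 7):
            pairs += [(i, "A"), (i, "D")]
        pairs += [(7, "A"), (7, "E")]
        net = comorbidity_network(self.from_pairs(pairs), top_frac=0.5)
        kept = {frozenset(e) for e in net.edges}
        assert kept == {frozenset("AB"), frozenset("AC"), frozenset("AD")}

    def test_no_multi_trait_module_warns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            net = comorbidity_network(self.from_pairs([(0, "X"), (1, "Y")]))
        assert net.number_of_edges() == 0
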