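"""Clustering variants, efficiency, betweenness ratios, communities, attacks."""

import networkx as nx
import numpy as np
import pytest

from connectocore import (
    betweenness_ratio,
    consensus_louvain,
    degree_preserving_swap,
    degree_strength_spearman,
    directed_clustering,
    directed_modularity,
    global_efficiency,
    summarize,
    targeted_attack,
)

from conftest import (
    betweenness_bruteforce,
    complete_digraph,
    random_digraph,
    toy,
)


class TestDirectedClustering:
    def test_complete_triangle_both_variants(self):
        c = complete_digraph(3)
        # printed ratio: each node has 2 distinct neighbors with 2 links
        # between them, and k_i = 4, so 2 / (4 * 3) = 1/6
        printed, mean_printed = directed_clustering(c, variant="printed_formula")
        assert all(v == pytest.approx(1 / 6) for v in printed.values())
        fagiolo, mean_f = directed_clustering(c, variant="fagiolo")
        assert all(v == pytest.approx(1.0) for v in fagiolo.values())

    def test_directed_three_cycle(self):
        c = toy([("a", "b"), ("b", "c"), ("c", "a")])
        fagiolo, _ = directed_clustering(c, variant="fagiolo")
        assert all(v > 0 for v in fagiolo.values())  # cyclic triangle counts
        printed, _ = directed_clustering(c, variant="printed_formula")
        # node a's neighbors are {b, c}; exactly one link (b -> c) exists
        assert printed["a"] == pytest.approx(1 / (2 * 1))

    def test_star_with_no_neighbor_links_is_zero(self):
        c = toy([("hub", f"s{i}") for i in range(4)])
        for variant in ("fagiolo", "printed_formula"):
            per_node, mean = directed_clustering(c, variant=variant)
            assert mean == 0.0

    def test_low_degree_nodes_clustering_zero(self):
        c = toy([("a", "b")])
        per_node, _ = directed_clustering(c, variant="printed_formula")
        assert per_node == {"a": 0.0, "b": 0.0}


class TestGlobalEfficiency:
    def test_complete_digraph_is_one(self):
        assert global_efficiency(complete_digraph(6)) == pytest.approx(1.0)

    def test_directed_cycle_closed_form(self):
        n = 6
        c = toy([(f"v{i}", f"v{(i + 1) % n}") for i in range(n)])
        expected = sum(1 / t for t in range(1, n)) / (n - 1)
        assert global_efficiency(c) == pytest.approx(expected)
        # and against brute-force all-pairs BFS
        total = 0.0
        for s in c.graph.nodes:
            lengths = nx.single_source_shortest_path_length(c.graph, s)
            total += sum(1 / d for d in lengths.values() if d > 0)
        assert global_efficiency(c) == pytest.approx(total / (n * (n - 1)))

    def test_single_node_undefined(self):
        assert np.isnan(global_efficiency(toy([], nodes=["a"])))

    def test_restricted_to_largest_scc(self):
        # a 3-cycle plus an unreachable pendant must score like the pure cycle
        cyc = toy([("a", "b"), ("b", "c"), ("c", "a")])
        with_pendant = toy([("a", "b"), ("b", "c"), ("c", "a"), ("x", "a")])
        assert global_efficiency(with_pendant) == pytest.approx(
            global_efficiency(cyc)
        )


class TestBetweennessRatio:
    def test_full_node_set_ratio_is_one(self):
        c = random_digraph(30, 0.2, seed=0)
        assert betweenness_ratio(c, c.graph.nodes) == pytest.approx(1.0)

    def test_cycle_singletons_all_one(self):
        c = toy([(f"v{i}", f"v{(i + 1) % 7}") for i in range(7)])
        for n in c.graph.nodes:
            assert betweenness_ratio(c, {n}) == pytest.approx(1.0)

    def test_hub_matches_bruteforce_path_count(self):
        # strongly connected line-with-shortcut on 6 nodes
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "a"),
                 ("b", "e"), ("c", "a")]
        c = toy(edges)
        brute = betweenness_bruteforce(c.graph)
        mean_all = np.mean(list(brute.values()))
        for node in c.graph.nodes:
            assert betweenness_ratio(c, {node}) == pytest.approx(
                brute[node] / mean_all
            )

    def test_disjoint_set_rejected(self):
        c = toy([("a", "b"), ("b", "a"), ("x", "a")])
        with pytest.raises(ValueError, match="intersect"):
            betweenness_ratio(c, {"x"})

    def test_partitioned_ratios_reconstruct_global_mean(self):
        c = random_digraph(25, 0.25, seed=3)
        from connectocore.topology import largest_scc

        scc = sorted(largest_scc(c))
        half = len(scc) // 2
        parts = [set(scc[:half]), set(scc[half:])]
        total = sum(len(p) * betweenness_ratio(c, p) for p in parts)
        assert total == pytest.approx(len(scc))


class TestCommunities:
    def _two_blocks(self):
        edges = []
        for block in (0, 1):
            names = [f"b{block}_{i}" for i in range(5)]
            edges += [(u, v) for u in names for v in names if u != v]
        edges.append(("b0_0", "b1_0"))
        return toy(edges)

    def test_two_complete_blocks_recovered(self):
        c = self._two_blocks()
        part = consensus_louvain(c, n_runs=20, seed=0)
        comms = part.as_sets()
        assert len(comms) == 2
        assert {frozenset(s) for s in comms} == {
            frozenset(f"b0_{i}" for i in range(5)),
            frozenset(f"b1_{i}" for i in range(5)),
        }

    def test_edgeless_graph_singleton_communities(self):
        c = toy([], nodes=list("abcd"))
        part = consensus_louvain(c, n_runs=5, seed=1)
        assert len(part.as_sets()) == 4

    def test_seeded_repeatability(self):
        c = random_digraph(40, 0.1, seed=5)
        a = consensus_louvain(c, n_runs=10, seed=42)
        b = consensus_louvain(c, n_runs=10, seed=42)
        assert a.communities == b.communities


class TestDirectedModularity:
    def test_single_community_formula_instantiation(self):
        c = random_digraph(20, 0.2, seed=1)
        part = {n: 0 for n in c.graph.nodes}
        m = c.n_edges
        expected = 1.0 - (m * m) / (2 * m * m)  # k_in = k_out = m here
        assert directed_modularity(c, part) == pytest.approx(expected)

    def test_block_partition_beats_random_bisection(self):
        c = TestCommunities()._two_blocks()
        blocks = {n: (0 if n.startswith("b0") else 1) for n in c.graph.nodes}
        rng = np.random.default_rng(0)
        random_part = {n: int(rng.integers(2)) for n in c.graph.nodes}
        assert directed_modularity(c, blocks) > directed_modularity(c, random_part)

    def test_resolution_zero_upper_bound(self):
        c = random_digraph(15, 0.2, seed=2)
        part = consensus_louvain(c, n_runs=5, seed=0).communities
        q0 = directed_modularity(c, part, resolution=0.0)
        assert 0.0 <= q0 <= 1.0

    def test_m2_variant_larger_null_term(self):
        c = random_digraph(15, 0.2, seed=3)
        part = {n: 0 for n in c.graph.nodes}
        assert directed_modularity(c, part, denominator="m2") <= directed_modularity(
            c, part, denominator="2m2"
        )

    def test_missing_nodes_rejected(self):
        c = toy([("a", "b")])
        with pytest.raises(ValueError, match="missing"):
            directed_modularity(c, {"a": 0})


class TestSummarizeAndAttack:
    def test_complete_digraph_summary(self):
        s = summarize(complete_digraph(4), n_nulls_clustering=2,
                      n_nulls_modularity=1, n_louvain_runs=2, seed=0)
        assert s.density == pytest.approx(1.0)
        assert s.strongly_connected and s.weakly_connected
        assert s.global_efficiency == pytest.approx(1.0)

    def test_disjoint_dyads_not_connected(self):
        c = toy([("a", "b"), ("b", "a"), ("c", "d"), ("d", "c")])
        s = summarize(c, n_nulls_clustering=1, n_nulls_modularity=1,
                      n_louvain_runs=2, seed=0)
        assert not s.strongly_connected and not s.weakly_connected

    def test_summary_deterministic_from_seed(self, planted):
        c, _, _ = planted
        kw = dict(n_nulls_clustering=2, n_nulls_modularity=1,
                  n_louvain_runs=3, seed=9)
        assert summarize(c, **kw) == summarize(c, **kw)

    def test_remove_nothing_keeps_ratios_one(self, planted):
        c, _, _ = planted
        res = targeted_attack(c, set())
        assert res.clustering_ratio == pytest.approx(1.0)
        assert res.efficiency_ratio == pytest.approx(1.0)

    def test_remove_isolated_node_touches_no_path_or_triangle(self):
        c = toy([("a", "b"), ("b", "c"), ("c", "a"), ("a", "c"), ("c", "b"),
                 ("b", "a")], nodes=["iso"])
        res = targeted_attack(c, {"iso"})
        # no path is touched, so efficiency is exactly preserved; the mean
        # clustering rises only because the zero-clustering isolate leaves
        # the average (ratio N / (N - 1) = 4/3), with every surviving
        # node's own value unchanged
        assert res.efficiency_ratio == pytest.approx(1.0)
        assert res.clustering_ratio == pytest.approx(4 / 3)
        before, _ = directed_clustering(c)
        survivors = toy([("a", "b"), ("b", "c"), ("c", "a"), ("a", "c"),
                         ("c", "b"), ("b", "a")])
        after, _ = directed_clustering(survivors)
        for n in "abc":
            assert before[n] == after[n]

    def test_removing_planted_core_degrades_efficiency(self, planted):
        c, planted_nodes, _ = planted
        res = targeted_attack(c, planted_nodes)
        assert res.efficiency_ratio < 1.0


class TestDegreeStrengthSpearman:
    def test_equal_weights_give_perfect_correlation(self):
        c = random_digraph(20, 0.2, seed=0)
        assert degree_strength_spearman(c) == pytest.approx(1.0)

    def test_engineered_inversion(self):
        # a low-degree pair joined by heavy reciprocal edges vs. a
        # light complete triangle: degree and strength ranks invert
        heavy = [("x", "y"), ("y", "x")]
        tri = [(u, v) for u in "abc" for v in "abc" if u != v]
        c = toy(heavy + tri, weights=[100, 100] + [1] * 6)
        assert degree_strength_spearman(c) == pytest.approx(-1.0)

    def test_null_surrogates_preserve_spearman_value_domain(self, planted):
        c, _, _ = planted
        null = degree_preserving_swap(c, seed=0)
        assert -1.0 <= degree_strength_spearman(null) <= 1.0
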