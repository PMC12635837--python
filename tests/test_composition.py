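"""Neighbor sets, type-frequency profiles, diversity, type matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connectocore import (
    neighbor_set,
    shannon_diversity,
    simpson_diversity,
    type_connectivity_matrix,
    type_frequencies,
    type_score,
)

from conftest import complete_digraph, random_digraph, toy


class TestNeighborSet:
    def test_chain_orders(self):
        c = toy([("a", "b"), ("b", "c")])
        assert neighbor_set(c, {"c"}, "predecessors", 1) == {"b"}
        assert neighbor_set(c, {"c"}, "predecessors", 2) == {"a"}

    def test_cycle_second_order_successors(self):
        c = toy([("a", "b"), ("b", "c"), ("c", "a")])
        assert neighbor_set(c, {"a"}, "successors", 2) == {"c"}

    def test_seed_exclusion_flag(self):
        c = toy([("a", "b"), ("b", "a")])
        assert neighbor_set(c, {"a"}, "successors", 2, exclude_seeds=True) == set()
        assert neighbor_set(c, {"a"}, "successors", 2, exclude_seeds=False) == {"a"}

    def test_empty_seed_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            neighbor_set(toy([("a", "b")]), set(), "successors", 1)

    def test_matches_two_hop_breadth_search(self):
        c = random_digraph(50, 0.08, seed=2)
        rng = np.random.default_rng(1)
        seeds = set(rng.choice(sorted(c.graph.nodes), size=5, replace=False))
        # brute force: explicit two-hop walk along reversed edges
        hop1 = {p for s in seeds for p in c.graph.predecessors(s)}
        hop2 = {p for s in hop1 for p in c.graph.predecessors(s)} - seeds
        assert neighbor_set(c, seeds, "predecessors", 2) == hop2

    def test_order_two_is_order_one_applied_twice(self):
        c = random_digraph(40, 0.1, seed=7)
        seeds = set(sorted(c.graph.nodes)[:4])
        once = neighbor_set(c, seeds, "successors", 1, exclude_seeds=False)
        twice = (
            neighbor_set(c, once, "successors", 1, exclude_seeds=False)
            if once else set()
        )
        assert neighbor_set(c, seeds, "successors", 2, exclude_seeds=False) == twice


class TestTypeFrequencies:
    def test_single_type(self):
        prof = type_frequencies(["a", "b"], {"a": "KC", "b": "KC"})
        assert prof.freq == {"KC": 1.0} and prof.n_types == 1

    def test_two_plus_two(self):
        ann = {"a": "KC", "b": "KC", "c": "PN", "d": "PN"}
        prof = type_frequencies(list("abcd"), ann)
        assert prof.freq == {"KC": 0.5, "PN": 0.5}

    def test_unannotated_fall_into_unassigned(self):
        prof = type_frequencies(["a", "b"], {"a": "KC"})
        assert prof.freq["unassigned"] == 0.5

    def test_frequencies_sum_to_one(self, planted):
        c, core, _ = planted
        prof = type_frequencies(c.graph.nodes, c.type_of)
        assert sum(prof.freq.values()) == pytest.approx(1.0)

    def test_vocabulary_fixes_n_types(self):
        prof = type_frequencies(["a"], {"a": "KC"}, vocabulary=["KC", "PN", "LN"])
        assert prof.n_types == 3 and prof.counts["PN"] == 0


class TestDiversityIndices:
    def _profile(self, freqs, n=None):
        counts = {f"t{i}": int(round(f * 1000)) for i, f in enumerate(freqs)}
        vocab = list(counts) if n is None else [f"t{i}" for i in range(n)]
        nodes = [t for t, k in counts.items() for _ in range(k)]
        ann = {f"{t}_{j}": t for t, k in counts.items() for j in range(k)}
        expanded = [f"{t}_{j}" for t, k in counts.items() for j in range(k)]
        return type_frequencies(expanded, ann, vocabulary=vocab)

    def test_uniform_profile_maximal(self):
        prof = self._profile([0.25] * 4)
        assert shannon_diversity(prof) == pytest.approx(1.0)
        assert simpson_diversity(prof) == pytest.approx(1.0)
        assert simpson_diversity(prof, form="as_printed") == pytest.approx(1.0)

    def test_single_type_minimal(self):
        prof = self._profile([1.0])
        assert shannon_diversity(prof) == 0.0
        prof4 = self._profile([1.0], n=4)
        assert simpson_diversity(prof4, form="as_printed") == pytest.approx(4.0)
        assert simpson_diversity(prof4) == pytest.approx(0.25)

    def test_shannon_direct_evaluation(self):
        prof = self._profile([0.5, 0.25, 0.25])
        expected = (1.5 * np.log(2)) / np.log(3)
        assert shannon_diversity(prof) == pytest.approx(expected, abs=1e-9)

    def test_simpson_as_printed_direct_evaluation(self):
        prof = self._profile([0.5, 0.5], n=4)
        assert simpson_diversity(prof, form="as_printed") == pytest.approx(2.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 50), min_size=2, max_size=6))
    def test_permutation_invariance_and_bounds(self, counts):
        ann = {}
        nodes = []
        for i, k in enumerate(counts):
            for j in range(k):
                ann[f"t{i}_{j}"] = f"t{i}"
                nodes.append(f"t{i}_{j}")
        prof = type_frequencies(nodes, ann)
        h = shannon_diversity(prof)
        s = simpson_diversity(prof)
        assert 0.0 <= h <= 1.0 + 1e-12
        assert 0.0 < s <= 1.0 + 1e-12
        # permute type labels: indices must not move
        perm_ann = {n: "p" + t for n, t in ann.items()}
        perm_prof = type_frequencies(nodes, perm_ann)
        assert shannon_diversity(perm_prof) == pytest.approx(h)
        assert simpson_diversity(perm_prof) == pytest.approx(s)


class TestTypeMatrix:
    def test_formula_arithmetic(self):
        ann = {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y", "y3": "Y"}
        c = toy([("x1", "y1"), ("x1", "y2"), ("x2", "y3")], type_of=ann)
        tm = type_connectivity_matrix(c)
        assert tm.P.loc["X", "Y"] == pytest.approx(3 / 6)
        assert tm.E_counts.loc["X", "Y"] == 3

    def test_complete_one_type_diagonal_is_one(self):
        c = complete_digraph(4)
        c = c.with_labels({n: "T" for n in c.graph.nodes})
        tm = type_connectivity_matrix(c)
        assert tm.P.loc["T", "T"] == pytest.approx(1.0)

    def test_singleton_type_diagonal_is_nan(self):
        c = toy([("a", "b")], type_of={"a": "X", "b": "Y"})
        tm = type_connectivity_matrix(c)
        assert np.isnan(tm.P.loc["X", "X"])

    def test_edge_count_conservation(self, planted):
        c, _, _ = planted
        tm = type_connectivity_matrix(c)
        assert tm.E_counts.to_numpy().sum() == c.n_edges
        # row sums equal per-type out-degree totals
        for t in tm.labels:
            out_total = sum(
                c.graph.out_degree(n) for n in c.graph.nodes if c.label(n) == t
            )
            assert tm.E_counts.loc[t].sum() == out_total


class TestTypeScore:
    def test_single_type_sits_at_max_level(self):
        c = complete_digraph(3).with_labels(
            {n: "T" for n in complete_digraph(3).graph.nodes}
        )
        tm = type_connectivity_matrix(c)
        sc = type_score(tm)
        assert sc.max_core() == {"T"}

    def test_heavy_block_survives_last(self):
        # 4 types: A, B densely and strongly interconnected, C, D weakly
        ann = {}
        edges, weights = [], []
        for t, members in (("A", 3), ("B", 3), ("C", 3), ("D", 3)):
            for i in range(members):
                ann[f"{t}{i}"] = t
        for u in ("A", "B"):
            for v in ("A", "B"):
                for i in range(3):
                    for j in range(3):
                        if f"{u}{i}" != f"{v}{j}":
                            edges.append((f"{u}{i}", f"{v}{j}"))
        edges += [("C0", "D0"), ("D0", "C0"), ("C1", "A0"), ("A0", "C1")]
        c = toy(edges, type_of=ann)
        sc = type_score(type_connectivity_matrix(c))
        assert {"A", "B"} <= sc.max_core()
        assert sc.levels["C"] < min(sc.levels["A"], sc.levels["B"])

    def test_directional_variants_run_and_rank(self, planted):
        c, _, _ = planted
        tm = type_connectivity_matrix(c)
        for variant in ("in", "out", "total"):
            sc = type_score(tm, variant=variant)
            assert set(sc.levels) == set(tm.labels)
            assert all(v >= 0 for v in sc.levels.values())
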