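"""Shared fixtures and small independent oracles."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from connectocore import Connectome, from_edges


def toy(edges, nodes=(), weights=None, type_of=None) -> Connectome:
    """Connectome from a list of (u, v) pairs (unit weights by default)."""
    if weights is None:
        triples = [(u, v, 1) for u, v in edges]
    else:
        triples = [(u, v, w) for (u, v), w in zip(edges, weights)]
    return from_edges(triples, nodes=nodes, type_of=type_of)


def complete_digraph(n: int) -> Connectome:
    return toy([(f"v{i}", f"v{j}") for i in range(n) for j in range(n) if i != j])


def random_digraph(n: int, p: float, seed: int) -> Connectome:
    g = nx.gnp_random_graph(n, p, seed=seed, directed=True)
    return toy([(f"v{u}", f"v{v}") for u, v in g.edges()],
               nodes=[f"v{i}" for i in range(n)])


def dcore_bruteforce(c: Connectome, k: int, l: int) -> set[str]:
    """Exhaustive maximal feasible subgraph for tiny graphs.

    Feasible node sets (every member has in-degree >= k and out-degree
    >= l inside the set) are closed under union, so the maximal one is
    the union of all feasible subsets.
    """
    nodes = list(c.graph.nodes)
    assert len(nodes) <= 10, "oracle is exponential"
    best: set[str] = set()
    for r in range(len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            s = set(sub)
            ok = all(
                sum(1 for p in c.graph.predecessors(v) if p in s and p != v) >= k
                and sum(1 for q in c.graph.successors(v) if q in s and q != v) >= l
                for v in s
            )
            if ok:
                best |= s
    return best


def betweenness_bruteforce(g: nx.DiGraph) -> dict:
    """Raw betweenness by explicit shortest-path enumeration."""
    btw = {v: 0.0 for v in g.nodes}
    for s in g.nodes:
        for t in g.nodes:
            if s == t:
                continue
            try:
                paths = list(nx.all_shortest_paths(g, s, t))
            except nx.NetworkXNoPath:
                continue
            for v in g.nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p[1:-1])
                btw[v] += through / len(paths)
    return btw


@pytest.fixture(scope="session")
def planted():
    """Default planted-core synthetic connectome plus its ground truth."""
    from connectocore import SyntheticSpec, generate_planted_core, planted_core_nodes

    spec = SyntheticSpec(seed=1)
    return generate_planted_core(spec), planted_core_nodes(spec), spec


@pytest.fixture(scope="session")
def er100():
    """Mid-density Erdős–Rényi digraph for null-model self-consistency."""
    return random_digraph(100, 0.3, seed=5)
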