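"""D-core, k-core, and s-core decompositions of directed graphs.

The D-core(k, l) of a directed graph is the maximal subgraph in which
every node has in-degree >= k and out-degree >= l within the subgraph.
Scanning all (k, l) pairs yields the D-core matrix; its Pareto-maximal
non-empty cells are the frontier D-cores, and the union of their members
is taken as the structural core of the network.

All three decompositions share one pruning kernel: iteratively delete
nodes whose score (in/out-degree pair, total degree, or total strength)
falls below the threshold, until a fixed point.  The result is the
unique maximal feasible subgraph, independent of deletion order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .connectome import Connectome


def _adjacency(c: Connectome) -> tuple[dict, dict]:
    """Successor and predecessor sets (self-loops ignored)."""
    succ = {n: set(c.graph.successors(n)) - {n} for n in c.graph.nodes}
    pred = {n: set(c.graph.predecessors(n)) - {n} for n in c.graph.nodes}
    return succ, pred


def _prune(
    succ: dict, pred: dict, nodes: set, k: int, l: int
) -> set:
    """Maximal subset of ``nodes`` with in-degree >= k, out-degree >= l.

    Worklist deletion: any node violating the bound is removed and its
    neighbors re-checked.  Because feasible sets are closed under union,
    the fixed point is the unique maximal feasible subgraph regardless
    of processing order.
    """
    alive = set(nodes)
    indeg = {n: len(pred[n] & alive) for n in alive}
    outdeg = {n: len(succ[n] & alive) for n in alive}
    stack = [n for n in alive if indeg[n] < k or outdeg[n] < l]
    while stack:
        n = stack.pop()
        if n not in alive:
            continue
        alive.discard(n)
        for m in succ[n]:
            if m in alive:
                indeg[m] -= 1
                if indeg[m] < k:
                    stack.append(m)
        for m in pred[n]:
            if m in alive:
                outdeg[m] -= 1
                if outdeg[m] < l:
                    stack.append(m)
    return alive


def dcore(c: Connectome, k: int, l: int) -> set[str]:
    """Node set of the D-core(k, l); empty set if none exists."""
    if k < 0 or l < 0:
        raise ValueError("k and l must be non-negative")
    succ, pred = _adjacency(c)
    return _prune(succ, pred, set(succ), k, l)


@dataclass
class DCoreMatrix:
    """Grid of D-core sizes over (k, l) with memberships and frontier.

    ``sizes[k, l]`` is the node count of D-core(k, l) for
    0 <= k <= k_max + 1 and 0 <= l <= l_max + 1, where k_max (l_max) is
    the largest k (l) at which D-core(k, 0) (D-core(0, l)) is non-empty.
    The final row and column are therefore all zero.
    """

    sizes: np.ndarray
    membership: dict[tuple[int, int], frozenset] = field(repr=False)
    k_max: int = 0
    l_max: int = 0

    def frontier_cells(self) -> list[tuple[int, int]]:
        """Pareto-maximal non-empty cells: no other non-empty cell
        dominates them in both k and l."""
        nonempty = list(zip(*np.nonzero(self.sizes)))
        cells = []
        for (k, l) in nonempty:
            dominated = any(
                (k2 >= k and l2 >= l and (k2, l2) != (k, l))
                for k2, l2 in nonempty
            )
            if not dominated:
                cells.append((int(k), int(l)))
        return sorted(cells)

    def frontier_core(self) -> set[str]:
        """Union of members over the frontier cells — the structural core."""
        out: set[str] = set()
        for cell in self.frontier_cells():
            out |= self.membership[cell]
        return out

    def percentages(self) -> np.ndarray:
        """Cell sizes as percentages of the full node count."""
        total = self.sizes[0, 0]
        return 100.0 * self.sizes / total if total else self.sizes.astype(float)


def dcore_matrix(c: Connectome) -> DCoreMatrix:
    """Compute the full D-core matrix of a connectome.

    Exploits nesting — D-core(k, l) contains D-core(k+1, l) and
    D-core(k, l+1) — by pruning each cell from its neighbor's members
    instead of from the whole graph.
    """
    succ, pred = _adjacency(c)
    all_nodes = set(succ)

    # k_max: last non-empty D-core(k, 0) walking down the k axis.
    col0: list[set] = [all_nodes]
    while col0[-1]:
        col0.append(_prune(succ, pred, col0[-1], len(col0), 0))
    k_max = len(col0) - 2  # last index with a non-empty set

    row0: list[set] = [all_nodes]
    while row0[-1]:
        row0.append(_prune(succ, pred, row0[-1], 0, len(row0)))
    l_max = len(row0) - 2

    nk, nl = k_max + 2, l_max + 2
    sizes = np.zeros((nk, nl), dtype=int)
    membership: dict[tuple[int, int], frozenset] = {}
    for k in range(nk):
        current = col0[k] if k < len(col0) else set()
        for l in range(nl):
            if l > 0:
                current = _prune(succ, pred, current, k, l)
            membership[(k, l)] = frozenset(current)
            sizes[k, l] = len(current)
    return DCoreMatrix(sizes, membership, k_max=k_max, l_max=l_max)


def frontier_dcores(
    m: DCoreMatrix,
) -> tuple[list[tuple[int, int]], set[str]]:
    """Frontier cells and the union of their member nodes."""
    cells = m.frontier_cells()
    return cells, m.frontier_core()


@dataclass
class CoreAssignment:
    """Per-node core index from a one-dimensional decomposition.

    For the k-core variant the index is the classical core number on
    total (in + out) degree; for the s-core variant it is the largest
    observed-strength threshold at which the node still survives.
    """

    levels: dict[str, float]
    variant: str

    def core_at(self, level: float) -> set[str]:
        return {n for n, s in self.levels.items() if s >= level}

    def max_core(self) -> set[str]:
        top = max(self.levels.values(), default=0)
        return self.core_at(top)


def _peel_levels(
    c: Connectome, score: str, thresholds: Iterable[float]
) -> dict[str, float]:
    """Generic threshold sweep: level = max threshold survived."""
    weight = "weight" if score == "strength" else None
    levels = {n: 0.0 for n in c.graph.nodes}
    g = c.graph.copy()
    g.remove_edges_from(nx_selfloops(g))
    for s in sorted(thresholds):
        while True:
            doomed = [n for n, d in g.degree(weight=weight) if d < s]
            if not doomed:
                break
            g.remove_nodes_from(doomed)
        if g.number_of_nodes() == 0:
            break
        for n in g.nodes:
            levels[n] = float(s)
    return levels


def nx_selfloops(g) -> list:
    return [(u, v) for u, v in g.edges if u == v]


def kcore_numbers(c: Connectome) -> CoreAssignment:
    """Classical core numbers by peeling on total degree."""
    max_deg = max((d for _, d in c.graph.degree()), default=0)
    levels = _peel_levels(c, "degree", range(1, max_deg + 1))
    return CoreAssignment({n: float(v) for n, v in levels.items()},
                          variant="kcore_total_degree")


def score_numbers(c: Connectome) -> CoreAssignment:
    """s-core levels by peeling on total strength (weighted degree).

    Thresholds are the sorted set of observed node strengths — a finite,
    exact sweep sufficient for ranking nodes (or cell types) by how
    deep in the weighted core they sit.
    """
    for _, _, d in c.graph.edges(data=True):
        if d.get("weight", 1) <= 0:
            raise ValueError("s-core requires positive edge weights")
    strengths = sorted({s for _, s in c.graph.degree(weight="weight")})
    levels = _peel_levels(c, "strength", [s for s in strengths if s > 0])
    return CoreAssignment(levels, variant="score_weighted")
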