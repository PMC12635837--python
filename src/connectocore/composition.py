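"""Neighbor-set cell-type composition, diversity indices, type matrices.

Given a seed population (typically the structural core), these tools
extract its predecessors/successors at first or second order, profile
their cell-type frequencies, quantify diversity with normalized Shannon
and Simpson indices, and build the type-to-type connection-probability
matrix used to analyze the network of cell types.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .connectome import Connectome, UNASSIGNED
from .cores import CoreAssignment, score_numbers


def neighbor_set(
    c: Connectome,
    seeds: Iterable[str],
    direction: str = "predecessors",
    order: int = 1,
    exclude_seeds: bool = True,
) -> set[str]:
    """Distinct neighbors of a seed set at order 1 or 2.

    Order 1 is the union of in-neighbors (``predecessors``) or
    out-neighbors (``successors``) of the seeds; order 2 applies the
    same step again to the order-1 set (predecessors-of-predecessors or
    successors-of-successors).  Neurons are counted as distinct nodes,
    not synapse-weighted.  ``exclude_seeds`` removes the seeds from the
    returned set.
    """
    seed_set = set(seeds)
    if not seed_set:
        raise ValueError("empty seed set")
    missing = seed_set - set(c.graph.nodes)
    if missing:
        raise ValueError(f"seed(s) not in graph: {sorted(missing)[:5]}")
    if direction not in {"predecessors", "successors"}:
        raise ValueError("direction must be 'predecessors' or 'successors'")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")

    step = (
        c.graph.predecessors if direction == "predecessors" else c.graph.successors
    )

    def expand(nodes: set[str]) -> set[str]:
        out: set[str] = set()
        for n in nodes:
            out.update(step(n))
        return out

    result = expand(seed_set)
    if order == 2:
        result = expand(result)
    if exclude_seeds:
        result -= seed_set
    return result


@dataclass
class CompositionProfile:
    """Normalized cell-type frequency vector for a neuron set."""

    counts: dict[str, int]
    freq: dict[str, float]
    n_types: int
    n_neurons: int
    order: int | None = None
    direction: str | None = None


def type_frequencies(
    nodes: Iterable[str],
    annotation: Mapping[str, str],
    vocabulary: Sequence[str] | None = None,
) -> CompositionProfile:
    """Cell-type counts and normalized frequencies of a neuron set.

    Unannotated neurons fall into ``"unassigned"``.  ``vocabulary``
    fixes the type universe (so n counts all types studied, observed or
    not); by default n is the number of types observed in the set.
    """
    counts: dict[str, int] = {}
    total = 0
    for n in sorted(nodes):  # deterministic dict order for set inputs
        label = annotation.get(n, UNASSIGNED) or UNASSIGNED
        counts[label] = counts.get(label, 0) + 1
        total += 1
    if vocabulary is not None:
        for label in vocabulary:
            counts.setdefault(label, 0)
        n_types = len(vocabulary)
    else:
        n_types = sum(1 for v in counts.values() if v > 0)
    freq = {t: (v / total if total else 0.0) for t, v in counts.items()}
    return CompositionProfile(counts, freq, n_types, total)


def shannon_diversity(profile: CompositionProfile) -> float:
    """Normalized Shannon entropy, H = -sum p_i ln p_i / ln n, in [0, 1].

    1 for a uniform profile over the vocabulary, 0 for a single type
    (n = 1 returns 0 by convention).
    """
    n = profile.n_types
    if n <= 1:
        return 0.0
    p = np.array([v for v in profile.freq.values() if v > 0])
    return float(-(p * np.log(p)).sum() / np.log(n))


def simpson_diversity(
    profile: CompositionProfile, form: str = "inverse_normalized"
) -> float:
    """Simpson concentration-based diversity.

    ``as_printed`` returns n * sum(p_i^2), which is >= 1 and *decreases*
    with diversity down to 1 at uniformity.  ``inverse_normalized``
    (default) returns 1 / (n * sum(p_i^2)), which lies in (0, 1] and
    increases with diversity, matching the reading that higher values
    mean greater diversity.
    """
    n = profile.n_types
    if n < 1 or profile.n_neurons == 0:
        return float("nan")
    s2 = float(sum(v * v for v in profile.freq.values()))
    printed = n * s2
    if form == "as_printed":
        return printed
    if form == "inverse_normalized":
        return 1.0 / printed
    raise ValueError(f"unknown Simpson form {form!r}")


@dataclass
class TypeMatrix:
    """Type-to-type connection probabilities and raw counts.

    ``P.loc[i, j]`` is the probability of a directed connection from a
    neuron of type i to one of type j: E_ij / (N_i * N_j) off-diagonal
    and E_ii / (N_i (N_i - 1)) on the diagonal (self-connections of a
    type exclude self-loops of neurons).  Diagonals for singleton types
    are NaN, never a division by zero.
    """

    labels: list[str]
    P: pd.DataFrame
    E_counts: pd.DataFrame
    N_counts: pd.Series

    def as_connectome(self) -> Connectome:
        """The weighted cell-type digraph (weights = probabilities)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.labels)
        for i in self.labels:
            for j in self.labels:
                w = self.P.loc[i, j]
                if pd.notna(w) and w > 0:
                    g.add_edge(i, j, weight=float(w))
        return Connectome(g, {t: t for t in self.labels})


def type_connectivity_matrix(
    c: Connectome, annotation: Mapping[str, str] | None = None
) -> TypeMatrix:
    """Build the cell-type connection-probability matrix of a connectome."""
    ann = annotation if annotation is not None else c.type_of
    label_of = {n: (ann.get(n, UNASSIGNED) or UNASSIGNED) for n in c.graph.nodes}
    labels = sorted(set(label_of.values()))
    n_counts = pd.Series(
        {t: sum(1 for v in label_of.values() if v == t) for t in labels}
    )

    e = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for u, v in c.graph.edges:
        if u == v:
            continue
        e.loc[label_of[u], label_of[v]] += 1

    p = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for i in labels:
        for j in labels:
            if i == j:
                denom = n_counts[i] * (n_counts[i] - 1)
            else:
                denom = n_counts[i] * n_counts[j]
            if denom > 0:
                p.loc[i, j] = e.loc[i, j] / denom
    return TypeMatrix(labels, p, e, n_counts)


def type_score(
    tm: TypeMatrix, variant: str = "total"
) -> CoreAssignment:
    """s-core levels of the cell-type network.

    ``variant`` selects which strength drives the peeling: ``"in"``,
    ``"out"``, or ``"total"``.  Weights are the connection
    probabilities P_ij.
    """
    c = tm.as_connectome()
    if variant == "total":
        return score_numbers(c)
    if variant not in {"in", "out"}:
        raise ValueError("variant must be 'in', 'out', or 'total'")

    # directional s-core: peel on in- or out-strength only
    g = c.graph.copy()
    deg_fn = (
        (lambda h: dict(h.in_degree(weight="weight")))
        if variant == "in"
        else (lambda h: dict(h.out_degree(weight="weight")))
    )
    strengths = sorted({s for s in deg_fn(g).values() if s > 0})
    levels = {n: 0.0 for n in g.nodes}
    for s in strengths:
        while True:
            d = deg_fn(g)
            doomed = [n for n, v in d.items() if v < s]
            if not doomed:
                break
            g.remove_nodes_from(doomed)
        if g.number_of_nodes() == 0:
            break
        for n in g.nodes:
            levels[n] = float(s)
    return CoreAssignment(levels, variant=f"score_{variant}_strength")
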