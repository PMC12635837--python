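"""Synthetic labeled digraphs with the structure the analyses assume.

Real whole-brain connectomes are large external datasets; the generators
here emulate the statistical features the pipeline depends on — a densely
interconnected planted core confined to one cell type, heavy-tailed
in/out-degree sequences drawn from discrete Weibull or power-law models,
and tunable overall density — so that every downstream stage is testable
without any download.

The generators make no attempt to match a real connectome's joint
in/out-degree correlation, reciprocity, or spatial embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .connectome import Connectome


@dataclass(frozen=True)
class DegreeModel:
    """Discrete degree-distribution model for sequence sampling.

    ``family`` is ``"weibull"`` (params ``lam`` scale, ``beta`` shape;
    P(k) ∝ k^(beta-1) exp(-lam k^beta)) or ``"powerlaw"`` (params
    ``alpha`` > 1, ``x_min``; P(k) ∝ k^(-alpha)).
    """

    family: str
    lam: float = 0.025
    beta: float = 1.3
    alpha: float = 2.5
    x_min: int = 1

    def pmf(self, k_cap: int) -> tuple[np.ndarray, np.ndarray]:
        """Normalized mass function over support x_min..k_cap."""
        k = np.arange(self.x_min, k_cap + 1, dtype=float)
        if self.family == "weibull":
            if self.lam <= 0 or self.beta <= 0:
                raise ValueError("weibull requires lam > 0 and beta > 0")
            logp = (self.beta - 1) * np.log(k) - self.lam * k**self.beta
        elif self.family == "powerlaw":
            if self.alpha <= 1:
                raise ValueError("power-law exponent must exceed 1 to normalize")
            logp = -self.alpha * np.log(k)
        else:
            raise ValueError(f"unknown family {self.family!r}")
        p = np.exp(logp - logp.max())
        return k.astype(int), p / p.sum()

    def mean(self, k_cap: int = 100_000) -> float:
        k, p = self.pmf(k_cap)
        return float((k * p).sum())


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters for the planted-core block generator.

    The defaults are larval-like in scale: a couple hundred neurons, a
    20-neuron core of one cell type wired at 0.6 internal density, a
    sparse 0.01 periphery, and 0.05 core-periphery coupling.
    """

    n_nodes: int = 200
    type_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"KC": 0.3, "MBON": 0.2, "MBIN": 0.2, "PN": 0.3}
    )
    n_core: int = 20
    core_label: str = "KC"
    p_core_core: float = 0.6
    p_core_periph: float = 0.05
    p_periph_periph: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_core_core, self.p_core_periph, self.p_periph_periph):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"block probability {p} outside [0, 1]")
        if self.n_core > self.n_nodes:
            raise ValueError("n_core exceeds n_nodes")
        total = sum(self.type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type proportions sum to {total}, not 1")


def generate_planted_core(spec: SyntheticSpec) -> Connectome:
    """Directed block-model graph with a dense core confined to one type.

    Each ordered pair (i, j), i != j, is an edge independently with the
    block probability given by core membership.  Core nodes are the first
    ``n_core`` ids and all carry ``core_label``; periphery labels are
    sampled i.i.d. from ``type_proportions``.  Reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n, nc = spec.n_nodes, spec.n_core
    is_core = np.zeros(n, dtype=bool)
    is_core[:nc] = True

    p = np.full((n, n), spec.p_periph_periph)
    p[np.ix_(is_core, is_core)] = spec.p_core_core
    p[np.ix_(is_core, ~is_core)] = spec.p_core_periph
    p[np.ix_(~is_core, is_core)] = spec.p_core_periph
    np.fill_diagonal(p, 0.0)

    adj = rng.random((n, n)) < p
    names = [f"n{i:04d}" for i in range(n)]
    g = nx.DiGraph()
    g.add_nodes_from(names)
    src, tgt = np.nonzero(adj)
    g.add_edges_from(
        ((names[i], names[j], {"weight": 1}) for i, j in zip(src, tgt))
    )

    labels = list(spec.type_proportions)
    probs = np.array([spec.type_proportions[t] for t in labels])
    drawn = rng.choice(labels, size=n - nc, p=probs)
    type_of = {names[i]: spec.core_label for i in range(nc)}
    type_of.update({names[nc + i]: str(t) for i, t in enumerate(drawn)})
    return Connectome(g, type_of)


def planted_core_nodes(spec: SyntheticSpec) -> set[str]:
    """Node ids of the planted core for a given spec."""
    return {f"n{i:04d}" for i in range(spec.n_core)}


def sample_degree_sequence(
    model: DegreeModel,
    n: int,
    seed: int,
    k_cap: int | None = None,
    fix_parity: bool = False,
) -> np.ndarray:
    """Draw ``n`` i.i.d. degrees from the discrete model by inverse CDF.

    Support runs from the model's x_min up to ``k_cap`` (default n - 1,
    since a simple graph's degree cannot exceed that).  ``fix_parity``
    bumps the last element by +1 if the sum is odd, for pairing uses.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    k, p = model.pmf(k_cap if k_cap is not None else max(n - 1, model.x_min))
    rng = np.random.default_rng(seed)
    seq = rng.choice(k, size=n, p=p)
    if fix_parity and seq.sum() % 2:
        seq[-1] += 1
    return seq


def directed_configuration_graph(
    in_seq: Sequence[int],
    out_seq: Sequence[int],
    seed: int,
) -> tuple[Connectome, dict[str, int]]:
    """Stub-matching realization of a directed degree sequence pair.

    Self-loops and parallel edges created by the matching are dropped
    (standard practice for configuration-model surrogates); the returned
    diagnostics count the losses so callers can bound the distortion.
    """
    s_in, s_out = int(np.sum(in_seq)), int(np.sum(out_seq))
    if s_in != s_out:
        raise ValueError(
            f"in-degree sum {s_in} does not match out-degree sum {s_out}"
        )
    if len(in_seq) != len(out_seq):
        raise ValueError("in_seq and out_seq must have the same length")

    rng = np.random.default_rng(seed)
    heads = np.repeat(np.arange(len(in_seq)), in_seq)
    tails = np.repeat(np.arange(len(out_seq)), out_seq)
    rng.shuffle(heads)

    names = [f"n{i:04d}" for i in range(len(in_seq))]
    g = nx.DiGraph()
    g.add_nodes_from(names)
    self_loops = parallels = 0
    for t, h in zip(tails, heads):
        if t == h:
            self_loops += 1
        elif g.has_edge(names[t], names[h]):
            parallels += 1
        else:
            g.add_edge(names[t], names[h], weight=1)
    diag = {"self_loops_dropped": self_loops, "parallel_dropped": parallels}
    return Connectome(g, {}), diag


def assign_type_labels(
    c: Connectome, proportions: Mapping[str, float], seed: int
) -> Connectome:
    """Attach i.i.d. cell-type labels drawn from ``proportions``."""
    labels = list(proportions)
    probs = np.array([proportions[t] for t in labels], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    nodes = sorted(c.graph.nodes)
    drawn = rng.choice(labels, size=len(nodes), p=probs)
    return c.with_labels({n: str(t) for n, t in zip(nodes, drawn)})
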