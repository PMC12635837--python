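"""Directed connectome container and synapse-table I/O.

A connectome is a directed graph whose nodes are neurons (opaque string
ids) and whose edges are synaptic connections carrying a positive integer
synapse count.  Parallel records in a raw synapse table are aggregated by
summation; self-loops are dropped by default because the density and
rich-club denominators downstream assume ``i != j``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

UNASSIGNED = "unassigned"

#: Built-in column-name presets for common synapse-table layouts.
DIALECTS: dict[str, dict[str, str | None]] = {
    "generic": {"source": "source", "target": "target", "weight": "weight"},
    "larval": {"source": "pre", "target": "post", "weight": "weight"},
    "flywire": {
        "source": "pre_root_id",
        "target": "post_root_id",
        "weight": "syn_count",
    },
}


class FormatError(ValueError):
    """Raised when an input table does not match the expected layout."""


@dataclass
class Connectome:
    """A directed, simplified graph of neurons with cell-type labels.

    Parameters
    ----------
    graph
        ``networkx.DiGraph`` with string node ids and integer ``weight``
        edge attributes (synapse counts).
    type_of
        Mapping from node id to cell-type label.  Nodes absent from the
        mapping are reported as ``"unassigned"``.
    self_loops_dropped
        Number of self-loop records removed while building the graph.
    """

    graph: nx.DiGraph
    type_of: dict[str, str] = field(default_factory=dict)
    self_loops_dropped: int = 0

    # -- basic accessors -------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def label(self, node: str) -> str:
        return self.type_of.get(node, UNASSIGNED) or UNASSIGNED

    def weight(self, u: str, v: str) -> int:
        return self.graph.edges[u, v]["weight"]

    def density(self) -> float:
        """Directed density E / (N (N - 1))."""
        n = self.n_nodes
        if n < 2:
            return 0.0
        return self.n_edges / (n * (n - 1))

    def in_degree(self) -> dict[str, int]:
        return dict(self.graph.in_degree())

    def out_degree(self) -> dict[str, int]:
        return dict(self.graph.out_degree())

    def total_degree(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def total_strength(self) -> dict[str, float]:
        return dict(self.graph.degree(weight="weight"))

    def copy(self) -> "Connectome":
        return Connectome(
            self.graph.copy(), dict(self.type_of), self.self_loops_dropped
        )

    def with_labels(self, type_of: Mapping[str, str]) -> "Connectome":
        return Connectome(self.graph, dict(type_of), self.self_loops_dropped)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Connectome):
            return NotImplemented
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        mine = {(u, v): d["weight"] for u, v, d in self.graph.edges(data=True)}
        theirs = {(u, v): d["weight"] for u, v, d in other.graph.edges(data=True)}
        return mine == theirs


def from_edges(
    edges: Iterable[tuple[str, str, int]],
    nodes: Iterable[str] = (),
    type_of: Mapping[str, str] | None = None,
    keep_self_loops: bool = False,
) -> Connectome:
    """Build a :class:`Connectome` from ``(u, v, weight)`` records.

    Duplicate ordered pairs are summed; self-loops are dropped (and
    counted) unless ``keep_self_loops``.
    """
    g = nx.DiGraph()
    g.add_nodes_from(str(n) for n in nodes)
    dropped = 0
    for u, v, w in edges:
        u, v = str(u), str(v)
        if u == v and not keep_self_loops:
            dropped += 1
            g.add_node(u)
            continue
        if g.has_edge(u, v):
            g.edges[u, v]["weight"] += int(w)
        else:
            g.add_edge(u, v, weight=int(w))
    return Connectome(g, dict(type_of or {}), self_loops_dropped=dropped)


def read_edge_table(
    path: str | Path,
    dialect: str | Mapping[str, str | None] = "generic",
    min_weight: int = 1,
    keep_self_loops: bool = False,
) -> Connectome:
    """Read a delimited synapse table into a :class:`Connectome`.

    Parameters
    ----------
    path
        CSV or TSV file with a header row.
    dialect
        Preset name (``generic``, ``larval``, ``flywire``) or a mapping
        with keys ``source``, ``target`` and optionally ``weight``.  A
        missing/None weight column means every record counts one synapse.
    min_weight
        Minimum aggregated synapse count for an edge to be kept (default
        1: any synapse makes an edge).
    """
    cols = DIALECTS[dialect] if isinstance(dialect, str) else dict(dialect)
    src_col, tgt_col = cols["source"], cols["target"]
    w_col = cols.get("weight")

    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)

    for col in (src_col, tgt_col):
        if col not in df.columns:
            raise FormatError(f"required column {col!r} not found in {path.name}")
    if w_col is not None and w_col not in df.columns:
        w_col = None  # tolerate absent optional weight column

    if w_col is None:
        weights = pd.Series([1] * len(df), index=df.index)
    else:
        weights = pd.to_numeric(df[w_col], errors="coerce")
        bad = df.index[weights.isna() | (weights <= 0)]
        if len(bad):
            row = int(bad[0]) + 2  # 1-based with header
            raise FormatError(
                f"non-positive or non-numeric weight at row {row} of {path.name}"
            )
        weights = weights.astype(int)

    c = from_edges(
        zip(df[src_col], df[tgt_col], weights),
        keep_self_loops=keep_self_loops,
    )
    if min_weight > 1:
        drop = [
            (u, v)
            for u, v, d in c.graph.edges(data=True)
            if d["weight"] < min_weight
        ]
        c.graph.remove_edges_from(drop)
    return c


def read_annotations(
    path: str | Path,
    id_column: str = "node_id",
    label_column: str = "label",
) -> dict[str, str]:
    """Read a node-annotation table into a node-id -> label mapping.

    Empty labels map to ``"unassigned"``.  Duplicate ids with conflicting
    labels raise an error naming the offenders.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in (id_column, label_column):
        if col not in df.columns:
            raise FormatError(f"required column {col!r} not found in {path.name}")

    mapping: dict[str, str] = {}
    conflicts: list[str] = []
    for node, raw in zip(df[id_column], df[label_column]):
        node = str(node)
        label = UNASSIGNED if pd.isna(raw) or str(raw).strip() == "" else str(raw)
        if node in mapping and mapping[node] != label:
            conflicts.append(node)
        mapping[node] = label
    if conflicts:
        raise FormatError(
            "conflicting labels for node id(s): " + ", ".join(sorted(set(conflicts)))
        )
    return mapping


def binarize(c: Connectome) -> Connectome:
    """Return a copy with every synapse count set to 1.

    Node and edge sets (hence density) are unchanged; the input is left
    unmodified.
    """
    out = c.copy()
    nx.set_edge_attributes(out.graph, 1, "weight")
    return out


def write_graph(
    c: Connectome, path: str | Path, format: str = "edge-csv"
) -> Path:
    """Write a connectome as an edge CSV or GraphML file.

    The edge-CSV form round-trips through :func:`read_edge_table`
    (isolated nodes excepted, as an edge list cannot represent them).
    """
    path = Path(path)
    if format == "edge-csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "weight"])
            for u, v, d in c.graph.edges(data=True):
                writer.writerow([u, v, d["weight"]])
    elif format == "graphml":
        g = c.graph.copy()
        for node in g.nodes:
            g.nodes[node]["cell_type"] = c.label(node)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def write_annotations(
    type_of: Mapping[str, str],
    path: str | Path,
    id_column: str = "node_id",
    label_column: str = "label",
) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([id_column, label_column])
        for node in sorted(type_of):
            writer.writerow([node, type_of[node]])
    return path
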