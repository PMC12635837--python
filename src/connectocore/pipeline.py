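"""Config-driven orchestration of the full comparison workflow.

A run takes one or two annotated digraphs (from synapse tables or the
built-in synthetic generator), executes the enabled stages — structural
summary, degree fitting, D-core extraction, rich-club analysis,
neighbor composition/diversity, targeted attack, type matrix — and
writes CSV/JSON artifacts plus a side-by-side comparison table when two
networks are given.

Stage seeds are derived from the global seed through fixed per-stage
identifiers, so enabling or adding stages never shifts another stage's
random stream, and a stage failure is isolated and logged without
aborting independent stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import composition as comp
from . import cores, degree_fit, richclub, topology
from .connectome import Connectome, read_annotations, read_edge_table, write_graph
from .synthetic import SyntheticSpec, generate_planted_core

logger = logging.getLogger("connectocore.pipeline")

SCHEMA_VERSION = "1.0"

ALL_STAGES = (
    "summary", "fit", "dcore", "richclub", "composition", "attack", "typematrix",
)

#: Fixed identifiers feeding the per-stage seed derivation.
_STAGE_IDS = {name: i + 1 for i, name in enumerate(ALL_STAGES)}


def stage_seed(global_seed: int, stage: str, network_index: int = 0) -> int:
    """Deterministic per-stage, per-network seed below 2**31."""
    ss = np.random.SeedSequence([global_seed, _STAGE_IDS[stage], network_index])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class NetworkSource:
    """One input network: a synapse table on disk or a synthetic spec."""

    name: str
    edge_path: str | None = None
    annotation_path: str | None = None
    dialect: str = "generic"
    id_column: str = "node_id"
    label_column: str = "label"
    synthetic: Mapping[str, Any] | None = None

    def load(self) -> Connectome:
        if self.synthetic is not None:
            return generate_planted_core(SyntheticSpec(**dict(self.synthetic)))
        if self.edge_path is None:
            raise ValueError(f"network {self.name!r} has no edge table or spec")
        c = read_edge_table(self.edge_path, dialect=self.dialect)
        if self.annotation_path:
            ann = read_annotations(
                self.annotation_path, self.id_column, self.label_column
            )
            c = c.with_labels(ann)
        return c


@dataclass
class RunConfig:
    """Everything a pipeline run needs, reproducible from the seed."""

    networks: list[NetworkSource]
    outdir: str = "connectocore_out"
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in ALL_STAGES}
    )
    seed: int = 0
    n_nulls_richclub: int = 20
    n_nulls_clustering: int = 10
    n_nulls_modularity: int = 5
    n_louvain_runs: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        networks = [NetworkSource(**n) for n in raw.pop("networks")]
        stages = {s: True for s in ALL_STAGES}
        stages.update(raw.pop("stages", {}))
        return cls(networks=networks, stages=stages, **raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _dump_json(obj: Any, path: Path) -> None:
    def default(o: Any) -> Any:
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=default))


def _fit_payload(f: degree_fit.DegreeFit) -> dict[str, Any]:
    return {
        "family": f.family,
        "params": f.params,
        "x_min": f.x_min,
        "ks_distance": f.ks_distance,
        "n_tail": f.n_tail,
        "loglik": f.loglik,
        "direction": f.direction,
    }


def _run_network(
    src: NetworkSource, cfg: RunConfig, index: int, outdir: Path
) -> dict[str, Any]:
    c = src.load()
    results: dict[str, Any] = {
        "name": src.name, "n_nodes": c.n_nodes, "n_edges": c.n_edges,
        "density": c.density(), "errors": {},
    }
    on = cfg.stages

    def guarded(stage: str, fn) -> None:
        if not on.get(stage, False):
            return
        try:
            fn()
        except Exception as exc:  # stage isolation by contract
            logger.exception("stage %s failed for %s", stage, src.name)
            results["errors"][stage] = f"{type(exc).__name__}: {exc}"

    # --- summary ---------------------------------------------------------
    def do_summary() -> None:
        s = topology.summarize(
            c,
            n_nulls_clustering=cfg.n_nulls_clustering,
            n_nulls_modularity=cfg.n_nulls_modularity,
            n_louvain_runs=cfg.n_louvain_runs,
            seed=stage_seed(cfg.seed, "summary", index),
        )
        results["summary"] = dataclasses.asdict(s)
        _dump_json(results["summary"], outdir / "summary.json")

    guarded("summary", do_summary)

    # --- degree fits -----------------------------------------------------
    def do_fit() -> None:
        payload = {}
        for direction, degs in (
            ("in", list(c.in_degree().values())),
            ("out", list(c.out_degree().values())),
        ):
            rep = degree_fit.compare_families(degs, direction=direction)
            payload[direction] = {
                "weibull": _fit_payload(rep.weibull),
                "powerlaw": _fit_payload(rep.powerlaw),
                "preferred_by_ks": rep.preferred_by_ks,
                "preferred_by_loglik": rep.preferred_by_loglik,
            }
            payload[direction]["powerlaw_scanned"] = _fit_payload(
                degree_fit.fit_powerlaw(degs, direction=direction)
            )
        results["fit"] = payload
        _dump_json(payload, outdir / "degree_fits.json")

    guarded("fit", do_fit)

    # --- D-core ----------------------------------------------------------
    def do_dcore() -> None:
        m = cores.dcore_matrix(c)
        cells, core_nodes = cores.frontier_dcores(m)
        pd.DataFrame(
            m.sizes,
            index=pd.Index(range(m.sizes.shape[0]), name="k"),
            columns=pd.Index(range(m.sizes.shape[1]), name="l"),
        ).to_csv(outdir / "dcore_matrix.csv")
        pd.DataFrame({"node_id": sorted(core_nodes)}).assign(
            label=lambda d: d.node_id.map(c.label)
        ).to_csv(outdir / "core_nodes.csv", index=False)
        results["dcore"] = {
            "k_max": m.k_max, "l_max": m.l_max,
            "frontier_cells": cells, "core_size": len(core_nodes),
            "core_density": (
                richclub.subgraph_density(c, core_nodes)
                if len(core_nodes) >= 2 else float("nan")
            ),
        }

    guarded("dcore", do_dcore)

    # --- rich club -------------------------------------------------------
    def do_richclub() -> None:
        payload = {}
        for direction in ("in", "out"):
            curve = richclub.normalized_rcc(
                c, direction, n_nulls=cfg.n_nulls_richclub,
                seed=stage_seed(cfg.seed, "richclub", index),
            )
            pd.DataFrame(
                {
                    "k": curve.k_values, "raw": curve.raw,
                    "null_mean": curve.null_mean, "null_sd": curve.null_sd,
                    "normalized": curve.normalized,
                }
            ).to_csv(outdir / f"richclub_{direction}.csv", index=False)
            members = richclub.rc_membership(curve, c)
            payload[direction] = {
                "first_crossing": curve.first_crossing(),
                "n_members": len(members),
                "member_fraction": len(members) / c.n_nodes if c.n_nodes else 0.0,
                "rc_density": (
                    richclub.subgraph_density(c, members)
                    if len(members) >= 2 else float("nan")
                ),
            }
            pd.DataFrame({"node_id": sorted(members)}).to_csv(
                outdir / f"rc_members_{direction}.csv", index=False
            )
        payload["graph_density"] = c.density()
        results["richclub"] = payload
        _dump_json(payload, outdir / "richclub.json")

    guarded("richclub", do_richclub)

    # --- composition around the core --------------------------------------
    def do_composition() -> None:
        core_nodes = cores.dcore_matrix(c).frontier_core()
        if not core_nodes:
            results["composition"] = {"note": "empty frontier core"}
            return
        vocab = sorted(set(c.label(n) for n in c.graph.nodes))
        payload: dict[str, Any] = {"core_size": len(core_nodes)}
        rows = []
        for direction in ("predecessors", "successors"):
            for order in (1, 2):
                nbrs = comp.neighbor_set(c, core_nodes, direction, order)
                prof = comp.type_frequencies(nbrs, c.type_of, vocabulary=vocab)
                key = f"{direction}_order{order}"
                payload[key] = {
                    "n_neurons": prof.n_neurons,
                    "shannon": comp.shannon_diversity(prof),
                    "simpson_inverse_normalized": comp.simpson_diversity(prof),
                    "simpson_as_printed": comp.simpson_diversity(
                        prof, form="as_printed"
                    ),
                }
                for t, f_ in sorted(prof.freq.items()):
                    rows.append(
                        {"set": key, "cell_type": t, "count": prof.counts[t],
                         "freq": f_}
                    )
        pd.DataFrame(rows).to_csv(outdir / "composition_profiles.csv", index=False)
        results["composition"] = payload
        _dump_json(payload, outdir / "diversity.json")

    guarded("composition", do_composition)

    # --- targeted attack ---------------------------------------------------
    def do_attack() -> None:
        core_nodes = cores.dcore_matrix(c).frontier_core()
        res = topology.targeted_attack(c, core_nodes)
        rng = np.random.default_rng(stage_seed(cfg.seed, "attack", index))
        random_set = set(
            rng.choice(sorted(c.graph.nodes), size=len(res.removed), replace=False)
        ) if res.removed else set()
        rand = topology.targeted_attack(c, random_set)
        payload = {
            "core_clustering_ratio": res.clustering_ratio,
            "core_efficiency_ratio": res.efficiency_ratio,
            "n_removed": len(res.removed),
            "random_clustering_ratio": rand.clustering_ratio,
            "random_efficiency_ratio": rand.efficiency_ratio,
        }
        results["attack"] = payload
        _dump_json(payload, outdir / "attack.json")

    guarded("attack", do_attack)

    # --- type matrix -------------------------------------------------------
    def do_typematrix() -> None:
        tm = comp.type_connectivity_matrix(c)
        tm.P.to_csv(outdir / "type_matrix.csv")
        tm.E_counts.to_csv(outdir / "type_edge_counts.csv")
        scores = {
            variant: comp.type_score(tm, variant=variant).levels
            for variant in ("in", "out", "total")
        }
        _dump_json(scores, outdir / "type_scores.json")
        results["typematrix"] = {"n_types": len(tm.labels)}

    guarded("typematrix", do_typematrix)

    write_graph(c, outdir / "graph.csv", format="edge-csv")
    return results


_COMPARISON_FIELDS = (
    ("n_nodes", lambda r: r.get("n_nodes")),
    ("n_edges", lambda r: r.get("n_edges")),
    ("density", lambda r: r.get("density")),
    ("clustering_normalized", lambda r: r.get("summary", {}).get(
        "mean_clustering_normalized")),
    ("modularity_normalized", lambda r: r.get("summary", {}).get(
        "modularity_normalized")),
    ("core_size", lambda r: r.get("dcore", {}).get("core_size")),
    ("core_density", lambda r: r.get("dcore", {}).get("core_density")),
    ("attack_efficiency_ratio", lambda r: r.get("attack", {}).get(
        "core_efficiency_ratio")),
)


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute all enabled stages for every configured network.

    Returns the report bundle (also written as ``manifest.json``); each
    numeric in the comparison table traces back to a stage output file
    in the per-network directory.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    per_network = []
    for i, src in enumerate(cfg.networks):
        ndir = outdir / src.name
        ndir.mkdir(parents=True, exist_ok=True)
        per_network.append(_run_network(src, cfg, i, ndir))

    bundle: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "stage_seeds": {
            f"{src.name}:{stage}": stage_seed(cfg.seed, stage, i)
            for i, src in enumerate(cfg.networks)
            for stage in ALL_STAGES
            if cfg.stages.get(stage)
        },
        "networks": per_network,
    }

    if len(per_network) == 2:
        rows = [
            {
                "quantity": name,
                per_network[0]["name"]: get(per_network[0]),
                per_network[1]["name"]: get(per_network[1]),
            }
            for name, get in _COMPARISON_FIELDS
        ]
        pd.DataFrame(rows).to_csv(outdir / "comparison.csv", index=False)

    _dump_json(bundle, outdir / "manifest.json")
    return bundle
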