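"""End-to-end comparative pipeline: deviation → ENM → PRS → networks → paths.

One config drives all stages so a full comparison (every pairwise
combination of the configured states) is reproducible from a single file.
The :class:`PipelineConfig` defaults carry the parameter set used for
ribosomal complexes: 15 Å elastic cutoff, γ = 1, 80% variance modes, Z > 2
effector/sensor threshold, 1,000 random forces, top 10% of network nodes.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import communication as comm
from . import deviation as dev
from . import enm, prs, rin
from .structures import CoarseGrainedStructure, map_chains, read_structure, write_structure

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_compare", "load_config"]


@dataclass
class PipelineConfig:
    """Validated parameters for a comparative run."""

    structures: list[dict]                    # [{"name": ..., "path": ...}, ...]
    reference_chains: list[str] = field(default_factory=list)
    chain_aliases: dict[str, dict[str, str]] = field(default_factory=dict)
    enm_cutoff: float = 15.0
    gamma: float = 1.0
    variance_fraction: float = 0.8
    flex_threshold: float = 2.0
    prs_mode: str = "analytic"                # analytic | montecarlo
    n_forces: int = 1000
    seed: int = 0
    prs_threshold: float = 2.0
    pair_threshold: float = 2.0
    network_cutoff: float = 8.0
    top_fraction: float = 0.10
    communication_cutoff: float = 15.0
    path_weighting: str = "commute"
    output_dir: str = "ribomech_out"

    def validate(self) -> None:
        names = [s["name"] for s in self.structures]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate structure names: {names}")
        if len(names) < 2:
            raise ValueError("need at least two structures to compare")
        for s in self.structures:
            if not Path(s["path"]).exists():
                raise FileNotFoundError(f"structure file {s['path']} does not exist")
        for val, what in [(self.prs_threshold, "prs_threshold"),
                          (self.pair_threshold, "pair_threshold"),
                          (self.flex_threshold, "flex_threshold"),
                          (self.enm_cutoff, "enm_cutoff"),
                          (self.network_cutoff, "network_cutoff")]:
            if not val > 0:
                raise ValueError(f"{what} must be > 0")
        if self.prs_mode not in ("analytic", "montecarlo"):
            raise ValueError(f"unknown prs_mode {self.prs_mode!r}")


def load_config(path) -> PipelineConfig:
    """Read a YAML pipeline config; unspecified keys keep preset defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _node_label(s: CoarseGrainedStructure, i: int) -> str:
    n = s.nodes[i]
    return f"{n.chain_id}:{n.residue_number}{n.icode}"


def _state_analysis(s: CoarseGrainedStructure, cfg: PipelineConfig, out: Path) -> dict:
    """ENM, flexibility, PRS and network tables for one state."""
    model = enm.build_hessian(s, cutoff=cfg.enm_cutoff, gamma=cfg.gamma)
    enm.compute_modes(model, variance_fraction=cfg.variance_fraction)
    profile = enm.square_fluctuations(model)
    pd.DataFrame({
        "node": [_node_label(s, i) for i in range(len(s))],
        "msf": profile.msf,
        "zscore": profile.zscore,
        "flexible": np.isin(np.arange(len(s)), profile.flexible),
    }).to_csv(out / f"{s.name}_flexibility.csv", index=False)

    if cfg.prs_mode == "montecarlo":
        result = prs.prs_montecarlo(model, n_forces=cfg.n_forces, seed=cfg.seed)
    else:
        result = prs.prs_analytic(model)
    effectors, sensors = prs.call_effectors_sensors(result, threshold=cfg.prs_threshold)
    pd.DataFrame({
        "node": [_node_label(s, i) for i in range(len(s))],
        "effectiveness": result.effectiveness,
        "sensitivity": result.sensitivity,
        "eff_z": result.eff_z,
        "sens_z": result.sens_z,
        "effector": np.isin(np.arange(len(s)), effectors),
        "sensor": np.isin(np.arange(len(s)), sensors),
    }).to_csv(out / f"{s.name}_prs_profiles.csv", index=False)
    sub = prs.subunit_matrix(result, s, pair_threshold=cfg.pair_threshold)
    pd.DataFrame(sub.interacting, index=sub.chains, columns=sub.chains).to_csv(
        out / f"{s.name}_subunit_matrix.csv"
    )

    graph = rin.build_rin(s, contact_cutoff=cfg.network_cutoff)
    cents = rin.centralities(graph)
    cents.insert(0, "node", [_node_label(s, i) for i in cents.index])
    cents.to_csv(out / f"{s.name}_centralities.csv", index=False)
    rin.write_edge_list(graph, s, out / f"{s.name}_edges.tsv")

    return {
        "structure": s, "model": model, "profile": profile, "prs": result,
        "effectors": effectors, "sensors": sensors, "graph": graph,
        "centralities": cents,
        "counts": {
            "nodes": len(s),
            "modes_selected": int(model.selected_modes.size),
            "effectors": int(effectors.size),
            "sensors": int(sensors.size),
            "edges": graph.number_of_edges(),
        },
    }


def _pair_analysis(sa: dict, sb: dict, cfg: PipelineConfig, out: Path) -> dict:
    a: CoarseGrainedStructure = sa["structure"]
    b: CoarseGrainedStructure = sb["structure"]
    aliases = cfg.chain_aliases.get(f"{a.name}:{b.name}")
    cmap = map_chains(a, b, aliases)
    refs = cfg.reference_chains or None
    report = dev.deviation_report(a, b, cmap, reference_chains=refs)

    tag = f"{a.name}_vs_{b.name}"
    pd.DataFrame({
        "node_a": [_node_label(a, r.index_a) for r in report.per_residue],
        "node_b": [_node_label(b, r.index_b) for r in report.per_residue],
        "deviation": [r.deviation for r in report.per_residue],
        "significant": [r.significant for r in report.per_residue],
    }).to_csv(out / f"{tag}_per_residue.csv", index=False)
    summary = {
        "global_rmsd": report.global_rmsd,
        "mean_dev": report.mean_dev,
        "sd_dev": report.sd_dev,
        "per_protein": [
            {"chain": p.chain_id, "local_rmsd": p.local_rmsd,
             "angle_of_deviation": p.angle_of_deviation}
            for p in report.per_protein
        ],
    }
    (out / f"{tag}_deviation.json").write_text(json.dumps(summary, indent=2))
    # deviations painted into the B-factor column for visualisation
    devs = np.zeros(len(a))
    for r in report.per_residue:
        devs[r.index_a] = r.deviation
    (out / f"{tag}_deviation.pdb").write_text(write_structure(a, bfactors=devs))

    delta, edge_summary = rin.compare_networks(sa["graph"], sb["graph"], cmap)
    delta.insert(0, "node_a", [_node_label(a, i) for i in delta.index])
    delta.to_csv(out / f"{tag}_network_delta.csv", index=False)
    return {"tag": tag, "deviation": summary, "edges": edge_summary}


def _paths_analysis(state: dict, cfg: PipelineConfig, out: Path) -> dict:
    """Sensor→effector communication paths within one state."""
    s: CoarseGrainedStructure = state["structure"]
    sources = [int(v) for v in state["sensors"]]
    sinks = [int(v) for v in state["effectors"] if int(v) not in set(sources)]
    if not sources or not sinks:
        logger.warning("%s: no sensors or no effectors; skipping path extraction", s.name)
        return {"paths": 0}
    affinity = comm.affinity_from_contacts(s, cutoff=cfg.communication_cutoff)
    model = comm.hitting_commute(affinity)
    graph = rin.build_rin(s, contact_cutoff=cfg.communication_cutoff)
    paths = comm.extract_paths(model, graph, sources, sinks,
                               weighting=cfg.path_weighting)
    (out / f"{s.name}_paths.json").write_text(json.dumps({
        "sources": [_node_label(s, v) for v in sources],
        "sinks": [_node_label(s, v) for v in sinks],
        "paths": [[_node_label(s, v) for v in p] for p in paths.found],
    }, indent=2))
    pd.DataFrame(
        [(_node_label(s, i), _node_label(s, j), c)
         for (i, j), c in sorted(paths.edge_usage.items())],
        columns=["node_i", "node_j", "crossings"],
    ).to_csv(out / f"{s.name}_edge_usage.tsv", sep="\t", index=False)
    return {"paths": paths.n_paths, "n_sources": len(sources), "n_sinks": len(sinks)}


def run_compare(cfg: PipelineConfig,
                structures: list[CoarseGrainedStructure] | None = None) -> dict:
    """Run the full comparative analysis; returns the manifest dict.

    ``structures`` may be passed directly (already-parsed states, e.g.
    synthetic ones); otherwise they are read from the configured paths.
    Every output is a CSV/JSON/TSV/PDB file under ``cfg.output_dir``; the
    manifest records all parameters, counts and failures.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if structures is None:
        cfg.validate()
        structures = [read_structure(s["path"], s["name"]) for s in cfg.structures]

    manifest: dict = {
        "parameters": {k: v for k, v in asdict(cfg).items() if k != "structures"},
        "structures": [{"name": s.name, "nodes": len(s)} for s in structures],
        "states": {}, "pairs": {}, "paths": {}, "failed": [],
    }
    states: dict[str, dict] = {}
    for s in structures:
        try:
            states[s.name] = _state_analysis(s, cfg, out)
            manifest["states"][s.name] = states[s.name]["counts"]
        except Exception as exc:
            logger.error("state analysis failed for %s: %s", s.name, exc)
            manifest["failed"].append({"stage": "state", "input": s.name, "error": str(exc)})

    for a, b in itertools.combinations([s.name for s in structures], 2):
        if a not in states or b not in states:
            continue
        try:
            pair = _pair_analysis(states[a], states[b], cfg, out)
            manifest["pairs"][pair["tag"]] = {
                "global_rmsd": pair["deviation"]["global_rmsd"],
                "per_protein": pair["deviation"]["per_protein"],
                **pair["edges"],
            }
        except Exception as exc:
            logger.error("pair analysis failed for %s vs %s: %s", a, b, exc)
            manifest["failed"].append({"stage": "pair", "input": f"{a}:{b}", "error": str(exc)})

    for name, state in states.items():
        try:
            manifest["paths"][name] = _paths_analysis(state, cfg, out)
        except Exception as exc:
            logger.error("path extraction failed for %s: %s", name, exc)
            manifest["failed"].append({"stage": "paths", "input": name, "error": str(exc)})

    if manifest["failed"]:
        (out / "FAILED").write_text(json.dumps(manifest["failed"], indent=2))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
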