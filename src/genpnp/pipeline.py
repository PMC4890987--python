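"""End-to-end orchestration: simulate/load -> pool -> identify -> pnp -> compare.

Stages communicate only through the delimited-text artifacts written under
the configured output directory, so any stage can be rerun in isolation
from the files the previous one produced.  A manifest records the package
version, seed, configuration hash and a SHA-256 checksum of every artifact;
reruns with the same configuration and seed are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd

from . import io
from .compare import compare_core_gens, flag_differential_expression, flag_methylation_candidates
from .config import RunConfig
from .datatypes import CandidateGEN, CohortDataset, CoreGEN, IdentifiedGEN
from .identification import identify_gen
from .pnp import build_network_matrix, extract_core, pnp_decompose, project_and_score, thresholds_from_quantile
from .pool import assemble_candidate_gen, select_protein_pool
from .synthetic import SimulationConfig, emit_candidate_network, generate_ground_truth, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class _RunState:
    outdir: Path
    cohorts: dict[str, CohortDataset] = field(default_factory=dict)
    edge_frame: Optional[pd.DataFrame] = None
    node_ids: list[str] = field(default_factory=list)
    mirna_ids: list[str] = field(default_factory=list)
    pool: set[str] = field(default_factory=set)
    gens: dict[str, IdentifiedGEN] = field(default_factory=dict)
    cores: dict[str, CoreGEN] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(manifest: dict, name: str, outdir: Path, outputs: list[Path], counts: dict) -> None:
    manifest["stages"].append(
        {
            "name": name,
            "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(outputs)},
            "counts": counts,
        }
    )
    logger.info("stage %-10s %s", name, counts)


def _stage_data(config: RunConfig, state: _RunState) -> tuple[list[Path], dict]:
    outputs: list[Path] = []
    if config.simulation is not None:
        block = dict(config.simulation)
        block.pop("seed", None)
        sim = SimulationConfig(**block, seed=config.seed)
        gt = generate_ground_truth(sim)
        cand = emit_candidate_network(gt, sim.fp_fraction, seed=config.seed + 1)
        state.edge_frame = io.candidate_to_frame(cand)
        state.node_ids, state.mirna_ids = gt.node_ids, gt.mirna_ids
        for i, (group, n) in enumerate(sim.n_samples.items()):
            state.cohorts[group] = simulate_cohort(gt, group, n, seed=config.seed + 2 + i)
        path = state.outdir / "candidate_edges.tsv"
        io.write_table(state.edge_frame, path)
        outputs.append(path)
        path = state.outdir / "truth_abilities.tsv"
        io.write_table(gt.ability_frame(), path)
        outputs.append(path)
    else:
        assert config.inputs is not None
        for group, prefix in config.inputs["cohorts"].items():
            state.cohorts[group] = io.read_cohort(prefix)
        state.edge_frame = io.read_edge_table(config.inputs["edges"])
        first = next(iter(state.cohorts.values()))
        state.node_ids, state.mirna_ids = first.node_ids, first.mirna_ids
    for group, data in state.cohorts.items():
        outputs.extend(io.write_cohort(data, state.outdir / f"cohort_{group}").values())
    counts = {
        "groups": len(state.cohorts),
        "nodes": len(state.node_ids),
        "mirnas": len(state.mirna_ids),
        "candidate_edges": int(len(state.edge_frame)),
        "samples": {g: d.n_samples for g, d in state.cohorts.items()},
    }
    return outputs, counts


def _stage_pool(config: RunConfig, state: _RunState) -> tuple[list[Path], dict]:
    state.pool = select_protein_pool(list(state.cohorts.values()), config.alphas.pool)
    path = state.outdir / "pool.txt"
    io.write_pool(state.pool, path)
    return [path], {"pool_size": len(state.pool)}


def _candidates(state: _RunState) -> CandidateGEN:
    assert state.edge_frame is not None
    return assemble_candidate_gen(
        state.pool, state.edge_frame, state.node_ids, state.mirna_ids
    )


def _stage_identify(config: RunConfig, state: _RunState) -> tuple[list[Path], dict]:
    cand = _candidates(state)
    outputs: list[Path] = []
    counts: dict[str, Any] = {"candidate_edges_in_pool": cand.n_edges()}
    for group, data in state.cohorts.items():
        gen = identify_gen(data, cand, config.alphas.prune)
        state.gens[group] = gen
        edges_path = state.outdir / f"identified_{group}.edges.tsv"
        basal_path = state.outdir / f"identified_{group}.basal.tsv"
        io.write_identified(gen, edges_path, basal_path)
        outputs += [edges_path, basal_path]
        counts[f"edges_{group}"] = int(len(gen.edges))
    return outputs, counts


def _stage_pnp(config: RunConfig, state: _RunState) -> tuple[list[Path], dict]:
    outputs: list[Path] = []
    counts: dict[str, Any] = {}
    for group, gen in state.gens.items():
        nm = build_network_matrix(gen)
        result = project_and_score(pnp_decompose(nm, config.energy), nm)
        if group in config.thresholds:
            ths = config.thresholds[group]
        elif config.threshold_quantile is not None:
            ths = thresholds_from_quantile(result, config.threshold_quantile)
        else:
            raise ValueError(f"no thresholds configured for group {group!r}")
        core = extract_core(result, gen, *ths)
        state.cores[group] = core
        paths = {
            "scores": state.outdir / f"scores_{group}.tsv",
            "components": state.outdir / f"components_{group}.tsv",
            "core_edges": state.outdir / f"core_{group}.edges.tsv",
        }
        io.write_table(core.scores, paths["scores"])
        io.write_table(result.components_frame(), paths["components"])
        io.write_table(core.edges, paths["core_edges"])
        outputs += list(paths.values())
        counts[group] = {
            "M": result.M,
            "thresholds": [float(t) for t in ths],
            "core_nodes": len(core.core_nodes),
            "core_mirnas": len(core.core_mirnas),
            "core_edges": int(len(core.edges)),
        }
    return outputs, counts


def _stage_compare(config: RunConfig, state: _RunState) -> tuple[list[Path], dict]:
    groups = list(state.cohorts)
    if len(groups) < 2:
        return [], {"skipped": "single cohort"}
    a, b = groups[0], groups[1]
    comparison = compare_core_gens(state.cores[a], state.cores[b])
    comparison.methylation = flag_methylation_candidates(
        state.gens[a], state.gens[b], config.alphas.methylation
    )
    comparison.mutation = flag_differential_expression(
        state.cohorts[a], state.cohorts[b], config.alphas.de
    )
    membership = pd.DataFrame(
        [("common", n) for n in sorted(comparison.common_nodes)]
        + [(f"specific_{a}", n) for n in sorted(comparison.specific_nodes_a)]
        + [(f"specific_{b}", n) for n in sorted(comparison.specific_nodes_b)],
        columns=["membership", "node"],
    )
    edge_frame = pd.DataFrame(
        [("common",) + e for e in sorted(comparison.common_edges)]
        + [(f"specific_{a}",) + e for e in sorted(comparison.specific_edges_a)]
        + [(f"specific_{b}",) + e for e in sorted(comparison.specific_edges_b)],
        columns=["membership", "regulator", "target", "edge_type"],
    )
    paths = {
        "nodes": state.outdir / "comparison_nodes.tsv",
        "edges": state.outdir / "comparison_edges.tsv",
        "methylation": state.outdir / "methylation_candidates.tsv",
        "mutation": state.outdir / "mutation_candidates.tsv",
    }
    io.write_table(membership, paths["nodes"])
    io.write_table(edge_frame, paths["edges"])
    io.write_table(comparison.methylation, paths["methylation"])
    io.write_table(comparison.mutation, paths["mutation"])
    counts = {
        "common_nodes": len(comparison.common_nodes),
        f"specific_{a}": len(comparison.specific_nodes_a),
        f"specific_{b}": len(comparison.specific_nodes_b),
        "methylation_candidates": len(comparison.methylation_candidates()),
        "mutation_candidates": len(comparison.mutation_candidates()),
    }
    return list(paths.values()), counts


_STAGES = [
    ("data", _stage_data),
    ("pool", _stage_pool),
    ("identify", _stage_identify),
    ("pnp", _stage_pnp),
    ("compare", _stage_compare),
]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    from . import __version__

    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    state = _RunState(outdir=outdir)
    config_json = json.dumps(config.as_dict(), sort_keys=True)
    manifest: dict[str, Any] = {
        "package": "genpnp",
        "version": __version__,
        "seed": config.seed,
        "config": config.as_dict(),
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "stages": [],
    }
    for name, fn in _STAGES:
        try:
            outputs, counts = fn(config, state)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        _stage(manifest, name, outdir, outputs, counts)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    return manifest
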