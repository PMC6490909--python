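"""End-to-end pipeline: simulate/read -> discretize -> learn -> infer ->
sensitivity -> cross-validate, with all artifacts written to disk.

All parameters live in one YAML/JSON config; a manifest records the
config hash and seed so any run is reproducible bit-for-bit from
config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import networkx as nx
import yaml

from . import io as bio
from .analysis import kfold_cv, scenario_compare, sensitivity_analysis
from .core import Network, infer_posterior, save_network, validate_network
from .learning import LearningConfig, learn_cpts
from .model import (
    EXPERT_NODES,
    OBSERVED_NODES,
    DiscretizationScheme,
    ESMatrixTable,
    ExpertCPTParams,
    build_network,
    default_scheme,
    discretize_record,
)
from .synthetic import default_generator_config, generate_grid

log = logging.getLogger("bbnes")

__all__ = ["RunConfig", "run_pipeline", "load_config"]

DEFAULT_SCENARIOS = [
    {"label": "huegelland", "evidence": {"landscape_type": "huegelland"}},
    {"label": "geest", "evidence": {"landscape_type": "geest"}},
    {"label": "marsch", "evidence": {"landscape_type": "marsch"}},
]

DEFAULT_QUERY = [
    "soil_texture",
    "slope",
    "nutrient_regulation_potential",
    "reclassified_potential",
    "demand",
    "budget",
]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, resolvable from one config file."""

    output_dir: Path
    grid_csv: Path | None = None  # read this grid instead of simulating
    generator: dict = field(default_factory=lambda: {"region": "schleswig-holstein"})
    n_cells: int = 2000
    seed: int = 0
    column_mapping: dict[str, str] = field(default_factory=dict)
    es_scores: dict[int, int] | None = None  # default: generator's table
    slope_breaks: tuple[float, float] | None = None  # default: shipped scheme
    expert_cpt: dict = field(default_factory=dict)
    alpha: float = 1.0
    scenarios: list[dict] = field(default_factory=lambda: list(DEFAULT_SCENARIOS))
    query: list[str] = field(default_factory=lambda: list(DEFAULT_QUERY))
    cv_k: int = 5
    cv_node: str = "soil_texture"
    cv_seed: int = 0
    sensitivity_target: str = "nutrient_regulation_potential"
    raw: dict = field(default_factory=dict)  # the config document, for hashing

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "RunConfig":
        doc = dict(doc)
        paths = doc.get("paths", {})
        cv = doc.get("cv", {})
        gen = dict(doc.get("generator", {}))
        return cls(
            output_dir=Path(paths.get("output_dir", "bbnes_out")),
            grid_csv=Path(paths["grid_csv"]) if paths.get("grid_csv") else None,
            generator=gen or {"region": "schleswig-holstein"},
            n_cells=int(doc.get("n_cells", gen.pop("n_cells", 2000))),
            seed=int(doc.get("seed", 0)),
            column_mapping=dict(doc.get("column_mapping", {})),
            es_scores={int(k): int(v) for k, v in doc["es_matrix"].items()}
            if doc.get("es_matrix")
            else None,
            slope_breaks=tuple(doc["slope_breaks"]) if doc.get("slope_breaks") else None,
            expert_cpt=dict(doc.get("expert_cpt", {})),
            alpha=float(doc.get("learning", {}).get("alpha", 1.0)),
            scenarios=list(doc.get("scenarios", DEFAULT_SCENARIOS)),
            query=list(doc.get("query", DEFAULT_QUERY)),
            cv_k=int(cv.get("k", 5)),
            cv_node=str(cv.get("node", "soil_texture")),
            cv_seed=int(cv.get("seed", 0)),
            sensitivity_target=str(
                doc.get("sensitivity", {}).get("target", "nutrient_regulation_potential")
            ),
            raw=dict(doc),
        )

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(doc)


def _relevant_evidence_vars(net: Network, node: str, observed: Sequence[str]) -> list[str]:
    """Observed variables that can influence the node's posterior; the rest
    are d-separated given the others and safely dropped from cache keys."""
    g = net.graph()
    obs = [v for v in observed if v != node]
    keep = []
    for v in obs:
        rest = set(obs) - {v}
        if not nx.is_d_separator(g, {v}, {node}, rest):
            keep.append(v)
    return keep


def map_states_per_cell(
    net: Network,
    records: Sequence[Mapping[str, str]],
    grid: Sequence,
    nodes: Sequence[str] = EXPERT_NODES,
) -> list[dict]:
    """MAP state of each unobserved node for every cell, given the cell's
    observed states as evidence.  Posteriors are cached on the subset of
    evidence that can actually reach each node."""
    relevant = {n: _relevant_evidence_vars(net, n, OBSERVED_NODES) for n in nodes}
    caches: dict[str, dict[tuple, str]] = {n: {} for n in nodes}
    rows = []
    for rec, cell in zip(records, grid):
        row = {"cell_id": cell.cell_id, "x": cell.x, "y": cell.y}
        for n in nodes:
            key = tuple(rec[v] for v in relevant[n])
            if key not in caches[n]:
                ev = {v: rec[v] for v in relevant[n]}
                caches[n][key] = infer_posterior(net, n, ev)[n].argmax_state()
            row[n] = caches[n][key]
        rows.append(row)
    return rows


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute all stages; returns the artifact paths, keyed by name."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name: str):
        log.info("stage: %s", name)

    # -- input grid --------------------------------------------------------
    gen_cfg = default_generator_config(
        region=cfg.generator.get("region", "schleswig-holstein"),
        n_cells=cfg.n_cells,
        seed=cfg.seed,
    )
    if cfg.grid_csv is None:
        stage("simulate")
        grid = generate_grid(gen_cfg)
        artifacts["grid"] = out / "grid.csv"
        bio.write_grid_csv(grid, artifacts["grid"], cfg.column_mapping)
    else:
        stage("read grid")
        artifacts["grid"] = Path(cfg.grid_csv)
        grid = bio.read_grid_csv(cfg.grid_csv, cfg.column_mapping)
    log.info("%d grid records", len(grid))

    # -- discretize --------------------------------------------------------
    stage("discretize")
    scheme = default_scheme()
    if cfg.slope_breaks:
        scheme = scheme.with_slope_breaks(*cfg.slope_breaks)
    matrix = ESMatrixTable(cfg.es_scores) if cfg.es_scores else gen_cfg.es_matrix()
    records = [discretize_record(r, scheme, matrix) for r in grid]
    artifacts["states"] = out / "state_records.csv"
    bio.write_state_records_csv(records, artifacts["states"])

    # -- learn -------------------------------------------------------------
    stage("learn")
    expert = ExpertCPTParams(**cfg.expert_cpt) if cfg.expert_cpt else ExpertCPTParams()
    structure = build_network(expert_params=expert)
    lcfg = LearningConfig(alpha=cfg.alpha)
    net = learn_cpts(structure, records, lcfg)
    violations = validate_network(net)
    if violations:
        raise RuntimeError("learned network invalid: " + "; ".join(violations[:3]))
    artifacts["network"] = out / "network.json"
    save_network(net, artifacts["network"])

    # -- scenarios ---------------------------------------------------------
    stage("infer")
    scen = [(s["label"], dict(s["evidence"])) for s in cfg.scenarios]
    table = scenario_compare(net, scen, cfg.query)
    artifacts["scenarios"] = out / "scenarios.csv"
    bio.write_scenario_csv(table, artifacts["scenarios"])

    stage("map states")
    rows = map_states_per_cell(net, records, grid)
    artifacts["map_states"] = out / "map_states.csv"
    bio.write_map_states_csv(rows, EXPERT_NODES, artifacts["map_states"])

    # -- sensitivity -------------------------------------------------------
    stage("sensitivity")
    report = sensitivity_analysis(net, cfg.sensitivity_target)
    artifacts["sensitivity"] = out / "sensitivity.csv"
    bio.write_sensitivity_csv(report, artifacts["sensitivity"])

    # -- cross-validation --------------------------------------------------
    stage("crossval")
    cv = kfold_cv(structure, records, cfg.cv_k, cfg.cv_node, lcfg, seed=cfg.cv_seed)
    artifacts["cv"] = out / "cv.csv"
    bio.write_cv_csv(cv, artifacts["cv"])

    # -- manifest ----------------------------------------------------------
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_records": len(grid),
        "cv": {"k": cv.k, "node": cv.node, "accuracy": cv.accuracy},
        "sensitivity_target": report.target,
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    artifacts["manifest"] = out / "manifest.json"
    with open(artifacts["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return artifacts
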