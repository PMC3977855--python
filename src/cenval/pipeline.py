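"""End-to-end run: load or generate a network, compute the five measures,
run the comparison stages, and write a reproducible report bundle.

Bundle contents (all plain text):
    nodes.csv         per-node scores and ranks
    extremes.csv      one row per measure: extreme values, tie and bin counts
    correlations.json rank-correlation matrix + top-k overlap matrix
    validation.json   ground-truth scoring (with warnings)
    annotated.gml     the graph with scores as numeric node attributes
    diffusion.json    optional SI association summary
    run_config.yaml   the resolved configuration, echoed for reproducibility
    run.log           convention flags and warnings
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synth
from .centrality import MEASURES, compute_profile
from .diffusion import centrality_diffusion_association
from .graph import Graph, read_edge_list, read_gml, round_sig, write_annotated_gml
from .synth import AnnotatedGraph, ERParameters
from .validation import (
    INVERTED_MEASURES,
    extreme_node_sets,
    rank_correlation,
    ranked_nodes,
    score_against_ground_truth,
    top_k_overlap,
)

logger = logging.getLogger("cenval")

__all__ = ["PipelineConfig", "run_pipeline", "load_source"]


@dataclass
class PipelineConfig:
    """One serializable record of everything a run depends on."""

    input_path: str | None = None
    fixture: str | None = None
    generator: dict | None = None  # e.g. {"model": "er", "n": 50, "p": 0.1}
    degree_normalized: bool = True
    betweenness_normalized: bool = False
    closeness_variant: str = "inverse_farness"
    k: int = 5
    correlation_method: str = "kendall"
    diffusion: bool = False
    beta: float = 0.3
    replicates: int = 200
    steps: int | None = None
    rng_seed: int = 0
    outdir: str = "cenval_out"

    def validate(self) -> None:
        sources = [s for s in (self.input_path, self.fixture, self.generator) if s]
        if len(sources) != 1:
            raise ValueError("exactly one input source (input/fixture/generator) required")
        if self.fixture and self.fixture not in synth.FIXTURE_NAMES:
            raise ValueError(f"unknown fixture {self.fixture!r}")
        if self.closeness_variant not in ("inverse_farness", "freeman"):
            raise ValueError(f"unknown closeness variant {self.closeness_variant!r}")
        if self.correlation_method not in ("kendall", "spearman"):
            raise ValueError(f"unknown correlation method {self.correlation_method!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config file; explicit keyword flags override file values."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def generate_graph(spec: dict, rng_seed: int) -> AnnotatedGraph | Graph:
    model = spec.get("model")
    seed = int(spec.get("seed", rng_seed))
    if model == "er":
        return synth.erdos_renyi(
            ERParameters(n=int(spec["n"]), p=float(spec["p"]), seed=seed)
        )
    if model == "hub":
        return synth.planted_hub(
            n_spokes=int(spec.get("n_spokes", 10)),
            rewire=float(spec.get("rewire", 0.1)),
            seed=seed,
        )
    if model == "bridge":
        return synth.planted_bridge(clique_size=int(spec.get("clique_size", 5)), seed=seed)
    raise ValueError(f"unknown generator model {model!r}; valid: er, hub, bridge")


def load_source(cfg: PipelineConfig) -> tuple[Graph, AnnotatedGraph | None, str]:
    """Resolve the configured input into (graph, ground truth or None, id)."""
    if cfg.input_path:
        path = Path(cfg.input_path)
        if not path.is_file():
            raise FileNotFoundError(f"input file not found: {path}")
        text = path.read_text()
        if path.suffix.lower() == ".gml":
            g = read_gml(text)
        else:
            g = read_edge_list(text)
        return g, None, path.stem
    if cfg.fixture:
        ann = synth.bundled_fixture(cfg.fixture)
        return ann.graph, ann, cfg.fixture
    result = generate_graph(cfg.generator, cfg.rng_seed)
    if isinstance(result, AnnotatedGraph):
        return result.graph, result, result.construction
    return result, None, f"er(n={cfg.generator['n']},p={cfg.generator['p']})"


def _matrix_json(measures, values: np.ndarray) -> dict:
    return {
        "measures": list(measures),
        "matrix": [[round_sig(float(x)) for x in row] for row in values],
    }


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Execute every stage and write the bundle; returns the file map."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cenval")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(cfg, outdir, log_path)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(cfg: PipelineConfig, outdir: Path, log_path: Path) -> dict[str, Path]:
    graph, annotated, graph_id = load_source(cfg)
    logger.info(
        "loaded %s: n=%d, M=%d; conventions: degree_normalized=%s, "
        "betweenness_normalized=%s, closeness_variant=%s, inverted_for_ranking=%s",
        graph_id,
        graph.n,
        graph.m,
        cfg.degree_normalized,
        cfg.betweenness_normalized,
        cfg.closeness_variant,
        ",".join(INVERTED_MEASURES),
    )
    profile = compute_profile(
        graph,
        graph_id=graph_id,
        degree_normalized=cfg.degree_normalized,
        betweenness_normalized=cfg.betweenness_normalized,
        closeness_variant=cfg.closeness_variant,
    )
    for w in profile.warnings:
        logger.warning("%s", w)

    files: dict[str, Path] = {}

    # per-node table: five scores and five ranks
    rows = []
    ranks = {
        m: {v: i + 1 for i, v in enumerate(ranked_nodes(profile, m))} for m in MEASURES
    }
    for v in graph.nodes:
        row: dict[str, object] = {"node": v}
        for m in MEASURES:
            s = profile[m].scores.get(v)
            row[m] = round_sig(float(s)) if s is not None else ""
            row[f"{m}_rank"] = ranks[m].get(v, "")
        rows.append(row)
    nodes_csv = outdir / "nodes.csv"
    pd.DataFrame(rows).to_csv(nodes_csv, index=False)
    files["nodes"] = nodes_csv

    # extreme summaries
    ext_rows = []
    for m in MEASURES:
        s = extreme_node_sets(profile[m])
        ext_rows.append(
            {
                "measure": m,
                "max_value": s.max_value,
                "n_argmax": len(s.argmax_nodes),
                "argmax_nodes": ";".join(sorted(s.argmax_nodes)),
                "min_value": s.min_value,
                "n_argmin": len(s.argmin_nodes),
                "argmin_nodes": ";".join(sorted(s.argmin_nodes)),
                "constant": s.constant,
                "histogram_max_count": s.histogram_max_count,
                "histogram_min_count": s.histogram_min_count,
            }
        )
    extremes_csv = outdir / "extremes.csv"
    pd.DataFrame(ext_rows).to_csv(extremes_csv, index=False)
    files["extremes"] = extremes_csv

    corr = rank_correlation(profile, method=cfg.correlation_method)
    k_eff = min(cfg.k, graph.n)
    if k_eff < cfg.k:
        logger.warning("k=%d exceeds node count; using k=%d", cfg.k, k_eff)
    overlap = top_k_overlap(profile, k_eff)
    corr_json = outdir / "correlations.json"
    corr_json.write_text(
        json.dumps(
            {
                "method": corr.method,
                "n_shared": corr.n_shared,
                "adjusted": list(corr.adjusted),
                "correlation": _matrix_json(corr.measures, corr.values),
                "top_k": {
                    "k": overlap.k,
                    "boundary_ties": dict(overlap.boundary_ties),
                    **_matrix_json(overlap.measures, overlap.values),
                },
            },
            indent=2,
            allow_nan=True,
        )
    )
    files["correlations"] = corr_json

    # ground-truth validation
    val: dict[str, object] = {"dataset": graph_id, "k": k_eff}
    if annotated is not None:
        report = score_against_ground_truth(profile, annotated, k=k_eff)
        val["influential"] = sorted(annotated.influential)
        val["scores"] = {
            m: {
                "hits": s.hits,
                "reciprocal_rank": round_sig(s.reciprocal_rank),
                "best_node": s.best_node,
                "best_rank": s.best_rank,
            }
            for m, s in report.scores.items()
        }
        val["warnings"] = list(report.warnings)
        for w in report.warnings:
            logger.warning("validation: %s", w)
    else:
        val["warnings"] = ["no ground-truth influential set for this input"]
        logger.warning("validation skipped: no ground truth available")
    val_json = outdir / "validation.json"
    val_json.write_text(json.dumps(val, indent=2))
    files["validation"] = val_json

    gml_path = outdir / "annotated.gml"
    gml_path.write_text(write_annotated_gml(graph, profile))
    files["annotated"] = gml_path

    if cfg.diffusion:
        assoc = centrality_diffusion_association(
            graph,
            profile,
            beta=cfg.beta,
            replicates=cfg.replicates,
            rng_seed=cfg.rng_seed,
            steps=cfg.steps,
        )
        diff_json = outdir / "diffusion.json"
        diff_json.write_text(
            json.dumps(
                {
                    "beta": assoc.beta,
                    "replicates": assoc.replicates,
                    "tau": {m: round_sig(t) if t == t else None for m, t in assoc.tau.items()},
                    "direction": dict(assoc.direction),
                },
                indent=2,
            )
        )
        files["diffusion"] = diff_json

    cfg_path = outdir / "run_config.yaml"
    cfg_path.write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True))
    files["config"] = cfg_path
    files["log"] = log_path
    return files
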