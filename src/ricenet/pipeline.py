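"""YAML-configured end-to-end pipeline with a reproducibility manifest.

Stage order: simulate/load -> normalize -> correlate + calibrate -> mutual
rank -> network -> subnetwork(s) -> expression coherence -> enrichment ->
tissue preference.  Stages can be disabled individually; every stochastic
stage takes its seed from the single mandatory top-level ``seed`` (no silent
defaults), and a run manifest records the config snapshot, input digests,
seeds, package version, output paths and timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .coexpression import (
    build_network, calibrate_pcc_threshold, mutual_rank, pearson_matrix,
)
from .expression_io import (
    ExpressionCompendium, GuideSet, read_expression_table, read_gene_sets,
    read_guide_list, read_sample_metadata, write_expression_table,
    write_gene_sets, write_sample_metadata,
)
from .functional import (
    classify_tissue_preference, ec_analysis, ec_category_curve,
    hypergeom_enrichment, write_ec_results, write_enrichment_results,
    write_tissue_preference,
)
from .normalization import normalize
from .simulate import (
    SimulationConfig, generate_compendium, generate_go_catalog,
    generate_raw_intensities,
)
from .subnetwork import component_summary, extract_subnetwork

logger = logging.getLogger("ricenet")


class ConfigError(ValueError):
    pass


_KNOWN_SECTIONS = {
    "seed", "output_dir", "simulate", "inputs", "normalize", "network",
    "subnetwork", "ec", "enrichment", "tissue_preference",
}


def _validate_config(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(cfg) - _KNOWN_SECTIONS
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    if "seed" not in cfg or not isinstance(cfg["seed"], int):
        raise ConfigError("config requires an explicit integer 'seed'")
    if "output_dir" not in cfg:
        raise ConfigError("config requires 'output_dir'")
    sim = cfg.get("simulate", {}).get("enabled", False)
    if not sim and "expression" not in cfg.get("inputs", {}):
        raise ConfigError("either simulate.enabled or inputs.expression is required")
    for section in ("simulate", "inputs", "normalize", "network", "subnetwork",
                    "ec", "enrichment", "tissue_preference"):
        if section in cfg and not isinstance(cfg[section], dict):
            raise ConfigError(f"section {section!r} must be a mapping")
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written alongside every pipeline run."""

    config: dict
    seed: int
    version: str = __version__
    started: str = ""
    finished: str = ""
    input_digests: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)  # stage -> status / counts

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   default=str) + "\n")


def run_pipeline(config_path: str | Path) -> RunManifest:
    """Execute the configured stages in dependency order; returns a manifest.

    The config is validated before any stage runs; a stage failure leaves
    the manifest recording partial completion (and re-raises).
    """
    config_path = Path(config_path)
    cfg = _validate_config(yaml.safe_load(config_path.read_text()))
    seed = cfg["seed"]
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=seed,
                           started=datetime.now(timezone.utc).isoformat())
    manifest.input_digests["config"] = _digest(config_path)
    manifest_path = out_dir / "manifest.json"
    try:
        _run_stages(cfg, seed, out_dir, manifest)
    except Exception as e:
        manifest.stages["error"] = f"{type(e).__name__}: {e}"
        manifest.finished = datetime.now(timezone.utc).isoformat()
        manifest.write(manifest_path)
        raise
    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.write(manifest_path)
    manifest.outputs["manifest"] = str(manifest_path)
    return manifest


def _run_stages(cfg: dict, seed: int, out_dir: Path,
                manifest: RunManifest) -> None:
    # ---- inputs: simulate or load -----------------------------------------
    sim_cfg = cfg.get("simulate", {})
    catalogs = {}
    guides: GuideSet | None = None
    truth = None
    if sim_cfg.get("enabled", False):
        fields = {f.name for f in dataclasses.fields(SimulationConfig)}
        params = {k: v for k, v in sim_cfg.items() if k in fields}
        params["seed"] = seed
        scfg = SimulationConfig(**params)
        comp, truth = generate_compendium(scfg)
        catalogs = generate_go_catalog(truth, scfg, gene_ids=comp.gene_ids)
        guides = truth.guides(n_guides=int(sim_cfg.get("n_guides", 3)))
        raw = None
        if cfg.get("normalize", {}).get("enabled", False):
            raw, _, _ = generate_raw_intensities(comp, scfg, truth)
        write_expression_table(comp, out_dir / "expression.tsv")
        write_sample_metadata(comp.samples_meta, out_dir / "samples.tsv")
        for ns, cat in catalogs.items():
            write_gene_sets(cat, out_dir / f"go_{ns}.tsv")
        (out_dir / "guides.txt").write_text("\n".join(guides.guide_ids) + "\n")
        manifest.stages["simulate"] = {
            "n_genes": comp.n_genes, "n_samples": comp.n_samples,
            "n_modules": scfg.n_modules,
        }
    else:
        inputs = cfg["inputs"]
        meta = None
        if "metadata" in inputs:
            meta = read_sample_metadata(inputs["metadata"])
            manifest.input_digests["metadata"] = _digest(Path(inputs["metadata"]))
        comp = read_expression_table(
            inputs["expression"], dialect=inputs.get("dialect", "tsv"),
            samples_meta=meta,
        )
        manifest.input_digests["expression"] = _digest(Path(inputs["expression"]))
        raw = comp.values if cfg.get("normalize", {}).get("enabled") else None
        for ns, path in inputs.get("go_annotations", {}).items():
            catalogs[ns] = read_gene_sets(path, namespace=ns, compendium=comp)
            manifest.input_digests[f"go_{ns}"] = _digest(Path(path))
        if "guides" in inputs:
            guides = read_guide_list(inputs["guides"])
            manifest.input_digests["guides"] = _digest(Path(inputs["guides"]))
        manifest.stages["load"] = {
            "n_genes": comp.n_genes, "n_samples": comp.n_samples,
        }

    # ---- normalization ----------------------------------------------------
    norm_cfg = cfg.get("normalize", {})
    if norm_cfg.get("enabled", False):
        comp, model = normalize(
            raw, method=norm_cfg.get("method", "vsn"),
            trim_fraction=float(norm_cfg.get("trim_fraction", 0.1)),
            samples_meta=comp.samples_meta,
        )
        model.to_tsv(out_dir / "normalization_model.tsv")
        write_expression_table(comp, out_dir / "normalized.tsv")
        manifest.outputs["normalized"] = str(out_dir / "normalized.tsv")
        manifest.stages["normalize"] = {"method": norm_cfg.get("method", "vsn")}

    # ---- network ----------------------------------------------------------
    net_cfg = cfg.get("network", {})
    comp = comp.drop_constant_genes()
    calibration = None
    pcc_min = net_cfg.get("pcc_min")
    if net_cfg.get("calibrate", pcc_min is None):
        calibration = calibrate_pcc_threshold(
            comp,
            n_random=min(int(net_cfg.get("n_random", 1000)), comp.n_genes),
            percentile=float(net_cfg.get("percentile", 99.0)),
            seed=seed,
        )
        pcc_min = calibration.threshold
    corr = pearson_matrix(comp, block_size=net_cfg.get("block_size"))
    mr = mutual_rank(corr, tie_method=net_cfg.get("tie_method", "stable"))
    network = build_network(corr, mr, pcc_min=float(pcc_min),
                            mr_max=float(net_cfg.get("mr_max", 10.0)),
                            calibration=calibration)
    network.write_edges_tsv(out_dir / "edges.tsv")
    network.write_sif(out_dir / "network.sif")
    network.write_graphml(out_dir / "network.graphml")
    manifest.outputs["edges"] = str(out_dir / "edges.tsv")
    manifest.stages["network"] = {
        "pcc_min": float(pcc_min), "mr_max": float(net_cfg.get("mr_max", 10.0)),
        "nodes": network.node_count, "edges": network.edge_count,
        "calibrated": calibration is not None,
    }

    # ---- subnetwork -------------------------------------------------------
    sub_cfg = cfg.get("subnetwork", {})
    if sub_cfg.get("enabled", guides is not None) and guides is not None:
        sub = extract_subnetwork(network, guides,
                                 steps=int(sub_cfg.get("steps", 2)))
        sub.write_sif(out_dir / "subnetwork.sif")
        sub.write_graphml(out_dir / "subnetwork.graphml")
        sub.write_node_attributes(out_dir / "subnetwork_nodes.tsv")
        comps = component_summary(sub)
        manifest.stages["subnetwork"] = {
            "nodes": sub.node_count, "edges": sub.edge_count,
            "components": len(comps), "steps": sub.steps,
            "missing_guides": list(sub.missing_guides),
        }
    else:
        sub = None

    # ---- expression coherence ---------------------------------------------
    ec_cfg = cfg.get("ec", {})
    if ec_cfg.get("enabled", bool(catalogs)) and catalogs:
        all_results = []
        for ns, catalog in sorted(catalogs.items()):
            all_results.extend(ec_analysis(
                corr, catalog.restrict(corr.gene_ids),
                pcc_threshold=float(pcc_min),
                n_draws=int(ec_cfg.get("n_draws", 1000)),
                seed=seed,
            ))
        if all_results:
            write_ec_results(all_results, out_dir / "ec.tsv")
            curve = ec_category_curve(all_results)
            curve.to_csv(out_dir / "ec_curve.tsv", sep="\t", index=False,
                         float_format="%.6g")
            manifest.stages["ec"] = {"categories": len(all_results)}

    # ---- enrichment -------------------------------------------------------
    enr_cfg = cfg.get("enrichment", {})
    if enr_cfg.get("enabled", bool(catalogs) and sub is not None) \
            and catalogs and sub is not None:
        if enr_cfg.get("background", "connected") == "connected":
            background = network.connected_gene_ids()
        else:
            background = comp.gene_ids
        results = []
        for ns, catalog in sorted(catalogs.items()):
            results.extend(hypergeom_enrichment(
                sorted(sub.graph.nodes), background,
                catalog.restrict(background),
                alpha=float(enr_cfg.get("alpha", 0.05)),
                bh_correct=bool(enr_cfg.get("bh_correct", False)),
            ))
        results.sort(key=lambda r: (r.p_value, r.term_id))
        write_enrichment_results(results, out_dir / "enrichment.tsv")
        manifest.stages["enrichment"] = {
            "terms": len(results),
            "significant": sum(r.enriched for r in results),
            "background_size": len(background),
        }

    # ---- tissue preference ------------------------------------------------
    tp_cfg = cfg.get("tissue_preference", {})
    if tp_cfg.get("enabled", comp.samples_meta is not None) \
            and comp.samples_meta is not None:
        tp = classify_tissue_preference(comp, mode=tp_cfg.get("mode", "max_sample"))
        write_tissue_preference(tp, out_dir / "tissue_preference.tsv")
        manifest.stages["tissue_preference"] = {
            "categories": int(tp.category_counts().size),
        }
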