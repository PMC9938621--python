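"""End-to-end orchestration: simulate/load -> normalize -> DEG -> network ->
markers -> train/CV -> predict -> clinical association.

A single YAML config (or plain dict) drives the run; every stage writes its
output under the run directory and a manifest records the config hash and a
SHA-256 digest of every artifact, so identical config+seed reruns are
verifiably byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinstats, coexnet, degstats, ertmodel, exprio, markers, synthdata

log = logging.getLogger("fluidert")

#: desk-scale defaults; SimulationConfig itself defaults to the full study
#: design (48 patients, 15k genes, 864 planted DEGs).
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "fluidert_run",
    "simulate": True,
    "simulation": {"n_genes": 3000, "n_deg": 200, "emit_counts": True},
    "data": {},  # expr/meta/lengths/scale when simulate is false
    "normalization": {"pseudocount": 1.0},
    "qc": {"min_genes_detected": 1000, "min_total": 0},
    "deg": {"q_threshold": 0.05, "p_cut": 0.05, "fc_cut": 2.0},
    "network": {"soft_power": 6.0, "sign": "unsigned",
                "cut_height": 0.25, "min_module_size": 30},
    "markers": {"panel_size": 87, "alpha": 0.05,
                "n_trees": 300, "n_permutations": 3},
    "model": {"tau": 0.6, "n_trees": 500, "cv_folds": 10,
              "group_by_patient": True},
}


class PipelineConfigError(ValueError):
    """The pipeline config is malformed."""


def load_config(source) -> dict:
    """Merge a YAML file / dict over the documented defaults."""
    if source is None:
        user: dict = {}
    elif isinstance(source, (str, Path)):
        user = yaml.safe_load(Path(source).read_text()) or {}
    elif isinstance(source, dict):
        user = source
    else:
        raise PipelineConfigError(f"unsupported config source {type(source)}")
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    if not cfg.get("simulate") and not cfg.get("data", {}).get("expr"):
        raise PipelineConfigError("non-simulate mode requires data.expr")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()


def _sim_config(cfg: dict) -> synthdata.SimulationConfig:
    fields = {f.name for f in dataclasses.fields(synthdata.SimulationConfig)}
    extra = set(cfg["simulation"]) - fields
    if extra:
        raise PipelineConfigError(f"unknown simulation fields: {sorted(extra)}")
    kwargs = dict(cfg["simulation"])
    for tup in ("module_sizes", "gene_length_range", "validation_stage_probs"):
        if tup in kwargs and isinstance(kwargs[tup], list):
            kwargs[tup] = tuple(kwargs[tup])
    kwargs.setdefault("seed", cfg["seed"])
    return synthdata.SimulationConfig(**kwargs)


def run_pipeline(config=None) -> dict:
    """Execute the full workflow; returns the in-memory results bundle.

    Writes per-stage TSV/JSON artifacts plus ``manifest.json`` into the run
    directory.
    """
    cfg = load_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    results: dict = {"config": cfg}

    # --- acquire training data -------------------------------------------
    truth = None
    validation = None
    if cfg["simulate"]:
        sim_cfg = _sim_config(cfg)
        log.info("simulating training cohort (%d patients, %d genes)",
                 sim_cfg.n_patients, sim_cfg.n_genes)
        training, truth = synthdata.simulate_training_cohort(sim_cfg)
        validation = synthdata.simulate_validation_cohort(sim_cfg, truth)
        truth.to_json(out / "truth.json")
    else:
        d = cfg["data"]
        training = exprio.read_dataset(d["expr"], d["meta"], d.get("scale", "counts"),
                                       d.get("lengths"))
        if d.get("validation_expr"):
            validation = exprio.read_dataset(d["validation_expr"], d["validation_meta"],
                                             d.get("scale", "counts"), d.get("lengths"))

    # --- normalise + QC ----------------------------------------------------
    def to_log2(ds):
        if ds.scale == "counts":
            ds = exprio.log2_transform(exprio.fpkm(ds), cfg["normalization"]["pseudocount"])
        elif ds.scale == "fpkm":
            ds = exprio.log2_transform(ds, cfg["normalization"]["pseudocount"])
        return ds

    training_qc, train_report = exprio.qc_filter(
        training, cfg["qc"]["min_genes_detected"], cfg["qc"]["min_total"])
    train_log2 = to_log2(training_qc)
    exprio.write_dataset(train_log2, out, expr_name="train_log2.tsv",
                         meta_name="train_meta.tsv")
    train_report.to_json(out / "train_qc.json")

    # --- DEG statistics ----------------------------------------------------
    log.info("per-gene ANOVA + Tukey on %d genes", train_log2.n_genes)
    gene_stats = degstats.compute_gene_stats(
        train_log2, p_cut=cfg["deg"]["p_cut"], fc_cut=cfg["deg"]["fc_cut"])
    gene_stats.to_csv(out / "genestats.tsv", sep="\t", float_format="%.10g",
                      index_label="gene_id")
    deg_genes = list(gene_stats.index[(gene_stats["q_value"] < cfg["deg"]["q_threshold"])
                                      & (gene_stats["degenerate"] == "")])
    results["deg_genes"] = deg_genes
    log.info("%d DEGs at q < %s", len(deg_genes), cfg["deg"]["q_threshold"])

    # --- co-expression network --------------------------------------------
    net_params = coexnet.NetworkParams(**cfg["network"])
    assignment = coexnet.analyze_network(train_log2, deg_genes, net_params)
    hubs = coexnet.panel_hubs(assignment)
    modules_payload = {
        "labels": assignment.labels.to_dict(),
        "stage_correlation": {m: {k: (None if pd.isna(v) else float(v))
                                  for k, v in row.items()}
                              for m, row in assignment.stage_correlation.iterrows()},
        "k_within": {g: float(v) for g, v in assignment.k_within.items()},
        "hub_genes": assignment.hub_genes,
        "panel_hubs": hubs,
    }
    (out / "modules.json").write_text(json.dumps(modules_payload, indent=2, sort_keys=True))
    results["modules"] = assignment

    # --- marker selection --------------------------------------------------
    mk = cfg["markers"]
    rf_sel = markers.RFConfig(n_trees=mk["n_trees"], n_permutations=mk["n_permutations"],
                              seed=seed)
    panel = markers.select_markers(train_log2, gene_stats, hubs,
                                   panel_size=mk["panel_size"], alpha=mk["alpha"],
                                   rf_config=rf_sel)
    panel.to_tsv(out / "panel.tsv")
    results["panel"] = panel
    log.info("marker panel: %d genes (%d hubs appended)", len(panel.genes),
             int((panel.table["source"] == "hub").sum()))

    # --- train + cross-validate -------------------------------------------
    md = cfg["model"]
    rf_model = markers.RFConfig(n_trees=md["n_trees"], seed=seed)
    model = ertmodel.train(train_log2, panel.genes, rf_model, tau=md["tau"])
    model.save(out / "model.json")
    cv = ertmodel.cross_validate(train_log2, panel.genes, k=md["cv_folds"],
                                 rf_config=rf_model,
                                 group_by_patient=md["group_by_patient"])
    cv.to_json(out / "cv.json")
    results["cv"] = cv
    log.info("CV mean accuracy %.3f", cv.mean["accuracy"])

    # --- validation prediction + clinical association ----------------------
    if validation is not None:
        val_qc, val_report = exprio.qc_filter(
            validation, cfg["qc"]["min_genes_detected"], cfg["qc"]["min_total"])
        val_report.to_json(out / "validation_qc.json")
        val_log2 = to_log2(val_qc)
        predictions = ertmodel.predict_with_threshold(model, val_log2,
                                                      failed_samples=val_report.failed)
        predictions.to_csv(out / "predictions.tsv", sep="\t", float_format="%.10g")
        results["predictions"] = predictions
        outcomes = validation.sample_meta["outcome"]
        assoc = clinstats.outcome_association(predictions, outcomes)
        assoc.to_json(out / "assoc.json")
        results["association"] = assoc
        log.info("validation: normal-WOI rate %.3f, Fisher p %.4f",
                 assoc.normal_rate, assoc.fisher_p)

    # --- manifest -----------------------------------------------------------
    artifacts = sorted(p.name for p in out.iterdir()
                       if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "artifacts": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
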