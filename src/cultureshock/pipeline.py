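"""Configuration, orchestration and report-bundle assembly.

A single YAML/dict config with per-stage blocks drives the stage graph

    synth (optional) -> qc -> cluster -> score/classify -> DE
                     -> coexpression -> causal/KDA

Every artifact is written with provenance (config hash, seed, package
version); identical configs produce byte-identical numeric outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import (
    ClusterParams,
    cluster_cells,
    downsample_per_cluster,
    normalize_log,
)
from .data import CellMatrix, ValidationError, read_counts, write_counts
from .de import culture_shock_signature, pairwise_de
from .kda import (
    build_effector_sets,
    driver_records,
    kda_enrich,
    learn_dag,
    prioritize,
    top_varying_genes,
)
from .network import build_correlation_graph
from .network import write_network as write_coexpr_network
from .qc import apply_filter, compute_qc_metrics, preset_rules
from .scoring import classify_clusters, detection_summary, score_table
from .scoring import default_state_sets
from .synth import generate_truth, inject_qc_artifacts, save_truth, simulate_counts

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and a snapshot path."""


DEFAULT_CONFIG: dict = {
    "run_id": "run0",
    "seed": 0,
    "synthetic": {
        "enabled": True,
        "n_genes": 1500,
        "n_states": 4,
        "n_modules": 3,
        "n_dag_nodes": 150,
        "n_drivers": 5,
        "n_condition_genes": 60,
        "effect_size": 1.0,
        "cells_per_state": 150,
        "conditions": ["fresh", "astro", "micro"],
        "dispersion": 0.5,
        "frac_high_mito": 0.0,
        "frac_low_count": 0.0,
    },
    "input": {"matrix": None, "features": None, "barcodes": None, "cell_meta": None},
    "qc": {"preset_rounds": ["fresh_round1", "fresh_round2"], "mito_prefix": "mt-"},
    "cluster": {
        "n_pcs": 50,
        "snn_dims": 30,
        "resolution": 0.6,
        "k_neighbors": 20,
        "n_hvg": 2000,
        "method": "louvain",
        "covariates": ["percent_mito"],
    },
    "score": {"min_cells": 10},
    "de": {
        "group_by": "condition",
        "group_a": "astro",
        "group_b": "fresh",
        "lfc_min": 0.5,
        "alpha": 0.05,
        "adjust": "bonferroni",
        "signature_n": 20,
    },
    "network": {
        "min_cells": 10,
        "fdr": 0.05,
        "n_per_cluster": 400,
        "strength_mode": "abs_r",
    },
    "kda": {
        "n_top": 150,
        "max_parents": 3,
        "depth": 3,
        "alpha": 0.05,
        "networks_by": "condition",
        "network_groups": ["astro", "micro"],
    },
}


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def merge_config(overrides: dict | None) -> dict:
    """Deep-merge user overrides onto the defaults."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(base: dict, over: dict, path: str) -> None:
        for k, v in over.items():
            if isinstance(v, dict) and isinstance(base.get(k), dict):
                merge(base[k], v, f"{path}{k}.")
            else:
                base[k] = v

    if overrides:
        merge(cfg, overrides, "")
    return cfg


def validate_config(config: dict) -> list[str]:
    """Return all violations (empty list = valid)."""
    errors: list[str] = []

    def check_keys(base: dict, given: dict, path: str) -> None:
        for k, v in given.items():
            if k not in base:
                errors.append(f"unknown config key: {path}{k}")
            elif isinstance(v, dict) and isinstance(base[k], dict):
                check_keys(base[k], v, f"{path}{k}.")

    check_keys(DEFAULT_CONFIG, config, "")
    cl = config.get("cluster", {})
    if cl.get("snn_dims", 30) > cl.get("n_pcs", 50):
        errors.append("cluster.snn_dims must be <= cluster.n_pcs")
    if cl.get("resolution", 0.6) <= 0:
        errors.append("cluster.resolution must be > 0")
    if "seed" not in config or not isinstance(config["seed"], int):
        errors.append("top-level integer seed is required (no unseeded randomness)")
    syn = config.get("synthetic", {})
    if not syn.get("enabled", True):
        inp = config.get("input", {})
        if not (inp.get("matrix") and inp.get("features") and inp.get("barcodes")):
            errors.append("synthetic disabled but input paths incomplete")
    return errors


def _write_tsv(df: pd.DataFrame, path: Path, chash: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, sep="\t", index=index)


def load_matrix_dir(path: str | Path) -> CellMatrix:
    """Read the matrix.mtx / features.tsv / barcodes.tsv triplet (plus
    optional cell_meta.tsv) from a directory."""
    p = Path(path)
    m = read_counts(p / "matrix.mtx", p / "features.tsv", p / "barcodes.tsv")
    meta_path = p / "cell_meta.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col=0, comment="#")
        m.cell_meta = meta.loc[m.cell_ids]
    return m


def run_pipeline(config: dict | None, out_dir: str | Path) -> dict:
    """Execute the full stage graph; returns a report-bundle summary dict.

    Any stage failure raises :class:`PipelineError` naming the stage and
    pointing at a cell-metadata snapshot of the stage input.
    """
    cfg = merge_config(config)
    errors = validate_config(cfg)
    if errors:
        raise ValidationError("invalid config: " + "; ".join(errors))
    chash = config_hash(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report: dict = {
        "run_id": cfg["run_id"],
        "config_hash": chash,
        "seed": seed,
        "version": __version__,
        "stages": {},
    }

    (out / "config.json").write_text(json.dumps(cfg, indent=2, default=str))

    current: CellMatrix | None = None
    stage = "init"
    t0 = time.time()

    def enter(name: str) -> None:
        nonlocal stage, t0
        stage = name
        t0 = time.time()
        logger.info("stage %s starting", name)

    def done(**info) -> None:
        report["stages"][stage] = {"seconds": round(time.time() - t0, 2), **info}
        logger.info("stage %s done (%s)", stage, info)

    try:
        enter("synth")
        if cfg["synthetic"]["enabled"]:
            syn = cfg["synthetic"]
            truth = generate_truth(
                n_genes=syn["n_genes"],
                n_states=syn["n_states"],
                n_modules=syn["n_modules"],
                n_dag_nodes=syn["n_dag_nodes"],
                n_drivers=syn["n_drivers"],
                n_condition_genes=syn["n_condition_genes"],
                effect_size=syn["effect_size"],
                seed=seed,
            )
            current = simulate_counts(
                truth,
                cells_per_state=syn["cells_per_state"],
                conditions=tuple(syn["conditions"]),
                seed=seed + 1,
                dispersion=syn["dispersion"],
            )
            if syn["frac_high_mito"] or syn["frac_low_count"]:
                current = inject_qc_artifacts(
                    current, syn["frac_high_mito"], syn["frac_low_count"],
                    seed=seed + 2,
                )
            save_truth(truth, out / "truth.json")
            write_counts(current, out / "counts")
        else:
            inp = cfg["input"]
            current = read_counts(inp["matrix"], inp["features"], inp["barcodes"])
            if inp.get("cell_meta"):
                meta = pd.read_csv(inp["cell_meta"], sep="\t", index_col=0, comment="#")
                current.cell_meta = meta.loc[current.cell_ids]
        done(cells=current.n_cells, genes=current.n_genes)

        enter("qc")
        current = compute_qc_metrics(current, cfg["qc"]["mito_prefix"])
        logs = []
        for preset in cfg["qc"]["preset_rounds"]:
            current, log = apply_filter(current, preset_rules(preset))
            log.insert(0, "preset", preset)
            logs.append(log)
        qc_log = pd.concat(logs, ignore_index=True)
        _write_tsv(qc_log, out / "qc_removal_log.tsv", chash, index=False)
        done(cells=current.n_cells)

        enter("cluster")
        params = ClusterParams(
            n_pcs=cfg["cluster"]["n_pcs"],
            snn_dims=cfg["cluster"]["snn_dims"],
            resolution=cfg["cluster"]["resolution"],
            k_neighbors=cfg["cluster"]["k_neighbors"],
            seed=seed + 3,
            n_hvg=cfg["cluster"]["n_hvg"],
            method=cfg["cluster"]["method"],
        )
        covs = tuple(
            c for c in cfg["cluster"]["covariates"] if c in current.cell_meta.columns
        )
        assignment = cluster_cells(current, params, covariates=covs)
        current.cell_meta["cluster"] = assignment.labels
        _write_tsv(
            current.cell_meta[["cluster"]], out / "clusters.tsv", chash
        )
        done(n_clusters=assignment.n_clusters)

        enter("score")
        if cfg["synthetic"]["enabled"]:
            # score against the planted state programs
            present = {
                state: list(program)
                for state, program in truth.state_programs.items()
            }
        else:
            sets = default_state_sets()
            present = {
                name: genes
                for name, genes in sets.sets.items()
                if set(genes) & set(current.gene_symbols)
            }
        if present:
            from .data import GeneSetCollection

            coll = GeneSetCollection(present)
            scores = score_table(current, coll)
            summary = detection_summary(current, coll, cfg["score"]["min_cells"])
            _write_tsv(summary, out / "detection_summary.tsv", chash)
            class_map = {name: name.lower() for name in coll.sets}
            labels = classify_clusters(
                scores, current.cell_meta["cluster"].to_numpy(), class_map
            )
            current.cell_meta["state"] = [
                labels.labels[int(c)] for c in current.cell_meta["cluster"]
            ]
            _write_tsv(labels.scaled_scores, out / "cluster_state_scores.tsv", chash)
            done(n_sets=len(coll))
        else:
            logger.warning("no state-panel genes present; scoring skipped")
            done(n_sets=0)

        enter("de")
        decfg = cfg["de"]
        gb = current.cell_meta[decfg["group_by"]].to_numpy()
        mask_a = gb == decfg["group_a"]
        mask_b = gb == decfg["group_b"]
        result = pairwise_de(
            current,
            mask_a,
            mask_b,
            lfc_min=decfg["lfc_min"],
            alpha=decfg["alpha"],
            labels=(decfg["group_a"], decfg["group_b"]),
            adjust=decfg["adjust"],
        )
        _write_tsv(result.table, out / "de_table.tsv", chash)
        up, down = culture_shock_signature(
            result, n=decfg["signature_n"], alpha=decfg["alpha"],
            lfc_min=decfg["lfc_min"],
        )
        (out / "signature.json").write_text(
            json.dumps({"up": up, "down": down, "_config_hash": chash})
        )
        sig = result.significant(decfg["alpha"], decfg["lfc_min"])
        done(n_significant=int(len(sig)))

        enter("network")
        down_mat = downsample_per_cluster(
            current,
            current.cell_meta["cluster"].to_numpy(),
            cfg["network"]["n_per_cluster"],
            seed=seed + 4,
        )
        net = build_correlation_graph(
            down_mat,
            min_cells=cfg["network"]["min_cells"],
            fdr=cfg["network"]["fdr"],
            strength_mode=cfg["network"]["strength_mode"],
            seed=seed + 5,
        )
        write_coexpr_network(
            net, out / "network_edges.tsv", out / "network_nodes.tsv"
        )
        done(n_nodes=len(net.genes), n_edges=int(len(net.edges)))

        enter("kda")
        kcfg = cfg["kda"]
        de_set = set(sig.index)
        records = {}
        groups = [
            g
            for g in kcfg["network_groups"]
            if (current.cell_meta[kcfg["networks_by"]] == g).sum() >= 50
        ]
        for grp in groups:
            sub = current.subset_cells(
                (current.cell_meta[kcfg["networks_by"]] == grp).to_numpy()
            )
            covs = tuple(
                c for c in ("percent_mito", "cluster")
                if c in sub.cell_meta.columns
                and sub.cell_meta[c].nunique() > 1
            )
            genes = top_varying_genes(
                sub, covariates=covs, n_top=min(kcfg["n_top"], sub.n_genes)
            )
            dag = learn_dag(sub, genes, max_parents=kcfg["max_parents"],
                            covariates=covs, seed=seed + 6)
            eff = build_effector_sets(
                de_set, net.modules, dag, network_id=grp
            )
            enrich = kda_enrich(dag, eff, depth=kcfg["depth"], alpha=kcfg["alpha"])
            records[grp] = driver_records(enrich)
        if len(records) >= 2:
            keys = list(records)
            ranked = prioritize(records[keys[0]], records[keys[1]])
        elif len(records) == 1:
            only = list(records.values())[0]
            ranked = prioritize(only, only.iloc[0:0])
        else:
            ranked = pd.DataFrame()
        if len(ranked):
            _write_tsv(ranked, out / "key_drivers.tsv", chash)
        done(n_drivers=int(len(ranked)))
    except Exception as exc:
        snap = out / f"snapshot_{stage}_cell_meta.tsv"
        try:
            if current is not None:
                current.cell_meta.to_csv(snap, sep="\t")
        except Exception:  # pragma: no cover
            pass
        raise PipelineError(
            f"stage {stage!r} failed: {exc} (input snapshot: {snap})"
        ) from exc

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
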