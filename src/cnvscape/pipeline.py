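"""End-to-end orchestration: simulate -> QC -> reduce -> iLISI -> CNV ->
DEG-with-CNV -> signatures -> summary.

A run is driven by a strict YAML/dict configuration (unknown keys are
errors), uses one global seed fanned out deterministically to per-stage
child seeds, writes every stage artifact as plain TSV/JSON, and is
bit-identical across reruns with the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import batch, cnv, deg, io, preprocess, signatures, simulate

__all__ = ["child_seed", "load_config", "default_run_config", "run_pipeline"]

logger = logging.getLogger("cnvscape")

_SECTION_KEYS = {
    "simulation": None,  # validated by SimulationConfig
    "qc": {"min_umi", "min_genes", "max_genes", "max_mito_pct"},
    "normalize": {"scale_factor"},
    "hvg": {"n_top"},
    "pca": {"n_components"},
    "pc_selection": {"cum_threshold", "indiv_threshold", "diff_threshold"},
    "ilisi": {"perplexity"},
    "cnv": {"min_mean_cutoff", "window", "clamp", "sd_multipliers"},
    "deg": {"logfc_threshold", "alpha", "min_cnv_fraction"},
    "signatures": {"top_fraction", "mode", "threshold"},
}
_TOP_KEYS = {"seed", "input_dir", "reference_group", "log_level", *_SECTION_KEYS}


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _check_keys(d: dict, allowed: set, context: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {context}: {sorted(unknown)}")


def default_run_config(seed: int = 0) -> dict:
    cfg = simulate.default_config(seed)
    return {
        "seed": seed,
        "reference_group": "reference",
        "simulation": asdict(cfg),
        "qc": {"min_umi": 300, "min_genes": 200, "max_genes": 7500,
               "max_mito_pct": 20.0},
        "normalize": {"scale_factor": 10000},
        "hvg": {"n_top": 3000},
        "pca": {"n_components": 30},
        "pc_selection": {"cum_threshold": 90.0, "indiv_threshold": 5.0,
                         "diff_threshold": 0.1},
        "ilisi": {"perplexity": 30},
        "cnv": {"min_mean_cutoff": 0.1, "window": 101, "clamp": 3.0,
                "sd_multipliers": [2.5, 4.0, 5.5]},
        "deg": {"logfc_threshold": 0.25, "alpha": 0.05, "min_cnv_fraction": 0.3},
        "signatures": {"top_fraction": 0.05, "mode": "kmeans", "threshold": 0.5},
    }


def load_config(path: Path | str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a mapping")
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    """Merge onto defaults with strict unknown-key rejection."""
    _check_keys(cfg, _TOP_KEYS, "run config")
    merged = default_run_config(int(cfg.get("seed", 0)))
    for key, val in cfg.items():
        if key in _SECTION_KEYS and _SECTION_KEYS[key] is not None:
            if not isinstance(val, dict):
                raise ValueError(f"section {key!r} must be a mapping")
            _check_keys(val, _SECTION_KEYS[key], f"section {key!r}")
            merged[key] = {**merged[key], **val}
        else:
            merged[key] = val
    return merged


def _sim_config_from_dict(d: dict, seed: int) -> simulate.SimulationConfig:
    d = dict(d)
    clones = [simulate.CloneSpec(**c) for c in d.pop("clones", [])]
    batches = [simulate.BatchSpec(**b) for b in d.pop("batches", [])]
    d.setdefault("seed", seed)
    d["mito_pct_range"] = tuple(d.get("mito_pct_range", (1.0, 8.0)))
    cfg = simulate.SimulationConfig(clones=clones, batches=batches, **d)
    cfg.validate()
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_pipeline(config: dict, out_dir: Path | str, overwrite: bool = False) -> dict:
    """Run every stage and write all artifacts; returns the run summary."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(cfg.get("log_level", "INFO"))
    seed = int(cfg["seed"])
    summary: dict = {"seed": seed, "config_hash": _config_hash(cfg), "stages": {}}

    def stage(name):
        t0 = time.perf_counter()
        logger.info("stage %s started", name)
        return t0

    def done(name, t0, **info):
        # timings go to the log only, so the summary is bit-reproducible
        summary["stages"][name] = dict(info)
        logger.info("stage %s finished in %.2fs %s", name,
                    time.perf_counter() - t0, info)

    try:
        # ------------------------------------------------ data
        t0 = stage("data")
        if cfg.get("input_dir"):
            adata, truth = io.read_fixture(cfg["input_dir"])
        else:
            sim_cfg = _sim_config_from_dict(
                cfg["simulation"], child_seed(seed, "simulate")
            )
            ann = simulate.simulate_gene_annotation(
                sim_cfg.n_chromosomes, sim_cfg.genes_per_arm,
                seed=child_seed(seed, "annotation"),
            )
            adata, truth = simulate.simulate_counts(sim_cfg, ann)
            io.write_fixture(adata, truth, out / "fixture", overwrite=True)
        ref_group = cfg.get("reference_group", "reference")
        if ref_group not in set(adata.obs["group"].astype(str)):
            raise ValueError(f"reference group {ref_group!r} absent from cells")
        done("data", t0, n_cells=int(adata.n_obs), n_genes=int(adata.n_vars))

        # ------------------------------------------------ qc
        t0 = stage("qc")
        thresholds = preprocess.QCThresholds(**cfg["qc"])
        adata, report = preprocess.qc_filter(adata, thresholds)
        _write_tsv(report.per_cell, out / "qc_report.tsv")
        done("qc", t0, cells_before=report.n_before, cells_after=report.n_after)

        # ------------------------------------------------ reduce
        t0 = stage("reduce")
        X_norm = preprocess.normalize_log(
            adata.X, cfg["normalize"]["scale_factor"], cell_ids=adata.obs_names
        )
        hvgs = preprocess.select_hvg(X_norm, adata.var_names, cfg["hvg"]["n_top"])
        hvg_idx = adata.var_names.get_indexer(hvgs)
        n_comp = min(cfg["pca"]["n_components"], len(hvgs) - 1, adata.n_obs - 1)
        embedding, spectrum = preprocess.run_pca(X_norm, hvg_idx, n_comp)
        k = preprocess.select_significant_pcs(spectrum, **cfg["pc_selection"])
        _write_tsv(
            pd.DataFrame(embedding, index=adata.obs_names,
                         columns=[f"PC{i+1}" for i in range(n_comp)]),
            out / "embedding.tsv",
        )
        with open(out / "pca_summary.json", "w") as fh:
            json.dump({"spectrum_pct": [round(float(v), 6) for v in spectrum],
                       "significant_pcs": int(k)}, fh, indent=1)
        done("reduce", t0, n_hvg=len(hvgs), significant_pcs=int(k))

        # ------------------------------------------------ ilisi
        t0 = stage("ilisi")
        ilisi = batch.compute_ilisi(
            embedding[:, :k], adata.obs["batch"], cfg["ilisi"]["perplexity"]
        )
        _write_tsv(ilisi.scores.rename("ilisi").to_frame(), out / "ilisi.tsv")
        summary["mean_ilisi"] = round(ilisi.mean, 4)
        done("ilisi", t0, mean_ilisi=round(ilisi.mean, 4))

        # ------------------------------------------------ cnv
        t0 = stage("cnv")
        ref_mask = (adata.obs["group"].astype(str) == ref_group).to_numpy()
        ccfg = cfg["cnv"]
        smoothed, kept_ann = cnv.smooth_relative_expression(
            X_norm, adata.var.reset_index().rename(columns={"index": "gene_id"}),
            ref_mask, ccfg["min_mean_cutoff"], ccfg["window"], ccfg["clamp"],
        )
        states = cnv.call_states(smoothed, ref_mask,
                                 tuple(ccfg["sd_multipliers"]))
        scores = cnv.cell_cnv_score(states)
        levels = pd.Series(pd.NA, index=adata.obs_names, dtype=object, name="cnv_level")
        levels[~ref_mask] = cnv.classify_cnv_level(
            scores[~ref_mask], scores[ref_mask]
        ).astype(str)
        score_table = pd.DataFrame(
            {"group": adata.obs["group"].astype(str), "clone": adata.obs["clone"],
             "cnv_score": scores, "cnv_level": levels},
            index=adata.obs_names,
        )
        _write_tsv(score_table, out / "cnv_scores.tsv")
        landscape = cnv.arm_event_landscape(states, kept_ann, adata.obs["clone"])
        _write_tsv(landscape, out / "arm_landscape.tsv", index=False)
        level_props = (
            score_table.loc[~ref_mask, "cnv_level"].value_counts(normalize=True)
            .round(4).to_dict()
        )
        summary["cnv_level_proportions"] = level_props
        done("cnv", t0, genes_kept=len(kept_ann), **{f"prop_{k_}": v
             for k_, v in level_props.items()})

        # ------------------------------------------------ deg
        t0 = stage("deg")
        dcfg = cfg["deg"]
        degs = deg.wilcoxon_de(
            X_norm, adata.var_names, ~ref_mask, ref_mask,
            dcfg["logfc_threshold"], dcfg["alpha"],
        )
        _write_tsv(degs, out / "deg.tsv", index=False)
        deg_cnv = deg.intersect_deg_cnv(
            degs, states, kept_ann["gene_id"], ~ref_mask,
            min_cnv_fraction=dcfg["min_cnv_fraction"],
        )
        _write_tsv(deg_cnv, out / "deg_with_cnv.tsv", index=False)
        summary["n_deg"] = int(len(degs))
        summary["n_deg_with_cnv"] = int(len(deg_cnv))
        done("deg", t0, n_deg=len(degs), n_deg_with_cnv=len(deg_cnv))

        # ------------------------------------------------ signatures
        t0 = stage("signatures")
        scfg = cfg["signatures"]
        score_df = signatures.score_gene_sets(
            X_norm, adata.var_names, truth.gene_sets, scfg["top_fraction"],
            seed=child_seed(seed, "signatures"), cell_ids=adata.obs_names,
        )
        _write_tsv(score_df, out / "signature_scores.tsv")
        tumor_scores = score_df.loc[~ref_mask]
        labels = signatures.classify_activity(
            tumor_scores, mode=scfg["mode"], threshold=scfg["threshold"]
        )
        _write_tsv(labels, out / "activity_labels.tsv")
        act_props = labels["activity"].value_counts(normalize=True).round(4).to_dict()
        summary["activity_proportions"] = {str(k_): v for k_, v in act_props.items()}
        done("signatures", t0, **summary["activity_proportions"])

        summary["cells_after_qc"] = report.n_after
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        return summary
    except Exception:
        logger.exception("pipeline failed")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
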