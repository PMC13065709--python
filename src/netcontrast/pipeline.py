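"""End-to-end orchestration: simulate -> sweep -> univariate -> classify.

Each stage writes CSV/JSON outputs into the run directory together with a
provenance record (config hash, stage seeds, package version).  A single
global seed fans out to fixed per-stage child seeds so stages stay
independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    ConnectivityRecord,
    NodeTable,
    default_node_table,
    load_cohort,
    write_connectivity,
    write_manifest,
)
from .classify import CVConfig, features_from_metrics, permutation_classification, \
    degenerate_report
from .graph import CommunityPartition
from .sweep import CostGrid, metrics_table, metrics_to_global, metrics_to_long, \
    sweep_cohort
from .synth import SyntheticConfig, generate_cohort, summarize_truth
from .univariate import attach_node_labels, fit_global_contrast, run_mass_univariate

logger = logging.getLogger("netcontrast")

#: fixed offsets deriving stage seeds from the global seed
_STAGE_SEED_OFFSET = {"simulate": 11, "classify_pc": 23, "classify_bc": 37}
_SEED_MOD = 2**31


@dataclass
class PipelineConfig:
    out_dir: Path
    manifest: Path | None = None          # when None, a cohort is simulated
    node_table: NodeTable = field(default_factory=default_node_table)
    synthetic: SyntheticConfig | None = None
    cost_grid: CostGrid = field(default_factory=CostGrid)
    cv: CVConfig = field(default_factory=CVConfig)
    seed: int = 0
    n_jobs: int = 1

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000003 + _STAGE_SEED_OFFSET[stage]) % _SEED_MOD


def _config_hash(config: PipelineConfig) -> str:
    desc = {
        "seed": config.seed,
        "costs": list(config.cost_grid.costs),
        "cv": {
            "k_folds": config.cv.k_folds,
            "c_grid": list(config.cv.c_grid),
            "n_permutations": config.cv.n_permutations,
            "weight_z_threshold": config.cv.weight_z_threshold,
        },
        "n_nodes": config.node_table.n_nodes,
        "manifest": str(config.manifest) if config.manifest else None,
    }
    return hashlib.sha256(json.dumps(desc, sort_keys=True).encode()).hexdigest()[:16]


def simulate_stage(config: PipelineConfig) -> tuple[list[ConnectivityRecord],
                                                    pd.DataFrame]:
    """Generate (or reuse) the synthetic cohort and write its artifacts."""
    out = Path(config.out_dir)
    synth_cfg = config.synthetic
    if synth_cfg is None:
        synth_cfg = SyntheticConfig(partition=config.node_table,
                                    seed=config.stage_seed("simulate"))
    records, truth, manifest = generate_cohort(synth_cfg)
    mat_dir = out / "matrices"
    mat_dir.mkdir(parents=True, exist_ok=True)
    for rec in records:
        rel = f"matrices/{rec.participant_id}_{rec.condition}.tsv"
        write_connectivity(rec, out / rel)
        col = f"path_{rec.condition}"
        manifest.loc[manifest["participant_id"] == rec.participant_id, col] = rel
    write_manifest(manifest, out / "manifest.csv")
    config.node_table.to_csv(out / "nodes.csv")
    summarize_truth(truth, synth_cfg.partition).to_csv(
        out / "ground_truth.csv", index=False
    )
    return records, manifest


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a summary dict also written as JSON."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(config)
    provenance = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }
    failed_marker = out / "FAILED"

    def _stage(name, fn):
        t0 = time.time()
        logger.info("stage %s starting", name)
        try:
            result = fn()
        except Exception:
            failed_marker.write_text(f"stage {name} failed\n")
            logger.exception("stage %s failed", name)
            raise
        provenance["stages"][name] = {"seconds": round(time.time() - t0, 2)}
        return result

    if config.manifest is None:
        records, _ = _stage("simulate", lambda: simulate_stage(config))
    else:
        manifest_path = Path(config.manifest)
        if not manifest_path.exists():
            raise FileNotFoundError(f"manifest not found: {manifest_path}")
        records = _stage(
            "load", lambda: load_cohort(manifest_path, config.node_table)
        )

    partition = CommunityPartition(config.node_table.community_labels)

    def _sweep():
        metrics = sweep_cohort(records, config.cost_grid, partition,
                               n_jobs=config.n_jobs)
        metrics_table(metrics).to_csv(out / "metrics_local.csv", index=False)
        metrics_to_global(metrics).to_csv(out / "metrics_global.csv", index=False)
        return metrics

    metrics = _stage("sweep", _sweep)

    def _univariate():
        results = {}
        for metric in ("pc", "bc"):
            long = metrics_to_long(metrics, metric)
            res = run_mass_univariate(long)
            labeled = attach_node_labels(res, config.node_table)
            labeled["config_hash"] = cfg_hash
            labeled.to_csv(out / f"univariate_{metric}.csv", index=False)
            results[metric] = res
        glob_table = metrics_to_global(metrics)
        rows = []
        for metric in ("e_global", "q"):
            g = fit_global_contrast(glob_table, metric)
            rows.append(
                [g.metric, g.mean_diff, g.b, g.se, g.t, g.df, g.p]
            )
        gdf = pd.DataFrame(
            rows, columns=["metric", "mean_diff", "b", "se", "t", "df", "p"]
        )
        gdf["config_hash"] = cfg_hash
        gdf.to_csv(out / "univariate_global.csv", index=False)
        results["global"] = gdf
        return results

    univ = _stage("univariate", _univariate)

    def _classify(metric):
        long = metrics_to_long(metrics, metric)
        feats = features_from_metrics(long)
        cv = CVConfig(
            k_folds=config.cv.k_folds,
            c_grid=config.cv.c_grid,
            n_permutations=config.cv.n_permutations,
            weight_z_threshold=config.cv.weight_z_threshold,
            inner_folds=config.cv.inner_folds,
            add_one_p=config.cv.add_one_p,
            seed=config.stage_seed(f"classify_{metric}"),
        )
        result = permutation_classification(feats, cv)
        summary = {
            "metric": metric,
            "mean_accuracy": result.mean_accuracy,
            "mean_dice": result.mean_dice,
            "p_perm": result.p_perm,
            "flagged_features": result.flagged_features,
            "degenerate": degenerate_report(result)["degenerate"],
            "config_hash": cfg_hash,
        }
        with open(out / f"classification_{metric}.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        pd.DataFrame({"null_accuracy": result.null_accuracies}).to_csv(
            out / f"null_accuracies_{metric}.csv", index=False
        )
        pd.DataFrame(
            {
                "feature": result.feature_names,
                "mean_weight": result.mean_weights,
                "z": result.weight_z,
                "flagged": [f in result.flagged_features
                            for f in result.feature_names],
            }
        ).to_csv(out / f"feature_weights_{metric}.csv", index=False)
        return summary

    cls_pc = _stage("classify_pc", lambda: _classify("pc"))
    cls_bc = _stage("classify_bc", lambda: _classify("bc"))

    summary = {
        "provenance": provenance,
        "n_records": len(records),
        "univariate_global": univ["global"].to_dict(orient="records"),
        "classification": {"pc": cls_pc, "bc": cls_bc},
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    if failed_marker.exists():
        failed_marker.unlink()
    return summary
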