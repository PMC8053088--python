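"""Multi-stage benchmark runner with per-stage CSV outputs.

Stages: QC → correction(s) → mixing entropies → clustering evaluation →
marker consistency.  Each stage writes a CSV whose first lines are ``#``
provenance comments (config hash, seed, package version); read them back
with ``pd.read_csv(..., comment="#")``.  Stage failures are isolated:
downstream stages that depend on a failed or inapplicable stage are
skipped with an explicit status instead of aborting the run.
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
import yaml

from . import __version__
from .core import ExpressionDataset
from .correction import CorrectionOutput, applicable_stages, get_method
from .clustering import (
    FEATURE_FRACTIONS,
    cluster_graph_community,
    cluster_hierarchical,
    cluster_kmeans_correlation,
    preprocess_for_clustering,
    rank_by_cv,
    select_features,
    summarize_similarity,
)
from .entropy import DEFAULT_K, evaluate_mixing
from .markers import compare_markers
from .qc import QC_PRESETS, QCConfig, apply_qc

log = logging.getLogger("scbatcheval")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full benchmark run."""

    input_path: str
    output_dir: str
    metadata_path: str | None = None
    qc_preset: str | None = None
    qc: QCConfig | None = None
    methods: tuple[str, ...] = ("uncorrected", "linear")
    k: int = DEFAULT_K
    clustering_algorithms: tuple[str, ...] = ("ward", "leiden", "louvain", "kmeans", "kmedoids")
    feature_fractions: tuple[float, ...] = FEATURE_FRACTIONS
    n_clusters: int | None = None  # default: number of annotated cell types
    resolution: float = 1.0
    seed: int = 0
    marker_min_abs_logfc: float = 2.0
    marker_min_detection: float = 0.5
    marker_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "qc" in raw and isinstance(raw["qc"], dict):
            raw["qc"] = QCConfig(**raw["qc"])
        for key in ("methods", "clustering_algorithms", "feature_fractions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        payload = {k: str(v) for k, v in sorted(self.__dict__.items())}
        return hashlib.sha256(json.dumps(payload).encode()).hexdigest()[:12]


@dataclass
class StageStatus:
    name: str
    status: str  # ok | failed | skipped | not_applicable
    detail: str = ""
    seconds: float = 0.0


@dataclass
class PipelineResult:
    outputs: dict[str, Path] = field(default_factory=dict)
    stages: list[StageStatus] = field(default_factory=list)

    def status_of(self, name: str) -> str:
        for s in self.stages:
            if s.name == name:
                return s.status
        return "missing"


def _provenance_header(config: RunConfig) -> str:
    return (
        f"# scbatcheval {__version__}\n"
        f"# config_hash {config.digest()}\n"
        f"# seed {config.seed}\n"
    )


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(config))
        df.to_csv(fh, index=False)


def _run_clustering_sweep(ds: ExpressionDataset, config: RunConfig, n_clusters: int):
    ranking = rank_by_cv(ds)
    results = []
    for frac in config.feature_fractions:
        genes = set(select_features(ranking, frac))
        mask = np.array([g in genes for g in ds.gene_ids])
        sub = preprocess_for_clustering(ds.subset_genes(mask))
        for algo in config.clustering_algorithms:
            if algo == "ward":
                r = cluster_hierarchical(sub, n_clusters, feature_fraction=frac)
            elif algo in ("leiden", "louvain"):
                r = cluster_graph_community(
                    sub, method=algo, resolution=config.resolution,
                    k=min(config.k, sub.n_cells - 1), seed=config.seed,
                    feature_fraction=frac,
                )
            elif algo in ("kmeans", "kmedoids"):
                clipped = preprocess_for_clustering(sub, clip_negative=True)
                r = cluster_kmeans_correlation(
                    clipped, n_clusters, mode=algo, seed=config.seed,
                    feature_fraction=frac,
                )
            else:
                raise ValueError(f"unknown clustering algorithm {algo!r}")
            results.append((r, sub.cell_ids))
    return results


def run_pipeline(config: RunConfig, dataset: ExpressionDataset | None = None) -> PipelineResult:
    """Execute the benchmark; returns paths of written outputs and statuses.

    ``dataset`` may be passed directly (e.g. a synthetic fixture); otherwise
    it is read from ``config.input_path``.  Fixed seeds make reruns
    byte-identical.  Input files are never mutated.
    """
    from .io import read_dataset, write_h5ad

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
            result.stages.append(StageStatus(name, "ok", seconds=time.perf_counter() - t0))
        except Exception as exc:  # stage isolation: report, don't abort
            log.exception("stage %s failed", name)
            result.stages.append(
                StageStatus(name, "failed", detail=str(exc), seconds=time.perf_counter() - t0)
            )

    state: dict = {}

    # ---- load + QC ----------------------------------------------------
    def stage_qc():
        ds = dataset if dataset is not None else read_dataset(config.input_path, config.metadata_path)
        qc_cfg = config.qc
        if qc_cfg is None and config.qc_preset:
            qc_cfg = QC_PRESETS[config.qc_preset]
        if qc_cfg is None:
            qc_cfg = QCConfig(drop_unannotated=True)
        filtered, report = apply_qc(ds, qc_cfg)
        state["dataset"] = filtered
        rows = [{"rule": k, "cells_removed": v} for k, v in report.cells_removed_by_rule.items()]
        rows.append({"rule": "genes_removed", "cells_removed": report.genes_removed})
        path = out_dir / "qc_report.csv"
        _write_csv(pd.DataFrame(rows), path, config)
        result.outputs["qc_report"] = path

    run_stage("qc", stage_qc)
    if "dataset" not in state:
        for name in ("correction", "entropy", "clustering", "markers"):
            result.stages.append(StageStatus(name, "skipped", detail="qc failed"))
        return result

    ds = state["dataset"]
    n_types = len(set(np.asarray(ds.cell_type, dtype=object).astype(str)))
    n_clusters = config.n_clusters or n_types

    corrections: dict[str, CorrectionOutput] = {}

    def stage_correction():
        for name in config.methods:
            corrections[name] = get_method(name)(ds)
            if corrections[name].space_kind == "matrix":
                path = out_dir / f"corrected_{name}.h5ad"
                write_h5ad(corrections[name].payload, path)
                result.outputs[f"corrected_{name}"] = path

    run_stage("correction", stage_correction)

    def stage_entropy():
        rows = []
        for name, out in corrections.items():
            if out.space_kind == "graph":
                be, ce = evaluate_mixing(
                    out.payload, k=config.k, batch=ds.batch, cell_type=ds.cell_type
                )
                cell_ids = ds.cell_ids
            else:
                be, ce = evaluate_mixing(out.payload, k=config.k)
                cell_ids = out.payload.cell_ids
            for cid, b, c in zip(cell_ids, be.per_cell, ce.per_cell):
                rows.append({"method": name, "cell_id": cid,
                             "batch_entropy": b, "celltype_entropy": c})
            rows.append({"method": name, "cell_id": "__aggregate__",
                         "batch_entropy": be.aggregate, "celltype_entropy": ce.aggregate})
        path = out_dir / "entropy.csv"
        _write_csv(pd.DataFrame(rows), path, config)
        result.outputs["entropy"] = path

    run_stage("entropy", stage_entropy)

    def stage_clustering():
        rows = []
        for name, out in corrections.items():
            if out.space_kind != "matrix":
                continue  # feature sweep needs an expression matrix
            target = out.payload
            truth_by_id = dict(zip(ds.cell_ids, np.asarray(ds.cell_type, dtype=object).astype(str)))
            for r, cell_ids in _run_clustering_sweep(target, config, n_clusters):
                truth = np.asarray([truth_by_id[c] for c in cell_ids])
                summary = summarize_similarity([r], truth)
                row = summary.table.iloc[0].to_dict()
                row["method"] = name
                rows.append(row)
        path = out_dir / "clustering.csv"
        _write_csv(pd.DataFrame(rows), path, config)
        result.outputs["clustering"] = path

    run_stage("clustering", stage_clustering)

    def stage_markers():
        rows = []
        batch_labels = np.asarray(ds.batch, dtype=object).astype(str)
        batches = [
            ds.subset_cells(batch_labels == b) for b in sorted(set(batch_labels))
        ]
        any_applicable = False
        for name, out in corrections.items():
            if "markers" not in applicable_stages(out.space_kind):
                rows.append({"method": name, "population": "",
                             "jaccard": "", "status": "not_applicable"})
                continue
            any_applicable = True
            score = compare_markers(
                out.payload, batches,
                min_abs_logfc=config.marker_min_abs_logfc,
                min_detection=config.marker_min_detection,
                alpha=config.marker_alpha,
            )
            for pop, j in score.per_population.items():
                rows.append({"method": name, "population": pop,
                             "jaccard": "" if j is None else j, "status": "ok"})
            rows.append({"method": name, "population": "__fraction_with_markers__",
                         "jaccard": score.fraction_with_markers, "status": "ok"})
        path = out_dir / "markers.csv"
        _write_csv(pd.DataFrame(rows), path, config)
        result.outputs["markers"] = path
        if not any_applicable:
            raise RuntimeError("no matrix-space method: marker stage not applicable")

    # marker stage is inapplicable rather than failed when every method is
    # graph/embedding-space
    if all("markers" not in applicable_stages(o.space_kind) for o in corrections.values()) \
            and corrections:
        result.stages.append(
            StageStatus("markers", "not_applicable",
                        detail="no method returned an expression matrix")
        )
    else:
        run_stage("markers", stage_markers)

    return result
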