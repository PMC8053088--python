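"""Per-dataset quality control applied before benchmarking.

All thresholds remove items *strictly below* the cutoff, so a cell type
sitting exactly at the floor is retained.  The rule order is fixed:

1. drop cells with missing or excluded (e.g. "unclassified") labels,
2. per-cell filters (total counts, genes detected),
3. per-gene filter (cells expressing the gene),
4. cell-type-fraction floor,
5. batch-fraction floor,

with the fraction denominators in steps 4–5 computed on the population that
remains after step 3.  "Expressed" means count > 0.  One pass, no iteration
to a fixpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ExpressionDataset

__all__ = ["QCConfig", "QCReport", "QC_PRESETS", "apply_qc"]

DEFAULT_EXCLUDED_LABELS = frozenset({"unclassified", "unknown", "NA", "nan", "not applicable"})


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for the five filtering rules; zero disables a rule."""

    min_counts_per_cell: int = 0
    min_genes_per_cell: int = 0
    min_cells_per_gene: int = 0
    min_celltype_fraction: float = 0.0
    min_batch_fraction: float = 0.0
    drop_unannotated: bool = True
    excluded_label_values: frozenset[str] = DEFAULT_EXCLUDED_LABELS

    def __post_init__(self) -> None:
        for name in ("min_celltype_fraction", "min_batch_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("min_counts_per_cell", "min_genes_per_cell", "min_cells_per_gene"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# Profiles mirroring the published per-dataset settings: pancreas
# (<200 counts, gene in <3 cells), Mouse Cell Atlas (<250 genes, gene in
# <50 cells, 1% cell-type floor, 5% batch floor), Tabula Muris organs
# (<1000 genes, gene in <50 cells, same floors) and the merged atlas
# (>200 genes retained i.e. <=200 removed, gene in >3 cells retained).
QC_PRESETS: dict[str, QCConfig] = {
    "pancreas": QCConfig(min_counts_per_cell=200, min_cells_per_gene=3),
    "mca": QCConfig(
        min_genes_per_cell=250,
        min_cells_per_gene=50,
        min_celltype_fraction=0.01,
        min_batch_fraction=0.05,
    ),
    "tm": QCConfig(
        min_genes_per_cell=1000,
        min_cells_per_gene=50,
        min_celltype_fraction=0.01,
        min_batch_fraction=0.05,
    ),
    "atlas": QCConfig(
        min_genes_per_cell=201,
        min_cells_per_gene=4,
        min_celltype_fraction=0.01,
        min_batch_fraction=0.05,
    ),
}


@dataclass
class QCReport:
    cells_removed_by_rule: dict[str, int] = field(default_factory=dict)
    genes_removed: int = 0
    celltypes_removed: list[str] = field(default_factory=list)
    batches_removed: list[str] = field(default_factory=list)
    input_shape: tuple[int, int] = (0, 0)
    final_shape: tuple[int, int] = (0, 0)

    @property
    def cells_removed(self) -> int:
        return sum(self.cells_removed_by_rule.values())


def apply_qc(dataset: ExpressionDataset, config: QCConfig) -> tuple[ExpressionDataset, QCReport]:
    """Filter a dataset; returns a new dataset and a reconciling report.

    Count-based rules use the ``counts`` layer.  Raises if every cell or
    every gene would be removed.
    """
    report = QCReport(input_shape=dataset.shape)
    ds = dataset

    # 1. unannotated / excluded-label cells
    if config.drop_unannotated or config.excluded_label_values:
        bad = np.zeros(ds.n_cells, dtype=bool)
        if config.drop_unannotated:
            bad |= np.asarray(ds.batch.codes) == -1
            bad |= np.asarray(ds.cell_type.codes) == -1
        if config.excluded_label_values:
            excl = {v.lower() for v in config.excluded_label_values}
            for labels in (ds.batch, ds.cell_type):
                vals = np.asarray(labels, dtype=object)
                bad |= np.array(
                    [v is not None and str(v).lower() in excl for v in vals], dtype=bool
                )
        report.cells_removed_by_rule["unannotated"] = int(bad.sum())
        if bad.any():
            ds = ds.subset_cells(~bad)
    else:
        report.cells_removed_by_rule["unannotated"] = 0

    counts = ds.X("counts") if "counts" in ds.layers else None

    # 2. per-cell filters
    keep = np.ones(ds.n_cells, dtype=bool)
    if config.min_counts_per_cell > 0:
        if counts is None:
            raise ValueError("min_counts_per_cell requires a counts layer")
        keep &= counts.sum(axis=1) >= config.min_counts_per_cell
    if config.min_genes_per_cell > 0:
        if counts is None:
            raise ValueError("min_genes_per_cell requires a counts layer")
        keep &= (counts > 0).sum(axis=1) >= config.min_genes_per_cell
    report.cells_removed_by_rule["cell_filters"] = int((~keep).sum())
    if not keep.any():
        raise ValueError("QC would remove all cells")
    if not keep.all():
        ds = ds.subset_cells(keep)
        counts = ds.X("counts") if counts is not None else None

    # 3. per-gene filter
    if config.min_cells_per_gene > 0:
        if counts is None:
            raise ValueError("min_cells_per_gene requires a counts layer")
        keep_g = (counts > 0).sum(axis=0) >= config.min_cells_per_gene
        report.genes_removed = int((~keep_g).sum())
        if not keep_g.any():
            raise ValueError("QC would remove all genes")
        if not keep_g.all():
            ds = ds.subset_genes(keep_g)

    # 4-5. label-fraction floors; both fractions are evaluated on the
    # population remaining after step 3, then applied sequentially
    n3 = ds.n_cells
    for rule, labels_attr, threshold, removed_list in (
        ("celltype_fraction", "cell_type", config.min_celltype_fraction, report.celltypes_removed),
        ("batch_fraction", "batch", config.min_batch_fraction, report.batches_removed),
    ):
        if threshold > 0:
            labels = np.asarray(getattr(ds, labels_attr), dtype=object).astype(str)
            uniq, cnt = np.unique(labels, return_counts=True)
            drop_labels = {u for u, c in zip(uniq, cnt) if c / n3 < threshold}
            removed_list.extend(sorted(drop_labels))
            bad = np.isin(labels, sorted(drop_labels))
            report.cells_removed_by_rule[rule] = int(bad.sum())
            if bad.all():
                raise ValueError("QC would remove all cells")
            if bad.any():
                ds = ds.subset_cells(~bad)
        else:
            report.cells_removed_by_rule[rule] = 0

    report.final_shape = ds.shape
    return ds, report
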