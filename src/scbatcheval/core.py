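"""Shared data model: expression datasets, embeddings and neighbor graphs.

Everything downstream (entropy, clustering, marker analysis) consumes one of
three spaces:

* :class:`ExpressionDataset` — a cells × genes matrix with at least one of a
  ``counts`` layer (non-negative) and a ``lognorm`` layer (log-normalized,
  real-valued after correction), plus per-cell batch and cell-type labels.
* :class:`Embedding` — cells × dims coordinates, for correction methods that
  return a low-dimensional representation instead of a matrix.
* :class:`NeighborGraph` — a directed k-nearest-neighbor structure, for
  methods that return only a batch-balanced graph.

Cells are rows and genes are columns everywhere; readers transpose on load
when the on-disk convention differs.  Label columns are stored as pandas
categoricals with a lexicographic category order fixed at load, so that
probability vectors and entropy normalization are reproducible.  Missing
labels are representable (NaN codes) before QC; downstream stages require a
validated, fully labelled dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "Embedding",
    "NeighborGraph",
    "ValidationReport",
    "validate",
    "log_normalize",
    "as_categorical",
]


def as_categorical(values: Iterable) -> pd.Categorical:
    """Categorical with lexicographically ordered categories.

    Missing values (None / NaN / empty string) keep code -1.
    """
    arr = pd.array(list(values), dtype="object")
    arr = np.asarray(
        [None if (v is None or (isinstance(v, float) and np.isnan(v)) or v == "") else str(v) for v in arr],
        dtype=object,
    )
    cats = sorted({v for v in arr if v is not None})
    return pd.Categorical(arr, categories=cats)


def log_normalize(counts: np.ndarray, target_sum: float = 1e4) -> np.ndarray:
    """Depth-normalize each cell to ``target_sum`` total counts and log1p.

    Cells with zero total counts are left at zero.  This is the scanpy-style
    recipe; any log-scale layer may be designated instead — the metrics are
    computed on whatever layer the caller designates.
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    scale = np.divide(target_sum, totals, out=np.ones_like(totals), where=totals > 0)
    return np.log1p(counts * scale)


@dataclass
class ExpressionDataset:
    """Cells × genes expression matrix with batch and cell-type labels."""

    layers: dict[str, np.ndarray]
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    batch: pd.Categorical
    cell_type: pd.Categorical

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if not self.layers:
            raise ValueError("at least one layer (counts or lognorm) is required")
        self.layers = {k: np.asarray(v) for k, v in self.layers.items()}
        n, g = len(self.cell_ids), len(self.gene_ids)
        for name, mat in self.layers.items():
            if mat.shape != (n, g):
                raise ValueError(
                    f"layer {name!r} has shape {mat.shape}, expected ({n}, {g}) "
                    "(cells x genes)"
                )
        if not isinstance(self.batch, pd.Categorical):
            self.batch = as_categorical(self.batch)
        if not isinstance(self.cell_type, pd.Categorical):
            self.cell_type = as_categorical(self.cell_type)
        for label_name, labels in (("batch", self.batch), ("cell_type", self.cell_type)):
            if len(labels) != n:
                raise ValueError(f"{label_name} has {len(labels)} entries for {n} cells")

    # -- basic geometry -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_cells, self.n_genes)

    # -- layer access ---------------------------------------------------
    @property
    def default_layer(self) -> str:
        """The layer metrics run on: ``lognorm`` when present, else first."""
        if "lognorm" in self.layers:
            return "lognorm"
        return next(iter(self.layers))

    def X(self, layer: str | None = None) -> np.ndarray:
        name = layer or self.default_layer
        try:
            return self.layers[name]
        except KeyError:
            raise KeyError(f"layer {name!r} not present; have {sorted(self.layers)}") from None

    @property
    def counts(self) -> np.ndarray:
        return self.X("counts")

    @property
    def lognorm(self) -> np.ndarray:
        return self.X("lognorm")

    def with_layer(self, name: str, matrix: np.ndarray) -> "ExpressionDataset":
        layers = dict(self.layers)
        layers[name] = np.asarray(matrix)
        return replace(self, layers=layers)

    def recompute_lognorm(self, target_sum: float = 1e4) -> "ExpressionDataset":
        return self.with_layer("lognorm", log_normalize(self.counts, target_sum))

    # -- subsetting -----------------------------------------------------
    def subset_cells(self, index: np.ndarray) -> "ExpressionDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return ExpressionDataset(
            layers={k: v[index] for k, v in self.layers.items()},
            cell_ids=self.cell_ids[index],
            gene_ids=self.gene_ids,
            batch=_subset_categorical(self.batch, index),
            cell_type=_subset_categorical(self.cell_type, index),
        )

    def subset_genes(self, index: np.ndarray) -> "ExpressionDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return ExpressionDataset(
            layers={k: v[:, index] for k, v in self.layers.items()},
            cell_ids=self.cell_ids,
            gene_ids=self.gene_ids[index],
            batch=self.batch,
            cell_type=self.cell_type,
        )

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            layers={k: v.copy() for k, v in self.layers.items()},
            cell_ids=self.cell_ids.copy(),
            gene_ids=self.gene_ids.copy(),
            batch=self.batch.copy(),
            cell_type=self.cell_type.copy(),
        )


def _subset_categorical(cat: pd.Categorical, index: np.ndarray) -> pd.Categorical:
    sub = cat[index]
    # keep only categories still present, re-sorted, so downstream
    # "categories present in the dataset" stays well defined after QC
    present = sorted(set(sub.dropna()))
    return pd.Categorical(np.asarray(sub), categories=present)


@dataclass
class Embedding:
    """Cells × dims coordinates with the same label contract as a dataset."""

    coords: np.ndarray
    cell_ids: np.ndarray
    batch: pd.Categorical
    cell_type: pd.Categorical

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.coords.ndim != 2 or self.coords.shape[1] < 1:
            raise ValueError("coords must be a 2-D cells x dims matrix with dims >= 1")
        if self.coords.shape[0] != len(self.cell_ids):
            raise ValueError("coords row count does not match cell_ids")
        if not isinstance(self.batch, pd.Categorical):
            self.batch = as_categorical(self.batch)
        if not isinstance(self.cell_type, pd.Categorical):
            self.cell_type = as_categorical(self.cell_type)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class NeighborGraph:
    """Directed kNN structure: for each cell, its k nearest other cells.

    ``neighbors`` is an (n_cells, m) integer array with m = min(k, n-1);
    rows are ordered nearest-first.  No self-loops.
    """

    k: int
    neighbors: np.ndarray
    distances: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.neighbors = np.asarray(self.neighbors, dtype=int)
        if self.neighbors.ndim != 2:
            raise ValueError("neighbors must be a 2-D (cells x k) integer array")
        n, m = self.neighbors.shape
        if m != min(self.k, n - 1):
            raise ValueError(
                f"each neighbor list must have min(k, n-1) = {min(self.k, n - 1)} "
                f"entries, got {m}"
            )
        if (self.neighbors < 0).any() or (self.neighbors >= n).any():
            raise ValueError("neighbor indices out of range")
        if (self.neighbors == np.arange(n)[:, None]).any():
            raise ValueError("self-loops are not allowed")
        rows_sorted = np.sort(self.neighbors, axis=1)
        if (rows_sorted[:, 1:] == rows_sorted[:, :-1]).any():
            raise ValueError("duplicate neighbors within a cell's list")
        if self.distances is not None:
            self.distances = np.asarray(self.distances, dtype=float)
            if self.distances.shape != self.neighbors.shape:
                raise ValueError("distances shape must match neighbors")

    @property
    def n_cells(self) -> int:
        return self.neighbors.shape[0]


@dataclass
class ValidationReport:
    """Outcome of the input-contract check; empty issue lists mean valid."""

    duplicate_cell_ids: list = field(default_factory=list)
    duplicate_gene_ids: list = field(default_factory=list)
    cells_missing_batch: list = field(default_factory=list)
    cells_missing_cell_type: list = field(default_factory=list)
    negative_count_entries: int = 0

    @property
    def n_issues(self) -> int:
        return (
            len(self.duplicate_cell_ids)
            + len(self.duplicate_gene_ids)
            + len(self.cells_missing_batch)
            + len(self.cells_missing_cell_type)
            + (1 if self.negative_count_entries else 0)
        )

    @property
    def ok(self) -> bool:
        return self.n_issues == 0


def validate(dataset: ExpressionDataset) -> ValidationReport:
    """Check the input contract without mutating the dataset.

    Lists duplicate ids, cells missing batch or cell-type annotation, and
    negative entries in the counts layer.  Shape mismatches between layers
    and ids are unrepresentable — the constructor raises on those.
    """
    report = ValidationReport()
    for ids, out in (
        (dataset.cell_ids, report.duplicate_cell_ids),
        (dataset.gene_ids, report.duplicate_gene_ids),
    ):
        seen: dict = {}
        for i in ids:
            seen[i] = seen.get(i, 0) + 1
        out.extend(sorted(i for i, c in seen.items() if c > 1))
    codes_b = np.asarray(dataset.batch.codes)
    codes_c = np.asarray(dataset.cell_type.codes)
    report.cells_missing_batch = list(dataset.cell_ids[codes_b == -1])
    report.cells_missing_cell_type = list(dataset.cell_ids[codes_c == -1])
    if "counts" in dataset.layers:
        report.negative_count_entries = int((dataset.layers["counts"] < 0).sum())
    return report


def concatenate(datasets: Sequence[ExpressionDataset]) -> ExpressionDataset:
    """Stack datasets cell-wise; gene spaces must match exactly."""
    first = datasets[0]
    for d in datasets[1:]:
        if not np.array_equal(d.gene_ids, first.gene_ids):
            raise ValueError("gene spaces differ; cannot concatenate")
    common_layers = set(first.layers)
    for d in datasets[1:]:
        common_layers &= set(d.layers)
    if not common_layers:
        raise ValueError("datasets share no layer")
    return ExpressionDataset(
        layers={k: np.vstack([d.layers[k] for d in datasets]) for k in sorted(common_layers)},
        cell_ids=np.concatenate([d.cell_ids for d in datasets]),
        gene_ids=first.gene_ids,
        batch=as_categorical(np.concatenate([np.asarray(d.batch, dtype=object) for d in datasets])),
        cell_type=as_categorical(
            np.concatenate([np.asarray(d.cell_type, dtype=object) for d in datasets])
        ),
    )
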