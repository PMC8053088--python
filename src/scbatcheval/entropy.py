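"""kNN-graph mixing entropies — the primary benchmark metric.

Every correction output (expression matrix, embedding or neighbor graph) is
reduced to a directed kNN graph: each cell is connected to its k = 30
nearest neighbors by Euclidean distance on the designated space.  For each
cell i we compute the empirical frequency of each batch b (P_ib) and each
cell type c (P_ic) among its neighbors, and from these the per-cell Shannon
entropies H_i = −Σ P log P.  The aggregate statistic is the mean over cells
divided by the theoretical maximum log(C), where C is the number of label
categories present in the whole dataset, giving a value in [0, 1]:

* batch entropy 1 — batches perfectly mixed (desired after correction);
* cell-type entropy 0 — cell populations remain separate (desired).

The ratio H / log C is independent of the logarithm base; natural log is
used internally.  The kNN search is exact (blocked full distance matrix),
with ties in distance broken by ascending cell index, so graphs — and hence
entropies — are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import Embedding, ExpressionDataset, NeighborGraph, as_categorical

__all__ = [
    "EntropyResult",
    "build_knn_graph",
    "label_probabilities",
    "normalized_entropy",
    "evaluate_mixing",
]

DEFAULT_K = 30
_BLOCK = 1024  # rows per distance block; bounds memory at ~n*8KB per block


@dataclass
class EntropyResult:
    """Normalized Shannon mixing entropy for one label kind."""

    per_cell: np.ndarray  # normalized, in [0, 1]; raw H_i / log(C)
    aggregate: float
    label_kind: str
    n_categories: int
    k: int
    single_category: bool = False

    @property
    def per_cell_raw(self) -> np.ndarray:
        """Raw per-cell entropies in [0, log(n_categories)] (natural log)."""
        if self.single_category:
            return np.zeros_like(self.per_cell)
        return self.per_cell * np.log(self.n_categories)


def _space_matrix(space, layer: str | None = None) -> np.ndarray:
    if isinstance(space, ExpressionDataset):
        return np.asarray(space.X(layer), dtype=float)
    if isinstance(space, Embedding):
        return space.coords
    return np.asarray(space, dtype=float)


def build_knn_graph(space, k: int = DEFAULT_K, layer: str | None = None) -> NeighborGraph:
    """Exact Euclidean kNN graph with deterministic tie-breaking.

    ``space`` is an ExpressionDataset (designated layer), an Embedding, or a
    raw cells × dims array.  Each cell's list holds its min(k, n−1) nearest
    *other* cells, nearest first; equal distances are resolved in favor of
    the lower cell index.  k ≥ n_cells is clamped with a warning.
    """
    X = _space_matrix(space, layer)
    n = X.shape[0]
    if n < 2:
        raise ValueError("kNN graph requires at least 2 cells")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        warnings.warn(f"k={k} >= n_cells={n}; clamping to {n - 1}", stacklevel=2)
    m = min(k, n - 1)

    neighbors = np.empty((n, m), dtype=int)
    distances = np.empty((n, m), dtype=float)
    for start in range(0, n, _BLOCK):
        stop = min(start + _BLOCK, n)
        D = cdist(X[start:stop], X)
        D[np.arange(start, stop) - start, np.arange(start, stop)] = np.inf
        # stable sort on distance preserves ascending-index order among ties
        order = np.argsort(D, axis=1, kind="stable")[:, :m]
        neighbors[start:stop] = order
        distances[start:stop] = np.take_along_axis(D, order, axis=1)
    return NeighborGraph(k=k, neighbors=neighbors, distances=distances)


def _codes_and_categories(labels) -> tuple[np.ndarray, list]:
    if not isinstance(labels, pd.Categorical):
        labels = as_categorical(labels)
    codes = np.asarray(labels.codes)
    if (codes == -1).any():
        raise ValueError("labels contain missing values; run QC/validation first")
    # categories actually present in the dataset define the probability
    # support and the theoretical-maximum normalizer
    present = np.unique(codes)
    remap = -np.ones(len(labels.categories), dtype=int)
    remap[present] = np.arange(len(present))
    return remap[codes], [labels.categories[i] for i in present]


def label_probabilities(graph: NeighborGraph, labels) -> np.ndarray:
    """Per-cell neighborhood label frequencies P_i (rows sum to 1)."""
    codes, categories = _codes_and_categories(labels)
    if len(codes) != graph.n_cells:
        raise ValueError("labels do not align with the graph's cells")
    neigh = codes[graph.neighbors]  # (n, m)
    C = len(categories)
    P = np.empty((graph.n_cells, C), dtype=float)
    for c in range(C):
        P[:, c] = (neigh == c).mean(axis=1)
    return P


def normalized_entropy(graph: NeighborGraph, labels, label_kind: str = "label") -> EntropyResult:
    """Mean per-cell Shannon entropy over log(C), with 0·log 0 := 0.

    A single-category dataset is perfectly mixed vacuously: the aggregate is
    defined as 0 and flagged rather than raising on 0/0.
    """
    codes, categories = _codes_and_categories(labels)
    if len(codes) != graph.n_cells:
        raise ValueError("labels do not align with the graph's cells")
    C = len(categories)
    P = label_probabilities(graph, labels)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P), 0.0)
    raw = -terms.sum(axis=1)
    if C == 1:
        return EntropyResult(
            per_cell=np.zeros(graph.n_cells),
            aggregate=0.0,
            label_kind=label_kind,
            n_categories=1,
            k=graph.k,
            single_category=True,
        )
    norm = raw / np.log(C)
    return EntropyResult(
        per_cell=norm,
        aggregate=float(norm.mean()),
        label_kind=label_kind,
        n_categories=C,
        k=graph.k,
    )


def evaluate_mixing(space, k: int = DEFAULT_K, *, batch=None, cell_type=None,
                    layer: str | None = None) -> tuple[EntropyResult, EntropyResult]:
    """Batch and cell-type entropies from one shared kNN graph.

    ``space`` may be an ExpressionDataset, an Embedding, or a precomputed
    NeighborGraph (labels must then be passed explicitly).  The graph is
    built only when not supplied, so graph-space correction methods are
    evaluated on exactly the graph they return.
    """
    if isinstance(space, NeighborGraph):
        graph = space
        if batch is None or cell_type is None:
            raise ValueError("graph input requires explicit batch and cell_type labels")
    else:
        graph = build_knn_graph(space, k=k, layer=layer)
        batch = space.batch if batch is None else batch
        cell_type = space.cell_type if cell_type is None else cell_type
    return (
        normalized_entropy(graph, batch, label_kind="batch"),
        normalized_entropy(graph, cell_type, label_kind="cell_type"),
    )
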