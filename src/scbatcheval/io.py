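"""Readers and writers for the supported on-disk formats.

Three formats are accepted, all round-tripping through
:class:`~scbatcheval.core.ExpressionDataset`:

* H5AD — cells × genes AnnData; batch under ``obs["Batch"]`` and cell type
  under ``obs["cell_type1"]`` (the pipeline input contract), X holding the
  log-normalized layer and ``layers["counts"]`` the raw counts when present.
* Matrix Market — ``matrix.mtx`` plus ``barcodes.tsv`` / ``genes.tsv`` and a
  ``metadata.tsv`` with the label columns.  The single-cell MTX dialect is
  genes × cells on disk; it is transposed on load.
* Dense CSV — cells × genes with a header row of gene ids and an index
  column of cell ids, labels in a separate metadata CSV.

Internally cells are always rows.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .core import Embedding, ExpressionDataset, NeighborGraph, as_categorical

__all__ = [
    "read_h5ad",
    "write_h5ad",
    "read_mtx",
    "write_mtx",
    "read_csv",
    "write_csv",
    "read_edge_list",
    "write_edge_list",
    "from_anndata",
    "to_anndata",
    "read_dataset",
]

BATCH_KEY = "Batch"
CELLTYPE_KEY = "cell_type1"

_LABEL_ALIASES_BATCH = (BATCH_KEY, "batch")
_LABEL_ALIASES_CELLTYPE = (CELLTYPE_KEY, "cell_type", "celltype")


def _pick_column(df: pd.DataFrame, aliases) -> pd.Series:
    for name in aliases:
        if name in df.columns:
            return df[name]
    raise KeyError(f"none of {aliases} found in metadata columns {list(df.columns)}")


# ---------------------------------------------------------------------------
# AnnData / H5AD
# ---------------------------------------------------------------------------

def from_anndata(adata, batch_key: str = BATCH_KEY, celltype_key: str = CELLTYPE_KEY,
                 x_layer: str = "lognorm") -> ExpressionDataset:
    """Convert an AnnData object (cells × genes) to an ExpressionDataset.

    ``adata.X`` is taken as the ``x_layer`` layer (log-normalized counts per
    the input contract); an AnnData layer named ``counts`` is carried over.
    """
    def dense(m):
        return np.asarray(m.todense()) if scipy.sparse.issparse(m) else np.asarray(m)

    layers = {x_layer: dense(adata.X)}
    for name in adata.layers.keys():
        layers[name] = dense(adata.layers[name])
    obs = adata.obs
    return ExpressionDataset(
        layers=layers,
        cell_ids=np.asarray(adata.obs_names, dtype=object),
        gene_ids=np.asarray(adata.var_names, dtype=object),
        batch=as_categorical(_pick_column(obs, (batch_key,) + _LABEL_ALIASES_BATCH)),
        cell_type=as_categorical(_pick_column(obs, (celltype_key,) + _LABEL_ALIASES_CELLTYPE)),
    )


def to_anndata(dataset: ExpressionDataset):
    import anndata

    x_name = dataset.default_layer
    layers = {k: v for k, v in dataset.layers.items() if k != x_name}
    obs = pd.DataFrame(
        {
            BATCH_KEY: np.asarray(dataset.batch, dtype=object),
            CELLTYPE_KEY: np.asarray(dataset.cell_type, dtype=object),
        },
        index=np.asarray(dataset.cell_ids, dtype=str),
    )
    adata = anndata.AnnData(
        X=np.asarray(dataset.X(), dtype=float),
        obs=obs,
        var=pd.DataFrame(index=np.asarray(dataset.gene_ids, dtype=str)),
        layers=layers,
    )
    adata.uns["x_layer"] = x_name
    return adata


def read_h5ad(path: str | os.PathLike) -> ExpressionDataset:
    import anndata

    adata = anndata.read_h5ad(path)
    x_layer = adata.uns.get("x_layer", "lognorm")
    return from_anndata(adata, x_layer=str(x_layer))


def write_h5ad(dataset: ExpressionDataset, path: str | os.PathLike) -> None:
    to_anndata(dataset).write_h5ad(Path(path))


# ---------------------------------------------------------------------------
# Matrix Market
# ---------------------------------------------------------------------------

def write_mtx(dataset: ExpressionDataset, directory: str | os.PathLike,
              layer: str | None = None) -> None:
    """Write ``matrix.mtx`` (genes × cells dialect), id TSVs and metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = scipy.sparse.csr_matrix(np.asarray(dataset.X(layer), dtype=float).T)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), mat)
    pd.Series(dataset.gene_ids).to_csv(directory / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(dataset.cell_ids).to_csv(directory / "barcodes.tsv", sep="\t", index=False, header=False)
    meta = pd.DataFrame(
        {
            "cell_id": dataset.cell_ids,
            BATCH_KEY: np.asarray(dataset.batch, dtype=object),
            CELLTYPE_KEY: np.asarray(dataset.cell_type, dtype=object),
        }
    )
    meta.to_csv(directory / "metadata.tsv", sep="\t", index=False)


def read_mtx(directory: str | os.PathLike, layer: str = "counts",
             cells_as_rows: bool = False) -> ExpressionDataset:
    """Read an MTX bundle; transposes from the genes × cells dialect."""
    directory = Path(directory)
    mat = scipy.io.mmread(str(directory / "matrix.mtx"))
    mat = np.asarray(mat.todense()) if scipy.sparse.issparse(mat) else np.asarray(mat)
    if not cells_as_rows:
        mat = mat.T
    genes = pd.read_csv(directory / "genes.tsv", sep="\t", header=None)[0].astype(str).to_numpy()
    cells = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0].astype(str).to_numpy()
    meta = pd.read_csv(directory / "metadata.tsv", sep="\t").set_index("cell_id")
    meta = meta.loc[cells]
    return ExpressionDataset(
        layers={layer: mat},
        cell_ids=cells,
        gene_ids=genes,
        batch=as_categorical(_pick_column(meta, _LABEL_ALIASES_BATCH)),
        cell_type=as_categorical(_pick_column(meta, _LABEL_ALIASES_CELLTYPE)),
    )


# ---------------------------------------------------------------------------
# Dense CSV
# ---------------------------------------------------------------------------

def write_csv(dataset: ExpressionDataset, matrix_path: str | os.PathLike,
              metadata_path: str | os.PathLike, layer: str | None = None) -> None:
    df = pd.DataFrame(
        np.asarray(dataset.X(layer), dtype=float),
        index=np.asarray(dataset.cell_ids, dtype=str),
        columns=np.asarray(dataset.gene_ids, dtype=str),
    )
    df.to_csv(matrix_path)
    meta = pd.DataFrame(
        {
            BATCH_KEY: np.asarray(dataset.batch, dtype=object),
            CELLTYPE_KEY: np.asarray(dataset.cell_type, dtype=object),
        },
        index=np.asarray(dataset.cell_ids, dtype=str),
    )
    meta.to_csv(metadata_path, index_label="cell_id")


def read_csv(matrix_path: str | os.PathLike, metadata_path: str | os.PathLike,
             layer: str = "lognorm") -> ExpressionDataset:
    df = pd.read_csv(matrix_path, index_col=0)
    meta = pd.read_csv(metadata_path, index_col=0)
    meta = meta.loc[df.index]
    return ExpressionDataset(
        layers={layer: df.to_numpy(dtype=float)},
        cell_ids=df.index.astype(str).to_numpy(),
        gene_ids=df.columns.astype(str).to_numpy(),
        batch=as_categorical(_pick_column(meta, _LABEL_ALIASES_BATCH)),
        cell_type=as_categorical(_pick_column(meta, _LABEL_ALIASES_CELLTYPE)),
    )


# ---------------------------------------------------------------------------
# Neighbor-graph edge lists
# ---------------------------------------------------------------------------

def write_edge_list(graph: NeighborGraph, path: str | os.PathLike) -> None:
    n, m = graph.neighbors.shape
    rows = np.repeat(np.arange(n), m)
    cols = graph.neighbors.ravel()
    rank = np.tile(np.arange(m), n)
    df = pd.DataFrame({"source": rows, "target": cols, "rank": rank})
    if graph.distances is not None:
        df["distance"] = graph.distances.ravel()
    df.to_csv(path, index=False)


def read_edge_list(path: str | os.PathLike) -> NeighborGraph:
    df = pd.read_csv(path)
    n = int(df["source"].max()) + 1
    m = int(df["rank"].max()) + 1
    neighbors = np.empty((n, m), dtype=int)
    neighbors[df["source"], df["rank"]] = df["target"]
    distances = None
    if "distance" in df.columns:
        distances = np.empty((n, m), dtype=float)
        distances[df["source"], df["rank"]] = df["distance"]
    return NeighborGraph(k=m, neighbors=neighbors, distances=distances)


def read_dataset(path: str | os.PathLike, metadata: str | os.PathLike | None = None
                 ) -> ExpressionDataset:
    """Dispatch on extension: ``.h5ad``, MTX directory, or matrix CSV."""
    p = Path(path)
    if p.is_dir():
        return read_mtx(p)
    if p.suffix == ".h5ad":
        return read_h5ad(p)
    if p.suffix == ".csv":
        if metadata is None:
            raise ValueError("CSV input needs a metadata CSV path")
        return read_csv(p, metadata)
    raise ValueError(f"unrecognized input format: {p}")
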