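import numpy as np
import pandas as pd
import pytest

from scbatcheval import ExpressionDataset, make_fixture
from scbatcheval.core import as_categorical


def make_dataset(counts, batch, cell_type, lognorm=True):
    """Small helper: dataset from a raw counts array and label lists."""
    counts = np.asarray(counts, dtype=float)
    n, g = counts.shape
    ds = ExpressionDataset(
        layers={"counts": counts},
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        gene_ids=np.array([f"g{j}" for j in range(g)], dtype=object),
        batch=as_categorical(batch),
        cell_type=as_categorical(cell_type),
    )
    return ds.recompute_lognorm() if lognorm else ds


@pytest.fixture
def small_dataset():
    """10 cells x 6 genes, 2 batches, 2 cell types, fully annotated."""
    rng = np.random.default_rng(7)
    counts = rng.poisson(3.0, size=(10, 6)).astype(float)
    return make_dataset(
        counts,
        batch=["b1"] * 5 + ["b2"] * 5,
        cell_type=["tA", "tB"] * 5,
    )


@pytest.fixture
def mixed_fixture():
    """Two statistically identical batches, three separated cell types."""
    return make_fixture(
        n_cells=150, n_genes=60, n_celltypes=3, n_batches=2,
        separation=5.0, batch_shift=0.0, seed=11,
    )


def add_log_offsets(dataset, shift_sd, seed):
    """Add a constant per-gene offset to the log layer of every non-reference
    batch — a purely additive batch effect in the designated layer."""
    rng = np.random.default_rng(seed)
    X = dataset.lognorm.copy()
    labels = np.asarray(dataset.batch, dtype=object).astype(str)
    for b in sorted(set(labels))[1:]:
        offs = rng.normal(0.0, shift_sd, size=X.shape[1])
        X[labels == b] += offs
    return dataset.with_layer("lognorm", X)
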