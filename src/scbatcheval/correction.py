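"""Minimal in-repo batch correction and the pluggable method interface.

Published correction tools fall into three classes by output space: a
corrected expression matrix, a low-dimensional embedding, or a neighbor
graph.  The benchmark consumes any of the three through
:class:`CorrectionOutput`; which downstream stages apply depends on the
space (matrix → everything; embedding → entropies and graph clustering;
graph → entropies and graph clustering only, since expression is gone).

Two methods ship in-repo: ``identity`` (the uncorrected reference
condition) and ``linear`` (per-gene batch-mean removal by least squares on
batch indicators, preserving the grand mean — the limma/ComBat-class
location adjustment without shrinkage).  External tools plug in as
callables registered by name.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import Embedding, ExpressionDataset, NeighborGraph

__all__ = [
    "CorrectionOutput",
    "correct_identity",
    "correct_linear",
    "register_method",
    "get_method",
    "list_methods",
    "applicable_stages",
]

_SPACE_TYPES = {
    "matrix": ExpressionDataset,
    "embedding": Embedding,
    "graph": NeighborGraph,
}

# which downstream stages can consume each output space
_APPLICABILITY = {
    "matrix": ("entropy", "clustering", "markers"),
    "embedding": ("entropy", "graph_clustering"),
    "graph": ("entropy", "graph_clustering"),
}


@dataclass
class CorrectionOutput:
    space_kind: str  # matrix | embedding | graph
    payload: ExpressionDataset | Embedding | NeighborGraph
    method_name: str

    def __post_init__(self) -> None:
        expected = _SPACE_TYPES.get(self.space_kind)
        if expected is None:
            raise ValueError(f"unknown space_kind {self.space_kind!r}")
        if not isinstance(self.payload, expected):
            raise TypeError(
                f"space_kind {self.space_kind!r} requires a {expected.__name__}, "
                f"got {type(self.payload).__name__}"
            )


def applicable_stages(space_kind: str) -> tuple[str, ...]:
    return _APPLICABILITY[space_kind]


def correct_identity(dataset: ExpressionDataset) -> CorrectionOutput:
    """Pass-through: the uncorrected reference condition."""
    return CorrectionOutput(space_kind="matrix", payload=dataset, method_name="uncorrected")


def correct_linear(dataset: ExpressionDataset, layer: str | None = None) -> CorrectionOutput:
    """Per-gene batch-mean removal on the log layer.

    For each gene, batch means are the least-squares solution on batch
    indicators; subtracting them and restoring the per-gene grand mean
    removes a purely additive batch effect exactly while leaving
    within-batch variance untouched.  The corrected matrix may contain
    negatives; downstream clustering preprocessing clips them where a
    counts-like input is required.  A single-batch input is returned
    unchanged with a warning.
    """
    import warnings

    X = np.asarray(dataset.X(layer), dtype=float)
    codes = np.asarray(dataset.batch.codes)
    if (codes == -1).any():
        raise ValueError("batch labels contain missing values")
    n_batches = codes.max() + 1
    if n_batches < 2:
        warnings.warn("single batch: linear correction is the identity", stacklevel=2)
        return CorrectionOutput(space_kind="matrix", payload=dataset, method_name="linear")

    grand = X.mean(axis=0)
    corrected = X.copy()
    for b in range(n_batches):
        mask = codes == b
        corrected[mask] -= X[mask].mean(axis=0)
    corrected += grand

    out = dataset.with_layer("corrected", corrected)
    # designate the corrected matrix as the working log layer
    out = out.with_layer("lognorm", corrected)
    return CorrectionOutput(space_kind="matrix", payload=out, method_name="linear")


_REGISTRY: dict[str, Callable[[ExpressionDataset], CorrectionOutput]] = {}


def register_method(name: str, fn: Callable[[ExpressionDataset], CorrectionOutput] | None = None):
    """Register a correction callable for lookup by name (CLI ``--method``).

    Usable directly or as a decorator::

        @register_method("mytool")
        def run_mytool(dataset): ...
    """
    if fn is None:
        def deco(f):
            _REGISTRY[name] = f
            return f
        return deco
    _REGISTRY[name] = fn
    return fn


def get_method(name: str) -> Callable[[ExpressionDataset], CorrectionOutput]:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown correction method {name!r}; have {sorted(_REGISTRY)}") from None


def list_methods() -> list[str]:
    return sorted(_REGISTRY)


register_method("uncorrected", correct_identity)
register_method("linear", correct_linear)
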