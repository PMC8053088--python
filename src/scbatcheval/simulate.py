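"""Controlled benchmark inputs: downsampling, artificial batch effects,
and fully synthetic labelled fixtures.

``downsample`` subsets a dataset by uniform sampling without replacement
while preserving batch proportions (round-half-up total, largest-remainder
per-batch quotas).

``simulate_batches`` implements the additive-Gaussian artificial batch
generator: each simulated batch is a copy of a single-batch base to which,
per drawn (f, d), one Normal(0, d) offset per (cell type, gene) is added —
only for genes expressed (count > 0) in more than a fraction f of the base
cells — and negatives are clipped to 0.  The dispersion d is drawn from
[0.5, 1.0, …, n] and f from [0.05, 0.10, …, 1.0], with n the number of
batches.  The generator is deliberately simple: it produces a structured,
correctable batch effect that leaves cell populations separable.

``make_fixture`` draws a labelled sparse count dataset with distinct
cell-type mean profiles and additive per-(batch, gene) offsets, for tests
and self-contained benchmark runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import ExpressionDataset, as_categorical, concatenate, log_normalize

__all__ = [
    "SimulationConfig",
    "BatchEffectRecord",
    "downsample",
    "downsample_target",
    "batch_quotas",
    "simulate_batches",
    "make_fixture",
]

DEFAULT_F_GRID = tuple(np.round(np.arange(1, 21) * 0.05, 10))  # 0.05 .. 1.0
DOWNSAMPLE_FRACTIONS = (0.01, 0.02, 0.05, 0.10, 0.20, 0.50)


def default_d_grid(n_batches: int) -> tuple[float, ...]:
    """Dispersion grid [0.5, 1.0, …, n]; ends at the largest multiple ≤ n."""
    steps = int(math.floor(n_batches / 0.5 + 1e-9))
    return tuple(np.round(np.arange(1, steps + 1) * 0.5, 10))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the artificial batch generator."""

    n_batches: int = 2
    cells_per_batch: int = 1001
    f_grid: tuple[float, ...] = DEFAULT_F_GRID
    d_grid: tuple[float, ...] | None = None  # None -> [0.5 .. n_batches]
    per_cell: bool = False  # independent per-cell draws instead of shared
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_batches < 2:
            raise ValueError("n_batches must be >= 2")
        for name in ("f_grid", "d_grid"):
            g = getattr(self, name)
            if g is not None and not all(a < b for a, b in zip(g, g[1:])):
                raise ValueError(f"{name} must be strictly increasing")

    @property
    def resolved_d_grid(self) -> tuple[float, ...]:
        return self.d_grid if self.d_grid is not None else default_d_grid(self.n_batches)


@dataclass
class BatchEffectRecord:
    """Provenance of one simulated batch, for parameter-recovery tests."""

    batch_id: str
    f_drawn: float
    d_drawn: float
    perturbed_genes: np.ndarray  # column indices passing the >f threshold
    offsets: dict[str, np.ndarray] = field(default_factory=dict)
    # offsets[cell_type]: shared mode -> (n_perturbed,) per-gene draws;
    # per-cell mode -> (n_cells_of_type, n_perturbed)


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------

def downsample_target(n_cells: int, fraction: float) -> int:
    """Round-half-up target size for a uniform subset."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    return int(math.floor(n_cells * fraction + 0.5))


def batch_quotas(batch_counts: np.ndarray, target: int) -> np.ndarray:
    """Largest-remainder allocation of ``target`` cells across batches.

    Each quota deviates from exact proportionality by less than one cell,
    so the initial batch proportions are maintained in every subset.
    """
    batch_counts = np.asarray(batch_counts, dtype=float)
    total = batch_counts.sum()
    ideal = target * batch_counts / total
    base = np.floor(ideal).astype(int)
    remainder = target - base.sum()
    if remainder:
        frac = ideal - base
        # largest fractional parts first; ties to the lower batch index
        order = np.lexsort((np.arange(len(frac)), -frac))
        base[order[:remainder]] += 1
    return base


def downsample(dataset: ExpressionDataset, fraction: float, seed: int,
               drop_empty_batches: bool = False) -> ExpressionDataset:
    """Uniform, proportion-preserving subset without replacement.

    Raises if a batch's quota is zero while the batch exists, unless
    ``drop_empty_batches`` is set (then the batch is dropped with a
    warning-free skip).  Cell order of the input is preserved.
    """
    n = dataset.n_cells
    target = downsample_target(n, fraction)
    if target < 1:
        raise ValueError("fraction too small: target subset would be empty")
    labels = np.asarray(dataset.batch, dtype=object).astype(str)
    uniq = list(dataset.batch.categories)
    counts = np.array([(labels == str(u)).sum() for u in uniq])
    quotas = batch_quotas(counts, target)
    if (quotas == 0).any() and not drop_empty_batches:
        empty = [str(u) for u, q in zip(uniq, quotas) if q == 0]
        raise ValueError(
            f"batches {empty} would receive zero cells at fraction {fraction}; "
            "pass drop_empty_batches=True to drop them"
        )
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for u, q in zip(uniq, quotas):
        if q == 0:
            continue
        idx = np.flatnonzero(labels == str(u))
        chosen.append(rng.choice(idx, size=q, replace=False))
    keep = np.sort(np.concatenate(chosen))
    return dataset.subset_cells(keep)


# ---------------------------------------------------------------------------
# Artificial batches
# ---------------------------------------------------------------------------

def simulate_batches(base: ExpressionDataset, config: SimulationConfig
                     ) -> tuple[ExpressionDataset, list[BatchEffectRecord]]:
    """Append n−1 perturbed copies of a single-batch base dataset.

    The base counts as one of the n batches.  Each simulated batch draws
    (f, d) uniformly from the configured grids and perturbs only genes
    expressed in strictly more than a fraction f of the base cells; a
    single Normal(0, d) offset per (cell type, gene) is shared by all cells
    of that type (``per_cell=True`` switches to independent draws).
    Negative counts are clipped to 0 and the log-normalized layer is
    recomputed for the combined dataset.
    """
    if len(base.batch.categories) > 1:
        raise ValueError("base dataset must contain a single batch")
    if "counts" not in base.layers:
        raise ValueError("simulate_batches perturbs the counts layer")
    rng = np.random.default_rng(config.seed)

    base = base.copy()
    if base.n_cells > config.cells_per_batch:
        idx = np.sort(rng.choice(base.n_cells, size=config.cells_per_batch, replace=False))
        base = base.subset_cells(idx)

    counts = np.asarray(base.counts, dtype=float)
    expressed_frac = (counts > 0).mean(axis=0)
    type_labels = np.asarray(base.cell_type, dtype=object).astype(str)
    cell_types = sorted(set(type_labels))
    d_grid = np.asarray(config.resolved_d_grid, dtype=float)
    f_grid = np.asarray(config.f_grid, dtype=float)

    base_batch_name = str(base.batch.categories[0]) if len(base.batch.categories) else "batch0"
    pieces = [base]
    records: list[BatchEffectRecord] = []
    for b in range(1, config.n_batches):
        f = float(rng.choice(f_grid))
        d = float(rng.choice(d_grid))
        perturbed = np.flatnonzero(expressed_frac > f)
        new_counts = counts.copy()
        record = BatchEffectRecord(
            batch_id=f"simulated{b}", f_drawn=f, d_drawn=d, perturbed_genes=perturbed
        )
        for ct in cell_types:
            cells = np.flatnonzero(type_labels == ct)
            if config.per_cell:
                off = rng.normal(0.0, d, size=(len(cells), len(perturbed)))
                new_counts[np.ix_(cells, perturbed)] += off
            else:
                off = rng.normal(0.0, d, size=len(perturbed))
                new_counts[np.ix_(cells, perturbed)] += off[None, :]
            record.offsets[ct] = off
        np.clip(new_counts, 0.0, None, out=new_counts)
        records.append(record)
        pieces.append(
            ExpressionDataset(
                layers={"counts": new_counts},
                cell_ids=np.array(
                    [f"sim{b}_{cid}" for cid in base.cell_ids], dtype=object
                ),
                gene_ids=base.gene_ids,
                batch=as_categorical([record.batch_id] * base.n_cells),
                cell_type=base.cell_type.copy(),
            )
        )

    pieces[0] = ExpressionDataset(
        layers={"counts": counts},
        cell_ids=base.cell_ids,
        gene_ids=base.gene_ids,
        batch=as_categorical([base_batch_name] * base.n_cells),
        cell_type=base.cell_type,
    )
    combined = concatenate(pieces).recompute_lognorm()
    return combined, records


# ---------------------------------------------------------------------------
# Synthetic labelled fixtures
# ---------------------------------------------------------------------------

def make_fixture(n_cells: int = 200, n_genes: int = 100, n_celltypes: int = 3,
                 n_batches: int = 2, separation: float = 4.0, batch_shift: float = 0.0,
                 sparsity: float = 0.5, seed: int = 0) -> ExpressionDataset:
    """Labelled synthetic count dataset with known structure.

    Cell types are distinct Poisson mean profiles: every type up-regulates
    its own block of marker genes by ``separation`` (additive, on the rate
    scale).  Batches are additive per-(batch, gene) Gaussian offsets of
    standard deviation ``batch_shift`` applied to the rate before sampling,
    so ``batch_shift=0`` makes batches statistically identical.
    ``sparsity`` sets the approximate zero fraction of background genes via
    the Poisson zero probability.  Cells are assigned to types and batches
    in round-robin order; counts layer plus recomputed lognorm layer.
    """
    if min(n_cells, n_genes, n_celltypes, n_batches) < 1:
        raise ValueError("all sizes must be positive")
    rng = np.random.default_rng(seed)
    base_rate = max(-math.log(max(sparsity, 1e-6)), 1e-3)
    gene_base = rng.gamma(shape=2.0, scale=base_rate / 2.0, size=n_genes)

    types = np.arange(n_cells) % n_celltypes
    batches = (np.arange(n_cells) // n_celltypes) % n_batches

    # each type's marker block: a contiguous 1/n_celltypes slice of genes
    block = max(n_genes // n_celltypes, 1)
    rate = np.tile(gene_base, (n_cells, 1))
    for t in range(n_celltypes):
        lo = (t * block) % n_genes
        hi = min(lo + block, n_genes)
        rate[types == t, lo:hi] += separation

    if batch_shift > 0:
        offsets = rng.normal(0.0, batch_shift, size=(n_batches, n_genes))
        rate = rate + offsets[batches]
    rate = np.clip(rate, 0.0, None)
    counts = rng.poisson(rate).astype(float)

    ds = ExpressionDataset(
        layers={"counts": counts},
        cell_ids=np.array([f"cell{i}" for i in range(n_cells)], dtype=object),
        gene_ids=np.array([f"gene{j}" for j in range(n_genes)], dtype=object),
        batch=as_categorical([f"batch{b}" for b in batches]),
        cell_type=as_categorical([f"type{t}" for t in types]),
    )
    return ds.recompute_lognorm()
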