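# scbatcheval

Quantitative benchmarking of scRNA-seq batch-effect correction.

When single-cell RNA-seq samples are processed in separate runs, donors or
platforms, non-biological expression differences ("batch effects") separate
cells by sample instead of by biology. Many correction methods exist, and
they return different kinds of output — a corrected expression matrix, a
low-dimensional embedding, or only a batch-balanced neighbor graph.
`scbatcheval` evaluates any of the three without external datasets or
external correction tools, for computational biologists comparing methods
or checking that a correction did not destroy downstream signal.

## Metrics

**kNN mixing entropies.** The output space is reduced to a k-nearest-
neighbor graph (k = 30, exact Euclidean distances). For each cell *i* the
neighborhood frequency of each batch *b* is *P<sub>ib</sub>* and of each
cell type *c* is *P<sub>ic</sub>*; the per-cell Shannon entropy
*H<sub>i</sub>* = −Σ *P* log *P* is averaged over cells and divided by the
theoretical maximum log *C* so that the aggregate lies in [0, 1].
Good correction gives **batch entropy → 1** (batches indistinguishable in
every neighborhood) and **cell-type entropy → 0** (populations stay
separate).

**Clustering similarity.** Genes are ranked by coefficient of variation and
five feature fractions (0.05, 0.1, 0.2, 0.5, 1.0) feed three clustering
families — Ward hierarchical, Louvain/Leiden graph communities, and
k-means/k-medoids on the Pearson-correlation distance 1 − *r*. Partitions
are scored against the annotated cell types with the Adjusted Rand Index
(best = max over fractions) and the Variation of Information
VI = H(a) + H(b) − 2 I(a; b) (best = min), plus the Pearson correlation
between similarity and fraction.

**Marker consistency.** Per-population markers (two-sided Wilcoxon
rank-sum, |logFC| > 2, detected in ≥ half the population, adjusted
P < 0.05) are compared between the merged, corrected data and each
individual batch with the multiple-site generalized Jaccard index
J<sub>N</sub> = (Σ|A<sub>i</sub>| − |∪A|) / ((N−1)·|∪A|), restricted to
populations common to all batches, together with the fraction of
populations for which the merged data still yields any marker at all.

Also included: the published quality-control filters (count/gene floors,
1% cell-type and 5% batch fractions, strict "<" removal), a
proportion-preserving downsampler, an additive-Gaussian artificial batch
simulator with logged (f, d) parameters, a pluggable correction-method
interface with an in-repo linear (batch-mean removal) baseline, and a
labelled synthetic fixture generator.

## Worked example

```python
import numpy as np
from scbatcheval import make_fixture, evaluate_mixing, correct_linear

# two batches of identical cell populations, three separated cell types
ds = make_fixture(n_cells=300, n_genes=80, n_celltypes=3, n_batches=2,
                  separation=4.0, batch_shift=0.0, seed=55)

# impose a purely additive per-gene batch effect on the log layer
rng = np.random.default_rng(55)
X = ds.lognorm.copy()
labels = np.asarray(ds.batch, dtype=object).astype(str)
X[labels == "batch1"] += rng.normal(0.0, 3.0, size=X.shape[1])
shifted = ds.with_layer("lognorm", X)

be0, ce0 = evaluate_mixing(shifted, k=30)
print(f"uncorrected: batch entropy {be0.aggregate:.3f}, cell-type entropy {ce0.aggregate:.3f}")

out = correct_linear(shifted)
be1, ce1 = evaluate_mixing(out.payload, k=30)
print(f"linear:      batch entropy {be1.aggregate:.3f}, cell-type entropy {ce1.aggregate:.3f}")
```

```
uncorrected: batch entropy 0.000, cell-type entropy 0.000
linear:      batch entropy 0.987, cell-type entropy 0.000
```

Before correction every cell's neighborhood is pure in batch (batch
entropy 0 — the batches sit apart); removing the per-gene batch means
makes the batches exchangeable (entropy 0.987, near the mixing maximum 1)
while the cell types remain perfectly separate (cell-type entropy 0).

The same analyses run from the shell:

```bash
scbatch-eval simulate --cells 1001 --n-batches 5 --seed 1 --out sim.h5ad --log effects.csv
scbatch-eval entropy --in sim.h5ad --k 30 --out entropy.csv
scbatch-eval run --config run.yaml       # full QC → correction → metrics pipeline
```

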