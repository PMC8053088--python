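# Methods

This note documents the models, parameter choices and numerical decisions
behind `scbatcheval`, and what its synthetic benchmarks do and do not show
about real data.

## Mixing entropies

The central statistic treats a correction output as a directed k-nearest-
neighbor graph. For cell *i* with neighbor set N(i), the empirical
frequency of label value *v* among N(i) is P_iv; the per-cell Shannon
entropy is H_i = −Σ_v P_iv log P_iv (0·log 0 := 0) and the aggregate is
mean_i(H_i) / log C, where C is the number of label categories present in
the *whole dataset*. Using the dataset-level C makes the "theoretical
maximum" a constant of the dataset, so per-cell values are comparable and
the aggregate is guaranteed to lie in [0, 1]. The ratio H / log C is
independent of the logarithm base; natural log is used internally and a
test verifies base-invariance to 1e-12.

Choices that matter:

* **k = 30** by default, matching common practice for neighborhood-
  composition metrics. On fixed synthetic datasets the aggregate moves
  only modestly for k ∈ {15, 30, 50} (regression-tested at 0.12), so the
  statistic is not fragile in k.
* **Exact kNN.** Distances are Euclidean on the designated layer (the
  log-normalized matrix, an embedding, or whatever layer the caller
  designates), computed in row blocks of 1024 so memory stays bounded.
  Ties in distance are broken by ascending cell index via a stable sort,
  and self-neighbors are excluded, so graphs and entropies are
  bit-reproducible. An approximate backend could be plugged in behind the
  same `NeighborGraph` contract if inputs outgrow exact search.
* **Single-category labels** (e.g. one batch) give aggregate 0 with an
  explicit `single_category` flag rather than 0/0: a lone batch is
  vacuously "mixed" and must not crash a sweep over many tissues.
* Only marginal per-label-kind neighborhood frequencies are used; batch
  and cell-type entropies are computed from the same graph.

Interpretation: batch entropy 1 means every neighborhood reproduces the
global batch proportions; cell-type entropy 0 means neighborhoods are pure
in cell type. A good correction raises the former without raising the
latter.

## Quality control

Five rules run in a fixed order: (1) drop cells with missing or excluded
labels ("unclassified", "unknown", "NA", ...), (2) per-cell count/gene
floors, (3) per-gene cell floor, (4) cell-type fraction floor, (5) batch
fraction floor. All rules remove items strictly below threshold, so an
item exactly at a floor is retained (verified at boundary fixtures).
"Expressed" means count > 0. The fraction denominators in (4)–(5) are
computed on the population remaining after (3): the published filters list
thresholds but not an order, and computing fractions after cell-level
cleaning matches the intent of "fraction of the total population" for the
data actually analyzed. Filtering is a single pass — no iteration to a
fixpoint, since nothing suggests iterative filtering was intended. Preset
profiles (`pancreas`, `mca`, `tm`, `atlas`) carry the published per-dataset
thresholds.

## Downsampling

Targets are round-half-up of fraction × n; per-batch quotas use the
largest-remainder method, so every quota deviates from exact
proportionality by less than one cell and batch proportions are preserved.
This rounding scheme reproduces all six published subset sizes of the
60,828-cell atlas (608, 1217, 3041, 6083, 12,166, 30,414) — the test
checks each. Sampling is uniform without replacement within batch, with an
explicit seed. A batch whose quota is zero is an error by default
(silently losing a batch would bias entropies) with a `drop_empty_batches`
escape hatch.

## Artificial batch generator

Each simulated batch copies a single-batch base and draws a fraction
f ∈ {0.05, 0.10, …, 1.0} and a dispersion d ∈ {0.5, 1.0, …, n} uniformly
(n = number of batches; when n is not a multiple of 0.5 the grid ends at
the largest multiple ≤ n). For every cell type, one offset per gene is
drawn from Normal(0, d) and added to the counts of all that type's cells —
but only for genes expressed (count > 0) in strictly more than a fraction
f of the base cells. Negative results are clipped to 0. The base counts
as one of the n batches.

Open choices, resolved as follows:

* **Offset granularity.** One draw per (cell type, gene), shared by the
  type's cells, is the default: it produces a structured, additive effect
  that a location-adjustment method can in principle remove, and keeps
  cell types separable as batches accumulate (cell-type entropy stays low
  on fixtures as n grows — tested). An independent per-cell mode exists
  behind `per_cell=True`. Both are logged per batch in
  `BatchEffectRecord`, which stores the drawn (f, d), the perturbed gene
  indices and the offsets themselves, enabling exact parameter-recovery
  tests: the perturbed gene set must equal the >f rule exactly, and the
  dispersion estimated from observed offsets at 4168 genes must sit within
  three standard errors of truth.
* **The mean of the offset distribution is 0**: the dispersion d names
  only a standard deviation.
* **Counts, then re-normalize.** Perturbation happens on the counts layer
  and the log-normalized layer is recomputed afterwards (depth-normalize
  each cell to 10,000 counts, log1p), so the perturbed object satisfies
  the same input contract as a real dataset.

## Synthetic fixtures

`make_fixture` draws Poisson counts from per-gene base rates
(Gamma-distributed, scaled so the background zero fraction ≈ the
`sparsity` argument via the Poisson zero probability). Each cell type adds
`separation` to its own contiguous block of marker genes on the rate
scale; each batch adds per-gene Normal(0, `batch_shift`) offsets to the
rate before sampling; rates are clipped at 0. Cells are assigned to types
and batches round-robin, so labels are balanced by construction.

What this emulates: discrete populations with distinct mean profiles,
sparse non-negative counts, additive batch shifts. What it does not:
library-size variation, overdispersion beyond Poisson, dropout that
depends on expression, correlated gene modules, unbalanced or confounded
batch/type composition. Passing tests on fixtures therefore demonstrate
the *mechanics* of the metrics (bounds, oracle agreement, monotone
responses to known perturbations), not performance claims about any real
tissue. A rate-level Gaussian shift is also not exactly additive in the
log-normalized layer, which is why the linear-baseline demonstrations
impose their offsets on the log layer directly.

## Clustering evaluation

CV = sample standard deviation (ddof = 1) / mean, computed on the
designated log layer; genes with mean 0 get CV 0 and rank after all
nonzero-mean genes, remaining ties broken by gene id — full determinism of
the ranking. Feature selection takes the top ceil(fraction × G) genes, so
nesting across fractions holds and a fraction never selects zero genes.
Before distance-based clustering, cells and genes with zero variance are
removed (both masks computed on the same input matrix, then applied — the
sequential order would degenerate on single-gene matrices), and negatives
are clipped for the correlation-distance family only.

Ward linkage uses Euclidean distances and is cut at the annotated number
of cell types by default (the number of clusters is an explicit knob).
Louvain and Leiden run on the symmetrized kNN graph with an explicit
resolution (default 1.0) and mandatory seed. The correlation family embeds
cells as rows of the pairwise 1 − Pearson-r matrix; k-means runs on those
profiles, k-medoids as PAM-style alternation directly on the distance
matrix (implemented here; initialization from the seeded RNG, medoid
update minimizes within-cluster total distance, convergence on a stable
medoid set, 100-iteration cap). Constant cells are rejected before
correlation since r is undefined for them.

ARI uses the permutation-model expectation correction; VI uses natural
logs. Both are cross-checked against brute-force oracles (pair
enumeration for ARI at n ≤ 12; explicit entropy/MI sums) and VI's metric
properties are spot-checked on random triples. Summaries report the best
ARI (max) and best VI (min) over the sweep with their fractions, Pearson's
rho between similarity and fraction, and min–max normalization of VI
across a dataset collection (constant collections map to 0).

## Marker analysis

The test is a two-sided Wilcoxon rank-sum of the population against all
other cells, vectorized across genes, using the tie-corrected normal
approximation (the convention of the Seurat-era tooling this mirrors); an
exact-enumeration mode exists and is verified against a brute-force
permutation oracle for group sizes ≤ 8. The fold-change is the natural log
of (mean of expm1(log layer) + 1) ratios — i.e. computed on the expression
scale with pseudocount 1; the base and pseudocount are knobs since
published defaults vary across versions. Detection requires expression
> 0 in at least half of the population of interest (a stricter both-groups
mode is a flag). Adjustment is Bonferroni over tested genes by default,
Benjamini–Hochberg by flag. Populations below 3 cells return an empty set
with a reason rather than raising.

The generalized Jaccard over N sets is
(Σ|A_i| − |∪A|) / ((N−1)·|∪A|): 1 for identical non-empty sets, 0 for
pairwise disjoint ones, classic Jaccard at N = 2 (the reduction is tested
both algebraically and on random sets). When every compared set is empty
the index is undefined and reported as missing — *not* 0, because "no
markers anywhere" carries different information than "markers exist but
do not overlap". The comparison is restricted to populations present in
all batches; the fraction of those populations for which the merged data
yields any marker is reported alongside, since an aggressive correction
can erase markers wholesale while leaving mixing metrics looking fine.

## Linear baseline and the method interface

The in-repo baseline removes per-gene batch means (least-squares on batch
indicators) and restores the per-gene grand mean. It exactly undoes a
purely additive batch effect, leaves within-batch variance untouched
(tested to 1e-10), and may produce negatives — handled downstream by the
clustering preprocessor. It is deliberately minimal: the package's job is
evaluation, and the baseline exists so the full pipeline runs end-to-end
with no external tools. Real correction methods plug in as callables
returning a matrix, embedding or graph; the applicability of downstream
stages follows the output space (matrix → all stages; embedding/graph →
entropies and graph clustering only, since expression is gone).

## Pipeline determinism and problem sizes

Every stochastic step takes a mandatory seed and results carry it; fixed
seeds make rerun CSV bodies byte-identical (tested). Each output CSV
carries `#`-prefixed provenance lines (package version, config hash,
seed). Stage failures are isolated and reported as statuses.

The test suite and the acceptance script run on synthetic problems sized
for a desk machine: the randomized entropy-bound suite uses 1000 graphs of
50–500 cells; simulator conservation and parameter recovery run at the
full 4168-gene width with 400–1001 cells; clustering and marker tests use
tens-to-hundreds of cells, where the brute-force oracles remain exact.

## Known limitations

* Entropies evaluate neighborhood mixing only; they cannot detect
  expression-scale distortion (that is what the marker module is for) and
  are unsuitable for methods that directly optimize neighbor batch
  balance.
* The simulator's additive Gaussian effect is intentionally simple; it is
  not a realistic count model (no library-size, dispersion or dropout
  structure) and results on it bound only what the metrics do under
  controlled perturbations.
* Exact kNN is quadratic in cells; beyond ~10^5 cells an approximate
  backend would be needed.
* The Wilcoxon normal approximation is inaccurate for very small groups;
  the exact mode covers those, at combinatorial cost.
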