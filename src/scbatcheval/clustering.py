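"""Effect of batch correction on unsupervised clustering.

Features are ranked by coefficient of variation (sample sd / mean) and the
sweep runs each clustering family at five feature fractions (0.05, 0.1,
0.2, 0.5, 1.0).  Three families are implemented:

* Ward hierarchical clustering on Euclidean distances, cut at a requested
  number of clusters;
* Louvain / Leiden community detection on the kNN graph;
* k-means / k-medoids on the Pearson-correlation distance (1 − r) between
  cells, the RaceID-style core.

Partitions are compared to the annotated cell types with the Adjusted Rand
Index (higher is better, max over fractions is reported) and the Variation
of Information (a true metric, lower is better, min over fractions), plus
the Pearson correlation between similarity and feature fraction.  VI values
are min–max normalized when comparing across a dataset collection.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
from scipy.stats import pearsonr
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, mutual_info_score

from .core import ExpressionDataset, NeighborGraph
from .entropy import build_knn_graph

__all__ = [
    "FeatureRanking",
    "ClusteringResult",
    "SimilaritySummary",
    "rank_by_cv",
    "select_features",
    "preprocess_for_clustering",
    "cluster_hierarchical",
    "cluster_graph_community",
    "cluster_kmeans_correlation",
    "adjusted_rand_index",
    "variation_of_information",
    "summarize_similarity",
    "minmax_normalize",
]

FEATURE_FRACTIONS = (0.05, 0.1, 0.2, 0.5, 1.0)


@dataclass
class FeatureRanking:
    gene_ids: np.ndarray  # descending CV; ties by gene id; zero-mean last
    cv_values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.cv_values):
            raise ValueError("gene_ids and cv_values must align")


@dataclass
class ClusteringResult:
    partition: np.ndarray
    algorithm: str
    feature_fraction: float
    parameters: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.partition.tolist()))


def rank_by_cv(dataset: ExpressionDataset, layer: str | None = None) -> FeatureRanking:
    """Genes in descending order of CV = sample sd (ddof=1) / mean.

    Genes with mean 0 get CV 0 and rank after every nonzero-mean gene;
    remaining ties are broken by gene id (ascending).
    """
    X = np.asarray(dataset.X(layer), dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)
    zero_mean = (mean <= 0).astype(int)
    gene_ids = np.asarray(dataset.gene_ids, dtype=object)
    order = np.lexsort((gene_ids.astype(str), zero_mean, -cv))
    return FeatureRanking(gene_ids=gene_ids[order], cv_values=cv[order])


def select_features(ranking: FeatureRanking, fraction: float) -> np.ndarray:
    """Top ceil(fraction × n_genes) genes; fraction 1.0 returns all."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n = int(np.ceil(fraction * len(ranking.gene_ids)))
    return ranking.gene_ids[:n]


def preprocess_for_clustering(dataset: ExpressionDataset, layer: str | None = None,
                              clip_negative: bool = False) -> ExpressionDataset:
    """Drop zero-variance cells and genes; optionally clip negatives.

    Negative values can arise from matrix-space correction; count-based
    algorithms (the correlation-distance family) require them clipped.
    """
    ds = dataset
    X = np.asarray(ds.X(layer), dtype=float)
    if clip_negative and (X < 0).any():
        ds = ds.with_layer(ds.default_layer if layer is None else layer, np.clip(X, 0.0, None))
        X = np.asarray(ds.X(layer), dtype=float)
    # both masks are evaluated on the same input matrix, then applied
    keep_g = X.var(axis=0) > 0
    keep_c = X.var(axis=1) > 0
    if not keep_g.any():
        raise ValueError("preprocessing would remove every gene (all zero-variance)")
    if not keep_c.any():
        raise ValueError("preprocessing would remove every cell (all zero-variance)")
    if not keep_g.all():
        ds = ds.subset_genes(keep_g)
    if not keep_c.all():
        ds = ds.subset_cells(keep_c)
    return ds


# ---------------------------------------------------------------------------
# Clustering families
# ---------------------------------------------------------------------------

def cluster_hierarchical(dataset: ExpressionDataset, n_clusters: int,
                         layer: str | None = None,
                         feature_fraction: float = 1.0) -> ClusteringResult:
    """Ward agglomeration on Euclidean distances, cut at ``n_clusters``."""
    X = np.asarray(dataset.X(layer), dtype=float)
    if n_clusters > X.shape[0]:
        raise ValueError("n_clusters exceeds number of cells")
    Z = scipy.cluster.hierarchy.linkage(X, method="ward")
    labels = scipy.cluster.hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return ClusteringResult(
        partition=np.asarray(labels),
        algorithm="ward",
        feature_fraction=feature_fraction,
        parameters={"n_clusters": n_clusters},
    )


def cluster_graph_community(space, method: str = "leiden", resolution: float = 1.0,
                            k: int = 30, seed: int = 0, layer: str | None = None,
                            feature_fraction: float = 1.0) -> ClusteringResult:
    """Louvain or Leiden modularity communities on the kNN graph.

    Accepts a dataset/embedding (graph built at ``k``) or a precomputed
    NeighborGraph.  The directed kNN edges are symmetrized into a simple
    undirected graph before community detection.
    """
    import igraph
    import leidenalg

    graph = space if isinstance(space, NeighborGraph) else build_knn_graph(space, k=k, layer=layer)
    n, m = graph.neighbors.shape
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in graph.neighbors[i]}
    g = igraph.Graph(n=n, edges=sorted(edges), directed=False)

    if method == "leiden":
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=2,
        )
        labels = np.asarray(part.membership)
    elif method == "louvain":
        random.seed(seed)  # python-igraph draws from the stdlib RNG
        part = g.community_multilevel(resolution=resolution)
        labels = np.asarray(part.membership)
    else:
        raise ValueError(f"unknown method {method!r}; use 'louvain' or 'leiden'")
    return ClusteringResult(
        partition=labels,
        algorithm=method,
        feature_fraction=feature_fraction,
        parameters={"resolution": resolution, "k": graph.k, "seed": seed},
    )


def _pearson_distance(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0)
        raise ValueError(
            f"cells with constant expression have undefined correlation: indices {bad.tolist()}"
        )
    D = 1.0 - np.corrcoef(X)
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, None)


def cluster_kmeans_correlation(dataset: ExpressionDataset, n_clusters: int,
                               mode: str = "kmeans", seed: int = 0,
                               layer: str | None = None,
                               feature_fraction: float = 1.0) -> ClusteringResult:
    """k-means / k-medoids on the Pearson-correlation distance (1 − r).

    Cells are represented by their rows of the pairwise 1 − r matrix
    (negatives in the expression clipped first), so Euclidean k-means
    operates on correlation-distance profiles; k-medoids runs PAM-style
    alternation directly on the distance matrix.
    """
    X = np.clip(np.asarray(dataset.X(layer), dtype=float), 0.0, None)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    D = _pearson_distance(X)
    if mode == "kmeans":
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        labels = km.fit_predict(D)
    elif mode == "kmedoids":
        labels = _pam(D, n_clusters, seed)
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'kmeans' or 'kmedoids'")
    return ClusteringResult(
        partition=np.asarray(labels),
        algorithm=f"corr_{mode}",
        feature_fraction=feature_fraction,
        parameters={"n_clusters": n_clusters, "seed": seed},
    )


def _pam(D: np.ndarray, k: int, seed: int, max_iter: int = 100) -> np.ndarray:
    """Alternating k-medoids on a precomputed distance matrix."""
    n = D.shape[0]
    if k > n:
        raise ValueError("n_clusters exceeds number of cells")
    rng = np.random.default_rng(seed)
    medoids = rng.choice(n, size=k, replace=False)
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if len(members) == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[np.argmin(within)]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    return np.argmin(D[:, medoids], axis=1)


# ---------------------------------------------------------------------------
# Partition similarity
# ---------------------------------------------------------------------------

def _check_partitions(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("partitions must be 1-D and cover the same cells")
    return a, b


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected partition agreement (permutation-model ARI)."""
    a, b = _check_partitions(a, b)
    return float(adjusted_rand_score(a, b))


def variation_of_information(a, b) -> float:
    """VI(a, b) = H(a) + H(b) − 2 I(a; b), natural log; 0 iff identical."""
    a, b = _check_partitions(a, b)

    # H(x) = I(x; x); sharing the MI code path makes VI(a, a) exactly 0
    vi = (
        float(mutual_info_score(a, a))
        + float(mutual_info_score(b, b))
        - 2.0 * float(mutual_info_score(a, b))
    )
    return max(vi, 0.0)


@dataclass
class SimilaritySummary:
    """Best-over-fractions similarity of clusterings to the ground truth."""

    table: pd.DataFrame  # columns: algorithm, feature_fraction, ari, vi
    best_ari: float
    best_ari_fraction: float
    best_vi: float
    best_vi_fraction: float
    pearson_rho_ari: float | None
    pearson_rho_vi: float | None
    normalized_vi: pd.Series | None = None


def summarize_similarity(results, truth, across_datasets=None) -> SimilaritySummary:
    """Score a sweep of clusterings against the annotated cell types.

    ``results`` is an iterable of ClusteringResult over (algorithm,
    fraction); best ARI is the max and best VI the min across all entries,
    each with the fraction achieving it.  Pearson's rho between similarity
    and feature fraction is reported (None when fewer than 2 distinct
    fractions).  ``across_datasets``, when given as a mapping of dataset
    name → best VI, yields the min–max normalized VI series.
    """
    results = list(results)
    if not results:
        raise ValueError("empty result collection")
    truth = np.asarray(truth)
    rows = []
    for r in results:
        rows.append(
            {
                "algorithm": r.algorithm,
                "feature_fraction": r.feature_fraction,
                "ari": adjusted_rand_index(r.partition, truth),
                "vi": variation_of_information(r.partition, truth),
            }
        )
    table = pd.DataFrame(rows)
    i_ari = int(table["ari"].idxmax())
    i_vi = int(table["vi"].idxmin())

    rho_ari = rho_vi = None
    if table["feature_fraction"].nunique() >= 2:
        by_frac = table.groupby("feature_fraction")[["ari", "vi"]].mean()
        if by_frac["ari"].nunique() > 1:
            rho_ari = float(pearsonr(by_frac.index, by_frac["ari"]).statistic)
        if by_frac["vi"].nunique() > 1:
            rho_vi = float(pearsonr(by_frac.index, by_frac["vi"]).statistic)

    normalized = None
    if across_datasets is not None:
        normalized = minmax_normalize(pd.Series(across_datasets))
    return SimilaritySummary(
        table=table,
        best_ari=float(table.loc[i_ari, "ari"]),
        best_ari_fraction=float(table.loc[i_ari, "feature_fraction"]),
        best_vi=float(table.loc[i_vi, "vi"]),
        best_vi_fraction=float(table.loc[i_vi, "feature_fraction"]),
        pearson_rho_ari=rho_ari,
        pearson_rho_vi=rho_vi,
        normalized_vi=normalized,
    )


def minmax_normalize(values: pd.Series) -> pd.Series:
    """Scale a collection of values to [0, 1]; constant input maps to 0."""
    v = values.astype(float)
    span = v.max() - v.min()
    if span == 0:
        return v * 0.0
    return (v - v.min()) / span
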