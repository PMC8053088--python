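"""Feature selection, the three clustering families, ARI and VI."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from scbatcheval import (
    FeatureRanking,
    NeighborGraph,
    adjusted_rand_index,
    cluster_graph_community,
    cluster_hierarchical,
    cluster_kmeans_correlation,
    minmax_normalize,
    preprocess_for_clustering,
    rank_by_cv,
    select_features,
    summarize_similarity,
    variation_of_information,
)
from scbatcheval.clustering import ClusteringResult

from conftest import make_dataset


def dataset_from_matrix(X, layer="lognorm"):
    X = np.asarray(X, dtype=float)
    ds = make_dataset(np.abs(X), batch=["b"] * X.shape[0],
                      cell_type=["t"] * X.shape[0], lognorm=False)
    return ds.with_layer(layer, X)


def brute_force_ari(a, b):
    """Pair-enumeration oracle: count agreeing/disagreeing cell pairs."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    n11 = n00 = n10 = n01 = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        n11 += same_a and same_b
        n00 += (not same_a) and (not same_b)
        n10 += same_a and not same_b
        n01 += (not same_a) and same_b
    total = n11 + n00 + n10 + n01
    index = n11
    expected = (n11 + n10) * (n11 + n01) / total
    maximum = ((n11 + n10) + (n11 + n01)) / 2
    if maximum == expected:
        return 1.0 if index == expected else 0.0
    return (index - expected) / (maximum - expected)


class TestRankByCV:
    def test_direct_formula(self):
        # gene values (1,2,3): sample sd 1, mean 2 -> CV 0.5
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        ranking = rank_by_cv(dataset_from_matrix(X))
        assert ranking.cv_values[0] == pytest.approx(0.5)
        assert ranking.gene_ids[0] == "g0"

    def test_constant_nonzero_gene_ranks_last_of_nonzero(self):
        X = np.array([[1.0, 5.0, 0.0], [3.0, 5.0, 0.0]])
        ranking = rank_by_cv(dataset_from_matrix(X))
        # varying gene first, constant nonzero second, zero-mean last
        assert list(ranking.gene_ids) == ["g0", "g1", "g2"]

    def test_ties_broken_by_gene_id(self):
        X = np.array([[1.0, 1.0], [3.0, 3.0]])
        ranking = rank_by_cv(dataset_from_matrix(X))
        assert list(ranking.gene_ids) == ["g0", "g1"]


class TestSelectFeatures:
    def make_ranking(self, n):
        ids = np.array([f"g{i:05d}" for i in range(n)], dtype=object)
        return FeatureRanking(gene_ids=ids, cv_values=np.linspace(2, 0, n))

    def test_half_of_four(self):
        assert len(select_features(self.make_ranking(4), 0.5)) == 2

    def test_full_fraction_returns_all_in_order(self):
        r = self.make_ranking(4)
        np.testing.assert_array_equal(select_features(r, 1.0), r.gene_ids)

    def test_ceil_arithmetic_published_gene_count(self):
        # 5% of 4168 genes -> ceil(208.4) = 209
        assert len(select_features(self.make_ranking(4168), 0.05)) == 209

    def test_nesting_across_fractions(self):
        r = self.make_ranking(500)
        subsets = [set(select_features(r, f)) for f in (0.05, 0.1, 0.2, 0.5, 1.0)]
        for small, big in zip(subsets, subsets[1:]):
            assert small <= big


class TestPreprocess:
    def test_constant_gene_dropped(self):
        X = np.array([[1.0, 7.0], [2.0, 7.0], [3.0, 7.0]])
        out = preprocess_for_clustering(dataset_from_matrix(X))
        assert list(out.gene_ids) == ["g0"]

    def test_negative_clipped_when_requested(self):
        X = np.array([[1.0, -0.3], [2.0, 0.5], [0.5, 1.0]])
        out = preprocess_for_clustering(dataset_from_matrix(X), clip_negative=True)
        assert (out.lognorm >= 0).all()

    def test_strictly_varying_matrix_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 5))
        out = preprocess_for_clustering(dataset_from_matrix(X))
        np.testing.assert_array_equal(out.lognorm, X)


def two_blobs(n_per=20, sep=20.0, seed=0, dims=5):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per, dims))
    b = rng.normal(sep, 1.0, size=(n_per, dims))
    X = np.vstack([a, b])
    labels = np.array([0] * n_per + [1] * n_per)
    return X, labels


class TestHierarchical:
    def test_recovers_separated_blobs(self):
        X, truth = two_blobs()
        res = cluster_hierarchical(dataset_from_matrix(X), n_clusters=2)
        assert adjusted_rand_index(res.partition, truth) == 1.0

    def test_singletons_and_single_cluster(self):
        X, _ = two_blobs(n_per=5)
        singles = cluster_hierarchical(dataset_from_matrix(X), n_clusters=10)
        assert singles.n_clusters == 10
        one = cluster_hierarchical(dataset_from_matrix(X), n_clusters=1)
        assert one.n_clusters == 1


class TestGraphCommunity:
    def test_disconnected_components_become_communities(self):
        # two 4-cliques with kNN lists confined within each clique
        neighbors = np.array([
            [1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2],
            [5, 6, 7], [4, 6, 7], [4, 5, 7], [4, 5, 6],
        ])
        g = NeighborGraph(k=3, neighbors=neighbors)
        for method in ("louvain", "leiden"):
            res = cluster_graph_community(g, method=method, seed=0)
            assert res.n_clusters == 2
            assert adjusted_rand_index(res.partition, [0] * 4 + [1] * 4) == 1.0

    @pytest.mark.parametrize("method", ["louvain", "leiden"])
    def test_three_blob_recovery(self, method):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(c, 1.0, size=(30, 4)) for c in (0.0, 15.0, 30.0)])
        truth = np.repeat([0, 1, 2], 30)
        res = cluster_graph_community(dataset_from_matrix(X), method=method, k=10, seed=1)
        assert adjusted_rand_index(res.partition, truth) >= 0.9

    def test_determinism_per_seed(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 5))
        ds = dataset_from_matrix(X)
        a = cluster_graph_community(ds, method="leiden", k=8, seed=7)
        b = cluster_graph_community(ds, method="leiden", k=8, seed=7)
        np.testing.assert_array_equal(a.partition, b.partition)


class TestCorrelationKMeans:
    def correlated_groups(self):
        # two groups of perfectly correlated cells (r=1 within, r<1 across)
        base1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        base2 = np.array([6.0, 1.0, 5.0, 2.0, 4.0, 3.0])
        X = np.vstack([base1 * s for s in (1, 2, 3)] + [base2 * s for s in (1, 2, 3)])
        return X, np.array([0, 0, 0, 1, 1, 1])

    @pytest.mark.parametrize("mode", ["kmeans", "kmedoids"])
    def test_recovers_correlation_groups(self, mode):
        X, truth = self.correlated_groups()
        res = cluster_kmeans_correlation(dataset_from_matrix(X), 2, mode=mode, seed=0)
        assert adjusted_rand_index(res.partition, truth) == 1.0

    def test_k_one_single_cluster(self):
        X, _ = self.correlated_groups()
        res = cluster_kmeans_correlation(dataset_from_matrix(X), 1, seed=0)
        assert res.n_clusters == 1

    def test_determinism_per_seed(self):
        rng = np.random.default_rng(4)
        X = np.abs(rng.normal(size=(30, 8))) + 0.1
        ds = dataset_from_matrix(X)
        for mode in ("kmeans", "kmedoids"):
            a = cluster_kmeans_correlation(ds, 3, mode=mode, seed=5)
            b = cluster_kmeans_correlation(ds, 3, mode=mode, seed=5)
            np.testing.assert_array_equal(a.partition, b.partition)

    def test_constant_cell_rejected(self):
        X = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        with pytest.raises(ValueError, match="constant"):
            cluster_kmeans_correlation(dataset_from_matrix(X), 2, seed=0)


class TestARI:
    def test_identical_partitions(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_crossed_two_by_two(self):
        # contingency table of all ones: ARI = -0.5
        assert adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_singletons_vs_one_cluster(self):
        a = list(range(8))
        b = [0] * 8
        assert adjusted_rand_index(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 4, size=30)
        mapping = {0: 9, 1: 4, 2: 7, 3: 0}
        b = np.array([mapping[x] for x in a])
        assert adjusted_rand_index(a, b) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        a = rng.integers(0, 4, size=n)
        b = rng.integers(0, 3, size=n)
        assert adjusted_rand_index(a, b) == pytest.approx(brute_force_ari(a, b), abs=1e-12)


class TestVI:
    def test_identical_partitions_zero(self):
        assert variation_of_information([1, 1, 2, 2], [1, 1, 2, 2]) == 0.0

    def test_independent_partitions(self):
        # crossed 2x2 design: I = 0, H = ln 2 each -> VI = 2 ln 2
        vi = variation_of_information([1, 1, 2, 2], [1, 2, 1, 2])
        assert vi == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(5, 20))
            a, b, c = (rng.integers(0, 4, size=n) for _ in range(3))
            assert variation_of_information(a, b) == pytest.approx(
                variation_of_information(b, a), abs=1e-12
            )
            assert (
                variation_of_information(a, c)
                <= variation_of_information(a, b) + variation_of_information(b, c) + 1e-12
            )

    def test_inverse_rank_correlation_with_ari(self):
        # across random partition pairs, high ARI should mean low VI
        rng = np.random.default_rng(8)
        aris, vis = [], []
        base = rng.integers(0, 3, size=60)
        for noise in range(0, 55, 5):
            other = base.copy()
            idx = rng.choice(60, size=noise, replace=False)
            other[idx] = rng.integers(0, 3, size=noise)
            aris.append(adjusted_rand_index(base, other))
            vis.append(variation_of_information(base, other))
        rho = spearmanr(aris, vis).statistic
        assert rho < 0


class TestSummarize:
    def result(self, partition, fraction, algo="ward"):
        return ClusteringResult(np.asarray(partition), algo, fraction)

    def test_single_perfect_result(self):
        truth = [0, 0, 1, 1]
        s = summarize_similarity([self.result(truth, 0.2)], truth)
        assert s.best_ari == 1.0 and s.best_ari_fraction == 0.2
        assert s.best_vi == 0.0

    def test_minmax_normalization(self):
        out = minmax_normalize(pd.Series([2.0, 4.0, 6.0]))
        np.testing.assert_allclose(out.to_numpy(), [0.0, 0.5, 1.0])

    def test_rho_one_for_linearly_rising_similarity(self):
        truth = np.repeat([0, 1], 10)
        rng = np.random.default_rng(9)
        results = []
        # flip fewer cells at higher fractions -> ARI rises with fraction
        for fraction, flips in [(0.05, 8), (0.1, 6), (0.2, 4), (0.5, 2), (1.0, 0)]:
            part = truth.copy()
            part[rng.choice(20, size=flips, replace=False)] ^= 1
            results.append(self.result(part, fraction))
        s = summarize_similarity(results, truth)
        by_frac = s.table.sort_values("feature_fraction")["ari"].to_numpy()
        if np.all(np.diff(by_frac) > 0):
            assert s.pearson_rho_ari > 0.9

    def test_best_over_fractions(self):
        truth = [0, 0, 1, 1, 2, 2]
        good = self.result(truth, 0.5)
        bad = self.result([0, 1, 2, 0, 1, 2], 0.05)
        s = summarize_similarity([bad, good], truth)
        assert s.best_ari == 1.0 and s.best_ari_fraction == 0.5
        assert s.best_vi == 0.0 and s.best_vi_fraction == 0.5

    def test_empty_collection_raises(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_similarity([], [0, 1])
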