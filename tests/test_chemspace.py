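import itertools
import math

import numpy as np
import pytest

from metspace.chemspace import (
    ClusterContingency,
    cluster_purity,
    conditional_inference_tree,
    cut_by_inertia,
    exact_association_pvalue,
    pca,
    ward_cluster,
)


def planted_blobs(rng, k=3, n_per=20, dim=4, sep=50.0):
    centers = rng.normal(0, 1, (k, dim)) * sep
    X = np.vstack([c + rng.normal(0, 1, (n_per, dim)) for c in centers])
    labels = np.repeat(np.arange(k), n_per)
    return X, labels


class TestPCA:
    def test_standardized_columns(self, rng):
        X = rng.normal(5, 3, (40, 5))
        res = pca(X)
        Z = res.scores @ res.loadings.T
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(Z.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_variance_fractions_sum_to_one(self, rng):
        res = pca(rng.normal(0, 1, (30, 6)))
        assert res.explained.sum() == pytest.approx(1.0)
        assert (np.diff(np.cumsum(res.explained)) >= -1e-12).all()

    def test_two_variable_closed_form(self, rng):
        # correlation-matrix eigenvalues are 1 +/- |rho|
        rho = 0.6
        cov = np.array([[1.0, rho], [rho, 1.0]])
        X = rng.multivariate_normal([0, 0], cov, size=20000)
        res = pca(X)
        r = np.corrcoef(X.T)[0, 1]
        assert res.explained[0] == pytest.approx((1 + abs(r)) / 2, abs=1e-9)

    def test_reconstruction_with_all_components(self, rng):
        X = rng.normal(0, 2, (25, 4))
        res = pca(X)
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        assert np.allclose(res.scores @ res.loadings.T, Z, atol=1e-10)

    def test_constant_column_dropped_with_warning(self, rng):
        X = rng.normal(0, 1, (20, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning):
            res = pca(X, columns=["a", "b", "c"])
        assert res.dropped == ["b"] and res.loadings.shape[0] == 2

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pca(np.zeros((1, 3)))


class TestWardClustering:
    def test_merge_heights_non_decreasing(self, rng):
        d = ward_cluster(rng.normal(0, 1, (30, 3)))
        assert (np.diff(d.heights) >= -1e-12).all()

    def test_duplicated_groups_merge_at_zero(self):
        X = np.vstack([np.tile([0.0, 0.0], (5, 1)), np.tile([10.0, 0.0], (5, 1))])
        d = ward_cluster(X)
        assert np.allclose(d.heights[:8], 0.0)
        assert d.heights[-1] > 0

    def test_separated_blobs_dominate_total_height(self, rng):
        X, _ = planted_blobs(rng)
        d = ward_cluster(X)
        assert d.heights[-2:].sum() > 0.9 * d.heights.sum()


class TestCutByInertia:
    def test_two_duplicated_groups_give_k2(self):
        X = np.vstack([np.tile([0.0, 0.0], (6, 1)), np.tile([9.0, 1.0], (6, 1))])
        labels = cut_by_inertia(ward_cluster(X))
        assert len(set(labels)) == 2

    @pytest.mark.parametrize("seed", range(20))
    def test_three_planted_blobs_recovered(self, seed):
        rng = np.random.default_rng(seed)
        X, truth = planted_blobs(rng)
        labels = cut_by_inertia(ward_cluster(X))
        assert len(set(labels)) == 3
        # the partition matches the planted one up to relabeling
        for c in set(labels):
            assert len(set(truth[labels == c])) == 1


class TestClusterPurity:
    @pytest.mark.parametrize(
        "counts, expected",
        [((370, 157), 70.21), ((52, 6), 89.66), ((110, 369), 77.04),
         ((372, 100), 78.81), ((134, 363), 73.04), ((26, 69), 72.63), ((50, 50), 50.0)],
    )
    def test_purity_percent(self, counts, expected):
        assert cluster_purity(np.array([counts]))[0] == pytest.approx(expected, abs=0.005)

    def test_weighted_purity_at_least_majority_fraction(self, rng):
        table = rng.integers(1, 100, (4, 2))
        purity = cluster_purity(table)
        totals = table.sum(axis=1)
        weighted = (purity * totals).sum() / totals.sum()
        majority = 100.0 * table.sum(axis=0).max() / table.sum()
        assert weighted >= majority - 1e-9

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster_purity(np.array([[0, 0]]))

    def test_from_labels_crosstab(self):
        cc = ClusterContingency.from_labels([1, 1, 2, 2, 2], ["a", "b", "a", "a", "a"])
        assert cc.counts.loc[2, "a"] == 3


def permutation_pvalue_oracle(x, y):
    """Exhaustive enumeration over all label permutations of the 2x2 statistic.

    p = fraction of permutations whose table is no more probable than the
    observed one (the mass criterion of the exact two-sided test).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    n = len(y)
    perms = list(itertools.permutations(y))
    counts = [int(((x == 1) & (np.array(p) == 1)).sum()) for p in perms]
    obs = int(((x == 1) & (y == 1)).sum())
    freq = {}
    for c in counts:
        freq[c] = freq.get(c, 0) + 1
    p_obs = freq[obs] / len(perms)
    total = sum(f for c, f in freq.items() if f / len(perms) <= p_obs * (1 + 1e-9))
    return total / len(perms)


class TestConditionalInferenceTree:
    def test_exact_pvalue_matches_permutation_enumeration_n6(self, rng):
        for _ in range(20):
            x = rng.integers(0, 2, 6)
            y = rng.integers(0, 2, 6)
            if len(set(y)) < 2 or len(set(x)) < 2:
                continue
            assert exact_association_pvalue(x, y) == pytest.approx(
                permutation_pvalue_oracle(x, y), abs=1e-9
            )

    def test_perfect_feature_splits_root_pure_children(self, rng):
        n = 40
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        X = np.column_stack([y, rng.integers(0, 2, n)])
        tree = conditional_inference_tree(X, y, alpha=0.05, min_node=20)
        root = tree.root
        assert root.feature == 0
        assert root.left.n0 == 0 and root.right.n1 == 0

    def test_children_counts_sum_to_parent(self, rng):
        n = 60
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        X = np.column_stack([y ^ (rng.random(n) < 0.2), rng.integers(0, 2, n), rng.integers(0, 2, n)])
        tree = conditional_inference_tree(X.astype(int), y, alpha=0.2, min_node=10)

        def walk(node):
            if node.is_leaf:
                return
            assert node.left.n0 + node.right.n0 == node.n0
            assert node.left.n1 + node.right.n1 == node.n1
            walk(node.left)
            walk(node.right)

        walk(tree.root)

    def test_null_split_rate_at_most_alpha(self):
        # single pure-noise feature: family-wise type-I error <= alpha
        reps, alpha, n = 1000, 0.05, 40
        rng = np.random.default_rng(5)
        splits = 0
        for _ in range(reps):
            y = np.r_[np.zeros(20, int), np.ones(20, int)]
            x = rng.integers(0, 2, n)
            if x.sum() in (0, n):
                continue
            if exact_association_pvalue(x, y) <= alpha:
                splits += 1
        rate = splits / reps
        assert rate <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / reps)

    def test_min_node_stops_recursion(self, rng):
        y = np.r_[np.zeros(8, int), np.ones(8, int)]
        X = y.reshape(-1, 1)
        tree = conditional_inference_tree(X, y, alpha=0.05, min_node=20)
        assert tree.root.is_leaf

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            conditional_inference_tree(np.array([[2, 0]]), np.array([1]))

    def test_render_and_dot_outputs(self, rng):
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        X = np.column_stack([y]).astype(int)
        tree = conditional_inference_tree(X, y, min_node=10, feature_names=["hydroxyl"])
        assert "hydroxyl" in tree.render()
        assert tree.to_dot().startswith("digraph")
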