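"""Selector unit tests, checked against brute-force dense oracles."""

import numpy as np
import pytest

from vitabind import (
    FeatureWeights,
    fisher_score,
    jlfwl,
    laplacian_score,
    select_top_k,
    variance_score,
)
from vitabind.selection import LAPLACIAN_WORST


def brute_laplacian_scores(data, knn, heat_t=None):
    """Independent dense implementation of the Laplacian score."""
    M, D = data.shape
    d2 = ((data[:, None, :] - data[None, :, :]) ** 2).sum(axis=2)
    if heat_t is None:
        heat_t = d2[np.triu_indices(M, k=1)].mean()
    S = np.zeros((M, M))
    for i in range(M):
        order = [j for j in np.argsort(d2[i], kind="stable") if j != i][:knn]
        for j in order:
            S[i, j] = np.exp(-d2[i, j] / heat_t)
    S = np.maximum(S, S.T)
    deg = S.sum(axis=1)
    Dm = np.diag(deg)
    L = Dm - S
    one = np.ones(M)
    out = np.empty(D)
    for j in range(D):
        f = data[:, j]
        ft = f - (f @ Dm @ one) / (one @ Dm @ one)
        den = ft @ Dm @ ft
        out[j] = LAPLACIAN_WORST if den <= 1e-300 else (ft @ L @ ft) / den
    return out


class TestVarianceScore:
    def test_small_examples(self):
        X = np.array([[0.0, 3.0, 1.0], [1.0, 3.0, 1.5]])
        w = variance_score(X)
        assert w.weights[0] == pytest.approx(0.5)  # [0,1] with n-1 denominator
        assert w.weights[1] == 0.0  # constant column

    def test_quadratic_homogeneity(self, rng):
        X = rng.random((10, 4))
        base = variance_score(X).weights
        scaled = variance_score(X * 3.0).weights
        np.testing.assert_allclose(scaled, 9.0 * base)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            variance_score(np.ones((1, 3)))


class TestFisherScore:
    def test_known_value(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        assert fisher_score(X, y).weights[0] == pytest.approx(4.0)

    def test_class_invariant_feature_scores_zero(self):
        X = np.array([[1.0], [1.0], [1.0], [1.0]])
        assert fisher_score(X, [0, 0, 1, 1]).weights[0] == 0.0

    def test_perfect_separator_outranks_everything(self, rng):
        noisy = rng.random((4, 3))
        sep = np.array([[0.0], [0.0], [1.0], [1.0]])
        X = np.hstack([noisy, sep])
        w = fisher_score(X, [0, 0, 1, 1]).weights
        assert np.argmax(w) == 3
        assert np.isfinite(w).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fisher_score(np.ones((3, 2)), [1, 1, 1])

    def test_matches_brute_force_formula(self, rng):
        X = rng.random((12, 6))
        y = rng.integers(0, 2, 12)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, 12)
        got = fisher_score(X, y).weights
        mu = X.mean(axis=0)
        expected = []
        for j in range(6):
            num = den = 0.0
            for c in (0, 1):
                block = X[y == c, j]
                num += len(block) * (block.mean() - mu[j]) ** 2
                den += len(block) * block.var()
            expected.append(num / den)
        np.testing.assert_allclose(got, expected)


class TestLaplacianScore:
    def test_two_cluster_toy_matches_oracle(self):
        pts = np.array(
            [
                [0.0, 0.1, 1.0],
                [0.1, 0.0, 0.9],
                [0.05, 0.08, 1.1],
                [5.0, 5.1, 1.0],
                [5.1, 5.0, 0.95],
                [5.05, 4.9, 1.05],
            ]
        )
        got = laplacian_score(pts, knn=2).weights
        np.testing.assert_allclose(got, brute_laplacian_scores(pts, knn=2))
        # the cluster-separating features (0,1) preserve locality better
        assert got[0] < got[2] and got[1] < got[2]

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(20):
            X = rng.random((rng.integers(6, 12), rng.integers(2, 6)))
            np.testing.assert_allclose(
                laplacian_score(X, knn=3).weights, brute_laplacian_scores(X, knn=3)
            )

    def test_constant_column_gets_worst_rank(self, rng):
        X = rng.random((8, 3))
        X[:, 1] = 0.7
        w = laplacian_score(X, knn=3)
        assert not w.higher_is_better
        assert w.weights[1] == LAPLACIAN_WORST
        assert w.weights[1] >= w.weights.max()

    def test_duplicate_columns_equal_scores(self, rng):
        X = rng.random((9, 2))
        X = np.hstack([X, X[:, [0]]])
        w = laplacian_score(X, knn=3).weights
        assert w[0] == pytest.approx(w[2])

    def test_knn_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            laplacian_score(rng.random((4, 2)), knn=4)


class TestJlfwl:
    def test_identical_columns_all_kept_with_equal_weights(self, rng):
        col = rng.random((10, 1))
        X = np.tile(col, (1, 5))
        w, sub = jlfwl(X)
        assert len(np.unique(w.weights)) == 1
        assert sub.k in (0, 5) and sub.k == 5

    def test_sparsity_monotone_in_epsilon(self):
        sizes_low, sizes_high = [], []
        for seed in range(20):
            X = np.random.default_rng(seed).random((15, 8))
            _, s0 = jlfwl(X, epsilon=0.0)
            _, s9 = jlfwl(X, epsilon=0.9)
            sizes_low.append(s0.k)
            sizes_high.append(s9.k)
        assert all(lo >= hi for lo, hi in zip(sizes_low, sizes_high))
        assert all(k == 8 for k in sizes_low)  # no sparsity pressure at 0

    def test_objective_non_increasing(self, rng):
        X = rng.random((20, 10))
        w, _ = jlfwl(X, epsilon=0.5)
        hist = w.objective_history
        assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))

    def test_weights_nonnegative_finite_and_deterministic(self, rng):
        X = rng.random((18, 12))
        w1, s1 = jlfwl(X, epsilon=0.5, seed=3)
        w2, s2 = jlfwl(X, epsilon=0.5, seed=3)
        assert (w1.weights >= 0).all() and np.isfinite(w1.weights).all()
        np.testing.assert_array_equal(w1.weights, w2.weights)
        np.testing.assert_array_equal(s1.indices, s2.indices)

    def test_negative_epsilon_rejected(self, rng):
        with pytest.raises(ValueError):
            jlfwl(rng.random((8, 3)), epsilon=-0.1)


class TestSelectTopK:
    def test_identity_at_full_k(self):
        w = FeatureWeights(weights=np.array([3.0, 1.0, 2.0]), method="variance")
        assert select_top_k(w, 3).indices.tolist() == [0, 1, 2]

    def test_orientation_respected(self):
        lap = FeatureWeights(
            weights=np.array([0.9, 0.1, 0.5]), method="laplacian", higher_is_better=False
        )
        assert select_top_k(lap, 1).indices.tolist() == [1]

    def test_tie_goes_to_lower_index(self):
        w = FeatureWeights(weights=np.array([1.0, 2.0, 2.0, 1.0]), method="fisher")
        assert select_top_k(w, 3).indices.tolist() == [0, 1, 2]

    def test_out_of_range_k_rejected(self):
        w = FeatureWeights(weights=np.ones(4), method="fisher")
        for k in (0, 5):
            with pytest.raises(ValueError):
                select_top_k(w, k)
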