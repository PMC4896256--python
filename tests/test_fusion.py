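"""Similarity layers, normalizations and the weighted fusion iteration."""

import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import fluxfuse as ff
from fluxfuse.fusion import (
    MultiplexNetwork,
    SimilarityLayer,
    distance_matrix,
    fuse,
    local_affinity,
    normalize_native,
    normalize_p0,
    similarity_exp,
    similarity_scaled_kernel,
    weighted_update,
)


def _random_similarity(rng, n):
    M = rng.uniform(0.05, 1.0, size=(n, n))
    W = (M + M.T) / 2.0
    np.fill_diagonal(W, 1.0)
    return SimilarityLayer(W, [f"n{i}" for i in range(n)])


class TestDistanceAndKernels:
    def test_identical_rows_zero_distance(self):
        d = distance_matrix(np.ones((3, 4)))
        np.testing.assert_array_equal(d, np.zeros((3, 3)))

    def test_hand_computed_345(self):
        d = distance_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d[0, 1] == pytest.approx(5.0)

    def test_triangle_inequality_random(self):
        rng = np.random.default_rng(0)
        d = distance_matrix(rng.normal(size=(12, 5)))
        for i in range(12):
            for j in range(12):
                for k in range(12):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix(np.array([[np.nan, 0.0]]))

    def test_exp_kernel_values(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        W = similarity_exp(d).matrix
        assert W[0, 0] == 1.0
        assert W[0, 1] == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_exp_kernel_decreasing(self):
        d1 = similarity_exp(np.array([[0.0, 0.5], [0.5, 0.0]])).matrix[0, 1]
        d2 = similarity_exp(np.array([[0.0, 1.5], [1.5, 0.0]])).matrix[0, 1]
        assert d1 > d2

    def test_scaled_kernel_zero_distance_unit(self):
        d = np.zeros((3, 3))
        W = similarity_scaled_kernel(d, mu=0.5, K=2).matrix
        np.testing.assert_array_equal(W, np.ones((3, 3)))

    def test_scaled_kernel_scale_invariance(self):
        rng = np.random.default_rng(1)
        d = distance_matrix(rng.normal(size=(10, 4)))
        W1 = similarity_scaled_kernel(d, mu=0.6, K=4).matrix
        W2 = similarity_scaled_kernel(7.3 * d, mu=0.6, K=4).matrix
        np.testing.assert_allclose(W1, W2, rtol=1e-10)


class TestNormalizations:
    def test_native_square_over_max(self):
        lay = SimilarityLayer(np.array([[1.0, 1.0], [1.0, 2.0]]), ["a", "b"])
        out = normalize_native(lay).matrix
        np.testing.assert_allclose(out, [[0.25, 0.25], [0.25, 1.0]])
        assert out.max() == 1.0

    def test_native_all_zero_rejected(self):
        lay = SimilarityLayer(np.zeros((2, 2)), ["a", "b"])
        with pytest.raises(ValueError):
            normalize_native(lay)

    def test_robust_diagonal_half_rows_one(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            lay = _random_similarity(rng, 10)
            P = normalize_p0(lay, method="robust")
            np.testing.assert_allclose(np.diag(P), 0.5)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_robust_2x2_exchange(self):
        lay = SimilarityLayer(np.array([[0.0, 1.0], [1.0, 0.0]]), ["a", "b"])
        np.testing.assert_allclose(
            normalize_p0(lay, "robust"), [[0.5, 0.5], [0.5, 0.5]]
        )

    def test_row_stochastic_variant(self):
        rng = np.random.default_rng(4)
        P = normalize_p0(_random_similarity(rng, 8), method="row_stochastic")
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_row_sum_names_node(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        np.fill_diagonal(W, [1.0, 1.0, 0.0])
        lay = SimilarityLayer(W, ["a", "b", "lonely"])
        with pytest.raises(ValueError, match="lonely"):
            normalize_p0(lay, "robust")


class TestLocalAffinity:
    def test_rows_sum_one_and_sparsity(self):
        rng = np.random.default_rng(5)
        lay = _random_similarity(rng, 12)
        S = local_affinity(lay, K=4).matrix
        np.testing.assert_allclose(S.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((S > 0).sum(axis=1) <= 4)

    def test_k1_keeps_only_self_when_diagonal_dominates(self):
        rng = np.random.default_rng(6)
        lay = _random_similarity(rng, 7)  # diagonal 1 dominates
        S = local_affinity(lay, K=1).matrix
        np.testing.assert_array_equal(S, np.eye(7))

    def test_entries_outside_neighborhood_exactly_zero(self):
        rng = np.random.default_rng(7)
        lay = _random_similarity(rng, 9)
        K = 3
        S = local_affinity(lay, K).matrix
        for i in range(9):
            nbr = np.argsort(-lay.matrix[i], kind="stable")[:K]
            outside = np.setdiff1d(np.arange(9), nbr)
            assert np.all(S[i, outside] == 0.0)

    def test_k_out_of_range(self):
        rng = np.random.default_rng(8)
        lay = _random_similarity(rng, 5)
        with pytest.raises(ValueError):
            local_affinity(lay, 5)


class TestWeightedUpdate:
    def _setup(self, rng, n=10, m=3):
        layers = [_random_similarity(rng, n) for _ in range(m)]
        P = [normalize_p0(l, "robust") for l in layers]
        S = [local_affinity(l, 4).matrix for l in layers]
        return P, S

    def test_equal_bias_equals_unweighted(self):
        rng = np.random.default_rng(9)
        P, S = self._setup(rng, m=3)
        unweighted = weighted_update(P, S, None)
        weighted = weighted_update(P, S, [2.0, 2.0, 2.0])
        for a, b in zip(unweighted, weighted):
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_two_layer_bias_cancels_in_update(self):
        rng = np.random.default_rng(10)
        P, S = self._setup(rng, m=2)
        a = weighted_update(P, S, [1.0, 1.0])
        b = weighted_update(P, S, [5.0, 1.0])
        for x, y in zip(a, b):
            np.testing.assert_allclose(x, y, atol=1e-12)

    def test_rows_stochastic_and_symmetric_after_update(self):
        rng = np.random.default_rng(11)
        P, S = self._setup(rng, m=3)
        for M in weighted_update(P, S, [3.0, 1.0, 0.5]):
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-8)
            np.testing.assert_allclose(M, M.T, atol=1e-8)

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(12)
        P, S = self._setup(rng, m=2)
        with pytest.raises(ValueError):
            weighted_update(P, [S[0], S[1][:5, :5]], None)


class TestFuse:
    def _block_multiplex(self, seed=0, noise=0.1, n=90, **kw):
        spec = ff.FixtureSpec(seed=seed, n_conditions=n, noise_sd=noise)
        return spec, ff.planted_multiplex(spec, **kw)

    def test_identical_layers_fixed_point_blocks(self):
        spec = ff.FixtureSpec(seed=0, n_conditions=30, noise_sd=0.0)
        net = ff.planted_multiplex(spec, n_layers=2)
        # noiseless layers are identical; fused must preserve the exact blocks
        res = fuse(net)
        labels = np.concatenate(
            [np.full(s, c) for c, s in enumerate(spec.block_sizes)]
        )
        F = res.fused.matrix
        within = F[(labels[:, None] == labels[None, :]) & ~np.eye(30, dtype=bool)]
        between = F[labels[:, None] != labels[None, :]]
        assert within.min() > between.max() * 10

    def test_max_iter_zero_returns_weighted_p0_average(self):
        rng = np.random.default_rng(13)
        layers = [_random_similarity(rng, 8) for _ in range(2)]
        net = MultiplexNetwork(layers=layers, bias=np.array([2.0, 1.0]), K=3,
                               max_iter=0)
        res = fuse(net)
        expected = (
            2.0 * normalize_p0(layers[0], "robust")
            + 1.0 * normalize_p0(layers[1], "robust")
        ) / 3.0
        expected = (expected + expected.T) / 2.0
        np.testing.assert_allclose(res.fused.matrix, expected, atol=1e-12)

    def test_planted_recovery_and_contrast_gain(self):
        spec, net = self._block_multiplex(seed=3)
        res = fuse(net)
        labels = np.concatenate(
            [np.full(s, c) for c, s in enumerate(spec.block_sizes)]
        )
        assign = ff.spectral_cluster(res.fused, k=3, seed=0)
        assert adjusted_rand_score(labels, assign.labels) >= 0.9
        mask = labels[:, None] == labels[None, :]
        off = ~np.eye(len(labels), dtype=bool)

        def contrast(M):
            return M[mask & off].mean() / M[~mask].mean()

        fused_contrast = contrast(res.fused.matrix)
        for lay in net.layers:
            assert fused_contrast > contrast(lay.matrix)

    def test_rows_remain_stochastic_through_iterations(self):
        spec, net = self._block_multiplex(seed=4, n=45)
        res = fuse(net, bias_mode="update")
        # aggregate of row-stochastic matrices with equal weights
        np.testing.assert_allclose(res.fused.matrix.sum(axis=1), 1.0, atol=1e-8)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(14)
        layers = [_random_similarity(rng, 12) for _ in range(2)]
        ids = layers[0].node_ids
        perm = rng.permutation(12)
        permuted_layers = [
            SimilarityLayer(l.matrix[np.ix_(perm, perm)], [ids[i] for i in perm])
            for l in layers
        ]
        net = MultiplexNetwork(layers=layers, bias=np.ones(2), K=4, max_iter=5)
        net_p = MultiplexNetwork(layers=permuted_layers, bias=np.ones(2), K=4, max_iter=5)
        F = fuse(net).fused.matrix
        Fp = fuse(net_p).fused.matrix
        np.testing.assert_allclose(F[np.ix_(perm, perm)], Fp, atol=1e-10)

    def test_bias_moves_aggregate_toward_trusted_layer(self):
        rng = np.random.default_rng(15)
        layers = [_random_similarity(rng, 10) for _ in range(2)]
        net_eq = MultiplexNetwork(layers=layers, bias=np.array([1.0, 1.0]), K=4, max_iter=0)
        net_b = MultiplexNetwork(layers=layers, bias=np.array([9.0, 1.0]), K=4, max_iter=0)
        P0 = normalize_p0(layers[0], "robust")
        F_eq = fuse(net_eq).fused.matrix
        F_b = fuse(net_b).fused.matrix
        assert np.linalg.norm(F_b - P0) < np.linalg.norm(F_eq - P0)

    def test_estimator_front_end_matches_fuse(self):
        spec, net = self._block_multiplex(seed=5, n=30)
        res = fuse(net)
        est = ff.SimilarityNetworkFusion(K=net.K).fit(net.layers)
        np.testing.assert_allclose(est.fused_, res.fused.matrix, atol=1e-12)
        assert est.n_iter_ == res.iterations

    def test_layer_io_roundtrip(self, tmp_path):
        rng = np.random.default_rng(16)
        lay = _random_similarity(rng, 6)
        path = tmp_path / "layer.tsv"
        ff.fusion.write_layer(lay, path)
        back = ff.fusion.read_layer(path)
        assert back.node_ids == lay.node_ids
        np.testing.assert_allclose(back.matrix, lay.matrix, atol=1e-12)
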