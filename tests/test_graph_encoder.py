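"""Topology-adaptive graph convolution against dense polynomial oracles."""

import numpy as np
import pytest

from peppinet.graph_encoder import (
    GraphEncoder,
    TagConvParams,
    adjacency_power_features,
    pool_project,
    tag_conv,
)
from peppinet.structures_io import normalize_adjacency


def _dense_oracle(a_norm, x, params):
    """Literal sum_k g_k A^k x + b with explicit matrix powers."""
    y = np.zeros((x.shape[0], params.out_channels))
    for f in range(params.out_channels):
        for c in range(params.in_channels):
            for k in range(params.k + 1):
                y[:, f] += params.coefficients[c, f, k] * (
                    np.linalg.matrix_power(a_norm, k) @ x[:, c]
                )
        y[:, f] += params.bias[f]
    return y


def _random_graph(g, n):
    adj = np.triu((g.random((n, n)) < 0.5).astype(int), 1)
    return normalize_adjacency(adj + adj.T)


def _path_adjacency(n):
    adj = np.zeros((n, n), dtype=int)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = 1
    return adj


class TestTagConv:
    def test_identity_filter_reproduces_input(self, rng):
        c = 3
        coeff = np.zeros((c, c, 3))
        coeff[:, :, 0] = np.eye(c)  # A^0 = I picks out the input channel
        params = TagConvParams(coeff, np.zeros(c))
        x = rng.normal(size=(5, c))
        a = _random_graph(rng, 5)
        np.testing.assert_allclose(
            tag_conv(a, x, params, activation="identity"), x, atol=1e-12
        )

    def test_matches_dense_oracle_on_path_graph(self, rng):
        a = normalize_adjacency(_path_adjacency(3))
        params = TagConvParams(rng.normal(size=(2, 4, 3)), rng.normal(size=4))
        x = rng.normal(size=(3, 2))
        expected = np.maximum(_dense_oracle(a, x, params), 0)
        np.testing.assert_allclose(tag_conv(a, x, params), expected, atol=1e-5)

    def test_oracle_equivalence_on_random_graphs(self):
        g = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            n = int(g.integers(2, 11))
            k = int(g.integers(1, 5))
            c_in, c_out = int(g.integers(1, 4)), int(g.integers(1, 5))
            a = _random_graph(g, n)
            params = TagConvParams(g.normal(size=(c_in, c_out, k + 1)),
                                   g.normal(size=c_out))
            x = g.normal(size=(n, c_in))
            got = tag_conv(a, x, params)
            want = np.maximum(_dense_oracle(a, x, params), 0)
            worst = max(worst, np.abs(got - want).max())
        assert worst < 1e-5

    def test_k_hop_locality_on_path_graph(self, rng):
        # node 1 is six hops from node 7; K=3 filters cannot reach it
        n, k = 7, 3
        a = normalize_adjacency(_path_adjacency(n))
        params = TagConvParams(rng.normal(size=(1, 2, k + 1)), rng.normal(size=2))
        x = rng.normal(size=(n, 1))
        x2 = x.copy()
        x2[6, 0] += 10.0
        base = tag_conv(a, x, params)
        pert = tag_conv(a, x2, params)
        np.testing.assert_array_equal(base[0], pert[0])
        assert not np.array_equal(base[6], pert[6])

    def test_permutation_equivariance(self, rng):
        n = 8
        adj = np.triu((rng.random((n, n)) < 0.4).astype(int), 1)
        adj = adj + adj.T
        a = normalize_adjacency(adj)
        x = rng.normal(size=(n, 3))
        params = TagConvParams(rng.normal(size=(3, 4, 4)), rng.normal(size=4))
        perm = rng.permutation(n)
        a_p = normalize_adjacency(adj[perm][:, perm])
        out_p = tag_conv(a_p, x[perm], params)
        np.testing.assert_allclose(out_p, tag_conv(a, x, params)[perm],
                                   atol=1e-9)

    def test_zero_high_order_coefficients_means_no_mixing(self, rng):
        # only k=0 active: output is a per-node linear map of its own features
        coeff = np.zeros((2, 3, 4))
        coeff[:, :, 0] = rng.normal(size=(2, 3))
        params = TagConvParams(coeff, np.zeros(3))
        x = rng.normal(size=(6, 2))
        a = _random_graph(rng, 6)
        np.testing.assert_allclose(
            tag_conv(a, x, params, activation="identity"),
            x @ coeff[:, :, 0], atol=1e-12,
        )

    def test_shape_mismatch_raises(self, rng):
        params = TagConvParams(rng.normal(size=(3, 2, 2)), np.zeros(2))
        with pytest.raises(ValueError, match="channels"):
            tag_conv(np.eye(4), rng.normal(size=(4, 2)), params)


class TestPoolProject:
    def test_constant_features_project_the_constant(self, rng):
        v = rng.normal(size=4)
        x = np.tile(v, (6, 1))
        w = rng.normal(size=(4, 5))
        out = pool_project(x, w)
        np.testing.assert_allclose(out.values, v @ w, atol=1e-12)

    def test_permutation_invariance(self, rng):
        x = rng.normal(size=(7, 4))
        w = rng.normal(size=(4, 3))
        perm = rng.permutation(7)
        np.testing.assert_array_equal(pool_project(x, w).values,
                                      pool_project(x[perm], w).values)

    def test_identity_projection_gives_columnwise_max(self, rng):
        x = rng.normal(size=(5, 8))
        out = pool_project(x, np.eye(8))
        expected = [max(x[i, j] for i in range(5)) for j in range(8)]
        np.testing.assert_allclose(out.values, expected, atol=1e-12)


class TestGraphEncoder:
    def test_trainable_path_equals_pure_function(self, rng):
        """The stacked-power fast path is the same polynomial as tag_conv."""
        enc = GraphEncoder(in_channels=3, tag_channels=5, feature_dim=4,
                           k=2, rng=np.random.default_rng(0))
        adj = np.triu((rng.random((6, 6)) < 0.5).astype(int), 1)
        a = normalize_adjacency(adj + adj.T)
        x = rng.normal(size=(6, 3))
        z = adjacency_power_features(a, x, 2)
        fast = enc.forward_one(z).data.ravel()
        h = tag_conv(a, x, enc.tag_params())
        slow = pool_project(h, enc.proj_w.data, enc.proj_b.data).values
        np.testing.assert_allclose(fast, slow, atol=1e-9)

    def test_graph_feature_invariant_to_node_relabeling(self, rng):
        enc = GraphEncoder(2, 4, 3, 3, np.random.default_rng(5))
        adj = np.triu((rng.random((7, 7)) < 0.5).astype(int), 1)
        adj = adj + adj.T
        x = rng.normal(size=(7, 2))
        perm = rng.permutation(7)
        z1 = adjacency_power_features(normalize_adjacency(adj), x, 3)
        z2 = adjacency_power_features(
            normalize_adjacency(adj[perm][:, perm]), x[perm], 3)
        np.testing.assert_allclose(enc.forward_one(z1).data,
                                   enc.forward_one(z2).data, atol=1e-9)
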