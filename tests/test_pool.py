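"""Attention pooling: scalar oracles, assignment normalization, coarsening."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmaps import GMAPool, coarsen_adjacency, compute_assignment, normalize_adjacency, scaled_dot_attention
from gmaps.autodiff import Tensor

from conftest import random_graph


def attention_oracle(Q, K, V, scale):
    """Scalar-loop softmax(QK^T/scale)V."""
    m, n = Q.shape[0], K.shape[0]
    W = np.zeros((m, n))
    for i in range(m):
        logits = np.array([Q[i] @ K[j] / scale for j in range(n)])
        e = np.exp(logits - logits.max())
        W[i] = e / e.sum()
    return W @ V, W


class TestScaledDotAttention:
    def test_identical_keys_give_mean_of_values(self, rng):
        K = np.tile(rng.normal(size=2), (4, 1))
        V = rng.normal(size=(4, 3))
        out, w = scaled_dot_attention(rng.normal(size=(2, 2)), K, V)
        np.testing.assert_allclose(out.data, np.tile(V.mean(axis=0), (2, 1)), atol=1e-12)
        np.testing.assert_allclose(w.data, 0.25, atol=1e-12)

    def test_two_key_closed_form(self):
        out, w = scaled_dot_attention(np.array([[1.0, 0.0]]),
                                      np.array([[1.0, 0.0], [0.0, 1.0]]),
                                      np.array([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_allclose(w.data, [[0.6698, 0.3302]], atol=1e-4)
        np.testing.assert_allclose(out.data, [[1.6604, 2.6604]], atol=1e-4)

    def test_single_key_returns_value(self, rng):
        V = rng.normal(size=(1, 3))
        out, w = scaled_dot_attention(rng.normal(size=(4, 2)), rng.normal(size=(1, 2)), V)
        np.testing.assert_allclose(out.data, np.tile(V, (4, 1)), atol=1e-12)
        np.testing.assert_allclose(w.data, 1.0)

    def test_matches_scalar_oracle(self, rng):
        Q, K, V = rng.normal(size=(3, 4)), rng.normal(size=(6, 4)), rng.normal(size=(6, 5))
        out, w = scaled_dot_attention(Q, K, V)
        out_o, w_o = attention_oracle(Q, K, V, np.sqrt(4))
        np.testing.assert_allclose(out.data, out_o, atol=1e-6)
        np.testing.assert_allclose(w.data, w_o, atol=1e-6)

    def test_masked_keys_get_zero_weight(self, rng):
        mask = np.array([True, False, True, True])
        _, w = scaled_dot_attention(rng.normal(size=(2, 3)), rng.normal(size=(4, 3)),
                                    rng.normal(size=(4, 2)), key_mask=mask)
        assert (w.data[:, 1] == 0.0).all()
        np.testing.assert_allclose(w.data.sum(axis=1), 1.0, atol=1e-12)

    def test_all_masked_raises(self, rng):
        with pytest.raises(ValueError):
            scaled_dot_attention(np.zeros((1, 2)), np.zeros((3, 2)), np.zeros((3, 2)),
                                 key_mask=np.zeros(3, dtype=bool))


def make_pool(d, nc, heads, rng, **kw):
    return GMAPool(d, nc, heads, rng, **kw)


class TestMultihead:
    def test_single_head_identity_reduces_to_scaled_dot(self, rng):
        d = 4
        pool = make_pool(d, 2, 1, rng)
        pool.w_q[0].data = np.eye(d)
        pool.w_k[0].data = np.eye(d)
        pool.w_v[0].data = np.eye(d)
        pool.w_o.data = np.eye(d)
        Q, K, V = rng.normal(size=(2, d)), rng.normal(size=(5, d)), rng.normal(size=(5, d))
        out, _ = pool.multihead_attention(Tensor(Q), Tensor(K), Tensor(V))
        expect, _ = scaled_dot_attention(Q, K, V, scale=np.sqrt(d))
        np.testing.assert_allclose(out.data, expect.data, atol=1e-10)

    def test_output_shape_independent_of_n(self, rng):
        pool = make_pool(8, 3, 4, rng)
        for n in (2, 7, 20):
            out, weights = pool.multihead_attention(
                pool.seed_queries, Tensor(rng.normal(size=(n, 8))), Tensor(rng.normal(size=(n, 8))))
            assert out.shape == (3, 8)
            assert all(w.shape == (3, n) for w in weights)

    def test_matches_per_head_loop_oracle(self, rng):
        d, h, nc, n = 8, 2, 3, 6
        pool = make_pool(d, nc, h, rng)
        Q, K, V = rng.normal(size=(nc, d)), rng.normal(size=(n, d)), rng.normal(size=(n, d))
        out, _ = pool.multihead_attention(Tensor(Q), Tensor(K), Tensor(V))
        heads = []
        for i in range(h):
            o, _ = attention_oracle(Q @ pool.w_q[i].data, K @ pool.w_k[i].data,
                                    V @ pool.w_v[i].data, np.sqrt(d // h))
            heads.append(o)
        expect = np.concatenate(heads, axis=1) @ pool.w_o.data
        np.testing.assert_allclose(out.data, expect, atol=1e-6)

    def test_indivisible_heads_rejected(self, rng):
        with pytest.raises(ValueError):
            make_pool(6, 2, 4, rng)


class TestGMA:
    def test_zero_features_give_uniform_weights(self, rng):
        pool = make_pool(4, 2, 2, rng)
        a = normalize_adjacency(np.zeros((5, 5)))
        _, weights = pool.gma(Tensor(np.zeros((5, 4))), a)
        for w in weights:
            np.testing.assert_allclose(w.data, 0.2, atol=1e-12)

    def test_matches_composed_oracle(self, rng):
        d, h, n = 8, 2, 6
        g = random_graph(n, d, rng)
        pool = make_pool(d, 3, h, rng)
        a = normalize_adjacency(g.adjacency)
        out, _ = pool.gma(Tensor(g.features), a)
        # oracle: normalize -> conv -> per-head attention loops
        keys = np.maximum(a @ g.features @ pool.key_gnn.weight.data, 0.0)
        values = np.maximum(a @ g.features @ pool.value_gnn.weight.data, 0.0)
        Q = pool.seed_queries.data
        heads = []
        for i in range(h):
            o, _ = attention_oracle(Q @ pool.w_q[i].data, keys @ pool.w_k[i].data,
                                    values @ pool.w_v[i].data, np.sqrt(d // h))
            heads.append(o)
        expect = np.concatenate(heads, axis=1) @ pool.w_o.data
        np.testing.assert_allclose(out.data, expect, atol=1e-6)


class TestGMAPForward:
    def test_output_shape_for_any_n(self, rng):
        pool = make_pool(8, 3, 2, rng)
        for n in (3, 12):
            g = random_graph(n, 8, rng)
            out, s, _ = pool.forward(Tensor(g.features), normalize_adjacency(g.adjacency))
            assert out.shape == (3, 8) and s.shape == (n, 3)

    def test_permutation_invariance(self, rng, permutation):
        n = 9
        g = random_graph(n, 8, rng)
        pool = make_pool(8, 3, 2, rng)
        p, _ = permutation(n)
        out, s, _ = pool.forward(Tensor(g.features), normalize_adjacency(g.adjacency))
        out_p, s_p, _ = pool.forward(Tensor(g.features[p]),
                                     normalize_adjacency(g.adjacency[np.ix_(p, p)]))
        np.testing.assert_allclose(out_p.data, out.data, atol=1e-5)
        np.testing.assert_allclose(s_p.data, s.data[p], atol=1e-5)

    def test_zero_ffn_identity_ln_gives_z(self, rng):
        pool = make_pool(4, 2, 2, rng)
        pool.ffn_w1.data[:] = 0.0
        pool.ffn_b1.data[:] = 0.0
        pool.ffn_w2.data[:] = 0.0
        pool.ffn_b2.data[:] = 0.0
        g = random_graph(5, 4, rng)
        a = normalize_adjacency(g.adjacency)
        out, _, _ = pool.forward(Tensor(g.features), a)
        attended, _ = pool.gma(Tensor(g.features), a)
        from gmaps.autodiff import layer_norm
        z = layer_norm(pool.seed_queries + attended, pool.ln1_g, pool.ln1_b)
        # second LN is applied to Z + 0; with learnable params at init (gain 1, shift 0)
        z2 = layer_norm(z, pool.ln2_g, pool.ln2_b)
        np.testing.assert_allclose(out.data, z2.data, atol=1e-12)


class TestAssignment:
    def test_identical_heads_transpose(self, rng):
        w = Tensor(np.random.default_rng(0).dirichlet(np.ones(5), size=3))
        s = compute_assignment([w, w])
        np.testing.assert_allclose(s.data, w.data.T, atol=1e-15)

    def test_uniform_weights(self):
        w = Tensor(np.full((2, 4), 0.25))
        np.testing.assert_allclose(compute_assignment([w]).data, 0.25)

    def test_column_sums_one(self, rng):
        heads = [Tensor(np.random.default_rng(i).dirichlet(np.ones(7), size=4)) for i in range(3)]
        s = compute_assignment(heads)
        np.testing.assert_allclose(s.data.sum(axis=0), 1.0, atol=1e-9)


class TestCoarsen:
    def test_identity_assignment_keeps_adjacency(self, rng):
        g = random_graph(4, 2, rng)
        np.testing.assert_allclose(coarsen_adjacency(np.eye(4), g.adjacency), g.adjacency)

    def test_all_ones_column_sums_edges(self, rng):
        g = random_graph(6, 2, rng)
        n_edges = g.adjacency.sum() / 2
        out = coarsen_adjacency(np.ones((6, 1)), g.adjacency)
        np.testing.assert_allclose(out, [[2 * n_edges]])

    def test_block_indicator_on_disconnected_triangles(self):
        tri = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        A = np.block([[tri, np.zeros((3, 3))], [np.zeros((3, 3)), tri]])
        S = np.zeros((6, 2))
        S[:3, 0] = S[3:, 1] = 1.0
        out = coarsen_adjacency(S, A)
        np.testing.assert_allclose(out, np.diag([6.0, 6.0]))  # 2*3 edges per block

    def test_symmetry_and_mass_oracle(self, rng):
        g = random_graph(7, 2, rng)
        S = np.random.default_rng(1).dirichlet(np.ones(7), size=3).T  # 7x3, cols sum 1
        out = coarsen_adjacency(S, g.adjacency)
        np.testing.assert_allclose(out, out.T, atol=1e-12)
        assert (out >= -1e-12).all()
        mass = sum(g.adjacency[v, u] * S[v].sum() * S[u].sum()
                   for v in range(7) for u in range(7))
        np.testing.assert_allclose(out.sum(), mass, atol=1e-9)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            coarsen_adjacency(np.ones((4, 2)), np.eye(5))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(n=st.integers(2, 12), nc=st.integers(1, 5), heads=st.integers(1, 3),
       seed=st.integers(0, 10_000))
def test_pooling_invariants_hold_for_arbitrary_graphs(n, nc, heads, seed):
    """For any graph size, cluster count and head count: S columns sum to 1,
    padded-free rows are nonnegative, and S^T A S stays symmetric."""
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.random((n, n)) < 0.4, k=1).astype(float)
    adj = upper + upper.T
    d = 4 * heads
    pool = make_pool(d, nc, heads, rng)
    _, s, _ = pool.forward(Tensor(rng.normal(size=(n, d))), normalize_adjacency(adj))
    assert s.shape == (n, nc)
    assert (s.data >= 0).all() and (s.data <= 1).all()
    np.testing.assert_allclose(s.data.sum(axis=0), 1.0, atol=1e-9)
    a2 = coarsen_adjacency(s.data, adj)
    np.testing.assert_allclose(a2, a2.T, atol=1e-12)
    assert (a2 >= -1e-12).all()
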