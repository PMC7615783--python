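"""Graph construction, vertex scoring, GAT fusion and top-k pooling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csagp.config import token_schedule
from csagp.nn import Tensor
from csagp.pooling import (FBLM, GATFusion, RPR, SBLM, SFLM, TokenGraph,
                           graph_to_tokens, pooled_size, tokens_to_graph,
                           top_k_pool)
from csagp.types import TokenSequence


def naive_adjacency(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Double-loop Euclidean threshold oracle."""
    n = len(x)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            dist[i, j] = np.linalg.norm(x[i] - x[j])
    mu = dist.sum() / n**2
    adj = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            adj[i, j] = 1 if dist[i, j] < mu else 0
    return adj, mu


class TestTokensToGraph:
    def test_hand_worked_three_vertex_example(self):
        feats = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0]])
        graph = tokens_to_graph(feats)
        assert graph.mean_distance == pytest.approx(20.0 / 9.0)
        np.testing.assert_array_equal(
            graph.adjacency, [[1, 1, 0], [1, 1, 0], [0, 0, 1]])

    def test_identical_rows_fall_back_to_identity(self):
        graph = tokens_to_graph(np.ones((4, 3)))
        assert graph.mean_distance == 0.0
        np.testing.assert_array_equal(graph.adjacency, np.eye(4, dtype=int))

    def test_matches_naive_oracle_on_random_inputs(self, rng):
        x = rng.normal(size=(50, 8))
        expected, mu = naive_adjacency(x)
        graph = tokens_to_graph(x)
        np.testing.assert_array_equal(graph.adjacency, expected)
        assert graph.mean_distance == pytest.approx(mu)

    def test_adjacency_symmetric_with_unit_diagonal(self, rng):
        graph = tokens_to_graph(rng.normal(size=(20, 4)))
        np.testing.assert_array_equal(graph.adjacency, graph.adjacency.T)
        np.testing.assert_array_equal(np.diag(graph.adjacency), 1)

    def test_single_vertex_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            tokens_to_graph(np.ones((1, 3)))


class TestSBLM:
    def test_identity_adjacency_reduces_to_feature_projection(self, rng):
        sblm = SBLM(4, rng)
        graph = TokenGraph(Tensor(rng.normal(size=(6, 4))), np.eye(6, dtype=int))
        s1 = sblm(graph)
        logit = graph.features.data @ sblm.weight.data
        np.testing.assert_allclose(
            s1.data, 1 / (1 + np.exp(-logit.ravel())), atol=1e-12)

    def test_matches_dense_double_loop_oracle(self, rng):
        sblm = SBLM(8, rng)
        x = rng.normal(size=(10, 8))
        graph = tokens_to_graph(x)
        s1 = sblm(graph)
        a = graph.adjacency.astype(float)
        deg = np.maximum(a.sum(1), 1.0)
        w = sblm.weight.data.ravel()
        expected = np.empty(10)
        for i in range(10):
            acc = 0.0
            for j in range(10):
                acc += a[i, j] / np.sqrt(deg[i] * deg[j]) * (x[j] @ w)
            expected[i] = 1 / (1 + np.exp(-acc))
        np.testing.assert_allclose(s1.data, expected, atol=1e-6)

    def test_permutation_equivariance(self, rng):
        sblm = SBLM(5, rng)
        x = rng.normal(size=(12, 5))
        perm = rng.permutation(12)
        s = sblm(tokens_to_graph(x)).data
        s_perm = sblm(tokens_to_graph(x[perm])).data
        np.testing.assert_allclose(s_perm, s[perm], atol=1e-12)

    def test_isolated_vertex_degree_clamped(self, rng):
        sblm = SBLM(3, rng)
        adj = np.zeros((3, 3), dtype=int)  # fully isolated graph
        graph = TokenGraph(Tensor(rng.normal(size=(3, 3))), adj)
        assert np.isfinite(sblm(graph).data).all()


class TestFBLM:
    def test_identical_rows_get_identical_scores(self, rng):
        fblm = FBLM(4, rng)
        x = np.tile(rng.normal(size=(1, 4)), (3, 1))
        s2 = fblm(Tensor(x))
        assert s2.shape == (3,)
        np.testing.assert_allclose(s2.data, s2.data[0])

    def test_eval_mode_matches_affine_dot_product_oracle(self, rng):
        fblm = FBLM(6, rng)
        fblm.eval()  # BN with default running stats: near-identity transform
        x = rng.normal(size=(5, 6))
        raw = x @ fblm.conv.weight.data + fblm.conv.bias.data
        expected = 1 / (1 + np.exp(-(raw / np.sqrt(1 + fblm.bn.eps)).ravel()))
        np.testing.assert_allclose(fblm(Tensor(x)).data, expected, atol=1e-9)

    @pytest.mark.parametrize("n", [1, 2, 7])
    @pytest.mark.parametrize("variant", ["conv", "mlp"])
    def test_output_length_for_any_n(self, rng, n, variant):
        fblm = FBLM(4, rng, variant=variant)
        assert fblm(Tensor(rng.normal(size=(n, 4)))).shape == (n,)

    def test_mlp_variant_is_rowwise(self, rng):
        fblm = FBLM(4, rng, variant="mlp")
        x = rng.normal(size=(6, 4))
        full = fblm(Tensor(x)).data
        single = np.array([fblm(Tensor(x[i:i + 1])).data[0] for i in range(6)])
        np.testing.assert_allclose(full, single, atol=1e-12)


class TestSFLM:
    def test_zero_scores_zero_bias_give_zero(self, rng):
        sflm = SFLM(rng)
        sflm.conv.bias.data[:] = 0.0
        sflm.eval()  # BN identity-like with default running stats, beta=0
        z = Tensor(np.zeros(5))
        np.testing.assert_allclose(sflm(z, z).data, 0.0, atol=1e-12)

    def test_identity_conv_recovers_sum(self, rng):
        sflm = SFLM(rng)
        sflm.conv.weight.data[:] = 1.0
        sflm.conv.bias.data[:] = 0.0
        sflm.eval()
        s1 = Tensor(rng.normal(size=(6,)))
        s2 = Tensor(rng.normal(size=(6,)))
        np.testing.assert_allclose(sflm(s1, s2).data,
                                   (s1.data + s2.data), rtol=1e-5)

    def test_batchnorm_cancels_common_shift_in_ranking(self, rng):
        sflm = SFLM(rng)
        sflm.train()
        s1 = Tensor(rng.normal(size=(10,)))
        s2 = Tensor(rng.normal(size=(10,)))
        base = sflm(s1, s2).data
        shifted = sflm(s1 + 3.7, s2 + 3.7).data
        np.testing.assert_array_equal(np.argsort(base), np.argsort(shifted))

    def test_linear_variant_weighted_sum(self, rng):
        sflm = SFLM(rng, variant="linear")
        sflm.alpha.data[:] = 2.0
        sflm.beta.data[:] = -1.0
        s1 = Tensor(np.array([1.0, 2.0]))
        s2 = Tensor(np.array([0.5, 0.5]))
        np.testing.assert_allclose(sflm(s1, s2).data, [1.5, 3.5])

    def test_length_mismatch_raises(self, rng):
        sflm = SFLM(rng)
        with pytest.raises(ValueError, match="mismatch"):
            sflm(Tensor(np.zeros(3)), Tensor(np.zeros(4)))


class TestGATFusion:
    def test_uniform_logits_single_head_average_neighbors(self, rng):
        from scipy.special import erf

        gat = GATFusion(4, 1, rng)
        gat.a_src.data[:] = 0.0
        gat.a_dst.data[:] = 0.0
        x = rng.normal(size=(6, 4))
        graph = tokens_to_graph(x)
        out = gat(graph)
        h = x @ gat.w[0].weight.data
        adj = graph.adjacency.copy()
        np.fill_diagonal(adj, 1)
        for i in range(6):
            mean = h[np.flatnonzero(adj[i])].mean(axis=0)
            expected = mean * 0.5 * (1 + erf(mean / np.sqrt(2)))
            np.testing.assert_allclose(out.data[i], expected, atol=1e-10)

    def test_attention_coefficients_sum_to_one_per_vertex(self, rng):
        gat = GATFusion(5, 3, rng)
        graph = tokens_to_graph(rng.normal(size=(9, 5)))
        for alpha in gat.attention_coefficients(graph):
            np.testing.assert_allclose(alpha.data.sum(axis=1), 1.0, atol=1e-5)
            # no attention outside the neighborhood
            adj = graph.adjacency.copy()
            np.fill_diagonal(adj, 1)
            assert np.all(alpha.data[adj == 0] < 1e-12)

    def test_self_loop_only_vertex_keeps_own_features(self, rng):
        from scipy.special import erf

        gat = GATFusion(4, 1, rng)
        x = rng.normal(size=(4, 4))
        graph = TokenGraph(Tensor(x), np.eye(4, dtype=int))
        out = gat(graph)
        h = x @ gat.w[0].weight.data
        np.testing.assert_allclose(out.data, h * 0.5 * (1 + erf(h / np.sqrt(2))),
                                   atol=1e-10)


class TestTopKPool:
    def test_hand_example(self, rng):
        graph = tokens_to_graph(rng.normal(size=(4, 3)))
        pooled = top_k_pool(graph, np.array([0.9, 0.1, 0.5, 0.7]), 0.5)
        np.testing.assert_array_equal(pooled.kept_indices, [0, 3])
        np.testing.assert_array_equal(
            pooled.adjacency, graph.adjacency[np.ix_([0, 3], [0, 3])])

    def test_rate_one_is_identity_pooling(self, rng):
        x = rng.normal(size=(7, 3))
        graph = tokens_to_graph(x)
        pooled = top_k_pool(graph, rng.normal(size=7), 1.0)
        np.testing.assert_array_equal(pooled.kept_indices, np.arange(7))
        np.testing.assert_allclose(pooled.features.data, x)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1), st.floats(0.05, 1.0))
    def test_matches_argsort_oracle_including_ties(self, seed, r):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        # coarse quantization forces frequent ties
        scores = np.round(rng.normal(size=n), 1)
        graph = tokens_to_graph(rng.normal(size=(n, 3)))
        pooled = top_k_pool(graph, scores, r)
        k = max(1, int(np.floor(r * n)))
        oracle = sorted(sorted(range(n), key=lambda i: (-scores[i], i))[:k])
        np.testing.assert_array_equal(pooled.kept_indices, oracle)

    def test_invalid_rate_rejected(self, rng):
        graph = tokens_to_graph(rng.normal(size=(4, 2)))
        with pytest.raises(ValueError, match="rate"):
            top_k_pool(graph, np.zeros(4), 0.0)


class TestGraphToTokens:
    def test_zero_pe_concatenates_exactly(self, rng):
        graph = tokens_to_graph(rng.normal(size=(5, 3)))
        pooled = top_k_pool(graph, rng.normal(size=5), 0.5)
        cls = Tensor(rng.normal(size=(1, 3)))
        seq = graph_to_tokens(pooled, cls, Tensor(np.zeros((3, 3))))
        assert seq.length == 3
        np.testing.assert_array_equal(seq.tokens.data[0], cls.data[0])
        np.testing.assert_array_equal(seq.tokens.data[1:], pooled.features.data)

    def test_pe_shape_mismatch_raises(self, rng):
        graph = tokens_to_graph(rng.normal(size=(5, 3)))
        pooled = top_k_pool(graph, rng.normal(size=5), 0.5)
        with pytest.raises(ValueError, match="positional encoding"):
            graph_to_tokens(pooled, Tensor(np.zeros((1, 3))),
                            Tensor(np.zeros((5, 3))))


class TestRPRStage:
    def test_output_length_follows_schedule(self, rng):
        rpr = RPR(4, 196, 0.5, rng)
        seq = TokenSequence(Tensor(rng.normal(size=(197, 4))))
        assert rpr(seq).length == 99

    def test_schedule_iterates_197_99_50_25(self):
        assert token_schedule(196, 0.5, 3) == [197, 99, 50, 25]

    def test_rate_one_preserves_length(self, rng):
        rpr = RPR(4, 12, 1.0, rng)
        seq = TokenSequence(Tensor(rng.normal(size=(13, 4))))
        assert rpr(seq).length == 13

    def test_too_short_sequence_rejected(self, rng):
        rpr = RPR(4, 2, 0.5, rng)
        with pytest.raises(ValueError, match="class token"):
            rpr(TokenSequence(Tensor(np.zeros((2, 4)))))

    def test_score_and_selection_permutation_equivariance(self, rng):
        """Permuting patch rows permutes the scores and maps the kept set."""
        dim, n = 5, 14
        rpr = RPR(dim, n, 0.5, rng)
        rpr.train()
        x = rng.normal(size=(n, dim))
        perm = rng.permutation(n)

        def scores_and_kept(features):
            graph = tokens_to_graph(features)
            s = rpr.sflm(rpr.sblm(graph), rpr.fblm(graph.features))
            pooled = top_k_pool(graph, s, 0.5)
            return s.data, set(pooled.kept_indices.tolist())

        s_base, kept_base = scores_and_kept(x)
        s_perm, kept_perm = scores_and_kept(x[perm])
        np.testing.assert_allclose(s_perm, s_base[perm], atol=1e-10)
        # kept positions in the permuted graph name the same original rows
        assert {perm[i] for i in kept_perm} == kept_base


@settings(derandomize=True, max_examples=50)
@given(st.integers(4, 300), st.floats(0.05, 1.0), st.integers(1, 4))
def test_token_schedule_matches_iterated_formula(n_patches, r, k_blocks):
    lengths = token_schedule(n_patches, r, k_blocks)
    assert lengths[0] == n_patches + 1
    for prev, nxt in zip(lengths, lengths[1:]):
        assert nxt == max(1, int(np.floor(r * (prev - 1)))) + 1
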