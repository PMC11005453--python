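"""Nested transformer block: attention oracle, residual contracts, fusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from untca import nn
from untca.gnconv import ConfigurationError
from untca.transformer import (NestedBlock, NestedBlockConfig,
                               attention_weights, fuse_alpha,
                               scaled_dot_attention)


def attention_oracle(Q, K, V, d_k):
    """Explicit per-query softmax-matmul loop."""
    out = np.zeros((Q.shape[0], V.shape[1]))
    for i in range(Q.shape[0]):
        scores = np.array([Q[i] @ K[j] / np.sqrt(d_k)
                           for j in range(K.shape[0])])
        w = np.exp(scores - scores.max())
        w /= w.sum()
        out[i] = sum(w[j] * V[j] for j in range(V.shape[0]))
    return out


def plain_block(d, rng=None, alpha=0.3, identity=True):
    cfg = NestedBlockConfig(token_width=d, ffn_hidden=2 * d, dropout_rate=0.0,
                            alpha=alpha, norm=False)
    rng = rng if rng is not None else np.random.default_rng(0)
    return NestedBlock(cfg, rng, identity_projections=identity)


# ---------------------------------------------------------------------------
# scaled_dot_attention
# ---------------------------------------------------------------------------

def test_attention_matches_handfixed_oracle():
    Q = np.array([[[1.0, 2.0], [0.0, -1.0]]])          # 2 queries
    K = np.array([[[1.0, 0.0], [0.0, 1.0], [2.0, 1.0]]])  # 3 keys
    V = np.array([[[1.0, 0.0], [0.0, 3.0], [-2.0, 1.0]]])
    out = scaled_dot_attention(nn.Tensor(Q), nn.Tensor(K), nn.Tensor(V), 2).data
    assert np.abs(out[0] - attention_oracle(Q[0], K[0], V[0], 2)).max() < 1e-6


def test_attention_singleton_key_returns_value(rng):
    Q = nn.Tensor(rng.standard_normal((2, 5, 3)))
    K = nn.Tensor(rng.standard_normal((2, 1, 3)))
    V = nn.Tensor(rng.standard_normal((2, 1, 4)))
    out = scaled_dot_attention(Q, K, V, 3).data
    assert np.allclose(out, np.broadcast_to(V.data, (2, 5, 4)))


def test_attention_zero_scores_give_uniform_mean(rng):
    Q = nn.Tensor(np.zeros((1, 4, 3)))
    K = nn.Tensor(rng.standard_normal((1, 6, 3)))
    V = nn.Tensor(rng.standard_normal((1, 6, 2)))
    out = scaled_dot_attention(Q, K, V, 3).data
    assert np.allclose(out, V.data.mean(axis=1, keepdims=True))


def test_attention_rejects_token_count_mismatch(rng):
    Q = nn.Tensor(np.zeros((1, 2, 3)))
    K = nn.Tensor(np.zeros((1, 4, 3)))
    V = nn.Tensor(np.zeros((1, 5, 3)))
    with pytest.raises(ConfigurationError):
        scaled_dot_attention(Q, K, V, 3)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_attention_rows_sum_to_one(seed):
    r = np.random.default_rng(seed)
    Q = nn.Tensor(r.standard_normal((2, 4, 5)) * r.uniform(0.1, 10))
    K = nn.Tensor(r.standard_normal((2, 7, 5)) * r.uniform(0.1, 10))
    w = attention_weights(Q, K, 5).data
    assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-6)
    assert (w >= 0).all()


# ---------------------------------------------------------------------------
# Block operations (identity projections, no norm, no dropout)
# ---------------------------------------------------------------------------

def test_encode_upsample_zero_values_residual_identity(rng):
    blk = plain_block(4)
    x_u = nn.Tensor(rng.standard_normal((1, 5, 4)))
    x_d = nn.Tensor(rng.standard_normal((1, 7, 4)))
    g = nn.Tensor(np.zeros((1, 7, 4)))
    assert np.allclose(blk.encode_upsample(x_u, x_d, g).data, x_u.data)


def test_encode_upsample_composition_and_token_count(rng):
    blk = plain_block(4)
    x_u = nn.Tensor(rng.standard_normal((1, 5, 4)))
    x_d = nn.Tensor(rng.standard_normal((1, 9, 4)))
    g = nn.Tensor(rng.standard_normal((1, 9, 4)))
    out = blk.encode_upsample(x_u, x_d, g)
    assert out.shape == x_u.shape  # queries decide the token count
    expected = x_u.data + scaled_dot_attention(x_u, x_d, g, 4).data
    assert np.allclose(out.data, expected, atol=1e-12)


def test_decode_multiscale_zero_values_identity(rng):
    blk = plain_block(4)
    x_c = nn.Tensor(rng.standard_normal((1, 6, 4)))
    x_hat_u = nn.Tensor(rng.standard_normal((1, 8, 4)))
    zeros = nn.Tensor(np.zeros((1, 8, 4)))
    assert np.allclose(blk.decode_multiscale(x_c, x_hat_u, zeros).data,
                       x_c.data)


def test_decode_multiscale_permutation_equivariance(rng):
    blk = plain_block(16)
    x_c = nn.Tensor(rng.standard_normal((1, 6, 16)))
    k = rng.standard_normal((1, 8, 16))
    v = rng.standard_normal((1, 8, 16))
    out = blk.decode_multiscale(x_c, nn.Tensor(k), nn.Tensor(v)).data
    perm = rng.permutation(8)
    out_p = blk.decode_multiscale(x_c, nn.Tensor(k[:, perm]),
                                  nn.Tensor(v[:, perm])).data
    assert np.allclose(out, out_p, atol=1e-10)


def test_decode_multiscale_matches_composition_oracle(rng):
    blk = plain_block(16)
    x_c = nn.Tensor(rng.standard_normal((1, 6, 16)))
    k = nn.Tensor(rng.standard_normal((1, 8, 16)))
    v = nn.Tensor(rng.standard_normal((1, 8, 16)))
    expected = x_c.data + scaled_dot_attention(x_c, k, v, 16).data
    assert np.abs(blk.decode_multiscale(x_c, k, v).data - expected).max() < 1e-6


def test_ffn_zero_weights_residual_identity(rng):
    blk = plain_block(4)
    for lin in (blk.ffn1, blk.ffn2):
        lin.w.data[:] = 0.0
        lin.b.data[:] = 0.0
    x = nn.Tensor(rng.standard_normal((1, 3, 4)))
    assert np.allclose(blk.ffn_update(x).data, x.data)


def test_ffn_rectifier_saturation(rng):
    blk = plain_block(4)
    blk.ffn1.b.data[:] = -1e6  # rectifier kills the first layer entirely
    x = nn.Tensor(rng.standard_normal((1, 3, 4)))
    assert np.allclose(blk.ffn_update(x).data, x.data + blk.ffn2.b.data)


def test_ffn_matches_two_layer_perceptron_oracle(rng):
    blk = plain_block(4)
    x = rng.standard_normal((1, 2, 4))
    h = np.maximum(0.0, x @ blk.ffn1.w.data + blk.ffn1.b.data)
    expected = x + h @ blk.ffn2.w.data + blk.ffn2.b.data
    assert np.allclose(blk.ffn_update(nn.Tensor(x)).data, expected, atol=1e-12)


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

def test_fusion_published_ratio():
    ones = nn.Tensor(np.ones((1, 2, 3)))
    zeros = nn.Tensor(np.zeros((1, 2, 3)))
    assert np.allclose(fuse_alpha(ones, zeros, 0.3).data, 0.3)


def test_fusion_degenerate_and_idempotent(rng):
    a = nn.Tensor(rng.standard_normal((1, 4, 2)))
    b = nn.Tensor(rng.standard_normal((1, 4, 2)))
    assert np.array_equal(fuse_alpha(a, b, 1.0).data, a.data)
    for alpha in (0.0, 0.3, 0.9):
        assert np.allclose(fuse_alpha(a, a, alpha).data, a.data)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.floats(0.0, 1.0), st.integers(0, 2 ** 31 - 1))
def test_fusion_convexity_bounds(alpha, seed):
    r = np.random.default_rng(seed)
    a, b = r.standard_normal((2, 3, 4)), r.standard_normal((2, 3, 4))
    out = fuse_alpha(nn.Tensor(a), nn.Tensor(b), alpha).data
    assert (out >= np.minimum(a, b) - 1e-12).all()
    assert (out <= np.maximum(a, b) + 1e-12).all()


def test_fusion_rejects_shape_mismatch():
    with pytest.raises(ConfigurationError):
        fuse_alpha(nn.Tensor(np.zeros((1, 2, 3))),
                   nn.Tensor(np.zeros((1, 3, 3))), 0.5)


# ---------------------------------------------------------------------------
# Whole block
# ---------------------------------------------------------------------------

def test_block_eval_passes_bitwise_identical(rng):
    cfg = NestedBlockConfig(token_width=8, ffn_hidden=16, dropout_rate=0.5)
    blk = NestedBlock(cfg, rng)
    args = [nn.Tensor(rng.standard_normal((1, 6, 8))) for _ in range(4)]
    blk.eval()
    out1 = blk(*args)
    out2 = blk(*args)
    for a, b in zip(out1, out2):
        assert np.array_equal(a.data, b.data)
    blk.train()
    out3 = blk(*args)
    assert not np.array_equal(out1[1].data, out3[1].data)  # dropout active


def test_multihead_preserves_shape_and_rows(rng):
    cfg = NestedBlockConfig(token_width=8, ffn_hidden=16, dropout_rate=0.0,
                            heads=2, norm=False)
    blk = NestedBlock(cfg, rng)
    x_u = nn.Tensor(rng.standard_normal((2, 5, 8)))
    x_d = nn.Tensor(rng.standard_normal((2, 7, 8)))
    g = nn.Tensor(rng.standard_normal((2, 7, 8)))
    assert blk.encode_upsample(x_u, x_d, g).shape == (2, 5, 8)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        NestedBlockConfig(token_width=8, dropout_rate=1.0)
    with pytest.raises(ConfigurationError):
        NestedBlockConfig(token_width=8, alpha=1.5)
    with pytest.raises(ConfigurationError):
        NestedBlockConfig(token_width=9, heads=2)
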