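"""Backbone: stage geometry, aggregation H, recursive transmission, and an
independent plain-U-Net oracle for the fully ablated network."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from untca import nn
from untca.backbone import (AggregateH, BackboneConfig, ConvStage, UNTCA,
                            aggregate_h, param_count, reduced_config)
from untca.gnconv import ConfigurationError

TINY = dict(depth=3, input_size=16, width_schedule=(4, 8, 16),
            token_widths=(16, 16), ffn_hidden=32, dropout=0.0)


# ---------------------------------------------------------------------------
# Independent numpy oracle for the plain (fully ablated) U-Net forward
# ---------------------------------------------------------------------------

def conv_np(x, w, b, stride=1, pad=0):
    B, C, H, W = x.shape
    Co = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    k = w.shape[-1]
    Ho = (xp.shape[2] - k) // stride + 1
    Wo = (xp.shape[3] - k) // stride + 1
    out = np.zeros((B, Co, Ho, Wo))
    for bi in range(B):
        for o in range(Co):
            acc = np.zeros((xp.shape[2] - k + 1, xp.shape[3] - k + 1))
            for c in range(C):
                acc += correlate2d(xp[bi, c], w[o, c], mode="valid")
            out[bi, o] = acc[::stride, ::stride] + b[o]
    return out


def tconv_np(x, w, b):
    B, C, H, W = x.shape
    Co = w.shape[1]
    out = np.einsum("bcij,couv->boiujv", x, w).reshape(B, Co, 2 * H, 2 * W)
    return out + b[None, :, None, None]


def instnorm_np(x, gamma, beta, eps=1e-5):
    m = x.mean(axis=(2, 3), keepdims=True)
    v = ((x - m) ** 2).mean(axis=(2, 3), keepdims=True)
    return (x - m) / np.sqrt(v + eps) * gamma[None, :, None, None] + \
        beta[None, :, None, None]


def lrelu_np(x, s=0.01):
    return np.where(x > 0, x, s * x)


def stage_np(stage: ConvStage, x):
    p = {k: v.data for k, v in stage.named_parameters()}
    if stage.direction == "down":
        y = conv_np(x, p["op1.w"], p["op1.b"], stride=2, pad=1)
    elif stage.direction == "same":
        y = conv_np(x, p["op1.w"], p["op1.b"], pad=1)
    else:
        y = tconv_np(x, p["op1.w"], p["op1.b"])
    y = lrelu_np(instnorm_np(y, p["norm1.gamma"], p["norm1.beta"]))
    y = conv_np(y, p["conv2.w"], p["conv2.b"], pad=1)
    return lrelu_np(instnorm_np(y, p["norm2.gamma"], p["norm2.beta"]))


def plain_unet_oracle(model: UNTCA, x):
    """Forward pass of the fully ablated network in independent numpy."""
    feats = []
    y = x
    for stage in model.enc:
        y = stage_np(stage, y)
        feats.append(y)
    y = feats[-1]
    for level in range(model.cfg.depth - 2, -1, -1):
        up = model.ups[level]
        p = {k: v.data for k, v in up.named_parameters()}
        x_u = lrelu_np(instnorm_np(tconv_np(y, p["up.w"], p["up.b"]),
                                   p["norm.gamma"], p["norm.beta"]))
        y = stage_np(model.dec[level],
                     np.concatenate([x_u, feats[level]], axis=1))
    logits = conv_np(y, model.head.w.data, model.head.b.data)
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Conv stages
# ---------------------------------------------------------------------------

def test_down_stage_halves_full_resolution_input(rng):
    stage = ConvStage(1, 4, "down", rng)
    out = stage(nn.Tensor(rng.standard_normal((1, 1, 384, 384))))
    assert out.shape == (1, 4, 192, 192)


def test_down_then_up_round_trips_shape(rng):
    down = ConvStage(2, 4, "down", rng)
    up = ConvStage(4, 2, "up", rng)
    x = nn.Tensor(rng.standard_normal((1, 2, 12, 12)))
    assert up(down(x)).shape == (1, 2, 12, 12)


def test_down_stage_rejects_odd_size(rng):
    stage = ConvStage(1, 4, "down", rng)
    with pytest.raises(ConfigurationError):
        stage(nn.Tensor(np.zeros((1, 1, 7, 8))))


def test_leaky_activation_keeps_scaled_negatives(rng):
    stage = ConvStage(1, 4, "same", rng)
    out = stage(nn.Tensor(rng.standard_normal((1, 1, 8, 8)))).data
    assert (out < 0).any()  # a hard rectifier would zero these
    assert out.min() > -1.0  # but they are scaled far toward zero


# ---------------------------------------------------------------------------
# Aggregation H
# ---------------------------------------------------------------------------

def test_concatenation_of_identical_parts_is_stacking(rng):
    part = nn.Tensor(rng.standard_normal((1, 3, 4, 4)))
    out, pre = aggregate_h([part, part], "concatenation")
    assert pre == 6
    tokens = part.data.reshape(1, 3, 16).transpose(0, 2, 1)
    assert np.array_equal(out.data, np.concatenate([tokens, tokens], axis=2))


def test_interpolation_on_common_grid_is_elementwise_mean(rng):
    a = nn.Tensor(rng.standard_normal((1, 3, 4, 4)))
    b = nn.Tensor(rng.standard_normal((1, 3, 4, 4)))
    out, _ = aggregate_h([a, b], "interpolation")
    mean = 0.5 * (a.data + b.data)
    assert np.allclose(out.data,
                       mean.reshape(1, 3, 16).transpose(0, 2, 1))


def test_four_part_concatenation_width(rng):
    parts = [nn.Tensor(rng.standard_normal((1, c, 4, 4)))
             for c in (4, 4, 8, 16)]
    out, pre = aggregate_h(parts, "concatenation")
    assert pre == 32 and out.shape == (1, 16, 32)


def test_aggregate_rejects_empty_and_unknown():
    with pytest.raises(ConfigurationError):
        aggregate_h([], "concatenation")
    with pytest.raises(ConfigurationError):
        aggregate_h([nn.Tensor(np.zeros((1, 2, 2, 2)))], "nearest")


def test_learned_aggregate_strategies_project_to_target(rng):
    parts = [nn.Tensor(rng.standard_normal((1, c, 4, 4))) for c in (4, 8)]
    for strategy in ("concatenation", "interpolation"):
        agg = AggregateH((4, 8), 6, strategy, rng)
        out = agg(parts, (2, 2))
        assert out.shape == (1, 4, 6)


# ---------------------------------------------------------------------------
# Recursive transmission and the full forward
# ---------------------------------------------------------------------------

def test_depth_two_gives_one_block_and_one_bundle(rng):
    cfg = BackboneConfig(depth=2, input_size=16, width_schedule=(4, 8),
                         token_widths=(16,), ffn_hidden=32, dropout=0.0)
    model = UNTCA(cfg, seed=0)
    _, details = model.forward_details(nn.Tensor(rng.standard_normal((1, 1, 16, 16))))
    assert len(details["refined"]) == 1
    assert len(details["bundles"]) == 1


def test_bundles_have_arity_four_at_every_level(rng):
    model = UNTCA(BackboneConfig(**TINY), seed=0)
    _, details = model.forward_details(nn.Tensor(rng.standard_normal((1, 1, 16, 16))))
    assert len(details["bundles"]) == model.cfg.depth - 1
    assert all(len(b) == 4 for b in details["bundles"])


def test_forward_shape_and_per_pixel_normalisation(rng):
    model = UNTCA(reduced_config(dropout=0.0), seed=0)
    probs = model(nn.Tensor(rng.standard_normal((1, 1, 64, 64))))
    assert probs.shape == (1, 2, 64, 64)
    assert np.allclose(probs.data.sum(axis=1), 1.0)
    assert (probs.data >= 0).all()


def test_forward_rejects_indivisible_size_naming_minimum(rng):
    model = UNTCA(BackboneConfig(**TINY), seed=0)
    with pytest.raises(ConfigurationError, match="minimal valid size is 4"):
        model(nn.Tensor(np.zeros((1, 1, 18, 18))))


def test_eval_forward_deterministic(rng):
    model = UNTCA(BackboneConfig(**{**TINY, "dropout": 0.1}), seed=0).eval()
    x = rng.standard_normal((1, 1, 16, 16))
    a = model(nn.Tensor(x.copy())).data
    b = model(nn.Tensor(x.copy())).data
    assert np.array_equal(a, b)


def test_gradient_flows_to_every_parameter(rng):
    model = UNTCA(BackboneConfig(**TINY), seed=0)
    x = nn.Tensor(rng.standard_normal((1, 1, 16, 16)))
    loss = (model.logits(x) * model.logits(x)).mean()
    loss.backward()
    dead = [name for name, p in model.named_parameters()
            if p.grad is None or not np.any(p.grad)]
    assert dead == []


def test_parameter_count_is_pure_function_of_config():
    a = UNTCA(BackboneConfig(**TINY), seed=0)
    b = UNTCA(BackboneConfig(**TINY), seed=99)
    assert param_count(a) == param_count(b)
    assert all(pa.data.shape == pb.data.shape
               for pa, pb in zip(a.parameters(), b.parameters()))


@pytest.mark.parametrize("use_gn,use_tr", [(True, False), (False, True)])
def test_single_mechanism_ablations_run(use_gn, use_tr, rng):
    cfg = BackboneConfig(**{**TINY, "use_gnconv": use_gn,
                            "use_transformer": use_tr})
    probs = UNTCA(cfg, seed=0)(nn.Tensor(rng.standard_normal((1, 1, 16, 16))))
    assert np.allclose(probs.data.sum(axis=1), 1.0)


def test_fully_ablated_network_matches_plain_unet_oracle(rng):
    cfg = BackboneConfig(**{**TINY, "use_gnconv": False,
                            "use_transformer": False})
    model = UNTCA(cfg, seed=3).eval()
    x = rng.standard_normal((1, 1, 16, 16))
    ours = model(nn.Tensor(x)).data
    ref = plain_unet_oracle(model, x)
    assert np.abs(ours - ref).max() < 1e-5


def test_encoding_strategy_changes_weights_not_contract(rng):
    x = nn.Tensor(rng.standard_normal((1, 1, 16, 16)))
    outs = {}
    for strategy in ("concatenation", "interpolation"):
        cfg = BackboneConfig(**{**TINY, "encoding_strategy": strategy})
        outs[strategy] = UNTCA(cfg, seed=0)(x).data
        assert np.allclose(outs[strategy].sum(axis=1), 1.0)
    assert not np.allclose(outs["concatenation"], outs["interpolation"])
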