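"""Transformer block nested with channel attention.

At each decoder junction of the U-shaped network three token sequences meet:
the down-sampled (encoder) feature ``x_d``, the up-sampled (decoder) feature
``x_u``, and the gnConv-refined feature ``g = gn(x_u)``. Feature maps are
flattened so each spatial position is one token. The block runs

    encoder   x_hat_u = x_u + Attention(x_u, x_d, g)
    decoder   x_hat_c = x_c + Attention(x_c, x_hat_u, x_d)
    FFN       x_tld_c = x_hat_c + max(0, x_hat_c W1 + b1) W2 + b2
    fusion    x_tld_u = alpha * x_u + (1 - alpha) * x_tld_c

where ``x_c`` is the multi-scale bundle transmitted from lower layers and
``Attention(Q, K, V) = softmax(Q K^T / sqrt(d_k)) V``. The attention formula
is single-head as written; a multi-head split is available. Q/K/V receive
learned linear projections to the common token width (an identity-projection
mode exists so tests can compare against the bare formula), normalisation is
pre-norm by default with a no-norm switch, and dropout sits after each
attention and inside the FFN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .gnconv import ConfigurationError
from .nn import Tensor

__all__ = [
    "NestedBlockConfig",
    "attention_weights",
    "scaled_dot_attention",
    "fuse_alpha",
    "NestedBlock",
]


@dataclass
class NestedBlockConfig:
    """Shape and regularisation of one nested block.

    token_width : per-token feature width ``d`` (the ``d_k`` of the attention
        scaling when heads == 1).
    ffn_hidden : inner width of the two-layer FFN (default 2048).
    dropout_rate : dropout probability after attention and inside the FFN
        (default 0.1).
    alpha : fusion weight on the up-sampled feature (default 0.3, the "3" of
        the 3:7 fusion ratio).
    heads : attention head count (default 1, the formula as written).
    norm : apply pre-normalisation around attention/FFN sub-blocks.
    """

    token_width: int
    ffn_hidden: int = 2048
    dropout_rate: float = 0.1
    alpha: float = 0.3
    heads: int = 1
    norm: bool = True

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError(
                f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.token_width % self.heads != 0:
            raise ConfigurationError(
                f"token_width {self.token_width} not divisible by "
                f"heads {self.heads}")


def attention_weights(Q: Tensor, K: Tensor, d_k: int) -> Tensor:
    """``softmax(Q K^T / sqrt(d_k))``; each query row sums to one."""
    if Q.shape[-1] != K.shape[-1]:
        raise ConfigurationError(
            f"query/key widths differ: {Q.shape[-1]} vs {K.shape[-1]}")
    scores = nn.matmul(Q, nn.transpose(K, tuple(range(K.ndim - 2)) + (K.ndim - 1,
                                                K.ndim - 2)))
    return nn.softmax(scores * (1.0 / np.sqrt(d_k)), axis=-1)


def scaled_dot_attention(Q: Tensor, K: Tensor, V: Tensor, d_k: int) -> Tensor:
    """``softmax(Q K^T / sqrt(d_k)) V`` over (batch, token, feature) tensors.

    Every output token is a convex combination of the V tokens; each query's
    attention weights sum to one.
    """
    if K.shape[-2] != V.shape[-2]:
        raise ConfigurationError(
            f"key/value token counts differ: {K.shape[-2]} vs {V.shape[-2]}")
    return nn.matmul(attention_weights(Q, K, d_k), V)


def fuse_alpha(x_u: Tensor, x_c_refined: Tensor, alpha: float) -> Tensor:
    """Convex combination ``alpha * x_u + (1 - alpha) * x_c_refined``."""
    if not 0.0 <= alpha <= 1.0:
        raise ConfigurationError(f"alpha must be in [0, 1], got {alpha}")
    if x_u.shape != x_c_refined.shape:
        raise ConfigurationError(
            f"fusion shapes differ: {x_u.shape} vs {x_c_refined.shape}")
    return nn.add(nn.mul(x_u, alpha), nn.mul(x_c_refined, 1.0 - alpha))


class NestedBlock(nn.Module):
    """One nested attention block operating on token sequences (B, T, d)."""

    def __init__(self, cfg: NestedBlockConfig, rng: np.random.Generator,
                 identity_projections: bool = False):
        super().__init__()
        self.cfg = cfg
        d = cfg.token_width
        self.identity_projections = identity_projections
        if not identity_projections:
            self.enc_q = nn.Linear(d, d, rng)
            self.enc_k = nn.Linear(d, d, rng)
            self.enc_v = nn.Linear(d, d, rng)
            self.dec_q = nn.Linear(d, d, rng)
            self.dec_k = nn.Linear(d, d, rng)
            self.dec_v = nn.Linear(d, d, rng)
        self.ffn1 = nn.Linear(d, cfg.ffn_hidden, rng)
        self.ffn2 = nn.Linear(cfg.ffn_hidden, d, rng)
        if cfg.norm:
            self.norm_u = nn.LayerNorm(d)
            self.norm_d = nn.LayerNorm(d)
            self.norm_g = nn.LayerNorm(d)
            self.norm_c = nn.LayerNorm(d)
            self.norm_f = nn.LayerNorm(d)
        self.drop_enc = nn.Dropout(cfg.dropout_rate, np.random.default_rng(
            rng.integers(2 ** 31)))
        self.drop_dec = nn.Dropout(cfg.dropout_rate, np.random.default_rng(
            rng.integers(2 ** 31)))
        self.drop_ffn = nn.Dropout(cfg.dropout_rate, np.random.default_rng(
            rng.integers(2 ** 31)))

    # -- helpers ----------------------------------------------------------
    def _heads_split(self, x: Tensor) -> Tensor:
        h = self.cfg.heads
        if h == 1:
            return x
        B, T, d = x.shape
        return nn.transpose(nn.reshape(x, (B, T, h, d // h)), (0, 2, 1, 3))

    def _heads_merge(self, x: Tensor) -> Tensor:
        if self.cfg.heads == 1:
            return x
        B, h, T, dh = x.shape
        return nn.reshape(nn.transpose(x, (0, 2, 1, 3)), (B, T, h * dh))

    def _attend(self, q: Tensor, k: Tensor, v: Tensor) -> Tensor:
        d_head = self.cfg.token_width // self.cfg.heads
        out = scaled_dot_attention(self._heads_split(q), self._heads_split(k),
                                   self._heads_split(v), d_head)
        return self._heads_merge(out)

    def _maybe(self, norm_name: str, x: Tensor) -> Tensor:
        return getattr(self, norm_name)(x) if self.cfg.norm else x

    # -- the four operations ----------------------------------------------
    def encode_upsample(self, x_u: Tensor, x_d: Tensor, g: Tensor) -> Tensor:
        """x_hat_u = x_u + Attention(x_u, x_d, gn(x_u))."""
        if g.shape[-2] != x_d.shape[-2]:
            raise ConfigurationError(
                f"gnConv tokens ({g.shape[-2]}) must match down-sampled tokens "
                f"({x_d.shape[-2]})")
        q, k, v = self._maybe("norm_u", x_u), self._maybe("norm_d", x_d), \
            self._maybe("norm_g", g)
        if not self.identity_projections:
            q, k, v = self.enc_q(q), self.enc_k(k), self.enc_v(v)
        return x_u + self.drop_enc(self._attend(q, k, v))

    def decode_multiscale(self, x_c: Tensor, x_hat_u: Tensor,
                          x_d: Tensor) -> Tensor:
        """x_hat_c = x_c + Attention(x_c, x_hat_u, x_d)."""
        if x_hat_u.shape[-2] != x_d.shape[-2]:
            raise ConfigurationError(
                f"key tokens ({x_hat_u.shape[-2]}) must match value tokens "
                f"({x_d.shape[-2]})")
        q = self._maybe("norm_c", x_c)
        k, v = x_hat_u, x_d
        if not self.identity_projections:
            q, k, v = self.dec_q(q), self.dec_k(k), self.dec_v(v)
        return x_c + self.drop_dec(self._attend(q, k, v))

    def ffn_update(self, x_hat_c: Tensor) -> Tensor:
        """x_tld_c = x_hat_c + max(0, x_hat_c W1 + b1) W2 + b2."""
        h = self.ffn1(self._maybe("norm_f", x_hat_c))
        return x_hat_c + self.ffn2(self.drop_ffn(nn.relu(h)))

    def forward(self, x_u: Tensor, x_d: Tensor, g: Tensor,
                x_c: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """Run the whole block; returns (x_hat_u, x_tld_c, x_tld_u)."""
        x_hat_u = self.encode_upsample(x_u, x_d, g)
        x_hat_c = self.decode_multiscale(x_c, x_hat_u, x_d)
        x_tld_c = self.ffn_update(x_hat_c)
        x_tld_u = fuse_alpha(x_u, x_tld_c, self.cfg.alpha)
        return x_hat_u, x_tld_c, x_tld_u
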