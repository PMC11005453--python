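"""U-shaped encoder-decoder with nested transformers and gnConv attention.

The backbone follows the 2-D nnUNet conventions: paired convolution +
instance-norm + leaky-ReLU units, strided-convolution downsampling, 2x2
transposed-convolution upsampling, skip connections, and a per-pixel two-way
softmax head. On top of that sit the two contributed mechanisms:

* every decoder junction refines its up-sampled feature with a gnConv
  (high-order channel attention) and a nested transformer block, and
* a multi-scale bundle ``x_c`` is transmitted bottom-up: junction ``i``
  aggregates ``H(x_d, x_hat_u, x_c, gn(x_u))`` (at the lowest junction the
  phi_in intermediates of gnConv stand in for ``x_hat_u`` and ``x_c``) and
  hands the result to the junction above as its ``x_c``.

``H`` is either token concatenation followed by a learned linear projection
(the default) or fixed-weight combination after resampling to a common grid
("interpolation"). Both mechanisms can be ablated independently with
``use_gnconv`` / ``use_transformer``; with both off the network reduces
exactly to the plain backbone.

Token grids can be capped (``max_token_grid``): features entering a junction
are bilinearly resampled to at most that grid before attention and resampled
back after, which bounds the quadratic token-attention cost at high
resolutions and is how the desk-scale configurations stay tractable on a CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .gnconv import ConfigurationError, GnConv
from .nn import Tensor
from .transformer import NestedBlock, NestedBlockConfig

__all__ = [
    "BackboneConfig",
    "ConvStage",
    "aggregate_h",
    "AggregateH",
    "UNTCA",
    "param_count",
    "reduced_config",
]

LEAKY_SLOPE = 0.01
STRATEGIES = ("concatenation", "interpolation")


@dataclass
class BackboneConfig:
    """Architecture hyperparameters of the full network.

    ``token_widths`` is indexed bottom-up over the ``depth - 1`` decoder
    junctions (entry 0 = bottleneck junction). The published full-scale
    operating point uses 484 for the first three junctions and 256 for the
    fourth, which is the default pattern.
    """

    depth: int = 5
    in_channels: int = 1
    input_size: int = 384
    num_classes: int = 2
    width_schedule: tuple = None
    token_widths: tuple = None
    encoding_strategy: str = "concatenation"
    use_gnconv: bool = True
    use_transformer: bool = True
    gn_order: int = 3
    pad_policy: str = "pad"
    ffn_hidden: int = 2048
    dropout: float = 0.1
    alpha: float = 0.3
    heads: int = 1
    norm: bool = True
    max_token_grid: int = None

    def __post_init__(self):
        if self.depth < 2:
            raise ConfigurationError(f"depth must be >= 2, got {self.depth}")
        if self.encoding_strategy not in STRATEGIES:
            raise ConfigurationError(
                f"encoding_strategy must be one of {STRATEGIES}, "
                f"got {self.encoding_strategy!r}")
        if self.width_schedule is None:
            self.width_schedule = tuple(min(32 * 2 ** l, 512)
                                        for l in range(self.depth))
        else:
            self.width_schedule = tuple(self.width_schedule)
        if len(self.width_schedule) != self.depth:
            raise ConfigurationError(
                f"width_schedule length {len(self.width_schedule)} != depth "
                f"{self.depth}")
        n_junctions = self.depth - 1
        if self.token_widths is None:
            self.token_widths = tuple(
                484 if j < max(n_junctions - 1, 1) else 256
                for j in range(n_junctions))
        else:
            self.token_widths = tuple(self.token_widths)
        if len(self.token_widths) != n_junctions:
            raise ConfigurationError(
                f"token_widths needs {n_junctions} entries, got "
                f"{len(self.token_widths)}")
        if self.input_size % 2 ** (self.depth - 1) != 0:
            raise ConfigurationError(
                f"input_size {self.input_size} must be divisible by "
                f"2^(depth-1) = {2 ** (self.depth - 1)}")

    def junction_grid(self, j: int) -> int:
        """Token grid side of junction ``j`` (0 = bottleneck junction)."""
        level = self.depth - 2 - j
        full = self.input_size // 2 ** level
        if self.max_token_grid is not None:
            return min(full, self.max_token_grid)
        return full


def reduced_config(**overrides) -> BackboneConfig:
    """Desk-scale configuration: depth 3, base width 8, token width 64.

    Small enough to train on one CPU within minutes while exercising every
    mechanism of the full network; the token grid is capped at 16 so the
    spatial-token attention stays cheap.
    """
    kwargs = dict(depth=3, input_size=64, width_schedule=(8, 16, 32),
                  token_widths=(64, 64), ffn_hidden=128, max_token_grid=16,
                  dropout=0.1)
    kwargs.update(overrides)
    return BackboneConfig(**kwargs)


# ---------------------------------------------------------------------------
# Convolution stages
# ---------------------------------------------------------------------------

class ConvStage(nn.Module):
    """Two convolution + instance-norm + leaky-ReLU units.

    ``direction="down"`` halves the spatial size with a strided convolution,
    ``"up"`` doubles it with a transposed convolution, ``"same"`` keeps it.
    """

    def __init__(self, c_in: int, width: int, direction: str,
                 rng: np.random.Generator):
        super().__init__()
        if direction not in ("down", "up", "same"):
            raise ConfigurationError(f"unknown direction {direction!r}")
        self.direction = direction
        if direction == "down":
            self.op1 = nn.Conv2d(c_in, width, 3, rng, stride=2, padding=1)
        elif direction == "up":
            self.op1 = nn.ConvTranspose2x2(c_in, width, rng)
        else:
            self.op1 = nn.Conv2d(c_in, width, 3, rng, padding=1)
        self.norm1 = nn.InstanceNorm2d(width)
        self.conv2 = nn.Conv2d(width, width, 3, rng, padding=1)
        self.norm2 = nn.InstanceNorm2d(width)

    def forward(self, x: Tensor) -> Tensor:
        H, W = x.shape[2:]
        if self.direction == "down" and (H % 2 or W % 2):
            raise ConfigurationError(
                f"cannot downsample odd spatial size {(H, W)}")
        y = nn.leaky_relu(self.norm1(self.op1(x)), LEAKY_SLOPE)
        return nn.leaky_relu(self.norm2(self.conv2(y)), LEAKY_SLOPE)


class UpUnit(nn.Module):
    """Single transposed-convolution unit producing the up-sampled feature."""

    def __init__(self, c_in: int, width: int, rng: np.random.Generator):
        super().__init__()
        self.up = nn.ConvTranspose2x2(c_in, width, rng)
        self.norm = nn.InstanceNorm2d(width)

    def forward(self, x: Tensor) -> Tensor:
        return nn.leaky_relu(self.norm(self.up(x)), LEAKY_SLOPE)


# ---------------------------------------------------------------------------
# Multi-scale aggregation H
# ---------------------------------------------------------------------------

def _to_tokens(x_map: Tensor) -> Tensor:
    B, D, H, W = x_map.shape
    return nn.transpose(nn.reshape(x_map, (B, D, H * W)), (0, 2, 1))


def _to_map(tokens: Tensor, grid: tuple) -> Tensor:
    B, T, D = tokens.shape
    h, w = grid
    return nn.reshape(nn.transpose(tokens, (0, 2, 1)), (B, D, h, w))


def aggregate_h(parts, strategy: str, target_grid=None, projection=None):
    """Combine feature maps into one token sequence (the operator ``H``).

    ``parts`` are feature maps (B, D_i, h_i, w_i); each is bilinearly
    resampled to ``target_grid`` (default: the grid of the first part) and
    flattened to tokens. ``"concatenation"`` stacks the parts along the
    feature axis; ``"interpolation"`` combines them with equal fixed weights
    (requiring equal widths when no projection supplies a common width).
    ``projection`` (a callable on tokens) maps the combined width to the
    caller's target; ``None`` leaves the combination untouched.

    Returns ``(tokens, pre_projection_width)``.
    """
    parts = list(parts)
    if not parts:
        raise ConfigurationError("aggregate_h needs at least one part")
    if strategy not in STRATEGIES:
        raise ConfigurationError(f"unknown strategy {strategy!r}")
    if target_grid is None:
        target_grid = parts[0].shape[2:]
    aligned = [_to_tokens(nn.bilinear_resize(p, target_grid)) for p in parts]
    if strategy == "concatenation":
        combined = nn.concat(aligned, axis=2)
        pre_width = combined.shape[2]
    else:
        widths = {t.shape[2] for t in aligned}
        if len(widths) > 1:
            raise ConfigurationError(
                f"interpolation combine needs equal widths, got {sorted(widths)}")
        combined = aligned[0] * (1.0 / len(aligned))
        for t in aligned[1:]:
            combined = combined + t * (1.0 / len(aligned))
        pre_width = combined.shape[2]
    if projection is not None:
        combined = projection(combined)
    return combined, pre_width


class AggregateH(nn.Module):
    """Learned-projection wrapper around :func:`aggregate_h`.

    For concatenation, one linear map from the stacked width to the target;
    for interpolation, a per-part linear map to the target width followed by
    the equal-weight combination (parts generally have unequal widths, so the
    fixed-weight sum is taken after the per-part width alignment).
    """

    def __init__(self, in_widths, target_width: int, strategy: str,
                 rng: np.random.Generator):
        super().__init__()
        if strategy not in STRATEGIES:
            raise ConfigurationError(f"unknown strategy {strategy!r}")
        self.strategy = strategy
        self.in_widths = tuple(in_widths)
        self.pre_width = (sum(in_widths) if strategy == "concatenation"
                          else target_width)
        if strategy == "concatenation":
            self.proj = nn.Linear(sum(in_widths), target_width, rng)
        else:
            self.part_proj = nn.ModuleList(
                [nn.Linear(w, target_width, rng) for w in in_widths])

    def forward(self, parts, target_grid) -> Tensor:
        widths = tuple(p.shape[1] for p in parts)
        if widths != self.in_widths:
            raise ConfigurationError(
                f"aggregate built for widths {self.in_widths}, got {widths}")
        if self.strategy == "concatenation":
            tokens, _ = aggregate_h(parts, "concatenation", target_grid,
                                    projection=self.proj)
            return tokens
        aligned = [_to_tokens(nn.bilinear_resize(p, target_grid))
                   for p in parts]
        out = None
        for lin, t in zip(self.part_proj, aligned):
            term = lin(t) * (1.0 / len(aligned))
            out = term if out is None else out + term
        return out


# ---------------------------------------------------------------------------
# One decoder junction
# ---------------------------------------------------------------------------

class Junction(nn.Module):
    """gnConv + nested transformer machinery at one decoder junction."""

    def __init__(self, cfg: BackboneConfig, j: int, rng: np.random.Generator):
        super().__init__()
        self.j = j
        level = cfg.depth - 2 - j
        self.level = level
        self.grid = cfg.junction_grid(j)
        width = cfg.width_schedule[level]
        d = cfg.token_widths[j]
        self.width, self.d = width, d
        if cfg.use_gnconv:
            self.gn = GnConv(width, self.grid, self.grid, cfg.gn_order, rng,
                             cfg.pad_policy)
        if cfg.use_transformer:
            self.proj_u = nn.Linear(width, d, rng)
            self.proj_d = nn.Linear(width, d, rng)
            self.proj_g = nn.Linear(width, d, rng)
            self.block = NestedBlock(
                NestedBlockConfig(token_width=d, ffn_hidden=cfg.ffn_hidden,
                                  dropout_rate=cfg.dropout, alpha=cfg.alpha,
                                  heads=cfg.heads, norm=cfg.norm), rng)
            self.out_proj = nn.Linear(d, width, rng)
            # Every junction aggregates a 4-part bundle; all but the topmost
            # hand it to the junction above as its x_c. The topmost bundle has
            # no consumer, so it is aggregated without learned weights.
            if j < cfg.depth - 2:
                if j == 0 and cfg.use_gnconv:
                    sched = self.gn.cfg.channel_schedule
                    part_widths = (d, sched[0], sum(sched), d)
                else:
                    part_widths = (d, d, d, d)
                self.agg = AggregateH(part_widths, cfg.token_widths[j + 1],
                                      cfg.encoding_strategy, rng)


# ---------------------------------------------------------------------------
# The full network
# ---------------------------------------------------------------------------

class UNTCA(nn.Module):
    """Full segmentation network; forward maps images to per-pixel
    foreground/background probabilities."""

    def __init__(self, cfg: BackboneConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        w = cfg.width_schedule
        self.enc = nn.ModuleList()
        self.enc.append(ConvStage(cfg.in_channels, w[0], "same", rng))
        for l in range(1, cfg.depth):
            self.enc.append(ConvStage(w[l - 1], w[l], "down", rng))
        self.ups = nn.ModuleList(
            [UpUnit(w[l + 1], w[l], rng) for l in range(cfg.depth - 1)])
        self.dec = nn.ModuleList(
            [ConvStage(2 * w[l], w[l], "same", rng) for l in range(cfg.depth - 1)])
        self.junctions = nn.ModuleList(
            [Junction(cfg, j, rng) for j in range(cfg.depth - 1)])
        self.head = nn.Conv2d(w[0], cfg.num_classes, 1, rng)

    # -- helpers ----------------------------------------------------------
    def _validate_input(self, x: Tensor) -> None:
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ConfigurationError(
                f"expected (B, {self.cfg.in_channels}, H, W) input, got "
                f"shape {x.shape}")
        H, W = x.shape[2:]
        div = 2 ** (self.cfg.depth - 1)
        if H % div or W % div:
            raise ConfigurationError(
                f"spatial size {(H, W)} not divisible by {div}; the minimal "
                f"valid size is {div} x {div}")
        if self.cfg.max_token_grid is None and (H, W) != (
                self.cfg.input_size, self.cfg.input_size):
            raise ConfigurationError(
                f"model built for {self.cfg.input_size}^2 inputs, got {(H, W)}")

    def recursive_transmit(self, enc_feats: list) -> tuple[Tensor, dict]:
        """Bottom-up decoder pass with recursive multi-scale transmission.

        ``enc_feats`` are the encoder features, index 0 = full resolution.
        Returns the full-resolution decoder feature and a record of the
        per-junction refined features and transmitted bundles.
        """
        cfg = self.cfg
        if len(enc_feats) != cfg.depth:
            raise ConfigurationError(
                f"need {cfg.depth} encoder levels, got {len(enc_feats)}")
        details = {"bundles": [], "refined": []}
        y = enc_feats[-1]
        x_c = None
        for j in range(cfg.depth - 1):
            jct: Junction = self.junctions[j]
            level = jct.level
            skip = enc_feats[level]
            x_u = self.ups[level](y)
            full_grid = x_u.shape[2:]
            cap = (jct.grid, jct.grid)
            xu_c = nn.bilinear_resize(x_u, cap)
            xd_c = nn.bilinear_resize(skip, cap)
            inter = None
            if cfg.use_gnconv:
                g_map, inter = jct.gn.forward_with_intermediates(xu_c)
            else:
                g_map = xu_c
            if cfg.use_transformer:
                xu_t = jct.proj_u(_to_tokens(xu_c))
                xd_t = jct.proj_d(_to_tokens(xd_c))
                g_t = jct.proj_g(_to_tokens(g_map))
                if x_c is None:
                    # lowest junction: no bundle exists yet; the carrier is
                    # initialised from the down-sampled feature's tokens.
                    x_c = xd_t
                x_hat_u, x_tld_c, x_tld_u = jct.block(xu_t, xd_t, g_t, x_c)
                details["refined"].append(x_tld_u)
                refined_map = _to_map(jct.out_proj(x_tld_u), cap)
                merged_in = nn.bilinear_resize(refined_map, full_grid)
                if j == 0 and cfg.use_gnconv:
                    parts = [_to_map(xd_t, cap), inter["p0"], inter["q"],
                             _to_map(g_t, cap)]
                else:
                    parts = [_to_map(xd_t, cap), _to_map(x_hat_u, cap),
                             _to_map(x_c, cap), _to_map(g_t, cap)]
                if j < cfg.depth - 2:
                    nxt = self.junctions[j + 1].grid
                    x_c = jct.agg(parts, (nxt, nxt))
                else:
                    # unused output; stacked without learned weights
                    x_c, _ = aggregate_h(parts, "concatenation", cap)
                details["bundles"].append(parts)
            elif cfg.use_gnconv:
                merged_in = x_u + nn.bilinear_resize(g_map, full_grid)
            else:
                merged_in = x_u
            y = self.dec[level](nn.concat([merged_in, skip], axis=1))
        return y, details

    def forward(self, x: Tensor) -> Tensor:
        probs, _ = self.forward_details(x)
        return probs

    def forward_details(self, x: Tensor) -> tuple[Tensor, dict]:
        self._validate_input(x)
        enc_feats = []
        y = x
        for stage in self.enc:
            y = stage(y)
            enc_feats.append(y)
        y, details = self.recursive_transmit(enc_feats)
        logits = self.head(y)
        return nn.softmax(logits, axis=1), details

    def logits(self, x: Tensor) -> Tensor:
        """Unnormalised head output (used by the training loss)."""
        self._validate_input(x)
        enc_feats = []
        y = x
        for stage in self.enc:
            y = stage(y)
            enc_feats.append(y)
        y, _ = self.recursive_transmit(enc_feats)
        return self.head(y)


def param_count(model: nn.Module) -> int:
    return sum(p.data.size for p in model.parameters())
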