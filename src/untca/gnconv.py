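"""Recursive gated convolution (gnConv) with a channel-as-spatial reshape.

gnConv raises pixel interaction from second order to order ``n`` by repeated
elementwise gating of progressively wider feature groups: an input of width
``C`` is expanded to ``2C`` by a pointwise projection (phi_in), split into a
carrier ``p0`` and gate groups ``q_0..q_{n-1}`` whose widths follow the
doubling schedule ``C_k = C / 2^(n-k-1)``, and then gated ``n`` times,

    p_{k+1} = f_k(q_k) * g_k(p_k),

where ``f_k`` is a shared depthwise convolution over the gate groups and the
``g_k`` are pointwise width-raising maps. A final pointwise projection
(phi_out) returns to width ``C``.

Before the operator runs, the feature map is reinterpreted so that channels
become the spatial grid: a map with ``C0`` channels over an ``H0 x W0`` frame
is laid out on a ``sqrt(C0) x sqrt(C0)`` grid with ``H0*W0`` channels. This
lets the gating mix *channels* of the original map as if they were
neighbouring pixels, which is what makes the operator act as channel
attention. Non-square channel counts are zero-padded up to the next perfect
square (``pad_policy="pad"``, the default) or rejected (``"strict"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "ConfigurationError",
    "GnConvConfig",
    "channel_schedule",
    "channel_grid_reshape",
    "channel_grid_inverse",
    "GnConv",
    "preset_channel_rule",
    "preset_token_width",
    "PRESET_GRID_SIDE",
]


class ConfigurationError(ValueError):
    """Raised when a configuration cannot describe a valid operator."""


# Printed operating points for the published full-scale model: a 22 x 22
# reshape grid (484 reshaped channels) and the alternative per-level channel
# rule 9 * 2^(2i). They describe different tensors; both are exposed and the
# package does not guess which applies where.
PRESET_GRID_SIDE = 22


def preset_channel_rule(i: int) -> int:
    """Per-level channel count preset ``9 * 2^(2i)`` for levels i = 1..4."""
    if i < 1:
        raise ConfigurationError(f"level index must be >= 1, got {i}")
    return 9 * 2 ** (2 * i)


def preset_token_width(grid_side: int = PRESET_GRID_SIDE) -> int:
    """Token width implied by a reshape grid: grid_side**2 (22 -> 484)."""
    return grid_side * grid_side


def channel_schedule(C: int, n: int) -> list[int]:
    """Widths ``[C / 2^(n-1), ..., C/2, C]`` of the n gate groups.

    Strictly doubling; the last entry equals ``C``.  ``C`` must be divisible
    by ``2^(n-1)`` for every width to be an integer.
    """
    if n < 1:
        raise ConfigurationError(f"interaction order n must be >= 1, got n={n}")
    if C < 1 or C % (2 ** (n - 1)) != 0:
        raise ConfigurationError(
            f"base width C={C} is not divisible by 2^(n-1)={2 ** (n - 1)} "
            f"for interaction order n={n}")
    return [C // (2 ** (n - k - 1)) for k in range(n)]


@dataclass
class GnConvConfig:
    """Geometry of one gnConv operator.

    Parameters
    ----------
    n : interaction order (number of gating steps).
    base_channels : width ``C`` at the operator's input, i.e. ``H0*W0`` of the
        frame being reshaped.
    source_channels : channel count ``C0`` of the map before the reshape.
    pad_policy : ``"pad"`` zero-pads ``C0`` up to the next perfect square;
        ``"strict"`` requires a perfect square.
    """

    n: int
    base_channels: int
    source_channels: int
    pad_policy: str = "pad"
    channel_schedule: list[int] = field(init=False)
    grid_side: int = field(init=False)

    def __post_init__(self):
        if self.pad_policy not in ("pad", "strict"):
            raise ConfigurationError(f"unknown pad_policy {self.pad_policy!r}")
        self.channel_schedule = channel_schedule(self.base_channels, self.n)
        side = math.isqrt(self.source_channels)
        if side * side != self.source_channels:
            if self.pad_policy == "strict":
                raise ConfigurationError(
                    f"source channel count {self.source_channels} is not a "
                    f"perfect square and pad_policy is 'strict'")
            side += 1
        self.grid_side = side
        # phi_in doubles the width: C0 + sum(C_k) = 2C.
        assert self.channel_schedule[0] + sum(self.channel_schedule) == \
            2 * self.base_channels


# ---------------------------------------------------------------------------
# Channel-as-spatial reshape
# ---------------------------------------------------------------------------

def channel_grid_reshape(x: Tensor, pad_policy: str = "pad") -> tuple[Tensor, tuple]:
    """Lay the channels of ``(B, C0, H0, W0)`` on a square grid.

    Returns the reshaped tensor ``(B, H0*W0, s, s)`` with ``s = ceil(sqrt(C0))``
    and the original ``(C0, H0, W0)`` needed by the exact inverse.  The map is
    a bijection on indices: ``out[b, i*W0 + j, u, v] = x[b, u*s + v, i, j]``.
    """
    B, C0, H0, W0 = x.shape
    side = math.isqrt(C0)
    if side * side != C0:
        if pad_policy == "strict":
            raise ConfigurationError(
                f"channel count {C0} is not a perfect square (pad_policy='strict')")
        side += 1
        pad = Tensor(np.zeros((B, side * side - C0, H0, W0)))
        x = nn.concat([x, pad], axis=1)
    y = nn.transpose(x, (0, 2, 3, 1))
    y = nn.reshape(y, (B, H0 * W0, side, side))
    return y, (C0, H0, W0)


def channel_grid_inverse(y: Tensor, original: tuple) -> Tensor:
    """Exact inverse of :func:`channel_grid_reshape` on the unpadded channels."""
    C0, H0, W0 = original
    B = y.shape[0]
    side = y.shape[2]
    x = nn.reshape(y, (B, H0, W0, side * side))
    x = nn.transpose(x, (0, 3, 1, 2))
    return nn.narrow(x, 1, 0, C0)


def _pointwise(x: Tensor, lin: nn.Linear) -> Tensor:
    """Apply a learned linear map across the channel axis of (B, C, H, W)."""
    B, C, H, W = x.shape
    t = nn.transpose(nn.reshape(x, (B, C, H * W)), (0, 2, 1))
    t = lin(t)
    return nn.reshape(nn.transpose(t, (0, 2, 1)), (B, -1, H, W))


# ---------------------------------------------------------------------------
# The operator
# ---------------------------------------------------------------------------

class GnConv(nn.Module):
    """n-th order gated channel attention over a reshaped feature map.

    Construction fixes the source geometry ``(C0, H0, W0)``; the forward pass
    accepts any batch of that geometry and returns a map of identical shape.
    ``last_gate_count`` records the number of elementwise gates performed by
    the most recent forward pass (always equal to ``n``).
    """

    DW_KERNEL = 7

    def __init__(self, source_channels: int, h0: int, w0: int, n: int,
                 rng: np.random.Generator, pad_policy: str = "pad"):
        super().__init__()
        self.cfg = GnConvConfig(n=n, base_channels=h0 * w0,
                                source_channels=source_channels,
                                pad_policy=pad_policy)
        self.h0, self.w0 = h0, w0
        C = self.cfg.base_channels
        sched = self.cfg.channel_schedule
        self.phi_in = nn.Linear(C, 2 * C, rng)
        self.phi_out = nn.Linear(C, C, rng)
        k = self.DW_KERNEL
        q_total = sum(sched)
        self.dw = nn.Conv2d(q_total, q_total, k, rng, padding=k // 2,
                            groups=q_total, init="trunc_normal")
        # Width-raising carrier maps g_k: C_{k-1} -> C_k (first step identity).
        self.g = nn.ModuleList([nn.Linear(sched[k - 1], sched[k], rng)
                                for k in range(1, n)])
        self.last_gate_count = 0

    # -- pieces exposed for composition tests and the lowest-level bundle ---
    def project_in(self, x_grid: Tensor) -> tuple[Tensor, list[Tensor]]:
        """phi_in: expand to 2C channels and split into (p0, [q_0..q_{n-1}])."""
        C = self.cfg.base_channels
        if x_grid.shape[1] != C:
            raise ConfigurationError(
                f"phi_in expects {C} channels, got {x_grid.shape[1]}")
        expanded = _pointwise(x_grid, self.phi_in)
        sched = self.cfg.channel_schedule
        parts = nn.split(expanded, [sched[0]] + sched, axis=1)
        return parts[0], parts[1:]

    def gate(self, p0: Tensor, q: list[Tensor]) -> Tensor:
        """Run the n gating steps and the phi_out projection."""
        sched = self.cfg.channel_schedule
        if p0.shape[1] != sched[0] or [t.shape[1] for t in q] != sched:
            raise ConfigurationError(
                f"gate widths {[p0.shape[1]] + [t.shape[1] for t in q]} do not "
                f"match schedule p0={sched[0]}, q={sched}")
        f = nn.split(self.dw(nn.concat(q, axis=1)), sched, axis=1)
        self.last_gate_count = 0
        p = nn.mul(f[0], p0) * (1.0 / math.sqrt(sched[0]))
        self.last_gate_count += 1
        for k in range(1, self.cfg.n):
            p = nn.mul(f[k], _pointwise(p, self.g[k - 1])) \
                * (1.0 / math.sqrt(sched[k]))
            self.last_gate_count += 1
        return _pointwise(p, self.phi_out)

    def forward(self, x: Tensor) -> Tensor:
        out, _ = self.forward_with_intermediates(x)
        return out

    def forward_with_intermediates(self, x: Tensor) -> tuple[Tensor, dict]:
        """Forward pass also returning the named phi_in intermediates.

        The intermediates (carrier ``p0`` and the concatenated gate groups)
        are what the lowest decoder junction transmits upward in place of the
        refined features that do not exist yet at that depth.
        """
        B, C0, H0, W0 = x.shape
        if C0 != self.cfg.source_channels or (H0, W0) != (self.h0, self.w0):
            raise ConfigurationError(
                f"gnconv built for {(self.cfg.source_channels, self.h0, self.w0)}"
                f", got input {(C0, H0, W0)}")
        grid, original = channel_grid_reshape(x, self.cfg.pad_policy)
        p0, q = self.project_in(grid)
        gated = self.gate(p0, q)
        out = channel_grid_inverse(gated, original)
        return out, {"p0": p0, "q": nn.concat(q, axis=1)}
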