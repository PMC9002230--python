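"""Per-axis MLP token mixing with a learnable gate, and the MLP-Mixer baseline.

The triple-MLP (TM) core applies, in order, a channel-mixing, a height-mixing
and a width-mixing step to a (N,C,H,W) feature map.  Each step is

    y = g * FC_axis(LN(x)) + x

where LN normalises over the channel axis at every spatial site, FC_axis is a
single full connection along one axis (weight side equals that axis's extent,
applied independently at every position of the remaining axes) and ``g`` is a
learnable scalar gate.  With the gate at zero a step is exactly the identity,
so a model whose training data are too scarce to learn positional structure
can switch the positional encoding off.

The MLP-Mixer block (channel-mix then spatial-mix over the flattened H*W token
axis, two stacked FCs with a GELU between) is provided purely as the
complexity baseline, together with exact multiply-accumulate accountants for
both designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn

AXIS_INDEX = {"channel": 1, "high": 2, "wide": 3}


def _mix_axis(x, weight, bias, axis: int):
    """Apply a full connection along one axis of a 4-axis map.

    Works on autodiff Tensors and plain ndarrays alike (both expose
    ``transpose``/``reshape``/``@``-style ops through the same names).
    """
    order = [0, 1, 2, 3]
    order.remove(axis)
    order.append(axis)
    side = x.shape[axis]
    perm = x.transpose(tuple(order))
    kept = perm.shape[:-1]
    flat = perm.reshape((-1, side))
    mixed = (flat @ weight + bias).reshape(tuple(kept) + (side,))
    inv = tuple(int(i) for i in np.argsort(order))
    return mixed.transpose(inv)


class AxisMLP(nn.Module):
    """One pre-normalised full connection along ``axis`` with a gated residual."""

    def __init__(self, channels: int, side: int, axis: str, *, rng: np.random.Generator):
        super().__init__()
        if axis not in AXIS_INDEX:
            raise ValueError(f"unknown axis {axis!r}")
        self.axis = axis
        self.side = side
        self.norm = nn.ChannelLayerNorm(channels)
        self.weight = nn.Parameter(nn.xavier_fc(rng, side, side))
        self.bias = nn.Parameter(np.zeros(side))

    def forward(self, x, gate=1.0):
        return axis_step(x, self, gate)


def axis_step(x, params: AxisMLP, gate):
    """gate * FC_axis(LN(x)) + x, shape preserving."""
    axis = AXIS_INDEX[params.axis]
    if x.shape[axis] != params.side:
        raise ValueError(
            f"axis {params.axis!r}: weight side {params.side} does not match "
            f"input extent {x.shape[axis]}")
    mixed = _mix_axis(params.norm(x), params.weight, params.bias, axis)
    return gate * mixed + x


class GateVector(nn.Module):
    """Three learnable scalars (g_c, g_h, g_w) initialised at 1.

    When ``learnable`` is false the gates are frozen constants (the ablation
    without the gate-controlled mechanism).
    """

    def __init__(self, learnable: bool = True, init: float = 1.0):
        super().__init__()
        self.learnable = learnable
        if learnable:
            self.values = nn.Parameter(np.full(3, init))
        else:
            self.values = ad.Tensor(np.full(3, init))

    @property
    def g_c(self):
        return self.values[0]

    @property
    def g_h(self):
        return self.values[1]

    @property
    def g_w(self):
        return self.values[2]

    def numpy(self) -> np.ndarray:
        return np.asarray(self.values.data, dtype=float).copy()


class TripleMLP(nn.Module):
    """The TM core: channel -> high -> wide gated mixing steps."""

    def __init__(self, channels: int, height: int, width: int, *,
                 gated: bool = True, rng: np.random.Generator):
        super().__init__()
        self.channel_mlp = AxisMLP(channels, channels, "channel", rng=rng)
        self.high_mlp = AxisMLP(channels, height, "high", rng=rng)
        self.wide_mlp = AxisMLP(channels, width, "wide", rng=rng)
        self.gates = GateVector(learnable=gated)

    def forward(self, x):
        return tgmlp_core(x, self.channel_mlp, self.high_mlp, self.wide_mlp, self.gates)


def tgmlp_core(x, p_c: AxisMLP, p_h: AxisMLP, p_w: AxisMLP, gates: GateVector):
    """Compose the three gated axis steps in channel, high, wide order."""
    x = axis_step(x, p_c, gates.g_c)
    x = axis_step(x, p_h, gates.g_h)
    x = axis_step(x, p_w, gates.g_w)
    return x


class MixerBlock(nn.Module):
    """MLP-Mixer baseline: channel mix, then a two-FC spatial mix over H*W tokens."""

    def __init__(self, channels: int, height: int, width: int, hidden: int | None = None,
                 *, rng: np.random.Generator):
        super().__init__()
        tokens = height * width
        hidden = tokens if hidden is None else hidden
        self.height, self.width = height, width
        self.channel_mlp = AxisMLP(channels, channels, "channel", rng=rng)
        self.spatial_norm = nn.ChannelLayerNorm(channels)
        self.fc1 = nn.Parameter(nn.xavier_fc(rng, tokens, hidden))
        self.b1 = nn.Parameter(np.zeros(hidden))
        self.fc2 = nn.Parameter(nn.xavier_fc(rng, hidden, tokens))
        self.b2 = nn.Parameter(np.zeros(tokens))

    def forward(self, x):
        x = axis_step(x, self.channel_mlp, 1.0)
        n, c, h, w = x.shape
        y = self.spatial_norm(x).reshape((n, c, h * w)).reshape((n * c, h * w))
        y = ad.gelu(y @ self.fc1 + self.b1)
        y = y @ self.fc2 + self.b2
        return y.reshape((n, c, h, w)) + x


def mixer_block(x, params: MixerBlock):
    return params(x)


# ---------------------------------------------------------------------------
# multiply-accumulate accountants
# ---------------------------------------------------------------------------
# Conventions: one MAC per scalar multiply in a full connection; biases,
# normalisation, activations and residual adds are excluded.

@dataclass(frozen=True)
class AxisMacs:
    channel: int
    high: int
    wide: int

    @property
    def total(self) -> int:
        return self.channel + self.high + self.wide


def axis_macs(H: int, W: int, C: int) -> AxisMacs:
    """MACs of the three single-FC mixing steps on a (C,H,W) map."""
    if min(H, W, C) < 1:
        raise ValueError("extents must be >= 1")
    return AxisMacs(channel=H * W * C * C, high=C * W * H * H, wide=C * H * W * W)


@dataclass(frozen=True)
class MixerMacs:
    channel: int
    spatial: int

    @property
    def total(self) -> int:
        return self.channel + self.spatial


def mixer_macs(H: int, W: int, C: int, hidden: int | None = None) -> MixerMacs:
    """MACs of an MLP-Mixer block; ``hidden`` defaults to the token count H*W."""
    if min(H, W, C) < 1:
        raise ValueError("extents must be >= 1")
    tokens = H * W
    hidden = tokens if hidden is None else hidden
    return MixerMacs(channel=H * W * C * C, spatial=2 * C * hidden * tokens)
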