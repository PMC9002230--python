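"""Global Perceptron, Local Priors and the full TGMLP block.

The Global Perceptron (GP) splits a (N,C,H,W) map into an h x h grid of
spatial partitions, averages across the grid, and pushes the pooled vector
through BN and a two-layer MLP to produce one learned offset per
(within-partition position, channel).  The offset is broadcast back onto every
partition — a sparse full connection whose parameters are shared by all
partitions — and the block input is added back.

The Local Priors (LP) path runs four parallel same-resolution convolutions
(kernel sizes 1/3/5/7, paddings 0/1/2/3, each followed by BN) over the GP
output and sums them, re-injecting multi-scale local structure that pure MLP
mixing ignores.  The full block combines both with the triple-MLP core:

    s   = TripleMLP(x)                      (gated axis mixing)
    m   = GP(x)                             (partition-shared global offset)
    out = sum_i Conv_i(m) + s               (multi-scale local priors)

With every learnable tensor at zero and the gates at zero the block is the
identity map, which is the safe starting point the gate mechanism relies on.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import nn
from .tmlp import TripleMLP

LP_KERNELS = (1, 3, 5, 7)
LP_PADDINGS = (0, 1, 2, 3)


# ---------------------------------------------------------------------------
# partition re-layout
# ---------------------------------------------------------------------------

def partition(x, h: int):
    """Re-lay a (N,C,H,W) map as (N, W/h, H/h, C, h, h).

    Axes 1-2 are the within-partition (column, row) coordinates; the trailing
    two axes index the h x h grid of partitions (grid row, grid column). A
    pure permutation of elements; works on ndarrays and autodiff Tensors.
    """
    n, c, H, W = x.shape
    if H % h or W % h:
        raise ValueError(f"partition: extents H={H}, W={W} not divisible by h={h}")
    ph, pw = H // h, W // h
    # (N,C,H,W) -> (N,C,gy,ph,gx,pw) -> (N,pw,ph,C,gy,gx)
    return x.reshape((n, c, h, ph, h, pw)).transpose((0, 5, 3, 1, 2, 4))


def unpartition(pt):
    """Exact inverse of :func:`partition`, returning (N,C,H,W)."""
    n, pw, ph, c, h, h2 = pt.shape
    if h != h2:
        raise ValueError("partition grid must be square")
    # (N,pw,ph,C,gy,gx) -> (N,C,gy,ph,gx,pw)
    return pt.transpose((0, 3, 4, 2, 5, 1)).reshape((n, c, h * ph, h * pw))


# ---------------------------------------------------------------------------
# global perceptron
# ---------------------------------------------------------------------------

class GlobalPerceptron(nn.Module):
    """BN + two-layer MLP over the grid-pooled partition vector.

    ``length`` = (W/h)*(H/h)*C is both the input and output width of the MLP;
    the hidden width equals ``length`` with a ReLU between the two layers.
    """

    def __init__(self, channels: int, part_h: int, part_w: int, *,
                 rng: np.random.Generator, bn_eps: float = 1e-6, bn_momentum: float = 0.1):
        super().__init__()
        self.length = part_h * part_w * channels
        self.bn = nn.BatchNorm1d(self.length, eps=bn_eps, momentum=bn_momentum)
        self.fc1 = nn.Linear(self.length, self.length, rng=rng)
        self.fc2 = nn.Linear(self.length, self.length, rng=rng)

    def forward(self, pt):
        return gp_weights(pt, self)


def gp_weights(pt, params: GlobalPerceptron):
    """Pool over the partition grid and produce the (N, length) weight matrix."""
    n, pw, ph, c = pt.shape[:4]
    if pw * ph * c != params.length:
        raise ValueError(
            f"global perceptron expects pooled length {params.length}, "
            f"got {pw * ph * c}")
    pooled = pt.mean(axis=(4, 5)) if isinstance(pt, np.ndarray) else pt.mean((4, 5))
    flat = pooled.reshape((n, params.length))
    hidden = ad.relu(params.fc1(params.bn(flat)))
    return params.fc2(hidden)


def gp_apply(pt, v, x_in):
    """Broadcast the weight matrix onto every partition and add the block input.

    ``v`` has shape (N, (W/h)*(H/h)*C); it is reshaped to
    (N, W/h, H/h, C, 1, 1), added to ``pt`` across the grid axes, the result
    un-partitioned and ``x_in`` added.
    """
    n, pw, ph, c, h, _ = pt.shape
    if int(np.prod(v.shape[1:])) != pw * ph * c:
        raise ValueError("weight vector length does not match partition layout")
    offset = v.reshape((n, pw, ph, c, 1, 1))
    return unpartition(pt + offset) + x_in


# ---------------------------------------------------------------------------
# local priors
# ---------------------------------------------------------------------------

class LocalPriors(nn.Module):
    """Four parallel conv+BN branches (k = 1,3,5,7) preserving resolution."""

    def __init__(self, channels: int, *, rng: np.random.Generator,
                 bn_eps: float = 1e-6, bn_momentum: float = 0.1):
        super().__init__()
        self.convs = nn.ModuleList(
            nn.Conv2d(channels, channels, k, padding=p, rng=rng)
            for k, p in zip(LP_KERNELS, LP_PADDINGS))
        self.bns = nn.ModuleList(
            nn.BatchNorm2d(channels, eps=bn_eps, momentum=bn_momentum)
            for _ in LP_KERNELS)

    def forward(self, m, s):
        return local_priors(m, self, s)


def local_priors(m, params: LocalPriors, s):
    """Sum the four conv->BN branches of ``m`` and add the TM output ``s``."""
    if m.shape != s.shape:
        raise ValueError(f"local priors: shape mismatch {m.shape} vs {s.shape}")
    out = s
    for conv, bn in zip(params.convs, params.bns):
        out = out + bn(conv(m))
    return out


# ---------------------------------------------------------------------------
# the full block
# ---------------------------------------------------------------------------

class TGMLPBlock(nn.Module):
    """Triple-MLP core + Global Perceptron + Local Priors (shape preserving).

    ``use_tm`` / ``use_lgp`` / ``use_gate`` are the ablation switches: without
    TM the core is the identity; without LGP the partition/conv paths are
    dropped; without the gate mechanism the gates are frozen at 1.
    """

    def __init__(self, channels: int, height: int, width: int, h: int = 2, *,
                 use_tm: bool = True, use_lgp: bool = True, use_gate: bool = True,
                 rng: np.random.Generator, bn_eps: float = 1e-6, bn_momentum: float = 0.1):
        super().__init__()
        if use_lgp and (height % h or width % h):
            raise ValueError(
                f"feature extents ({height},{width}) not divisible by partition h={h}")
        self.h = h
        self.use_tm, self.use_lgp = use_tm, use_lgp
        if use_tm:
            self.core = TripleMLP(channels, height, width, gated=use_gate, rng=rng)
        if use_lgp:
            self.gp = GlobalPerceptron(channels, height // h, width // h, rng=rng,
                                       bn_eps=bn_eps, bn_momentum=bn_momentum)
            self.lp = LocalPriors(channels, rng=rng, bn_eps=bn_eps, bn_momentum=bn_momentum)

    def forward(self, x):
        s = self.core(x) if self.use_tm else x
        if not self.use_lgp:
            return s
        pt = partition(x, self.h)
        v = gp_weights(pt, self.gp)
        m = gp_apply(pt, v, x)
        return local_priors(m, self.lp, s)
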