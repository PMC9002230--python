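"""Segmentation loss functions: binary cross-entropy, focal and Dice.

All three act on a predicted foreground-probability map and a binary mask of
the same shape, averaging (or pooling) over every pixel. They are written
polymorphically: fed plain ndarrays they return floats; fed autodiff Tensors
they return a scalar Tensor that training can backpropagate through.

Probabilities are clipped to [eps, 1-eps] (eps = 1e-7) before any logarithm,
so a saturated prediction cannot produce an infinite loss. The focal loss is
the standard binary form with prediction-side modulation,

    -(1/wh) * sum[ a (1-p^)^g p log p^ + (1-a) p^^g (1-p) log(1-p^) ],

and the Dice loss uses additive smoothing s=1 so that an empty mask with an
empty prediction scores a perfect 0.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

CLIP_EPS = 1e-7


def _as_pair(prob, mask):
    if prob.shape != mask.shape:
        raise ValueError(f"shape mismatch: prob {prob.shape} vs mask {mask.shape}")
    return prob, mask


def _clip(prob):
    if isinstance(prob, Tensor):
        return ad.clip(prob, CLIP_EPS, 1.0 - CLIP_EPS)
    return np.clip(np.asarray(prob, dtype=np.float64), CLIP_EPS, 1.0 - CLIP_EPS)


def _log(x):
    return ad.log(x) if isinstance(x, Tensor) else np.log(x)


def _mean(x):
    return x.mean() if isinstance(x, Tensor) else float(np.mean(x))


def _sum(x):
    return x.sum() if isinstance(x, Tensor) else float(np.sum(x))


def _mask_array(mask):
    if isinstance(mask, Tensor):
        return mask
    m = np.asarray(mask, dtype=np.float64)
    if not np.isin(m, (0.0, 1.0)).all():
        raise ValueError("mask must be binary")
    return m


def cross_entropy(prob, mask):
    """Per-pixel binary cross-entropy averaged over the image."""
    prob, mask = _as_pair(prob, _mask_array(mask))
    p_hat = _clip(prob)
    ll = mask * _log(p_hat) + (1.0 - mask) * _log(1.0 - p_hat)
    return -_mean(ll)


def focal(prob, mask, alpha: float = 0.25, gamma: float = 2.0):
    """Binary focal loss; ``alpha`` weights the foreground, ``gamma`` the focus."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if gamma < 0.0:
        raise ValueError("gamma must be non-negative")
    prob, mask = _as_pair(prob, _mask_array(mask))
    p_hat = _clip(prob)
    fg = alpha * (1.0 - p_hat) ** gamma * mask * _log(p_hat)
    bg = (1.0 - alpha) * p_hat ** gamma * (1.0 - mask) * _log(1.0 - p_hat)
    return -_mean(fg + bg)


def dice_loss(prob, mask, smooth: float = 1.0):
    """1 - soft Dice overlap, smoothed so empty/empty scores zero."""
    prob, mask = _as_pair(prob, _mask_array(mask))
    p_hat = _clip(prob)
    inter = _sum(p_hat * mask)
    denom = _sum(p_hat) + _sum(mask)
    return 1.0 - (2.0 * inter + smooth) / (denom + smooth)


LOSSES = {"cross_entropy": cross_entropy, "focal": focal, "dice": dice_loss}


def get_loss(kind: str, alpha: float = 0.25, gamma: float = 2.0):
    """Return loss_fn(prob, mask) for a configured loss kind."""
    if kind == "focal":
        return lambda prob, mask: focal(prob, mask, alpha, gamma)
    try:
        return LOSSES[kind]
    except KeyError:
        raise ValueError(f"unknown loss kind {kind!r}") from None


def softmax_foreground(scores):
    """Foreground probability from (N, 2, H, W) class scores (autodiff-safe)."""
    if isinstance(scores, Tensor):
        shift = scores - Tensor(scores.data.max(axis=1, keepdims=True))
        e = ad.exp(shift)
        return e[:, 1] / e.sum(axis=1)
    shift = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(shift)
    return e[:, 1] / e.sum(axis=1)
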