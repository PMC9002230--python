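"""Independent brute-force reference implementations used by the tests.

Everything here is written directly from the mathematical definitions with
float64 numpy loops (or scipy for plain 2-D convolution), deliberately
sharing no code with the package's autodiff path.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

LN_EPS = 1e-5
BN_EPS = 1e-6


def channel_layernorm(x, gamma, beta, eps=LN_EPS):
    """LayerNorm over the channel axis at each (n,h,w) site of (N,C,H,W)."""
    x = np.asarray(x, dtype=np.float64)
    mu = x.mean(axis=1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=1, keepdims=True)
    xhat = (x - mu) / np.sqrt(var + eps)
    return xhat * np.reshape(gamma, (1, -1, 1, 1)) + np.reshape(beta, (1, -1, 1, 1))


def axis_mix_loops(y, weight, bias, axis):
    """Apply out_j = sum_i v_i W[i,j] + b_j along one axis with explicit loops."""
    y = np.asarray(y, dtype=np.float64)
    out = np.zeros_like(y)
    n_, c_, h_, w_ = y.shape
    if axis == 1:
        for n in range(n_):
            for h in range(h_):
                for w in range(w_):
                    out[n, :, h, w] = y[n, :, h, w] @ weight + bias
    elif axis == 2:
        for n in range(n_):
            for c in range(c_):
                for w in range(w_):
                    out[n, c, :, w] = y[n, c, :, w] @ weight + bias
    elif axis == 3:
        for n in range(n_):
            for c in range(c_):
                for h in range(h_):
                    out[n, c, h, :] = y[n, c, h, :] @ weight + bias
    else:
        raise ValueError(axis)
    return out


def axis_step_oracle(x, params, gate):
    axis = {"channel": 1, "high": 2, "wide": 3}[params.axis]
    y = channel_layernorm(x, params.norm.gamma.data, params.norm.beta.data)
    mixed = axis_mix_loops(y, params.weight.data.astype(np.float64),
                           params.bias.data.astype(np.float64), axis)
    return gate * mixed + np.asarray(x, dtype=np.float64)


def tgmlp_core_oracle(x, p_c, p_h, p_w, gates):
    g = np.asarray(gates, dtype=np.float64)
    x = axis_step_oracle(x, p_c, g[0])
    x = axis_step_oracle(x, p_h, g[1])
    x = axis_step_oracle(x, p_w, g[2])
    return x


def gelu_oracle(x):
    from scipy.special import erf

    return x * 0.5 * (1.0 + erf(x / np.sqrt(2.0)))


def mixer_block_oracle(x, params):
    """Channel mix then explicit flatten-matmul spatial mix."""
    x = axis_step_oracle(x, params.channel_mlp, 1.0)
    n_, c_, h_, w_ = x.shape
    y = channel_layernorm(x, params.spatial_norm.gamma.data,
                          params.spatial_norm.beta.data)
    tokens = y.reshape(n_, c_, h_ * w_)
    out = np.empty_like(tokens)
    W1, b1 = params.fc1.data.astype(np.float64), params.b1.data.astype(np.float64)
    W2, b2 = params.fc2.data.astype(np.float64), params.b2.data.astype(np.float64)
    for n in range(n_):
        for c in range(c_):
            hidden = gelu_oracle(tokens[n, c] @ W1 + b1)
            out[n, c] = hidden @ W2 + b2
    return out.reshape(n_, c_, h_, w_) + x


def partition_index_oracle(x, h):
    """Element-by-element construction of the (N, W/h, H/h, C, h, h) layout."""
    x = np.asarray(x)
    n_, c_, H, W = x.shape
    ph, pw = H // h, W // h
    pt = np.zeros((n_, pw, ph, c_, h, h), dtype=x.dtype)
    for n in range(n_):
        for c in range(c_):
            for gy in range(h):
                for gx in range(h):
                    for hp in range(ph):
                        for wp in range(pw):
                            pt[n, wp, hp, c, gy, gx] = x[n, c, gy * ph + hp,
                                                         gx * pw + wp]
    return pt


def gp_apply_oracle(pt, v, x_in):
    """Loop over grid cells adding the shared offset, then un-partition."""
    pt = np.asarray(pt, dtype=np.float64).copy()
    n_, pw, ph, c_, h, _ = pt.shape
    v = np.asarray(v, dtype=np.float64).reshape(n_, pw, ph, c_)
    for gy in range(h):
        for gx in range(h):
            pt[:, :, :, :, gy, gx] += v
    out = np.zeros((n_, c_, ph * h, pw * h), dtype=np.float64)
    for n in range(n_):
        for c in range(c_):
            for gy in range(h):
                for gx in range(h):
                    for hp in range(ph):
                        for wp in range(pw):
                            out[n, c, gy * ph + hp, gx * pw + wp] = \
                                pt[n, wp, hp, c, gy, gx]
    return out + np.asarray(x_in, dtype=np.float64)


def conv2d_oracle(x, weight, bias, padding):
    """Stride-1 multi-channel cross-correlation via scipy, per channel pair."""
    x = np.asarray(x, dtype=np.float64)
    n_, c_in, H, W = x.shape
    c_out = weight.shape[0]
    out = np.zeros((n_, c_out, H, W), dtype=np.float64)
    for n in range(n_):
        for o in range(c_out):
            acc = np.zeros((H + 2 * padding, W + 2 * padding))
            for i in range(c_in):
                xp = np.pad(x[n, i], padding)
                acc += ndimage.correlate(xp, weight[o, i].astype(np.float64),
                                         mode="constant")
            out[n, o] = acc[padding:padding + H, padding:padding + W] + bias[o]
    return out


def rates_counting_oracle(pred, true):
    """Recompute every rate by iterating over pixels one at a time."""
    tp = fp = fn = tn = 0
    for p, t in zip(np.asarray(pred).ravel(), np.asarray(true).ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    out = {}
    out["dice"] = 2 * tp / (2 * tp + fp + fn) if (tp + fp + fn) else 1.0
    out["iou"] = tp / (tp + fp + fn) if (tp + fp + fn) else 1.0
    out["sen"] = out["recall"] = tp / (tp + fn) if (tp + fn) else (
        1.0 if (tp + fp + fn) == 0 else 0.0)
    out["spc"] = tn / (tn + fp) if (tn + fp) else 1.0
    out["precision"] = tp / (tp + fp) if (tp + fp) else (
        1.0 if (tp + fp + fn) == 0 else 0.0)
    return out


def boundary_oracle(mask):
    """Foreground pixels with at least one non-foreground 8-neighbour."""
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    pts = []
    for r in range(H):
        for c in range(W):
            if not mask[r, c]:
                continue
            edge = False
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < H and 0 <= cc < W) or not mask[rr, cc]:
                        edge = True
            if edge:
                pts.append((r, c))
    return np.array(pts, dtype=float)


def hausdorff_bruteforce(mask_a, mask_b):
    """All-pairs symmetric Hausdorff distance over boundary pixels, in px."""
    pa, pb = boundary_oracle(mask_a), boundary_oracle(mask_b)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def flood_fill_components(mask) -> int:
    """Count 8-connected components with an explicit BFS flood fill."""
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    seen = np.zeros_like(mask)
    count = 0
    for r0 in range(H):
        for c0 in range(W):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            count += 1
            queue = [(r0, c0)]
            seen[r0, c0] = True
            while queue:
                r, c = queue.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < H and 0 <= cc < W and mask[rr, cc]
                                and not seen[rr, cc]):
                            seen[rr, cc] = True
                            queue.append((rr, cc))
    return count
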