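"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine: each ``Tensor`` wraps an ndarray and remembers the
operation that produced it. Calling :meth:`Tensor.backward` on a scalar result
walks the tape in reverse topological order and accumulates gradients into
every tensor created with ``requires_grad=True``.

Only the operations the segmentation network needs are provided: broadcasted
arithmetic, reshape/transpose, axis reductions, elementwise nonlinearities,
2-D (strided) convolution and 2x2-stride-2 transposed convolution. The
convolution primitives unroll the kernel window (k*k slice-tensordot pairs)
instead of materialising an im2col buffer, which keeps memory flat and maps
every inner product onto BLAS.

Tensors mirror a subset of the ndarray interface (``reshape``, ``transpose``,
arithmetic operators, ``shape``), so shape-shuffling helpers elsewhere in the
package can be written once and run on plain arrays and tensors alike.
"""

from __future__ import annotations

import math

import numpy as np

DEFAULT_DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make ndarray <op> Tensor defer to the reflected Tensor methods
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DEFAULT_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction -----------------------------------------------------
    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
            out.requires_grad = True
        return out

    # -- ndarray-ish surface ----------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- autodiff ----------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # -- operators ----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(as_tensor(other), self)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)

    def __getitem__(self, idx):
        return getitem(self, idx)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def backward(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return Tensor._from_op(out, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def backward(g):
        return (_unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape))

    return Tensor._from_op(out, (a, b), backward)


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    out = a.data ** exponent

    def backward(g):
        return (g * exponent * a.data ** (exponent - 1.0),)

    return Tensor._from_op(out, (a,), backward)


def matmul(a, b) -> Tensor:
    """2-D matrix product (m,k) @ (k,n)."""
    a, b = as_tensor(a), as_tensor(b)
    out = a.data @ b.data

    def backward(g):
        return g @ b.data.T, a.data.T @ g

    return Tensor._from_op(out, (a, b), backward)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    old = a.data.shape

    def backward(g):
        return (g.reshape(old),)

    return Tensor._from_op(a.data.reshape(shape), (a,), backward)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        return (g.transpose(inv),)

    return Tensor._from_op(a.data.transpose(axes), (a,), backward)


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)
    shape = a.data.shape

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, shape).astype(g.dtype, copy=False),)
        ax = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, ax)
        return (np.broadcast_to(g, shape),)

    return Tensor._from_op(out, (a,), backward)


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[i] for i in ax]))
    return mul(sum_(a, axis, keepdims), 1.0 / n)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)

    def backward(g):
        return (g * out,)

    return Tensor._from_op(out, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    out = np.log(a.data)

    def backward(g):
        return (g / a.data,)

    return Tensor._from_op(out, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0

    def backward(g):
        return (g * mask,)

    return Tensor._from_op(a.data * mask, (a,), backward)


_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(a) -> Tensor:
    """Exact Gaussian-error-linear unit x * Phi(x)."""
    from scipy.special import erf

    a = as_tensor(a)
    cdf = 0.5 * (1.0 + erf(a.data * _INV_SQRT2))
    out = a.data * cdf

    def backward(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * a.data * a.data)
        return (g * (cdf + a.data * pdf),)

    return Tensor._from_op(out, (a,), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values to [lo, hi]; gradient passes through the interior only."""
    a = as_tensor(a)
    out = np.clip(a.data, lo, hi)
    mask = (a.data >= lo) & (a.data <= hi)

    def backward(g):
        return (g * mask,)

    return Tensor._from_op(out, (a,), backward)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    shape = a.data.shape

    def backward(g):
        full = np.zeros(shape, dtype=g.dtype)
        np.add.at(full, idx, g)
        return (full,)

    return Tensor._from_op(a.data[idx], (a,), backward)


# ---------------------------------------------------------------------------
# convolution primitives
# ---------------------------------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation of (N,C,H,W) with (C_out,C_in,k,k) weights."""
    x, w = as_tensor(x), as_tensor(w)
    n, c_in, h, wd = x.data.shape
    c_out, c_in_w, kh, kw = w.data.shape
    if c_in != c_in_w:
        raise ValueError(f"conv2d channel mismatch: input {c_in} vs weight {c_in_w}")
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    out = np.zeros((n, c_out, ho, wo), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
            # (N,C,Ho,Wo) x (C,c_out) -> (N,Ho,Wo,c_out)
            out += np.tensordot(patch, w.data[:, :, i, j], axes=([1], [1])).transpose(0, 3, 1, 2)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        out = out + b.data.reshape(1, c_out, 1, 1)
        parents.append(b)

    def backward(g):
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(w.data)
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
                dw[:, :, i, j] = np.tensordot(g, patch, axes=([0, 2, 3], [0, 2, 3]))
                dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                    np.tensordot(g, w.data[:, :, i, j], axes=([1], [0])).transpose(0, 3, 1, 2)
        dx = dxp[:, :, padding:padding + h, padding:padding + wd] if padding else dxp
        grads = [dx, dw]
        if b is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return grads

    return Tensor._from_op(out, parents, backward)


def conv_transpose2x2(x, w, b=None) -> Tensor:
    """Transposed convolution, kernel 2, stride 2: (N,C,H,W) -> (N,C_out,2H,2W).

    Weight layout (C_in, C_out, 2, 2).
    """
    x, w = as_tensor(x), as_tensor(w)
    n, c_in, h, wd = x.data.shape
    c_in_w, c_out, kh, kw = w.data.shape
    if c_in != c_in_w:
        raise ValueError(f"conv_transpose channel mismatch: {c_in} vs {c_in_w}")
    out = np.empty((n, c_out, 2 * h, 2 * wd), dtype=x.data.dtype)
    for i in range(2):
        for j in range(2):
            out[:, :, i::2, j::2] = np.tensordot(
                x.data, w.data[:, :, i, j], axes=([1], [0])).transpose(0, 3, 1, 2)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        out = out + b.data.reshape(1, c_out, 1, 1)
        parents.append(b)

    def backward(g):
        dx = np.zeros_like(x.data)
        dw = np.zeros_like(w.data)
        for i in range(2):
            for j in range(2):
                gij = g[:, :, i::2, j::2]
                dx += np.tensordot(gij, w.data[:, :, i, j], axes=([1], [1])).transpose(0, 3, 1, 2)
                dw[:, :, i, j] = np.tensordot(x.data, gij, axes=([0, 2, 3], [0, 2, 3]))
        grads = [dx, dw]
        if b is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return grads

    return Tensor._from_op(out, parents, backward)
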