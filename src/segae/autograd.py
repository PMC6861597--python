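"""Minimal reverse-mode automatic differentiation over numpy arrays.

The segmentation autoencoder needs gradients of a composite objective
(cosine-proximity reconstruction terms, a Laplacian-filtered variant, and an
activity regularizer) through 3D convolutions, batch normalization, Softmax
and elementwise nonlinearities.  This module provides exactly the operation
set that network requires: a :class:`Tensor` wrapping an ``ndarray`` plus a
graph of backward closures, in the style of the classic define-by-run
frameworks but with no external dependency.

Dtype is preserved end to end, so float64 graphs can be checked against
central finite differences while training runs in float32.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "no_grad",
    "concat",
    "lrelu",
    "softmax",
    "conv3d",
    "upsample_nearest",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        g = np.asarray(g, dtype=self.data.dtype)
        if self.grad is None:
            self.grad = g if g.flags.owndata and g.flags.writeable else g.copy()
        else:
            self.grad = self.grad + g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data
        req = self.requires_grad or other.requires_grad

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, req, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            self._accumulate(-g)

        return Tensor(-self.data, self.requires_grad, (self,), back)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data
        req = self.requires_grad or other.requires_grad

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, req, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data
        req = self.requires_grad or other.requires_grad

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor(out_data, req, (self, other), back)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def back(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return Tensor(out_data, self.requires_grad, (self,), back)

    # -- reductions & shaping ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return Tensor(out_data, self.requires_grad, (self,), back)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)

        def back(g):
            self._accumulate(np.asarray(g).reshape(self.data.shape))

        return Tensor(out_data, self.requires_grad, (self,), back)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def back(g):
            self._accumulate(g * 0.5 / np.sqrt(self.data))

        return Tensor(out_data, self.requires_grad, (self,), back)

    def clip_min(self, lo: float):
        """max(x, lo); gradient flows only where x > lo (the floor is inert)."""
        out_data = np.maximum(self.data, lo)

        def back(g):
            self._accumulate(g * (self.data > lo))

        return Tensor(out_data, self.requires_grad, (self,), back)


# -- neural-network operations --------------------------------------------

def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]

    def back(g):
        start = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, start + s)
                t._accumulate(g[tuple(sl)])
            start += s

    return Tensor(out_data, req, tuple(tensors), back)


def lrelu(x: Tensor, slope: float = 0.1) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, slope * x.data)

    def back(g):
        x._accumulate(np.where(mask, g, slope * g))

    return Tensor(out_data, x.requires_grad, (x,), back)


def softmax(x: Tensor, axis: int = 0) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def back(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        x._accumulate(out_data * (g - dot))

    return Tensor(out_data, x.requires_grad, (x,), back)


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Per-channel normalization over the spatial axes of a (C, D, H, W) tensor.

    Returns (out, mean, var); the fused backward avoids the temporaries a
    composition of elementwise primitives would allocate.
    """
    axes = (1, 2, 3)
    n = x.data[0].size
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = gamma.data * xhat + beta.data
    req = x.requires_grad or gamma.requires_grad or beta.requires_grad

    def back(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes, keepdims=True))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes, keepdims=True))
        if x.requires_grad:
            dxhat = g * gamma.data
            m1 = dxhat.mean(axis=axes, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
            x._accumulate(inv * (dxhat - m1 - xhat * m2))

    return Tensor(out_data, req, (x, gamma, beta), back), mu, var


def masked_batchnorm(
    x: Tensor, gamma: Tensor, beta: Tensor, mask: np.ndarray, eps: float = 1e-5
):
    """Batch normalization whose statistics are computed over masked voxels.

    ``mask`` is a (D, H, W) indicator of the brain at the current
    resolution; per-channel mean and variance come from brain voxels only,
    so patch composition (how much zero background a patch contains) does
    not shift the normalization of tissue features.  All voxels are still
    normalized with the same affine transform.
    """
    axes = (1, 2, 3)
    w = mask[None].astype(x.data.dtype)
    n = max(float(w.sum()), 1.0)
    mu = (w * x.data).sum(axis=axes, keepdims=True) / n
    var = (w * (x.data - mu) ** 2).sum(axis=axes, keepdims=True) / n
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = gamma.data * xhat + beta.data
    req = x.requires_grad or gamma.requires_grad or beta.requires_grad

    def back(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes, keepdims=True))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes, keepdims=True))
        if x.requires_grad:
            dxhat = g * gamma.data
            s1 = dxhat.sum(axis=axes, keepdims=True)
            s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
            x._accumulate(inv * (dxhat - w * (s1 / n) - w * xhat * (s2 / n)))

    return Tensor(out_data, req, (x, gamma, beta), back), mu, var


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbor upsampling of a (C, D, H, W) tensor."""
    out_data = x.data.repeat(factor, axis=1).repeat(factor, axis=2).repeat(factor, axis=3)

    def back(g):
        c, d, h, w = x.data.shape
        g = np.asarray(g).reshape(c, d, factor, h, factor, w, factor)
        x._accumulate(g.sum(axis=(2, 4, 6)))

    return Tensor(out_data, x.requires_grad, (x,), back)


def conv3d(x: Tensor, w: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """3D cross-correlation of (Cin, D, H, W) with (Cout, Cin, kd, kh, kw).

    Computed as a sum of (Cout, Cin) matrix products over the kernel
    offsets, which keeps memory traffic low for the small channel counts
    this architecture uses.  No bias: the mixing layer must be bias-free,
    and batch-norm absorbs shifts elsewhere.
    """
    cout, cin, kd, kh, kw = w.data.shape
    p = padding
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p))) if p else x.data
    do = (xp.shape[1] - kd) // stride + 1
    ho = (xp.shape[2] - kh) // stride + 1
    wo = (xp.shape[3] - kw) // stride + 1
    n = do * ho * wo

    def views(arr):
        for a in range(kd):
            for b in range(kh):
                for c in range(kw):
                    yield (a, b, c), arr[
                        :,
                        a : a + stride * do : stride,
                        b : b + stride * ho : stride,
                        c : c + stride * wo : stride,
                    ]

    req = x.requires_grad or w.requires_grad
    cache: list[np.ndarray] = []
    out_data = np.zeros((cout, n), dtype=xp.dtype)
    for (a, b, c), xv in views(xp):
        col = np.ascontiguousarray(xv).reshape(cin, n)
        if req and _GRAD_ENABLED and w.requires_grad:
            cache.append(col)
        out_data += w.data[:, :, a, b, c] @ col
    out_data = out_data.reshape(cout, do, ho, wo)

    def back(g):
        g2 = np.ascontiguousarray(g).reshape(cout, n)
        dw = np.zeros_like(w.data) if w.requires_grad else None
        dxp = np.zeros_like(xp) if x.requires_grad else None
        for off, ((a, b, c), xv) in enumerate(views(xp)):
            if dw is not None:
                dw[:, :, a, b, c] = g2 @ cache[off].T
            if dxp is not None:
                dxp[
                    :,
                    a : a + stride * do : stride,
                    b : b + stride * ho : stride,
                    c : c + stride * wo : stride,
                ] += (w.data[:, :, a, b, c].T @ g2).reshape(cin, do, ho, wo)
        if dw is not None:
            w._accumulate(dw)
        if dxp is not None:
            x._accumulate(dxp[:, p:-p, p:-p, p:-p] if p else dxp)

    return Tensor(out_data, req, (x, w), back)
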