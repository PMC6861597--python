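"""Scale-invariant reconstruction objective and anti-overlap regularizer.

The reconstruction term is the negative cosine proximity between each true
channel and its reconstruction, plus the same proximity after filtering both
with the 3D discrete Laplacian (which annihilates constant and affine
intensity trends, making the term robust to slowly varying inhomogeneity).
The activity regularizer penalizes the summed pairwise cosine proximity of
the soft material maps, driving them toward disjoint supports; its double
sum runs over all (i, j) pairs including the diagonal, whose M unit terms
are gradient-free constants.

Every function accepts plain ndarrays (returns a float) or autograd
:class:`~segae.autograd.Tensor` inputs (returns a Tensor usable for
backprop); the two paths are the same code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, conv3d

__all__ = [
    "LossConfig",
    "LAPLACE_KERNEL",
    "cosine_proximity",
    "laplacian_filter",
    "reconstruction_loss",
    "activity_regularizer",
    "total_loss",
]

#: 3x3x3 six-neighbor discrete Laplace stencil: outer slices carry the two
#: axial neighbors, the middle slice the in-plane cross with -6 at center.
LAPLACE_KERNEL = np.zeros((3, 3, 3))
LAPLACE_KERNEL[0, 1, 1] = LAPLACE_KERNEL[2, 1, 1] = 1.0
LAPLACE_KERNEL[1] = [[0, 1, 0], [1, -6, 1], [0, 1, 0]]


@dataclass
class LossConfig:
    """alpha: regularization coefficient; epsilon: norm floor protecting
    all-zero vectors; include_laplacian: add the Laplacian-filtered term."""

    alpha: float = 0.0075
    epsilon: float = 1e-8
    include_laplacian: bool = True

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=float)), False


def _maybe_item(t: Tensor, keep: bool):
    return t if keep else t.item()


def cosine_proximity(y, y_hat, epsilon: float = 1e-8):
    """f(y, yhat) = y.yhat / (max(|y|, eps) * max(|yhat|, eps)), in [-1, 1]."""
    y, ka = _as_tensor(y)
    y_hat, kb = _as_tensor(y_hat)
    y = y.reshape(-1)
    y_hat = y_hat.reshape(-1)
    num = (y * y_hat).sum()
    ny = (y * y).sum().sqrt().clip_min(epsilon)
    nyh = (y_hat * y_hat).sum().sqrt().clip_min(epsilon)
    return _maybe_item(num / (ny * nyh), ka or kb)


def laplacian_filter(volume):
    """Convolve a 3D volume with the discrete Laplace stencil (zero-padded).

    At interior voxels this equals the 6-neighbor Laplacian
    (sum of neighbors - 6 * center).
    """
    v, keep = _as_tensor(volume)
    if v.data.ndim != 3 or min(v.data.shape) < 3:
        raise ValueError(f"volume must be 3D with every axis >= 3, got {v.data.shape}")
    x = v.reshape(1, *v.data.shape)
    k = Tensor(LAPLACE_KERNEL.reshape(1, 1, 3, 3, 3).astype(v.data.dtype))
    out = conv3d(x, k, stride=1, padding=1).reshape(*v.data.shape)
    return out if keep else out.data


def reconstruction_loss(Y, Y_hat, epsilon: float = 1e-8, include_laplacian: bool = True):
    """-(1/C) sum_c [ f(Y_c, Yhat_c) + f(K*Y_c, K*Yhat_c) ]; minimum -2."""
    Y, ka = _as_tensor(Y)
    Y_hat, kb = _as_tensor(Y_hat)
    if Y.data.shape != Y_hat.data.shape:
        raise ValueError(f"shape mismatch: {Y.data.shape} vs {Y_hat.data.shape}")
    C = Y.data.shape[0]
    total = Tensor(np.zeros((), dtype=Y_hat.data.dtype))
    for c in range(C):
        a = _channel(Y, c)
        b = _channel(Y_hat, c)
        total = total + cosine_proximity(a, b, epsilon)
        if include_laplacian:
            total = total + cosine_proximity(
                laplacian_filter(a), laplacian_filter(b), epsilon
            )
    return _maybe_item(total * (-1.0 / C), ka or kb)


def _channel(t: Tensor, c: int) -> Tensor:
    data = t.data[c]

    def back(g):
        full = np.zeros_like(t.data)
        full[c] = g
        t._accumulate(full)

    return Tensor(data, t.requires_grad, (t,), back)


def activity_regularizer(S, alpha: float, epsilon: float = 1e-8):
    """(alpha/M) * sum_{i,j} f(S_i, S_j), diagonal included.

    Equals alpha for pairwise-disjoint non-empty maps and alpha*M when all
    maps are identical.
    """
    S, keep = _as_tensor(S)
    M = S.data.shape[0]
    if M < 2:
        raise ValueError("activity regularizer needs at least 2 material maps")
    total = Tensor(np.zeros((), dtype=S.data.dtype))
    chans = [_channel(S, i) for i in range(M)]
    for i in range(M):
        for j in range(M):
            total = total + cosine_proximity(chans[i], chans[j], epsilon)
    return _maybe_item(total * (alpha / M), keep)


def total_loss(Y, Y_hat, S, config: LossConfig | None = None):
    """Training objective: reconstruction loss plus activity regularizer."""
    config = config or LossConfig()
    recon = reconstruction_loss(Y, Y_hat, config.epsilon, config.include_laplacian)
    reg = activity_regularizer(S, config.alpha, config.epsilon)
    if isinstance(recon, Tensor) or isinstance(reg, Tensor):
        recon, _ = _as_tensor(recon)
        reg, _ = _as_tensor(reg)
        return recon + reg
    return recon + reg
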