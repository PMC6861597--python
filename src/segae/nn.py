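"""Network building blocks on top of the autodiff engine.

Layers follow the conventions of the autoencoder architecture: 3D
convolutions with Glorot-uniform initialization and no bias, leaky-ReLU
activations, and per-channel batch normalization that uses batch statistics
in training and running averages at inference (the training batch is a
single patch, so "batch" statistics are spatial statistics per channel).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, batchnorm, conv3d, lrelu, masked_batchnorm

__all__ = ["Module", "Conv3d", "BatchNorm3d", "glorot_uniform"]


def glorot_uniform(
    rng: np.random.Generator, shape: tuple[int, ...], dtype=np.float32
) -> np.ndarray:
    """Glorot/Xavier uniform init for a (Cout, Cin, kd, kh, kw) kernel."""
    receptive = int(np.prod(shape[2:])) if len(shape) > 2 else 1
    fan_in = shape[1] * receptive
    fan_out = shape[0] * receptive
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Module:
    """Tiny container protocol: children discovered by attribute scan."""

    training: bool = True

    @staticmethod
    def _walk(value):
        if isinstance(value, (list, tuple)):
            for item in value:
                yield from Module._walk(item)
        else:
            yield value

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            for item in self._walk(value):
                if isinstance(item, Tensor) and item.requires_grad:
                    params.append(item)
                elif isinstance(item, Module):
                    params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in self.__dict__.values():
            for item in self._walk(value):
                if isinstance(item, Module):
                    mods.extend(item.modules())
        return mods

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Conv3d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        padding: int = 0,
        *,
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        k = kernel_size
        self.weight = Tensor(
            glorot_uniform(rng, (out_channels, in_channels, k, k, k), dtype),
            requires_grad=True,
        )
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, stride=self.stride, padding=self.padding)


class BatchNorm3d(Module):
    """Per-channel normalization over the spatial axes of a (C, D, H, W) tensor."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        self.gamma = Tensor(np.ones((channels, 1, 1, 1), dtype), requires_grad=True)
        self.beta = Tensor(np.zeros((channels, 1, 1, 1), dtype), requires_grad=True)
        self.running_mean = np.zeros((channels, 1, 1, 1), dtype)
        self.running_var = np.ones((channels, 1, 1, 1), dtype)
        self.eps = eps
        self.momentum = momentum

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        if self.training:
            if mask is None:
                out, mu, var = batchnorm(x, self.gamma, self.beta, self.eps)
            else:
                out, mu, var = masked_batchnorm(x, self.gamma, self.beta, mask, self.eps)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * var
            return out
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = (self.gamma.data * inv).astype(x.data.dtype)
        shift = (self.beta.data - self.gamma.data * self.running_mean * inv).astype(x.data.dtype)
        return x * Tensor(scale) + Tensor(shift)


class ConvBlock(Module):
    """conv -> LReLU -> batch-norm, in that order."""

    def __init__(self, cin: int, cout: int, *, kernel_size=3, stride=1, padding=1,
                 slope: float = 0.1, rng: np.random.Generator, dtype=np.float32):
        self.conv = Conv3d(cin, cout, kernel_size, stride, padding, rng=rng, dtype=dtype)
        self.bn = BatchNorm3d(cout, dtype=dtype)
        self.slope = slope

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        return self.bn(lrelu(self.conv(x), self.slope), mask)
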