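"""The constrained convolutional autoencoder.

A three-scale fully-convolutional encoder-decoder emits M Softmax material
maps, which are masked by the patch brainmask (1 where any input channel is
non-zero) and then linearly recombined into the C input channels by a
1x1x1 "mixing" convolution constrained to non-negative weights and zero
bias.  Because the mixing layer is the linear-unmixing model itself, its
weights are directly interpretable as per-material channel intensities, and
the Softmax output is a soft segmentation of the materials present in the
images.

Layer order inside each block is conv -> LReLU -> batch-norm.  Downsampling
is a 2x2x2 strided convolution; upsampling is 2x nearest-neighbor followed
by a 3x3x3 convolution; skip connections concatenate encoder activations
into the decoder at matching resolution.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .autograd import Tensor, concat, conv3d, no_grad, softmax, upsample_nearest
from .nn import ConvBlock, Module

__all__ = ["NetworkConfig", "MaterialMaps", "Network", "build_network",
           "project_nonnegative", "save_network", "load_network"]


@dataclass
class NetworkConfig:
    in_channels: int = 3
    n_materials: int = 5
    base_filters: int = 16
    n_scales: int = 3
    lrelu_slope: float = 0.1
    masked_norm: bool = False  # batch-norm statistics over brain voxels only

    def __post_init__(self):
        if self.n_scales < 2:
            raise ValueError("n_scales must be >= 2")
        if self.n_materials < 2:
            raise ValueError("n_materials must be >= 2")
        if self.base_filters < 4:
            raise ValueError("base_filters must be >= 4")

    @property
    def divisor(self) -> int:
        """Input patch dimensions must be divisible by this."""
        return 2 ** (self.n_scales - 1)


@dataclass
class MaterialMaps:
    """M soft segmentation volumes and the binary mask they sum to."""

    maps: np.ndarray  # (M, D, H, W), in [0, 1]
    mask: np.ndarray  # (D, H, W), {0, 1}

    def check(self, tol: float = 1e-5) -> None:
        total = self.maps.sum(axis=0)
        if np.abs(total - self.mask).max() > tol:
            raise AssertionError("material maps do not sum to the brain mask")


class Network(Module):
    """Encoder-decoder with Softmax head and non-negative mixing layer."""

    def __init__(self, config: NetworkConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        rng = np.random.default_rng(seed)
        f = config.base_filters
        s = config.lrelu_slope
        kw = dict(slope=s, rng=rng, dtype=dtype)

        self.enc_blocks: list[list[ConvBlock]] = []
        self.down_blocks: list[ConvBlock] = []
        cin = config.in_channels
        widths = [f * 2**i for i in range(config.n_scales)]
        for lvl, width in enumerate(widths):
            self.enc_blocks.append(
                [ConvBlock(cin, width, **kw), ConvBlock(width, width, **kw)]
            )
            cin = width
            if lvl < config.n_scales - 1:
                self.down_blocks.append(
                    ConvBlock(width, widths[lvl + 1], kernel_size=2, stride=2,
                              padding=0, **kw)
                )
                cin = widths[lvl + 1]

        self.up_blocks: list[ConvBlock] = []
        self.dec_blocks: list[list[ConvBlock]] = []
        for lvl in range(config.n_scales - 2, -1, -1):
            width = widths[lvl]
            self.up_blocks.append(ConvBlock(widths[lvl + 1], width, **kw))
            self.dec_blocks.append(
                [ConvBlock(2 * width, width, **kw), ConvBlock(width, width, **kw)]
            )

        self.head = nn.Conv3d(f, config.n_materials, kernel_size=1, rng=rng, dtype=dtype)
        # mixing layer: 1x1x1 conv, M -> C, non-negative, zero (absent) bias;
        # init non-negative so the projection starts feasible
        w0 = np.abs(nn.glorot_uniform(rng, (config.in_channels, config.n_materials, 1, 1, 1), dtype))
        self.mixing = Tensor(w0, requires_grad=True)

    # -- forward -----------------------------------------------------------
    def forward(
        self, patch: np.ndarray, mask: np.ndarray | None = None
    ) -> tuple[MaterialMaps, Tensor, Tensor]:
        """Run one patch; returns (MaterialMaps, S tensor, reconstruction).

        ``mask`` is the patch brainmask; by default it is obtained by
        binarizing the input patch (1 where any channel is non-zero).  When
        the input has been augmented with noise, pass the mask of the clean
        patch explicitly so the background stays masked.
        """
        patch = np.asarray(patch)
        if not np.all(np.isfinite(patch)):
            raise ValueError("non-finite values in input patch")
        d = self.config.divisor
        if any(s % d for s in patch.shape[1:]):
            raise ValueError(
                f"patch dimensions {patch.shape[1:]} must be divisible by {d} "
                f"for {self.config.n_scales} scales"
            )
        if mask is None:
            mask = np.any(patch != 0, axis=0)
        mask = mask.astype(patch.dtype)

        # per-scale brain masks for masked normalization (a 2x2x2 block is
        # "brain" at the coarser scale if any of its voxels is)
        if self.config.masked_norm:
            scale_masks = [mask]
            m = mask
            for _ in range(self.config.n_scales - 1):
                d, h, w = m.shape
                m = m.reshape(d // 2, 2, h // 2, 2, w // 2, 2).max(axis=(1, 3, 5))
                scale_masks.append(m)
        else:
            scale_masks = [None] * self.config.n_scales

        x = Tensor(patch)
        skips = []
        for lvl in range(self.config.n_scales):
            for blk in self.enc_blocks[lvl]:
                x = blk(x, scale_masks[lvl])
            if lvl < self.config.n_scales - 1:
                skips.append(x)
                x = self.down_blocks[lvl](x, scale_masks[lvl + 1])
        for i, lvl in enumerate(range(self.config.n_scales - 2, -1, -1)):
            x = self.up_blocks[i](upsample_nearest(x), scale_masks[lvl])
            x = concat([x, skips[lvl]], axis=0)
            for blk in self.dec_blocks[i]:
                x = blk(x, scale_masks[lvl])

        logits = self.head(x)
        S = softmax(logits, axis=0) * Tensor(mask[None])
        recon = conv3d(S, self.mixing)  # (C, D, H, W), zero-bias weighted sum
        return MaterialMaps(S.data, mask.astype(np.uint8)), S, recon

    def __call__(self, patch, mask=None):
        return self.forward(patch, mask)

    def predict(self, patch: np.ndarray) -> MaterialMaps:
        """Inference-mode forward (running batch-norm statistics, no graph)."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                maps, _, _ = self.forward(patch)
        finally:
            if was_training:
                self.train()
        return maps

    @property
    def mixing_weights(self) -> np.ndarray:
        """(M, C) non-negative mixing matrix w[i, c]."""
        return self.mixing.data[:, :, 0, 0, 0].T.copy()


def build_network(config: NetworkConfig, seed: int = 0) -> Network:
    """Deterministic construction: same config and seed give identical weights."""
    return Network(config, seed)


def project_nonnegative(network_or_weights) -> None:
    """Clip the mixing weights at zero in place (projected gradient step)."""
    t = network_or_weights.mixing if isinstance(network_or_weights, Network) else network_or_weights
    np.maximum(t.data, 0.0, out=t.data)


# -- serialization ---------------------------------------------------------

def save_network(network: Network, path) -> None:
    state = {
        "config": asdict(network.config),
        "params": [p.data for p in network.parameters()],
        "buffers": [
            (m.running_mean, m.running_var)
            for m in network.modules()
            if isinstance(m, nn.BatchNorm3d)
        ],
    }
    with open(path, "wb") as fh:
        pickle.dump(state, fh)


def load_network(path) -> Network:
    with open(path, "rb") as fh:
        state = pickle.load(fh)
    net = Network(NetworkConfig(**state["config"]))
    for p, data in zip(net.parameters(), state["params"]):
        p.data = data
    bns = [m for m in net.modules() if isinstance(m, nn.BatchNorm3d)]
    for m, (rm, rv) in zip(bns, state["buffers"]):
        m.running_mean, m.running_var = rm, rv
    return net
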