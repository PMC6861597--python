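"""Intensity normalization, PD-based enhancement, cropping, patching, augmentation.

All volumes are numpy arrays in NIfTI array order; multi-sequence data is a
(C, D, H, W) stack of co-registered, skull-stripped channels whose zero
background defines the brain mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PatchSet",
    "normalize_intensity",
    "enhance_with_pd",
    "crop_to_brain",
    "pad_to_patch",
    "extract_patches",
    "select_training_patches",
    "augment",
]


@dataclass
class PatchSet:
    """Fixed-size C-channel sub-volumes plus their corner coordinates.

    ``patches``: (N, C, pd, ph, pw) array; ``origins``: (N, 3) 0-based corner
    voxel coordinates in the (cropped) source volume.
    """

    patches: np.ndarray
    origins: np.ndarray
    patch_size: tuple[int, int, int]
    stride: int

    def __len__(self) -> int:
        return len(self.patches)


def normalize_intensity(volume: np.ndarray) -> np.ndarray:
    """Divide by the 99th percentile of the non-zero voxels (zeros stay zero).

    The percentile uses numpy's linear interpolation between order statistics.
    """
    volume = np.asarray(volume, dtype=float)
    nz = volume[volume != 0]
    if nz.size == 0:
        raise ValueError("cannot normalize an all-zero volume")
    p99 = np.percentile(nz, 99)
    if p99 == 0:
        raise ValueError("99th percentile of non-zero voxels is zero")
    return volume / p99


def enhance_with_pd(i_orig: np.ndarray, i_pd: np.ndarray) -> np.ndarray:
    """Contrast enhancement of a T1-w/T2-w image by an inverted PD-w image.

    Returns ``i_orig * (max(i_pd) - i_pd)`` elementwise; where the PD image
    attains its maximum the output is zero.  Homogeneous of degree 1 in both
    arguments.
    """
    i_orig = np.asarray(i_orig, dtype=float)
    i_pd = np.asarray(i_pd, dtype=float)
    if i_orig.shape != i_pd.shape:
        raise ValueError(f"shape mismatch: {i_orig.shape} vs {i_pd.shape}")
    if np.any(i_pd < 0):
        raise ValueError("PD-w image must be non-negative")
    return i_orig * (i_pd.max() - i_pd)


def crop_to_brain(volumes: np.ndarray) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Crop a (C, D, H, W) stack to the smallest cuboid containing the brain.

    The brain support is the union of non-zero voxels across channels.
    Returns the cropped stack and the 0-based offset of its corner.
    """
    volumes = np.asarray(volumes)
    support = np.any(volumes != 0, axis=0)
    if not support.any():
        raise ValueError("empty brain: no non-zero voxel in any channel")
    lo, hi = [], []
    for ax in range(3):
        axes = tuple(a for a in range(3) if a != ax)
        prof = support.any(axis=axes)
        nz = np.flatnonzero(prof)
        lo.append(int(nz[0]))
        hi.append(int(nz[-1]) + 1)
    cropped = volumes[:, lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].copy()
    return cropped, tuple(lo)


def pad_to_patch(
    volumes: np.ndarray, patch_size: tuple[int, int, int]
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Symmetric zero-padding of axes smaller than the patch size.

    Returns the padded stack and the (lo) padding offsets per axis, so
    results can be mapped back with ``result[pad0:pad0+d, ...]``.
    """
    volumes = np.asarray(volumes)
    pads = [(0, 0)]
    offs = []
    for ax, p in enumerate(patch_size):
        short = max(0, p - volumes.shape[1 + ax])
        lo = short // 2
        pads.append((lo, short - lo))
        offs.append(lo)
    if any(p != (0, 0) for p in pads[1:]):
        volumes = np.pad(volumes, pads)
    return volumes, tuple(offs)


def _axis_origins(length: int, patch: int, stride: int) -> list[int]:
    """Origins at stride multiples, with a final origin clamped so the last
    patch touches the boundary (no voxel unsampled)."""
    origins = list(range(0, length - patch + 1, stride))
    if origins[-1] != length - patch:
        origins.append(length - patch)
    return origins


def extract_patches(
    volumes: np.ndarray, patch_size: tuple[int, int, int], stride: int = 40
) -> PatchSet:
    """Regular clamped grid of C-channel patches from a (C, D, H, W) stack."""
    if stride <= 0:
        raise ValueError(f"stride must be positive, got {stride}")
    volumes = np.asarray(volumes)
    patch_size = tuple(int(p) for p in patch_size)
    for ax, p in enumerate(patch_size):
        if p > volumes.shape[1 + ax]:
            raise ValueError(
                f"patch size {p} exceeds volume extent {volumes.shape[1 + ax]} "
                f"on axis {ax}; pad first (pad_to_patch)"
            )
    grids = [_axis_origins(volumes.shape[1 + ax], patch_size[ax], stride) for ax in range(3)]
    origins = np.array([(i, j, k) for i in grids[0] for j in grids[1] for k in grids[2]])
    patches = np.stack(
        [
            volumes[
                :,
                i : i + patch_size[0],
                j : j + patch_size[1],
                k : k + patch_size[2],
            ].copy()
            for i, j, k in origins
        ]
    )
    return PatchSet(patches, origins, patch_size, stride)


def select_training_patches(patchset: PatchSet, fraction: float = 0.5) -> PatchSet:
    """Keep the ceil(fraction*N) patches with the fewest background voxels.

    Background is a voxel where ALL channels are exactly zero.  Ties are
    broken by lexicographic origin order, and the candidate list is sorted
    canonically by origin first, so the result is invariant to input order.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = len(patchset)
    if n == 0:
        raise ValueError("empty patch set")
    order0 = np.lexsort(patchset.origins.T[::-1])  # canonical origin order
    patches = patchset.patches[order0]
    origins = patchset.origins[order0]
    background = np.all(patches == 0, axis=1).reshape(n, -1).sum(axis=1)
    keep = math.ceil(fraction * n)
    order = np.argsort(background, kind="stable")[:keep]
    return PatchSet(patches[order], origins[order], patchset.patch_size, patchset.stride)


def augment(
    patch: np.ndarray,
    noise_sd: float = 0.05,
    scale_sd: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Training-time input augmentation: additive noise, then channel scaling.

    Adds i.i.d. N(0, noise_sd^2) per voxel, then multiplies each channel by
    its own scalar drawn from N(1, scale_sd^2) (not truncated).  Applied to
    the network input only; the reconstruction target stays unaugmented.
    """
    patch = np.asarray(patch)
    if not np.all(np.isfinite(patch)):
        raise ValueError("patch contains non-finite values")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dtype = patch.dtype if np.issubdtype(patch.dtype, np.floating) else np.float64
    out = patch.astype(dtype)
    if noise_sd > 0:
        out = out + (noise_sd * rng.standard_normal(patch.shape)).astype(dtype)
    if scale_sd > 0:
        scales = rng.normal(1.0, scale_sd, size=(patch.shape[0],) + (1,) * (patch.ndim - 1))
        out = out * scales.astype(dtype)
    return out
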