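"""Whole-volume prediction and lesion post-processing.

Prediction slides the trained network over a clamped patch grid (same rule
as patch extraction), averages the Softmax outputs of overlapping voxels,
re-applies the brain mask and renormalizes the averaged maps so they sum to
one inside the mask.  The lesion map is then binarized (strict threshold)
and components smaller than a minimum voxel count are removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .model import MaterialMaps, Network
from .preprocess import _axis_origins, pad_to_patch

__all__ = ["LesionMask", "predict_volume", "binarize", "remove_small_components",
           "connectivity_structure"]


@dataclass
class LesionMask:
    """Binary lesion mask with reporting metadata."""

    mask: np.ndarray
    voxel_volume: float = 1.0  # mm^3 per voxel
    threshold: float | None = None
    min_voxels: int | None = None

    @property
    def volume(self) -> float:
        return float(self.mask.sum()) * self.voxel_volume


def connectivity_structure(connectivity: int = 26) -> np.ndarray:
    """3D structuring element for component labelling (6 or 26 neighbors)."""
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def predict_volume(
    network: Network,
    volumes: np.ndarray,
    patch_size: tuple[int, int, int] | None = None,
    stride: int = 40,
) -> MaterialMaps:
    """Sliding-window prediction with overlap averaging.

    ``volumes`` is the normalized (C, D, H, W) stack.  Patches on the
    clamped grid are predicted in inference mode; per-voxel Softmax outputs
    are summed and divided by the visit count, the brain mask (any channel
    non-zero) is re-applied, and the maps are renormalized to sum to one
    inside the mask.
    """
    volumes = np.asarray(volumes)
    if volumes.shape[0] != network.config.in_channels:
        raise ValueError(
            f"network expects {network.config.in_channels} channels, got {volumes.shape[0]}"
        )
    if patch_size is None:
        patch_size = volumes.shape[1:]
    patch_size = tuple(int(p) for p in patch_size)
    d = network.config.divisor
    if any(p % d for p in patch_size):
        raise ValueError(f"patch size {patch_size} must be divisible by {d}")

    padded, offs = pad_to_patch(volumes, patch_size)
    shape = padded.shape[1:]
    m = network.config.n_materials
    acc = np.zeros((m,) + shape)
    count = np.zeros(shape)
    grids = [_axis_origins(shape[ax], patch_size[ax], stride) for ax in range(3)]
    for i in grids[0]:
        for j in grids[1]:
            for k in grids[2]:
                sl = (
                    slice(i, i + patch_size[0]),
                    slice(j, j + patch_size[1]),
                    slice(k, k + patch_size[2]),
                )
                maps = network.predict(padded[(slice(None),) + sl])
                acc[(slice(None),) + sl] += maps.maps
                count[sl] += 1.0
    acc /= count
    # unpad
    sl = tuple(slice(o, o + volumes.shape[1 + ax]) for ax, o in enumerate(offs))
    acc = acc[(slice(None),) + sl]
    mask = np.any(volumes != 0, axis=0)
    acc *= mask
    total = acc.sum(axis=0)
    nonzero = total > 0
    acc[:, nonzero] /= total[nonzero]
    return MaterialMaps(acc, mask.astype(np.uint8))


def binarize(
    s_material: np.ndarray, threshold: float = 0.5, voxel_volume: float = 1.0
) -> LesionMask:
    """mask = 1 where S > threshold (strictly), else 0."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    mask = (np.asarray(s_material) > threshold).astype(np.uint8)
    return LesionMask(mask, voxel_volume, threshold=threshold)


def remove_small_components(
    mask: LesionMask | np.ndarray, min_voxels: int = 3, connectivity: int = 26
) -> LesionMask:
    """Drop 3D connected components with fewer than ``min_voxels`` voxels.

    A component of exactly ``min_voxels`` voxels is kept.
    """
    if min_voxels < 1:
        raise ValueError(f"min_voxels must be >= 1, got {min_voxels}")
    lm = mask if isinstance(mask, LesionMask) else LesionMask(np.asarray(mask))
    structure = connectivity_structure(connectivity)
    labels, n = ndimage.label(lm.mask > 0, structure=structure)
    if n:
        counts = np.bincount(labels.ravel())
        keep = counts >= min_voxels
        keep[0] = False
        out = keep[labels].astype(np.uint8)
    else:
        out = np.zeros_like(lm.mask, dtype=np.uint8)
    return LesionMask(out, lm.voxel_volume, threshold=lm.threshold, min_voxels=min_voxels)
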