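"""Synthetic multi-sequence brain phantoms with known ground truth.

The segmentation model assumes each MRI channel is (approximately) a
non-negative weighted sum of M soft material maps, modulated by a smooth
multiplicative bias field plus additive noise.  This module builds exactly
that generative process on a simple nested-ellipsoid "brain": a CSF core
(ventricle-like), a white-matter interior, a gray-matter shell, an optional
thin meninges rim at the brain boundary, and randomly placed smoothed lesion
blobs inside the white matter.  Geometry is deliberately schematic — the
method's math depends only on the mixture structure, not on anatomy.

Canonical material order: CSF, GM, WM, WMH[, MENINGES].
Canonical channel order for default fixtures: FLAIR-like, T1-like, T2-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomTruth",
    "MATERIAL_NAMES",
    "DEFAULT_MIXING",
    "default_mixing_weights",
    "make_material_maps",
    "make_bias_field",
    "synthesize_volumes",
    "make_phantom",
]

MATERIAL_NAMES = ("CSF", "GM", "WM", "WMH", "MENINGES")


def _material_names(n_materials: int) -> tuple[str, ...]:
    return {
        2: ("WM", "WMH"),
        3: ("CSF", "WM", "WMH"),
        4: ("CSF", "GM", "WM", "WMH"),
        5: MATERIAL_NAMES,
    }[n_materials]

#: Default M=5 x C=3 mixing matrix (rows: CSF, GM, WM, WMH, MENINGES;
#: columns: FLAIR-like, T1-like, T2-like).  The lesion material is brightest
#: in the FLAIR-like channel, CSF is dark on FLAIR and bright on T2, WM is
#: bright on T1 — the intensity signatures the method exploits.  Any 3 rows
#: are linearly independent, so every C-material subset is identifiable.
DEFAULT_MIXING = np.array(
    [
        # FLAIR  T1    T2
        [0.05, 0.30, 1.00],  # CSF
        [0.60, 0.55, 0.65],  # GM
        [0.40, 1.00, 0.35],  # WM
        [1.00, 0.45, 0.85],  # WMH
        [0.30, 0.70, 0.50],  # MENINGES
    ]
)


def default_mixing_weights(n_materials: int, channels: int = 3) -> np.ndarray:
    """The first ``n_materials`` rows / ``channels`` columns of the default matrix."""
    if not (2 <= n_materials <= 5) or channels > DEFAULT_MIXING.shape[1]:
        raise ValueError("default mixing matrix supports 2 <= M <= 5, C <= 3")
    rows = [MATERIAL_NAMES.index(n) for n in _material_names(n_materials)]
    return DEFAULT_MIXING[np.ix_(rows, range(channels))].copy()


@dataclass
class PhantomTruth:
    """Ground truth of one synthetic subject.

    material_maps: (M, D, H, W) soft maps, non-negative, summing to the brain
        mask at every voxel; bias_fields: (C, D, H, W) strictly positive
        smooth fields (mean 1 over the mask); mixing_weights: (M, C).
    """

    material_maps: np.ndarray
    mixing_weights: np.ndarray
    bias_fields: np.ndarray
    brain_mask: np.ndarray
    noise_sd: float = 0.0
    seed: int = 0
    material_names: tuple[str, ...] = field(default=MATERIAL_NAMES[:4])


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def make_material_maps(
    shape: tuple[int, int, int],
    n_materials: int = 4,
    lesion_fraction: float = 0.05,
    softness: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Build M soft material maps and the brain mask.

    Returns ``(maps, brain_mask)`` where ``maps`` has shape (M, D, H, W),
    is non-negative and sums exactly to ``brain_mask`` per voxel.  Material
    order is CSF, GM, WM, WMH and, when ``n_materials == 5``, MENINGES.
    ``lesion_fraction`` is the target fraction of white-matter voxels
    replaced by lesion blobs; 0 yields an identically-zero lesion map.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 16 for s in shape):
        raise ValueError(f"shape must be 3D with every dimension >= 16, got {shape}")
    if not (2 <= n_materials <= 5):
        raise ValueError(
            "n_materials must be in [2, 5] "
            "(WM+WMH, +CSF, +GM, +meninges); " f"got {n_materials}"
        )
    if not (0.0 <= lesion_fraction <= 1.0):
        raise ValueError(f"lesion_fraction must be in [0, 1], got {lesion_fraction}")

    names = _material_names(n_materials)
    idx = {name: i for i, name in enumerate(names)}
    rng = np.random.default_rng(seed)
    center = [(s - 1) / 2 + rng.uniform(-1, 1) for s in shape]
    outer_axes = [0.42 * s * rng.uniform(0.95, 1.05) for s in shape]

    brain = _ellipsoid(shape, center, outer_axes)
    with_meninges = "MENINGES" in idx
    rim_frac = 0.93 if with_meninges else 1.0
    # compartment volumes roughly mimic an elderly brain with enlarged
    # ventricles: ~9% CSF, ~40% WM, ~50% GM of intracranial volume
    gm_outer = _ellipsoid(shape, center, [a * rim_frac for a in outer_axes])
    wm_outer = _ellipsoid(shape, center, [a * 0.80 * rim_frac for a in outer_axes])
    csf_core = _ellipsoid(shape, center, [a * 0.45 for a in outer_axes])

    labels = np.full(shape, -1, dtype=np.int8)  # -1 = background
    wm_i, wmh_i = idx["WM"], idx["WMH"]
    if with_meninges:
        labels[brain] = idx["MENINGES"]  # rim, overwritten inward
    labels[gm_outer] = idx.get("GM", wm_i)
    labels[wm_outer & gm_outer] = wm_i
    labels[csf_core & gm_outer] = idx.get("CSF", wm_i)

    wm_region = labels == wm_i
    n_wm = int(wm_region.sum())
    if lesion_fraction > 0 and n_wm > 0:
        target = lesion_fraction * n_wm
        wm_idx = np.argwhere(wm_region)
        lesion = np.zeros(shape, dtype=bool)
        attempts = 0
        while lesion.sum() < target and attempts < 10_000:
            attempts += 1
            ci = wm_idx[rng.integers(len(wm_idx))]
            r = rng.uniform(1.5, 3.5)
            blob = _ellipsoid(shape, ci, [r * rng.uniform(0.8, 1.25) for _ in range(3)])
            lesion |= blob & wm_region
        labels[lesion] = wmh_i

    # one-hot, soften by Gaussian blur, renormalize so the per-voxel sum is
    # exactly the brain mask (soft partial-volume boundaries, hard support)
    mask = labels >= 0
    maps = np.zeros((n_materials,) + shape)
    for i in range(n_materials):
        maps[i] = gaussian_filter((labels == i).astype(float), softness)
    total = maps.sum(axis=0)
    total[total == 0] = 1.0
    maps = maps / total * mask
    if lesion_fraction == 0:
        maps[wmh_i] = 0.0
    return maps, mask.astype(np.uint8)


def make_bias_field(
    shape: tuple[int, int, int],
    amplitude: float = 0.3,
    smoothness: float = 12.0,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Smooth strictly-positive multiplicative field exp(g), mean 1 over ``mask``.

    ``g`` is smoothed zero-mean Gaussian noise rescaled to ``max|g| =
    amplitude``; ``smoothness`` is the Gaussian correlation length in voxels.
    """
    if amplitude < 0 or amplitude >= 1:
        raise ValueError(f"amplitude must be in [0, 1), got {amplitude}")
    if smoothness < 4:
        raise ValueError(f"smoothness must be >= 4 voxels, got {smoothness}")
    shape = tuple(int(s) for s in shape)
    rng = np.random.default_rng(seed)
    if amplitude == 0:
        return np.ones(shape)
    g = gaussian_filter(rng.standard_normal(shape), smoothness)
    g -= g.mean()
    peak = np.abs(g).max()
    if peak > 0:
        g *= amplitude / peak
    fld = np.exp(g)
    region = np.ones(shape, bool) if mask is None else mask.astype(bool)
    fld /= fld[region].mean()
    return fld


def synthesize_volumes(truth: PhantomTruth, channels: int | None = None) -> np.ndarray:
    """Run the linear mixture generatively: Y_c = bias_c * sum_i w_ic S_i + noise.

    Output is clipped at zero and exactly zero outside the brain mask; with
    zero noise and unit bias it is the exact linear mixture.
    """
    w = np.asarray(truth.mixing_weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("mixing weights must be non-negative")
    maps = truth.material_maps
    if w.shape[0] != maps.shape[0]:
        raise ValueError(
            f"mixing_weights has {w.shape[0]} rows but there are {maps.shape[0]} materials"
        )
    c = w.shape[1] if channels is None else int(channels)
    if c != w.shape[1]:
        raise ValueError(f"requested {c} channels but mixing_weights has {w.shape[1]} columns")

    clean = np.tensordot(w.T, maps, axes=1)  # (C, D, H, W)
    out = clean * truth.bias_fields
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed + 0x5EA5)
        out = out + truth.noise_sd * rng.standard_normal(out.shape)
    out = np.clip(out, 0.0, None)
    return out * truth.brain_mask


def make_phantom(
    shape: tuple[int, int, int] = (48, 48, 48),
    channels: int = 3,
    n_materials: int = 4,
    lesion_fraction: float = 0.05,
    bias_amplitude: float = 0.0,
    bias_smoothness: float = 12.0,
    noise_sd: float = 0.0,
    softness: float = 1.0,
    seed: int = 0,
    mixing_weights: np.ndarray | None = None,
) -> tuple[PhantomTruth, np.ndarray]:
    """Convenience constructor: full truth plus synthesized volumes."""
    maps, mask = make_material_maps(shape, n_materials, lesion_fraction, softness, seed)
    w = (
        default_mixing_weights(n_materials, channels)
        if mixing_weights is None
        else np.asarray(mixing_weights, dtype=float)
    )
    bias = np.stack(
        [
            make_bias_field(shape, bias_amplitude, bias_smoothness, seed + 101 + c, mask)
            for c in range(w.shape[1])
        ]
    )
    truth = PhantomTruth(
        material_maps=maps,
        mixing_weights=w,
        bias_fields=bias,
        brain_mask=mask,
        noise_sd=noise_sd,
        seed=seed,
        material_names=_material_names(n_materials),
    )
    return truth, synthesize_volumes(truth)
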