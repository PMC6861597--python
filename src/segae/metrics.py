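"""Lesion evaluation metrics: DSC, AVD, H95, lesion-wise detection, volume fit.

Definitions are deliberately simple and brute-force-verifiable:

- ``dice``: 2TP / (2TP + FP + FN) over voxels.
- ``avd``: |V_T - V_P| / V_T (relative volume error; tables usually x100).
- ``hausdorff95``: symmetric 95th-percentile directed point-set distance in
  mm, computed on full voxel sets.
- ``lesion_detection``: 3D connected components; a truth lesion counts as
  detected if it overlaps the prediction in at least one voxel (at most once,
  so N_P <= N_T); a predicted component overlapping no truth lesion is a
  false detection.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import linregress

from .infer import connectivity_structure

__all__ = [
    "LesionEvaluation",
    "dice",
    "avd",
    "hausdorff95",
    "lesion_detection",
    "volume_correlation",
    "evaluate_masks",
    "hungarian_dice",
]


@dataclass
class LesionEvaluation:
    """Per-subject record against a reference mask (AVD also given x100)."""

    dsc: float
    h95: float | None
    avd: float
    avd_percent: float
    l_tpr: float | None
    l_f1: float | None
    n_true_lesions: int
    n_detected: int
    n_false: int

    def to_dict(self) -> dict:
        return asdict(self)


def _check_masks(T, P) -> tuple[np.ndarray, np.ndarray]:
    T = np.asarray(T).astype(bool)
    P = np.asarray(P).astype(bool)
    if T.shape != P.shape:
        raise ValueError(f"mask shape mismatch: {T.shape} vs {P.shape}")
    return T, P


def dice(T, P) -> float:
    """Dice similarity coefficient; 1 when both masks are empty, 0 when
    exactly one is empty."""
    T, P = _check_masks(T, P)
    tp = np.logical_and(T, P).sum()
    denom = 2 * tp + np.logical_and(P, ~T).sum() + np.logical_and(T, ~P).sum()
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom


def avd(T, P, voxel_volume: float = 1.0) -> float:
    """Absolute volume difference |V_T - V_P| / V_T (not symmetric)."""
    T, P = _check_masks(T, P)
    vt = T.sum() * voxel_volume
    if vt == 0:
        raise ValueError("AVD is undefined for an empty reference mask")
    vp = P.sum() * voxel_volume
    return abs(vt - vp) / vt


def hausdorff95(T, P, spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric 95th-percentile Hausdorff distance between voxel sets, in mm.

    Returns NaN (flagged undefined) if either mask is empty.  The percentile
    uses linear interpolation; the distance is Euclidean after scaling voxel
    indices by ``spacing``.
    """
    T, P = _check_masks(T, P)
    if not T.any() or not P.any():
        return float("nan")
    spacing = np.asarray(spacing, dtype=float)
    pts_t = np.argwhere(T) * spacing
    pts_p = np.argwhere(P) * spacing
    d_tp = cKDTree(pts_p).query(pts_t)[0]
    d_pt = cKDTree(pts_t).query(pts_p)[0]
    return float(max(np.percentile(d_tp, 95), np.percentile(d_pt, 95)))


def lesion_detection(T, P, connectivity: int = 26) -> tuple[int, int, int]:
    """Component-wise detection counts (N_T, N_P, N_F).

    N_T: truth lesions; N_P: truth lesions overlapping the prediction in at
    least one voxel (each counted once); N_F: predicted components with no
    overlap with any truth lesion.
    """
    T, P = _check_masks(T, P)
    structure = connectivity_structure(connectivity)
    lab_t, n_t = ndimage.label(T, structure=structure)
    lab_p, n_p_comps = ndimage.label(P, structure=structure)
    detected = len(np.unique(lab_t[(lab_t > 0) & P]))
    false = n_p_comps - len(np.unique(lab_p[(lab_p > 0) & T]))
    return int(n_t), int(detected), int(false)


def volume_correlation(true_volumes, predicted_volumes) -> tuple[float, float, float]:
    """Pearson r plus least-squares line of predicted on true volumes."""
    x = np.asarray(true_volumes, dtype=float)
    y = np.asarray(predicted_volumes, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired volumes")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("volume correlation undefined for zero-variance input")
    res = linregress(x, y)
    return float(res.rvalue), float(res.slope), float(res.intercept)


def evaluate_masks(
    T, P, spacing=(1.0, 1.0, 1.0), connectivity: int = 26
) -> LesionEvaluation:
    """All lesion metrics of one subject in one record."""
    T_, P_ = _check_masks(T, P)
    voxel_volume = float(np.prod(spacing))
    n_t, n_p, n_f = lesion_detection(T_, P_, connectivity)
    h = hausdorff95(T_, P_, spacing)
    a = avd(T_, P_, voxel_volume) if T_.any() else float("nan")
    return LesionEvaluation(
        dsc=dice(T_, P_),
        h95=None if np.isnan(h) else h,
        avd=a,
        avd_percent=100.0 * a,
        l_tpr=(n_p / n_t) if n_t > 0 else None,
        l_f1=(n_p / (n_p + n_f)) if (n_p + n_f) > 0 else None,
        n_true_lesions=n_t,
        n_detected=n_p,
        n_false=n_f,
    )


def hungarian_dice(
    pred_maps: np.ndarray, true_maps: np.ndarray, mask=None
) -> tuple[np.ndarray, float, np.ndarray]:
    """Best material-to-truth assignment by Dice of argmax label maps.

    Labels each voxel by its argmax material (inside ``mask``), computes the
    Dice matrix between predicted and true labels, and solves the assignment
    maximizing total Dice.  Returns ``(permutation, mean_dice, dice_matrix)``
    where ``permutation[i]`` is the truth index matched to predicted material
    ``i`` and the mean is over non-empty truth materials.
    """
    from scipy.optimize import linear_sum_assignment

    pred_maps = np.asarray(pred_maps)
    true_maps = np.asarray(true_maps)
    m = true_maps.shape[0]
    if pred_maps.shape != true_maps.shape:
        raise ValueError("prediction and truth must have the same (M, D, H, W) shape")
    if mask is None:
        mask = true_maps.sum(axis=0) > 0.5
    mask = np.asarray(mask).astype(bool)
    pred_lab = np.argmax(pred_maps, axis=0)
    true_lab = np.argmax(true_maps, axis=0)
    dmat = np.zeros((m, m))
    for i in range(m):
        pi = (pred_lab == i) & mask
        for j in range(m):
            tj = (true_lab == j) & mask
            dmat[i, j] = dice(tj, pi)
    rows, cols = linear_sum_assignment(-dmat)
    perm = np.empty(m, dtype=int)
    perm[rows] = cols
    nonempty = {j for j in range(m) if ((true_lab == j) & mask).any()}
    mean_dice = float(np.mean([dmat[i, perm[i]] for i in range(m) if perm[i] in nonempty]))
    return perm, mean_dice, dmat
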