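"""Independent brute-force oracles for the evaluation metrics.

These deliberately avoid scipy.ndimage / KDTree: confusion counts by
explicit voxel loops, distances by all-pairs computation, connected
components by breadth-first flood fill.
"""

import numpy as np


def confusion_counts(T, P):
    tp = fp = fn = 0
    for t, p in zip(np.asarray(T).ravel(), np.asarray(P).ravel()):
        if t and p:
            tp += 1
        elif p:
            fp += 1
        elif t:
            fn += 1
    return tp, fp, fn


def dice_oracle(T, P):
    tp, fp, fn = confusion_counts(T, P)
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2.0 * tp / denom


def avd_oracle(T, P, voxel_volume=1.0):
    vt = float(np.sum(np.asarray(T, bool))) * voxel_volume
    vp = float(np.sum(np.asarray(P, bool))) * voxel_volume
    return abs(vt - vp) / vt


def hausdorff95_oracle(T, P, spacing=(1.0, 1.0, 1.0)):
    spacing = np.asarray(spacing, float)
    pts_t = np.argwhere(np.asarray(T, bool)) * spacing
    pts_p = np.argwhere(np.asarray(P, bool)) * spacing
    # all-pairs distance matrix
    diff = pts_t[:, None, :] - pts_p[None, :, :]
    dmat = np.sqrt((diff**2).sum(axis=2))
    d_tp = dmat.min(axis=1)
    d_pt = dmat.min(axis=0)
    return max(np.percentile(d_tp, 95), np.percentile(d_pt, 95))


def flood_fill_components(mask, connectivity=26):
    """Label components by BFS; returns (labels, n)."""
    mask = np.asarray(mask, bool)
    if connectivity == 26:
        offsets = [
            (a, b, c)
            for a in (-1, 0, 1)
            for b in (-1, 0, 1)
            for c in (-1, 0, 1)
            if (a, b, c) != (0, 0, 0)
        ]
    else:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    labels = np.zeros(mask.shape, dtype=int)
    n = 0
    for idx in np.argwhere(mask):
        if labels[tuple(idx)]:
            continue
        n += 1
        queue = [tuple(idx)]
        labels[tuple(idx)] = n
        while queue:
            v = queue.pop()
            for off in offsets:
                nb = tuple(np.add(v, off))
                if any(i < 0 or i >= s for i, s in zip(nb, mask.shape)):
                    continue
                if mask[nb] and not labels[nb]:
                    labels[nb] = n
                    queue.append(nb)
    return labels, n


def lesion_detection_oracle(T, P, connectivity=26):
    lab_t, n_t = flood_fill_components(T, connectivity)
    lab_p, n_p = flood_fill_components(P, connectivity)
    P = np.asarray(P, bool)
    T = np.asarray(T, bool)
    detected = sum(1 for i in range(1, n_t + 1) if np.any((lab_t == i) & P))
    false = sum(1 for j in range(1, n_p + 1) if not np.any((lab_p == j) & T))
    return n_t, detected, false


def remove_small_oracle(mask, min_voxels=3, connectivity=26):
    labels, n = flood_fill_components(mask, connectivity)
    out = np.zeros_like(np.asarray(mask, bool))
    for i in range(1, n + 1):
        comp = labels == i
        if comp.sum() >= min_voxels:
            out |= comp
    return out
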