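"""Iterative pure-tissue inhomogeneity correction.

MR intensity inhomogeneity is modelled as a smooth, strictly positive
multiplicative field per sequence.  Correcting lesion-rich images naively
degrades lesion contrast, so the loop alternates segmentation and
correction: segment with the current model, build a pure-tissue probability
mask (CSF + GM + WM, excluding lesions and meninges) so lesion and
partial-volume voxels contribute minimally, estimate the field with that
mask, divide it out of the *targets*, and retrain from scratch with the
original images as input against the corrected targets.  The final model
thus learns to segment uncorrected images directly.

The default field estimator is a weighted log-domain smooth-field fit: the
log-ratio of the observed image to a reference (the model's own linear
reconstruction, which the scale-invariant loss makes robust to smooth
fields) is smoothed under the pure-tissue weights and exponentiated.  An
external N4 implementation can be substituted via the ``estimator``
argument of :func:`iterative_refinement`.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .model import MaterialMaps, Network, NetworkConfig, build_network
from .preprocess import PatchSet, extract_patches, select_training_patches
from .train import TrainConfig, TrainingLog, train

__all__ = [
    "ROLES",
    "validate_roles",
    "assign_roles",
    "pure_tissue_mask",
    "estimate_bias_field",
    "correct",
    "iterative_refinement",
]

ROLES = ("WMH", "WM", "GM", "CSF", "MENINGES", "OTHER")


def validate_roles(roles: dict[int, str], require=("CSF", "GM", "WM")) -> None:
    for idx, role in roles.items():
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r} for material {idx}")
    counts = [r for r in roles.values() if r != "OTHER"]
    if len(counts) != len(set(counts)):
        raise ValueError("each role other than OTHER may be assigned at most once")
    missing = [r for r in require if r not in roles.values()]
    if missing:
        raise ValueError(f"missing required roles: {missing}")


def assign_roles(
    mixing_weights: np.ndarray, reference: np.ndarray, reference_names
) -> dict[int, str]:
    """Identify material roles by their mixing-weight signature.

    Each recovered weight row (one material's intensity across channels) is
    normalized to unit length and matched to the normalized rows of a
    reference signature matrix (e.g. the default phantom mixing matrix) by
    maximal total cosine similarity (Hungarian assignment).  On real data
    roles are user-assigned in the run configuration instead.
    """
    from scipy.optimize import linear_sum_assignment

    w = np.asarray(mixing_weights, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if w.shape != ref.shape:
        raise ValueError("mixing weights and reference signature must share shape")

    def rows_unit(a):
        n = np.linalg.norm(a, axis=1, keepdims=True)
        n[n == 0] = 1.0
        return a / n

    sim = rows_unit(w) @ rows_unit(ref).T
    rows, cols = linear_sum_assignment(-sim)
    return {int(i): reference_names[j] for i, j in zip(rows, cols)}


def pure_tissue_mask(S: MaterialMaps, roles: dict[int, str]) -> np.ndarray:
    """S_CSF + S_GM + S_WM, clipped to [0, 1]; low where lesions/meninges
    dominate so those voxels barely influence the field estimate."""
    validate_roles(roles)
    idx = [i for i, r in roles.items() if r in ("CSF", "GM", "WM")]
    out = np.clip(S.maps[idx].sum(axis=0), 0.0, 1.0)
    return out * (S.mask > 0)


def estimate_bias_field(
    volume: np.ndarray,
    weight_mask: np.ndarray,
    smoothness: float = 12.0,
    reference: np.ndarray | None = None,
    n_iter: int = 2,
) -> np.ndarray:
    """Weighted log-domain smooth multiplicative field fit.

    ``weight_mask`` in [0, 1] downweights voxels (lesions, partial volume).
    When ``reference`` is given (an estimate of the bias-free image, e.g.
    the model reconstruction), the field is fit to log(volume / reference);
    otherwise directly to log(volume), which also absorbs smooth anatomical
    trends.  The fit is applied ``n_iter`` times, re-estimating the residual
    field of the corrected volume (weighted smoothing attenuates part of the
    field in one pass; iterating recovers it, as iterative correction
    schemes do).  The result is strictly positive, normalized to weighted
    mean 1.
    """
    if n_iter > 1:
        total = np.ones_like(np.asarray(volume, dtype=float))
        v = np.asarray(volume, dtype=float)
        for _ in range(n_iter):
            f = estimate_bias_field(v, weight_mask, smoothness, reference, n_iter=1)
            v = correct(v, f)
            total *= f
        w_eff = np.asarray(weight_mask, dtype=float) * (np.asarray(volume) > 0)
        total /= (w_eff * total).sum() / w_eff.sum()
        return total
    volume = np.asarray(volume, dtype=float)
    w = np.asarray(weight_mask, dtype=float)
    if w.min() < 0 or w.max() > 1:
        raise ValueError("weight_mask must lie in [0, 1]")
    w = w * (volume > 0)
    if reference is not None:
        w = w * (np.asarray(reference) > 0)
    if not w.any():
        raise ValueError("weight mask is empty where the volume is positive")

    logv = np.zeros_like(volume)
    pos = volume > 0
    if reference is None:
        logv[pos] = np.log(volume[pos])
    else:
        reference = np.asarray(reference, dtype=float)
        ok = pos & (reference > 0)
        logv[ok] = np.log(volume[ok] / reference[ok])

    # ``smoothness`` is the expected correlation length of the artifact;
    # smoothing with a kernel of that same width would attenuate the field
    # being estimated, so the fit uses a third of it.
    sigma = max(2.0, smoothness / 3.0)
    num = gaussian_filter(w * logv, sigma)
    den = gaussian_filter(w, sigma)
    smooth_log = num / np.maximum(den, 1e-12)
    smooth_log -= (w * smooth_log).sum() / w.sum()
    field = np.exp(smooth_log)
    field /= (w * field).sum() / w.sum()
    return field


def correct(volume: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Divide the multiplicative field out inside the support of ``volume``."""
    volume = np.asarray(volume, dtype=float)
    field = np.asarray(field, dtype=float)
    inside = volume != 0
    if np.any(field[inside] <= 0):
        raise ValueError("bias field must be strictly positive inside the mask")
    out = np.zeros_like(volume)
    out[inside] = volume[inside] / field[inside]
    return out


def iterative_refinement(
    volumes: np.ndarray,
    roles: dict[int, str],
    n_rounds: int = 2,
    train_config: TrainConfig | None = None,
    *,
    network_config: NetworkConfig | None = None,
    patch_size: tuple[int, int, int] | None = None,
    stride: int = 40,
    keep_fraction: float = 0.5,
    smoothness: float = 12.0,
    estimator=None,
    warm_start: bool = True,
) -> tuple[Network, np.ndarray, list[TrainingLog]]:
    """Alternate training and pure-tissue bias correction.

    Round 0 trains on the original volumes as both input and target.  Each
    later round segments with the current model, estimates one field per
    channel under the pure-tissue mask (reference = the model's linear
    reconstruction), corrects the *original* volumes into new targets, and
    retrains with original inputs against the corrected targets.  With
    ``warm_start`` (default) retraining continues from the previous round's
    network, so consecutive rounds are directly comparable; with
    ``warm_start=False`` each round restarts from a fresh initialization.
    Returns the final network, the final corrected targets, and per-round
    training logs.
    """
    from .infer import predict_volume

    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    # roles may be a fixed mapping (indices chosen by the user, as on real
    # data) or a callable network -> mapping that identifies materials by
    # their mixing-weight signature after each round's training
    roles_fn = roles if callable(roles) else None
    if roles_fn is None:
        validate_roles(roles)
    train_config = train_config or TrainConfig()
    volumes = np.asarray(volumes)
    c = volumes.shape[0]
    if network_config is None:
        if roles_fn is not None:
            raise ValueError("network_config is required when roles is a callable")
        network_config = NetworkConfig(in_channels=c, n_materials=len(roles))
    if patch_size is None:
        patch_size = volumes.shape[1:]
    est = estimator or estimate_bias_field

    def patchsets(targets: np.ndarray) -> tuple[PatchSet, PatchSet]:
        inp = extract_patches(volumes, patch_size, stride)
        tgt = extract_patches(targets, patch_size, stride)
        inp_sel = select_training_patches(inp, keep_fraction)
        where = {tuple(o): i for i, o in enumerate(tgt.origins)}
        idx = [where[tuple(o)] for o in inp_sel.origins]
        tgt_sel = PatchSet(
            tgt.patches[idx], tgt.origins[idx], tgt.patch_size, tgt.stride
        )
        return inp_sel, tgt_sel

    targets = volumes.copy()
    logs: list[TrainingLog] = []
    network = None
    from dataclasses import replace

    for rnd in range(n_rounds):
        cfg = train_config
        if rnd == 0 or not warm_start:
            network = build_network(network_config, seed=train_config.seed)
        else:
            # continue from the previous round's network: keep its learned
            # mixing weights and skip re-freezing them
            cfg = replace(train_config, mixing_init="keep", mixing_freeze_epochs=0)
        inp, tgt = patchsets(targets)
        network, log = train(network, inp, tgt, cfg)
        logs.append(log)
        if rnd == n_rounds - 1:
            break
        S = predict_volume(network, volumes, patch_size, stride)
        round_roles = roles_fn(network) if roles_fn is not None else roles
        validate_roles(round_roles)
        ptm = pure_tissue_mask(S, round_roles)
        # partial-volume voxels carry the largest reconstruction error, so
        # the field is estimated from near-pure voxels only
        ptm = ptm * (S.maps.max(axis=0) > 0.9)
        if not ptm.any():
            raise RuntimeError(
                f"degenerate segmentation in round {rnd}: pure-tissue mask is empty"
            )
        recon = np.tensordot(network.mixing_weights.T, S.maps, axes=1)
        corrected = np.empty_like(volumes, dtype=float)
        for ch in range(c):
            field = est(volumes[ch], ptm, smoothness, reference=recon[ch])
            corrected[ch] = correct(volumes[ch], field)
        targets = corrected
    return network, targets, logs
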