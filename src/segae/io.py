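"""NIfTI and provenance plumbing shared by the CLI stages."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["load_volume", "load_volumes", "save_volume", "write_sidecar"]


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load one NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def load_volumes(paths) -> tuple[np.ndarray, np.ndarray]:
    """Load co-registered channels into a (C, D, H, W) stack."""
    arrays, affine = [], None
    for p in paths:
        data, aff = load_volume(p)
        if affine is None:
            affine = aff
        if arrays and data.shape != arrays[0].shape:
            raise ValueError(f"{p}: shape {data.shape} differs from {arrays[0].shape}")
        arrays.append(data)
    return np.stack(arrays), affine


def save_volume(data: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def write_sidecar(path, payload: dict, config: dict | None = None) -> None:
    """JSON provenance sidecar: parameters plus a hash of the configuration."""
    from . import __version__

    record = dict(payload)
    record["segae_version"] = __version__
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        record["config_sha256"] = hashlib.sha256(blob).hexdigest()
        record["config"] = config
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True, default=str))
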