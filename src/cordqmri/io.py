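"""NIfTI and sidecar I/O helpers."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

from .protocol import Protocol

__all__ = ["save_image", "load_image", "load_series_with_protocol",
           "save_json", "load_json"]


def save_image(path: str | Path, data: np.ndarray,
               voxel_size: tuple[float, float, float] = (1.0, 1.0, 5.0),
               affine: Optional[np.ndarray] = None) -> None:
    """Write a 3D/4D array as NIfTI-1 with a diagonal affine by default."""
    if affine is None:
        affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_image(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def load_series_with_protocol(image_path: str | Path,
                              protocol_path: str | Path
                              ) -> tuple[np.ndarray, np.ndarray, Protocol]:
    """Load a 4D series plus its protocol sidecar, validating lengths."""
    data, affine = load_image(image_path)
    protocol = Protocol.from_json(protocol_path)
    if data.ndim != 4:
        raise ValueError(f"{image_path}: expected a 4D series")
    if data.shape[-1] != len(protocol):
        raise ValueError(
            f"{image_path}: 4th dimension ({data.shape[-1]}) does not match "
            f"the protocol length ({len(protocol)})")
    return data, affine, protocol


def save_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
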