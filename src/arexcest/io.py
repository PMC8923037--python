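"""NIfTI / TSV / JSON input-output helpers.

2D maps are written as single-slice 3D NIfTI volumes; spectral and dynamic
stacks put the offset/dynamic axis on the NIfTI 4th axis.  Offset schedules
travel as TSV (columns: index, offset_ppm, is_reference) and TI lists as
JSON or single-column TSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "save_map",
    "load_map",
    "save_stack",
    "load_stack",
    "save_ti_list",
    "load_ti_list",
    "file_sha256",
]


def _affine(voxel_mm: tuple[float, float, float] = (1.5, 1.5, 10.0)) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_mm
    return aff


def save_map(data: np.ndarray, path: str | Path) -> None:
    """Write a 2D map (H, W) as a single-slice NIfTI volume."""
    arr = np.asarray(data, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[..., None]
    nib.save(nib.Nifti1Image(arr, _affine()), str(path))


def load_map(path: str | Path) -> np.ndarray:
    arr = np.asarray(nib.load(str(path)).get_fdata())
    return arr[..., 0] if arr.ndim == 3 and arr.shape[-1] == 1 else arr


def save_stack(data: np.ndarray, path: str | Path) -> None:
    """Write a stack (H, W, n) as a 4D NIfTI (n on the 4th axis)."""
    arr = np.asarray(data, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[:, :, None, :]
    nib.save(nib.Nifti1Image(arr, _affine()), str(path))


def load_stack(path: str | Path) -> np.ndarray:
    arr = np.asarray(nib.load(str(path)).get_fdata())
    if arr.ndim == 4 and arr.shape[2] == 1:
        arr = arr[:, :, 0, :]
    return arr


def save_ti_list(ti_ms: Sequence[float], path: str | Path) -> None:
    Path(path).write_text(json.dumps({"ti_ms": list(map(float, ti_ms))}))


def load_ti_list(path: str | Path) -> list[float]:
    path = Path(path)
    if path.suffix == ".json":
        return [float(v) for v in json.loads(path.read_text())["ti_ms"]]
    vals = [float(line) for line in path.read_text().split() if line.strip()]
    return vals


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
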