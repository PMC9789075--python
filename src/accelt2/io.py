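"""NIfTI-based volume I/O with JSON sidecars.

Echo series are stored as 4-D NIfTI (y, x, z, echo) with a sidecar JSON
carrying the echo times (ms) and provenance (seed, notes); T2 maps as
float32 3-D NIfTI; ROI masks as uint8 label volumes.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .fitting import T2Map
from .phantom import EchoSeries, RoiMask

__all__ = ["write_echo_series", "read_echo_series", "write_map", "read_map",
           "write_roi", "read_roi", "sidecar_path"]


def sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[:-len(suffix)] + ".json")
    return p.with_suffix(".json")


def write_echo_series(path, series: EchoSeries, meta: dict | None = None):
    # (echo, y, x, z) -> (y, x, z, echo) so spatial axes come first
    arr = np.moveaxis(series.data, 0, -1).astype(np.float32)
    nib.save(nib.Nifti1Image(arr, np.eye(4)), str(path))
    side = {"echo_times_ms": list(series.echo_times)}
    if meta:
        side.update(meta)
    sidecar_path(path).write_text(json.dumps(side, indent=2))


def read_echo_series(path) -> EchoSeries:
    sp = sidecar_path(path)
    if not sp.exists():
        raise FileNotFoundError(
            f"echo series sidecar {sp} missing (echo times unknown)")
    side = json.loads(sp.read_text())
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if arr.ndim != 4:
        raise ValueError(f"expected 4-D echo volume, got {arr.ndim}-D")
    data = np.moveaxis(arr, -1, 0)
    return EchoSeries(data=np.ascontiguousarray(data, dtype=np.float64),
                      echo_times=tuple(side["echo_times_ms"]))


def write_map(path, t2_map: T2Map | np.ndarray):
    if isinstance(t2_map, T2Map):
        arr = t2_map.t2.astype(np.float32)
    else:
        arr = np.asarray(t2_map, dtype=np.float32)
    if arr.ndim != 3:
        raise ValueError("T2 map must be 3-D (y, x, z)")
    nib.save(nib.Nifti1Image(arr, np.eye(4)), str(path))


def read_map(path) -> np.ndarray:
    arr = np.asarray(nib.load(str(path)).dataobj)
    if arr.ndim != 3:
        raise ValueError(f"expected 3-D map, got {arr.ndim}-D")
    return arr.astype(np.float64)


def write_roi(path, roi: RoiMask | np.ndarray):
    labels = roi.labels if isinstance(roi, RoiMask) else np.asarray(roi)
    if labels.ndim != 3:
        raise ValueError("ROI mask must be 3-D (y, x, z)")
    nib.save(nib.Nifti1Image(labels.astype(np.uint8), np.eye(4)), str(path))


def read_roi(path) -> RoiMask:
    arr = np.asarray(nib.load(str(path)).dataobj)
    if arr.ndim != 3:
        raise ValueError(f"expected 3-D label volume, got {arr.ndim}-D")
    return RoiMask(labels=arr.astype(np.int16))
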