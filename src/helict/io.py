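"""Projection-stack I/O: multi-page TIFF, numbered TIFF directories, HDF5.

Stacks round-trip losslessly for 16-bit and float32 data.  Geometry and
role travel in a JSON sidecar next to TIFF files and in attributes of the
HDF5 dataset, so a written stack reloads with its full acquisition context.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import tifffile

from .errors import FormatError
from .geometry import ProjectionStack, ScanGeometry

__all__ = ["read_stack", "write_stack"]

_H5_DATASET = "frames"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ProjectionStack, path) -> None:
    """Write a stack as multi-page TIFF (``.tif``/``.tiff``) or HDF5
    (``.h5``/``.hdf5``); float64 frames are stored as float32."""
    path = Path(path)
    frames = stack.frames
    if frames.dtype == np.float64:
        frames = frames.astype(np.float32)
    meta = {
        "role": stack.role,
        "geometry": stack.geometry.to_dict(),
        "angle_offset": stack.angle_offset,
    }
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, frames, photometric="minisblack")
        _sidecar(path).write_text(json.dumps(meta, indent=1))
    elif path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset(_H5_DATASET, data=frames)
            ds.attrs["meta"] = json.dumps(meta)
            if stack.mask is not None:
                fh.create_dataset("mask", data=stack.mask)
    else:
        raise FormatError(f"unsupported output format {path.suffix!r}")


def _read_tiff_dir(path: Path) -> np.ndarray:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
    if not files:
        raise FormatError(f"no TIFF files in directory {path}")
    frames = []
    for f in files:
        try:
            frames.append(tifffile.imread(f))
        except Exception as exc:  # truncated/corrupt file: fail loudly
            raise FormatError(f"cannot read {f}: {exc}") from exc
    shapes = {a.shape for a in frames}
    dtypes = {a.dtype for a in frames}
    if len(shapes) > 1 or len(dtypes) > 1:
        raise FormatError(
            f"mixed frame shapes {shapes} or dtypes {dtypes} in {path}"
        )
    return np.stack(frames)


def read_stack(path, geometry: Optional[ScanGeometry] = None) -> ProjectionStack:
    """Read a stack written by :func:`write_stack` (or a plain TIFF stack /
    numbered TIFF directory, in which case ``geometry`` must be supplied)."""
    path = Path(path)
    meta = None
    mask = None
    if path.is_dir():
        frames = _read_tiff_dir(path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        try:
            frames = tifffile.imread(path)
        except Exception as exc:
            raise FormatError(f"cannot read {path}: {exc}") from exc
        if _sidecar(path).exists():
            meta = json.loads(_sidecar(path).read_text())
    elif path.suffix.lower() in (".h5", ".hdf5"):
        try:
            with h5py.File(path, "r") as fh:
                if _H5_DATASET not in fh:
                    raise FormatError(f"no '{_H5_DATASET}' dataset in {path}")
                frames = fh[_H5_DATASET][()]
                if "meta" in fh[_H5_DATASET].attrs:
                    meta = json.loads(fh[_H5_DATASET].attrs["meta"])
                if "mask" in fh:
                    mask = fh["mask"][()].astype(bool)
        except OSError as exc:
            raise FormatError(f"cannot read {path}: {exc}") from exc
    else:
        raise FormatError(f"unsupported input {path}")

    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise FormatError(f"expected a 3D stack, got shape {frames.shape}")

    role = "raw"
    angle_offset = 0.0
    if meta is not None:
        role = meta.get("role", "raw")
        angle_offset = float(meta.get("angle_offset", 0.0))
        if geometry is None:
            geometry = ScanGeometry.from_dict(meta["geometry"])
    if geometry is None:
        raise FormatError(
            f"{path} has no geometry sidecar/attributes; pass geometry explicitly"
        )
    return ProjectionStack(
        frames=frames,
        role=role,
        geometry=geometry,
        mask=mask,
        angle_offset=angle_offset,
    )
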