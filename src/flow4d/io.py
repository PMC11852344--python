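"""Readers and writers for the on-disk containers.

The native container is a single HDF5 file with named arrays and attributes:

* dataset ``velocity`` — float, shape (nx, ny, nz, nt, 3), m/s
* dataset ``magnitude`` — float, shape (nx, ny, nz, nt), optional
* datasets ``mask_lv``, ``mask_lvot``, ``mask_aorta``, ``mask_static_tissue``
  — uint8 volumes, optional
* attributes ``spacing_mm`` (3,), ``frame_duration_ms``, ``venc_ms``, ``rr_ms``

NIfTI import/export is provided for interoperability (one 4-D image per
velocity component); the voxel grid is authoritative and world coordinates
are ignored.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import h5py
import nibabel as nib
import numpy as np

from .errors import FormatError, ValidationError
from .fields import MagnitudeSeries, SegmentMaskSet, VelocityField4D, _MASK_NAMES

_REQUIRED_ATTRS = ("spacing_mm", "frame_duration_ms", "venc_ms", "rr_ms")


def _write_field_attrs(h5: h5py.File, field: VelocityField4D) -> None:
    h5.attrs["spacing_mm"] = field.spacing
    h5.attrs["frame_duration_ms"] = float(field.frame_duration)
    h5.attrs["venc_ms"] = float(field.venc)
    h5.attrs["rr_ms"] = float(field.rr_interval)


def _read_field_attrs(h5: h5py.File) -> dict:
    missing = [k for k in _REQUIRED_ATTRS if k not in h5.attrs]
    if missing:
        raise FormatError(f"container is missing required attributes: {missing}")
    return dict(
        spacing=np.asarray(h5.attrs["spacing_mm"], dtype=float),
        frame_duration=float(h5.attrs["frame_duration_ms"]),
        venc=float(h5.attrs["venc_ms"]),
        rr_interval=float(h5.attrs["rr_ms"]),
    )


def write_velocity_field(field: VelocityField4D, path: str | Path) -> Path:
    """Write a velocity field (alone) to an HDF5 container; returns the path."""
    field.validate()
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("velocity", data=field.data)
        _write_field_attrs(h5, field)
    return path


def read_velocity_field(path: str | Path) -> VelocityField4D:
    """Read a velocity field written by :func:`write_velocity_field` (bit-exact)."""
    with h5py.File(path, "r") as h5:
        if "velocity" not in h5:
            raise FormatError(f"{path} has no 'velocity' dataset")
        data = h5["velocity"][()]
        meta = _read_field_attrs(h5)
    return VelocityField4D(data=data, **meta)


def write_dataset(
    path: str | Path,
    field: VelocityField4D,
    magnitude: Optional[MagnitudeSeries] = None,
    masks: Optional[SegmentMaskSet] = None,
) -> Path:
    """Write a full subject dataset (velocity + magnitude + masks) to one container."""
    field.validate()
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("velocity", data=field.data)
        _write_field_attrs(h5, field)
        if magnitude is not None:
            magnitude.check_matches(field)
            h5.create_dataset("magnitude", data=magnitude.data)
        if masks is not None:
            masks.check_matches(field)
            for name in _MASK_NAMES:
                m = getattr(masks, name)
                if m is not None:
                    h5.create_dataset(f"mask_{name}", data=m.astype(np.uint8))
    return path


def read_dataset(
    path: str | Path,
) -> tuple[VelocityField4D, Optional[MagnitudeSeries], Optional[SegmentMaskSet]]:
    """Read a subject dataset written by :func:`write_dataset`."""
    with h5py.File(path, "r") as h5:
        if "velocity" not in h5:
            raise FormatError(f"{path} has no 'velocity' dataset")
        meta = _read_field_attrs(h5)
        field = VelocityField4D(data=h5["velocity"][()], **meta)
        magnitude = None
        if "magnitude" in h5:
            magnitude = MagnitudeSeries(data=h5["magnitude"][()])
            magnitude.check_matches(field)
        mask_kwargs = {}
        for name in _MASK_NAMES:
            key = f"mask_{name}"
            if key in h5:
                mask_kwargs[name] = h5[key][()].astype(bool)
        masks = SegmentMaskSet(**mask_kwargs) if mask_kwargs else None
        if masks is not None:
            masks.check_matches(field)
    return field, magnitude, masks


# ---------------------------------------------------------------------------
# NIfTI interoperability — one 4-D image per velocity component.

def export_velocity_nifti(field: VelocityField4D, prefix: str | Path) -> list[Path]:
    """Write ``<prefix>_vx.nii.gz`` etc.; the affine encodes voxel spacing only."""
    affine = np.diag([*field.spacing, 1.0])
    paths = []
    for i, comp in enumerate("xyz"):
        p = Path(f"{prefix}_v{comp}.nii.gz")
        img = nib.Nifti1Image(field.data[..., i].astype(np.float32), affine)
        img.header.set_zooms((*field.spacing, field.frame_duration))
        nib.save(img, p)
        paths.append(p)
    return paths


def import_velocity_nifti(
    prefix: str | Path, venc: float, rr_interval: float
) -> VelocityField4D:
    """Read the three component images written by :func:`export_velocity_nifti`.

    venc and rr_interval are not representable in NIfTI headers and must be
    supplied by the caller.
    """
    comps = []
    spacing = frame_duration = None
    for comp in "xyz":
        p = Path(f"{prefix}_v{comp}.nii.gz")
        if not p.exists():
            raise FormatError(f"missing NIfTI component file {p}")
        img = nib.load(p)
        arr = np.asanyarray(img.dataobj, dtype=np.float64)
        if arr.ndim != 4:
            raise FormatError(f"{p} is not a 4-D image")
        comps.append(arr)
        zooms = img.header.get_zooms()
        spacing = np.asarray(zooms[:3], dtype=float)
        frame_duration = float(zooms[3]) if len(zooms) > 3 else None
    if frame_duration is None or frame_duration <= 0:
        raise FormatError("NIfTI header does not carry a positive frame duration")
    data = np.stack(comps, axis=-1)
    if not np.all(np.isfinite(data)):
        raise ValidationError("NIfTI velocity data contains non-finite values")
    return VelocityField4D(
        data=data,
        spacing=spacing,
        frame_duration=frame_duration,
        venc=venc,
        rr_interval=rr_interval,
    )


def export_mask_nifti(mask: np.ndarray, spacing: np.ndarray, path: str | Path) -> Path:
    affine = np.diag([*np.asarray(spacing, dtype=float), 1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path))
    return Path(path)


def export_scalar_nifti(volume: np.ndarray, spacing: np.ndarray, path: str | Path) -> Path:
    """Write a 3-D scalar volume (e.g. a PC-MRA) as NIfTI."""
    affine = np.diag([*np.asarray(spacing, dtype=float), 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))
    return Path(path)
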