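"""Preprocessing of 4D-flow velocity data.

Three corrections standard in phase-contrast MRI, in the order a practitioner
applies them:

1. **Background phase-offset correction** — eddy currents and concomitant
   gradients add a spatially smooth, temporally stable velocity offset.  A
   2nd-order spatial polynomial is fitted per component to the velocities of
   static-tissue voxels (where true velocity is zero) and subtracted from the
   whole volume.
2. **Velocity anti-aliasing** — velocities beyond ±venc wrap by multiples of
   2·venc.  Wraps are detected and undone voxelwise along the time axis
   (temporal phase unwrapping); no spatial unwrapping is attempted.
3. **PC-MRA construction** — magnitude × speed averaged over time yields an
   angiogram-like volume used for segmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._basis import quadratic_basis
from .config import AnalysisConfig
from .errors import ValidationError
from .fields import MagnitudeSeries, VelocityField4D

logger = logging.getLogger(__name__)

#: Below this static-voxel count the offset fit is considered unreliable.
MIN_STATIC_VOXELS = 100


@dataclass
class PCMRA:
    """Phase-contrast angiogram: a non-negative 3-D scalar volume."""

    data: np.ndarray
    spacing: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError("PC-MRA must be a 3-D volume")
        if np.any(self.data < 0):
            raise ValidationError("PC-MRA values must be non-negative")


def detect_static_tissue(
    field: VelocityField4D, config: AnalysisConfig
) -> np.ndarray:
    """Classify voxels as static tissue from their temporal speed statistics.

    A voxel is static when both the temporal standard deviation and the
    temporal mean of its speed fall below ``static_sd_frac × venc``.  In
    static tissue, phase-contrast velocity is pure noise plus offset, so both
    statistics are small; flowing blood fails at least the SD criterion.
    """
    if field.n_frames < 4:
        raise ValidationError("static-tissue detection needs at least 4 frames")
    speed = field.speed()
    thr = config.static_sd_frac * field.venc
    mask = (speed.std(axis=-1) < thr) & (speed.mean(axis=-1) < thr)
    n = int(mask.sum())
    if n < MIN_STATIC_VOXELS:
        logger.warning(
            "only %d static voxels detected (< %d); offset correction may be "
            "unreliable", n, MIN_STATIC_VOXELS,
        )
    return mask


def correct_background_offset(
    field: VelocityField4D,
    static_mask: np.ndarray,
    config: AnalysisConfig,
) -> VelocityField4D:
    """Subtract a 2nd-order polynomial background offset fitted on static tissue.

    Per frame and velocity component, the static-voxel velocities are fitted
    by least squares on the 2nd-order spatial polynomial basis; the per-frame
    coefficients are averaged over frames (offsets are temporally stable in
    phase-contrast MRI) before the fitted polynomial is subtracted from every
    voxel of every frame.  Falls back to a constant (order-0) fit when the
    static voxels are spatially degenerate.
    """
    static_mask = np.asarray(static_mask, dtype=bool)
    if static_mask.shape != field.grid_shape:
        raise ValidationError("static mask shape does not match the velocity grid")
    if not static_mask.any():
        raise ValidationError("static mask is empty; cannot fit background offset")

    basis = quadratic_basis(field.grid_shape)          # (nx, ny, nz, 10)
    a = basis[static_mask]                             # (S, 10)
    nt = field.n_frames
    corrected = field.copy()

    # one lstsq per component over all frames at once: rhs (S, nt)
    rank_ok = np.linalg.matrix_rank(a) == a.shape[1]
    if not rank_ok:
        logger.warning(
            "static voxels are spatially degenerate; falling back to a "
            "constant (order-0) offset fit"
        )
        a = a[:, :1]
    for c in range(3):
        rhs = field.data[static_mask][:, :, c]         # (S, nt)
        coef, *_ = np.linalg.lstsq(a, rhs, rcond=None)  # (terms, nt)
        mean_coef = coef.mean(axis=1)                   # temporal average
        offset = (basis[..., : a.shape[1]] @ mean_coef)  # (nx, ny, nz)
        corrected.data[..., c] -= offset[..., None]
    return corrected


def unalias_velocity(field: VelocityField4D) -> VelocityField4D:
    """Undo venc wrap-around by temporal phase unwrapping.

    Scanning frames in time order per voxel and component: whenever the
    frame-to-frame difference exceeds venc in magnitude, the multiple of
    2·venc that minimizes the jump is added.  Output values may exceed venc;
    a jump of exactly venc is left untouched.  Idempotent on series whose
    jumps are already within ±venc.
    """
    venc = field.venc
    out = field.copy()
    v = out.data  # (nx, ny, nz, nt, 3)
    n_modified = 0
    for t in range(1, field.n_frames):
        diff = v[..., t, :] - v[..., t - 1, :]
        k = np.rint(diff / (2.0 * venc))
        k[np.abs(diff) <= venc] = 0.0
        n_modified += int(np.count_nonzero(k))
        v[..., t, :] -= 2.0 * venc * k
    logger.info("unalias_velocity corrected %d voxel-frame values", n_modified)
    return out


def compute_pcmra(mag: MagnitudeSeries, field: VelocityField4D) -> PCMRA:
    """PC-MRA: pcmra(x) = (1/T)·Σ_t mag(x,t)·‖v(x,t)‖₂."""
    mag.check_matches(field)
    data = np.mean(mag.data * field.speed(), axis=-1)
    return PCMRA(data=data, spacing=field.spacing.copy())


def preprocess_field(
    field: VelocityField4D,
    config: AnalysisConfig,
    static_mask: np.ndarray | None = None,
    *,
    do_offset: bool = True,
    do_unalias: bool = True,
) -> tuple[VelocityField4D, np.ndarray | None]:
    """Standard preprocessing chain: static detection → offset → unaliasing.

    When no static mask is supplied one is detected.  Returns the corrected
    field and the static mask used (``None`` if offset correction was
    disabled and none was supplied).
    """
    if do_offset:
        if static_mask is None:
            static_mask = detect_static_tissue(field, config)
        if not static_mask.any():
            raise ValidationError(
                "no static voxels available for background-offset correction"
            )
        field = correct_background_offset(field, static_mask, config)
    if do_unalias:
        field = unalias_velocity(field)
    return field, static_mask
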