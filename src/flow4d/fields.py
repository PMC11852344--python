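"""In-memory data model for 4D-flow velocity data and derived per-subject results.

A :class:`VelocityField4D` is a time-resolved volume of three-component blood
velocities on a regular voxel grid; it is the object every pipeline stage
transforms or consumes.  Axis order is (x, y, z, t[, component]); component
order is (vx, vy, vz).  Velocities are m/s, spacing mm, times ms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import ValidationError


@dataclass
class VelocityField4D:
    """Time-resolved three-component velocity volume with geometry/timing metadata.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz, nt, 3)
        Velocity in m/s.
    spacing : ndarray, shape (3,)
        Voxel size in mm along x, y, z.
    frame_duration : float
        Duration of one cardiac frame in ms.
    venc : float
        Velocity-encoding limit in m/s; velocities wrap at ±venc.
    rr_interval : float
        Cardiac cycle length in ms.
    """

    data: np.ndarray
    spacing: np.ndarray
    frame_duration: float
    venc: float
    rr_interval: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.validate()

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def speed(self) -> np.ndarray:
        """Voxelwise speed ‖v‖₂, shape (nx, ny, nz, nt)."""
        return np.linalg.norm(self.data, axis=-1)

    def validate(self) -> None:
        if self.data.ndim != 5 or self.data.shape[-1] != 3:
            raise ValidationError(
                f"velocity data must have shape (nx, ny, nz, nt, 3), got {self.data.shape}"
            )
        if self.data.shape[3] < 2:
            raise ValidationError("a velocity field needs at least 2 cardiac frames")
        if self.spacing.shape != (3,) or not np.all(self.spacing > 0):
            raise ValidationError("spacing must be 3 positive voxel sizes (mm)")
        if not self.frame_duration > 0:
            raise ValidationError("frame_duration must be > 0 ms")
        if not self.venc > 0:
            raise ValidationError("venc must be > 0 m/s")
        if abs(self.frame_duration * self.n_frames - self.rr_interval) > self.frame_duration:
            raise ValidationError(
                "frame_duration × n_frames must match rr_interval within one frame"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("velocity data contains non-finite values")

    def copy(self) -> "VelocityField4D":
        return replace(self, data=self.data.copy(), spacing=self.spacing.copy())


@dataclass
class MagnitudeSeries:
    """Phase-contrast magnitude images on the same grid/frames as the velocities."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValidationError(
                f"magnitude data must have shape (nx, ny, nz, nt), got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValidationError("magnitude data must be finite and non-negative")

    def check_matches(self, field: VelocityField4D) -> None:
        if self.data.shape != field.data.shape[:4]:
            raise ValidationError(
                f"magnitude grid {self.data.shape} does not match velocity grid "
                f"{field.data.shape[:4]}"
            )


_MASK_NAMES = ("lv", "lvot", "aorta", "static_tissue")


@dataclass
class SegmentMaskSet:
    """Binary analysis masks (LV, LVOT, ascending aorta, static tissue) on the velocity grid."""

    lv: Optional[np.ndarray] = None
    lvot: Optional[np.ndarray] = None
    aorta: Optional[np.ndarray] = None
    static_tissue: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        shape = None
        for name in _MASK_NAMES:
            m = getattr(self, name)
            if m is None:
                continue
            m = np.asarray(m, dtype=bool)
            setattr(self, name, m)
            if m.ndim != 3:
                raise ValidationError(f"mask '{name}' must be 3-D")
            if shape is None:
                shape = m.shape
            elif m.shape != shape:
                raise ValidationError("all masks must share one grid shape")
        if self.lv is not None and self.static_tissue is not None:
            if np.any(self.lv & self.static_tissue):
                raise ValidationError("lv and static_tissue masks overlap")

    def check_matches(self, field: VelocityField4D) -> None:
        for name in _MASK_NAMES:
            m = getattr(self, name)
            if m is not None and m.shape != field.grid_shape:
                raise ValidationError(
                    f"mask '{name}' shape {m.shape} does not match velocity grid "
                    f"{field.grid_shape}"
                )

    def require(self, name: str) -> np.ndarray:
        m = getattr(self, name)
        if m is None or not m.any():
            raise ValidationError(f"analysis mask '{name}' is absent or empty")
        return m


@dataclass
class SubjectResult:
    """Per-subject haemodynamic summary (one cohort-table row).

    Kinetic-energy densities are stored numerically in J/m³, which is the
    scale the clinical literature prints (labelled mJ/m³ by convention there).
    Metrics that were not computed for a subject are ``None``.
    """

    subject_id: str = ""
    group: str = ""
    wss_aorta: Optional[float] = None          # Pa
    peak_velocity_lvot: Optional[float] = None  # m/s
    ke_lvot: Optional[float] = None             # J/m^3 (printed as mJ/m^3)
    ke_aorta: Optional[float] = None            # J/m^3 (printed as mJ/m^3)
    peak_systole_frame: Optional[int] = None
    av_forward: Optional[float] = None          # ml/beat
    av_backward: Optional[float] = None         # ml/beat
    mv_forward: Optional[float] = None          # ml/beat
    mv_backward: Optional[float] = None         # ml/beat
    dp_mean: Optional[float] = None             # mmHg
    dp_max: Optional[float] = None              # mmHg
    strain_lvot: Optional[float] = None         # %

    def __post_init__(self) -> None:
        for name in ("wss_aorta", "ke_lvot", "ke_aorta", "av_forward",
                     "av_backward", "mv_forward", "mv_backward"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "wss_aorta": self.wss_aorta,
            "peak_velocity_lvot": self.peak_velocity_lvot,
            "ke_lvot": self.ke_lvot,
            "ke_aorta": self.ke_aorta,
            "peak_systole_frame": self.peak_systole_frame,
            "av_forward": self.av_forward,
            "av_backward": self.av_backward,
            "mv_forward": self.mv_forward,
            "mv_backward": self.mv_backward,
            "dp_mean": self.dp_mean,
            "dp_max": self.dp_max,
            "strain_lvot": self.strain_lvot,
        }
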