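"""Analysis masks, wall surfaces and peak-systole timing.

Threshold segmentation of the PC-MRA stands in for manual segmentation;
supplied masks always take precedence when present.  Wall surfaces are
triangulated iso-surfaces of the binary mask (marching cubes on a lightly
smoothed copy, which removes voxel staircasing so surface position, area and
normals converge to the analytic shape) with inward unit normals and
per-point area weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.measure import label as cc_label
from skimage.measure import marching_cubes

from .config import AnalysisConfig
from .errors import BorderError, SegmentationError, ValidationError
from .fields import VelocityField4D
from .preprocess import PCMRA


def segment_threshold(pcmra: PCMRA, frac: float) -> np.ndarray:
    """Threshold the PC-MRA at ``frac × max`` and keep the largest component.

    Connectivity is 26-neighbourhood, tolerant of thin oblique vessels.
    """
    if not 0 < frac < 1:
        raise ValidationError("threshold fraction must lie in (0, 1)")
    peak = pcmra.data.max()
    if peak <= 0:
        raise SegmentationError("PC-MRA carries no signal; nothing to segment")
    raw = pcmra.data >= frac * peak
    if not raw.any():
        raise SegmentationError("threshold segmentation produced an empty mask")
    labels = cc_label(raw, connectivity=3)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


@dataclass
class WallSurface:
    """Triangulated wall surface: points (mm), inward unit normals, area weights (mm²)."""

    points: np.ndarray          # (P, 3)
    inward_normals: np.ndarray  # (P, 3), unit length
    area_weights: np.ndarray    # (P,), > 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.inward_normals = np.asarray(self.inward_normals, dtype=float)
        self.area_weights = np.asarray(self.area_weights, dtype=float)
        if len(self.points) == 0:
            raise ValidationError("wall surface has no points")
        norms = np.linalg.norm(self.inward_normals, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValidationError("inward normals must be unit length")
        if np.any(self.area_weights <= 0):
            raise ValidationError("area weights must be positive")

    @property
    def total_area(self) -> float:
        return float(self.area_weights.sum())


def extract_wall_surface(
    mask: np.ndarray,
    spacing,
    *,
    smooth_sigma: float = 1.0,
    drop_caps_axis: int | None = None,
    cap_margin_mm: float | None = None,
) -> WallSurface:
    """Iso-surface (level 0.5) of a binary mask with inward normals.

    The binary mask is smoothed with a Gaussian of ``smooth_sigma`` voxels
    before marching cubes, which places the 0.5 level at the 50 %-occupancy
    boundary of the digitized shape — i.e. on the underlying smooth surface —
    and yields well-behaved normals.  Structures too small to survive
    smoothing fall back to the raw binary iso-surface.  Per-point area
    weights are one third of each adjacent triangle's area.

    ``drop_caps_axis`` removes the artificial end-cap faces of an open tube
    segment (points near the mask's extremes along that axis whose normals
    are nearly axial); vessel segments cut from a volume have such caps, and
    wall quantities are only meaningful on the lateral wall.
    ``cap_margin_mm`` additionally excludes all points within that distance
    of the segment ends along the axis — smoothing rounds the cut edges and
    pinches the lateral wall inward over roughly 2σ, so wall-shear evaluation
    should stay clear of the ends.
    """
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    if not mask.any():
        raise ValidationError("cannot extract a surface from an empty mask")
    border = (
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )
    if border:
        raise BorderError(
            "mask touches the volume border; pad the volume before extracting "
            "a wall surface"
        )

    volume = mask.astype(float)
    if smooth_sigma > 0:
        smoothed = gaussian_filter(volume, sigma=smooth_sigma)
        if smoothed.max() <= 0.5:  # structure too small for this smoothing
            smoothed = volume
    else:
        smoothed = volume
    verts, faces, _, _ = marching_cubes(smoothed, level=0.5, spacing=tuple(spacing))

    # per-vertex area weights: 1/3 of each adjacent triangle
    tri = verts[faces]  # (F, 3, 3)
    tri_areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    weights = np.zeros(len(verts))
    np.add.at(weights, faces.ravel(), np.repeat(tri_areas / 3.0, 3))

    # inward normals from the smoothed occupancy gradient (occupancy rises inward)
    coords = (verts / spacing[None, :]).T
    grad = np.stack(
        [
            map_coordinates(np.gradient(smoothed, axis=a), coords, order=1,
                            mode="nearest")
            for a in range(3)
        ],
        axis=1,
    ) / spacing[None, :]
    norms = np.linalg.norm(grad, axis=1)
    ok = norms > 1e-12
    normals = np.zeros_like(grad)
    normals[ok] = grad[ok] / norms[ok, None]
    # degenerate gradient points carry no orientation information — drop them
    keep = ok & (weights > 0)

    if drop_caps_axis is not None:
        a = drop_caps_axis
        idx = np.nonzero(mask)[a]
        lo, hi = idx.min() * spacing[a], idx.max() * spacing[a]
        near_end = (verts[:, a] < lo + 1.5 * spacing[a]) | (
            verts[:, a] > hi - 0.5 * spacing[a]
        )
        axial = np.abs(normals[:, a]) > 0.8
        keep &= ~(near_end & axial)
        # also trim any remaining points on the very end planes
        keep &= (verts[:, a] > lo + 0.25 * spacing[a]) & (
            verts[:, a] < hi + 0.75 * spacing[a]
        )
        if cap_margin_mm is not None:
            keep &= (verts[:, a] > lo + cap_margin_mm) & (
                verts[:, a] < hi - cap_margin_mm
            )

    if not keep.any():
        raise ValidationError("surface extraction left no usable points")
    return WallSurface(
        points=verts[keep],
        inward_normals=normals[keep],
        area_weights=weights[keep],
    )


def analytic_cylinder_surface(
    radius_mm: float,
    z_range_mm: tuple[float, float],
    center_xy_mm: tuple[float, float],
    *,
    n_theta: int = 48,
    n_z: int = 12,
) -> WallSurface:
    """Exact lateral surface of a cylinder (axis along z), for oracle tests.

    Points lie exactly on r = R with exact inward radial normals and uniform
    area weights summing to 2πR·L.
    """
    z0, z1 = z_range_mm
    theta = (np.arange(n_theta) + 0.5) * 2.0 * math.pi / n_theta
    z = np.linspace(z0, z1, n_z)
    tt, zz = np.meshgrid(theta, z, indexing="ij")
    cx, cy = center_xy_mm
    points = np.stack(
        [cx + radius_mm * np.cos(tt).ravel(),
         cy + radius_mm * np.sin(tt).ravel(),
         zz.ravel()],
        axis=1,
    )
    normals = np.stack(
        [-np.cos(tt).ravel(), -np.sin(tt).ravel(), np.zeros(tt.size)], axis=1
    )
    area = 2.0 * math.pi * radius_mm * (z1 - z0)
    weights = np.full(len(points), area / len(points))
    return WallSurface(points=points, inward_normals=normals, area_weights=weights)


def first_half_frames(n_frames: int) -> int:
    """Number of frames in the 'first half of the cardiac cycle' (⌈n/2⌉)."""
    return (n_frames + 1) // 2


def find_peak_systole(field: VelocityField4D, lv_mask: np.ndarray) -> int:
    """Frame with the highest mean LV speed within the first half of the cycle.

    Mean speed is the unweighted arithmetic mean of voxel ‖v‖₂ inside the LV
    mask; ties resolve to the earliest frame.
    """
    lv_mask = np.asarray(lv_mask, dtype=bool)
    if lv_mask.shape != field.grid_shape:
        raise ValidationError("LV mask shape does not match the velocity grid")
    if not lv_mask.any():
        raise ValidationError("LV mask is empty")
    half = first_half_frames(field.n_frames)
    mean_speed = field.speed()[lv_mask].mean(axis=0)[:half]
    return int(np.argmax(mean_speed))


def save_surface_ply(surface: WallSurface, path: str | Path) -> Path:
    """Write surface points + inward normals as ASCII PLY (point cloud)."""
    path = Path(path)
    p, n = surface.points, surface.inward_normals
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {len(p)}\n"
            "property float x\nproperty float y\nproperty float z\n"
            "property float nx\nproperty float ny\nproperty float nz\n"
            "end_header\n"
        )
        for (x, y, z), (nx, ny, nz) in zip(p, n):
            fh.write(f"{x:.4f} {y:.4f} {z:.4f} {nx:.4f} {ny:.4f} {nz:.4f}\n")
    return path
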