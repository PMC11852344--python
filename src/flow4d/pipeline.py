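"""Per-subject analysis pipeline: preprocessing → masks → timing → metrics.

This is the glue every entry point (analysis scripts, CLI, acceptance runs)
shares.  Supplied segmentation masks take precedence; threshold segmentation
of the PC-MRA is the fallback when none are given.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .config import AnalysisConfig
from .errors import ValidationError
from .fields import MagnitudeSeries, SegmentMaskSet, SubjectResult, VelocityField4D
from .hemodynamics import (
    bernoulli_gradient,
    compute_wss,
    kinetic_energy_density,
    longitudinal_strain,
    peak_velocity,
)
from .preprocess import compute_pcmra, preprocess_field
from .segmentation import (
    extract_wall_surface,
    find_peak_systole,
    first_half_frames,
    segment_threshold,
)
from .valve_flow import ValvePlaneTrack, transvalvular_flow

logger = logging.getLogger(__name__)

#: Fraction of the peak mean LV speed above which a first-half frame counts
#: as systolic (used for Bernoulli averaging when no waveform is known).
SYSTOLE_SPEED_FRAC = 0.25

#: Keep wall-shear evaluation this far (mm) from the artificial segment ends.
WSS_CAP_MARGIN_MM = 6.0


def systolic_frames(field: VelocityField4D, lv_mask: np.ndarray) -> list[int]:
    """First-half frames whose mean LV speed exceeds 25 % of the peak frame's."""
    lv_mask = np.asarray(lv_mask, dtype=bool)
    half = first_half_frames(field.n_frames)
    mean_speed = field.speed()[lv_mask].mean(axis=0)[:half]
    thr = SYSTOLE_SPEED_FRAC * mean_speed.max()
    return [int(i) for i in np.nonzero(mean_speed >= thr)[0]]


def analyze_subject(
    field: VelocityField4D,
    magnitude: Optional[MagnitudeSeries],
    masks: Optional[SegmentMaskSet],
    config: Optional[AnalysisConfig] = None,
    *,
    subject_id: str = "",
    group: str = "",
    av_track: Optional[ValvePlaneTrack] = None,
    mv_track: Optional[ValvePlaneTrack] = None,
    contour_lengths: Optional[Sequence[float]] = None,
    do_preprocess: bool = True,
    tube_axis: int = 2,
) -> SubjectResult:
    """Run the full measurement chain on one subject dataset.

    Metrics whose inputs (mask, track, series) are absent are left ``None``.
    All peak-systolic metrics are evaluated at the frame found by
    :func:`find_peak_systole` on the LV mask.
    """
    config = config or AnalysisConfig()
    static = masks.static_tissue if masks is not None else None
    if do_preprocess:
        field, _ = preprocess_field(field, config, static_mask=static)

    if masks is None or masks.lv is None:
        if magnitude is None:
            raise ValidationError(
                "need either an LV mask or magnitude images to segment from"
            )
        pcmra = compute_pcmra(magnitude, field)
        lumen = segment_threshold(pcmra, config.pcmra_threshold_frac)
        masks = SegmentMaskSet(lv=lumen, lvot=lumen, aorta=lumen,
                               static_tissue=static)
        logger.info("no masks supplied; threshold segmentation used for all")

    peak_frame = find_peak_systole(field, masks.require("lv"))
    result = SubjectResult(subject_id=subject_id, group=group,
                           peak_systole_frame=peak_frame)

    if masks.aorta is not None and masks.aorta.any():
        surface = extract_wall_surface(
            masks.aorta, field.spacing, drop_caps_axis=tube_axis,
            cap_margin_mm=WSS_CAP_MARGIN_MM,
        )
        result.wss_aorta = compute_wss(field, peak_frame, surface, config).summary
        result.ke_aorta = kinetic_energy_density(
            field, peak_frame, masks.aorta, config
        )

    if masks.lvot is not None and masks.lvot.any():
        result.peak_velocity_lvot = peak_velocity(field, peak_frame, masks.lvot)
        result.ke_lvot = kinetic_energy_density(field, peak_frame, masks.lvot, config)
        sys_frames = systolic_frames(field, masks.require("lv"))
        vpeak_series = [
            peak_velocity(field, t, masks.lvot) for t in range(field.n_frames)
        ]
        result.dp_mean, result.dp_max = bernoulli_gradient(vpeak_series, sys_frames)

    if av_track is not None:
        flow = transvalvular_flow(field, av_track)
        result.av_forward, result.av_backward = flow.forward, flow.backward
    if mv_track is not None:
        flow = transvalvular_flow(field, mv_track)
        result.mv_forward, result.mv_backward = flow.forward, flow.backward

    if contour_lengths is not None:
        result.strain_lvot = longitudinal_strain(contour_lengths)

    return result
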