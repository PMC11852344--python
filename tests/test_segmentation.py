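"""Threshold segmentation, wall-surface extraction and peak-systole timing."""

import math

import numpy as np
import pytest

from flow4d import (
    VelocityField4D,
    extract_wall_surface,
    find_peak_systole,
    segment_threshold,
)
from flow4d.errors import BorderError, SegmentationError, ValidationError
from flow4d.phantom import make_tube_phantom, tube_spec
from flow4d.preprocess import PCMRA, compute_pcmra
from flow4d.segmentation import analytic_cylinder_surface, first_half_frames


def _pcmra(data, spacing=(2.0, 2.0, 2.0)):
    return PCMRA(data=np.asarray(data, float), spacing=np.asarray(spacing))


class TestThresholdSegmentation:
    def test_two_valued_volume_thresholds_exactly(self):
        data = np.zeros((6, 6, 6))
        data[2:4, 2:4, 2:4] = 100.0
        mask = segment_threshold(_pcmra(data), 0.3)
        assert np.array_equal(mask, data == 100.0)

    def test_mask_shrinks_monotonically_with_fraction(self):
        x, y, z = np.meshgrid(*(np.linspace(-1, 1, 20),) * 3, indexing="ij")
        smooth = np.exp(-(x**2 + y**2 + z**2))
        lo = segment_threshold(_pcmra(smooth), 0.5)
        hi = segment_threshold(_pcmra(smooth), 0.999)
        assert hi.sum() < lo.sum()
        assert (hi & ~lo).sum() == 0  # nested

    def test_keeps_largest_connected_component_only(self):
        data = np.zeros((10, 10, 10))
        data[1:5, 1:5, 1:5] = 100.0   # 64 voxels
        data[7:9, 7:9, 7:9] = 100.0   # 8 voxels, disconnected
        mask = segment_threshold(_pcmra(data), 0.5)
        assert mask.sum() == 64
        assert not mask[7:9, 7:9, 7:9].any()

    def test_plug_flow_phantom_lumen_dice(self, cfg, waveform):
        """A blunt (plug-like) jet segments to the true lumen at half maximum."""
        spec = tube_spec(12.5, 1.5 * waveform, profile_exponent=20.0,
                         noise_frac=0.02, seed=4)
        field, mag, masks, _ = make_tube_phantom(spec, cfg)
        seg = segment_threshold(compute_pcmra(mag, field), 0.5)
        dice = 2 * (seg & masks.lv).sum() / (seg.sum() + masks.lv.sum())
        assert dice >= 0.9

    def test_empty_result_is_segmentation_error(self):
        with pytest.raises((SegmentationError, ValidationError)):
            segment_threshold(_pcmra(np.zeros((4, 4, 4))), 0.5)


class TestWallSurface:
    def test_cylinder_lateral_area_within_ten_percent(self, cfg, waveform):
        spec = tube_spec(10.0, 1.0 * waveform, length=40.0)
        _, _, masks, _ = make_tube_phantom(spec, cfg)
        surf = extract_wall_surface(masks.aorta, spec.spacing, drop_caps_axis=2)
        zspan = surf.points[:, 2].max() - surf.points[:, 2].min()
        assert surf.total_area == pytest.approx(2 * math.pi * 10.0 * zspan, rel=0.10)

    def test_area_error_shrinks_with_refinement(self, cfg, waveform):
        def rel_err(spacing):
            spec = tube_spec(10.0, 1.0 * waveform, length=40.0, spacing=spacing)
            _, _, masks, _ = make_tube_phantom(spec, cfg)
            surf = extract_wall_surface(masks.aorta, spec.spacing, drop_caps_axis=2)
            zspan = surf.points[:, 2].max() - surf.points[:, 2].min()
            return abs(surf.total_area / (2 * math.pi * 10.0 * zspan) - 1)

        coarse = rel_err((2.4, 2.4, 2.5))
        fine = rel_err((1.2, 1.2, 1.25))
        assert fine < coarse
        assert fine < 0.05

    def test_sphere_normals_point_inward(self):
        x, y, z = np.meshgrid(*(np.arange(16) - 7.5,) * 3, indexing="ij")
        mask = np.sqrt(x**2 + y**2 + z**2) < 5.5
        surf = extract_wall_surface(mask, (1.0, 1.0, 1.0))
        centre = np.array([7.5, 7.5, 7.5])
        outward = surf.points - centre
        outward /= np.linalg.norm(outward, axis=1, keepdims=True)
        dots = np.einsum("ij,ij->i", surf.inward_normals, outward)
        assert np.all(dots < 0)

    def test_single_voxel_yields_closed_inward_oriented_surface(self):
        mask = np.zeros((7, 7, 7), bool)
        mask[3, 3, 3] = True
        surf = extract_wall_surface(mask, (1.0, 1.0, 1.0))
        assert len(surf.points) >= 4
        assert surf.total_area > 0
        towards_centre = np.array([3.0, 3.0, 3.0]) - surf.points
        towards_centre /= np.linalg.norm(towards_centre, axis=1, keepdims=True)
        assert np.all(np.einsum("ij,ij->i", surf.inward_normals, towards_centre) > 0)

    def test_mask_on_border_raises(self):
        mask = np.ones((6, 6, 6), bool)
        with pytest.raises(BorderError):
            extract_wall_surface(mask, (1.0, 1.0, 1.0))

    def test_unit_normals_and_positive_weights(self, cfg, waveform):
        spec = tube_spec(10.0, waveform)
        _, _, masks, _ = make_tube_phantom(spec, cfg)
        surf = extract_wall_surface(masks.aorta, spec.spacing, drop_caps_axis=2)
        assert np.allclose(np.linalg.norm(surf.inward_normals, axis=1), 1.0,
                           atol=1e-6)
        assert np.all(surf.area_weights > 0)

    def test_analytic_cylinder_surface_is_exact(self):
        surf = analytic_cylinder_surface(10.0, (0.0, 40.0), (0.0, 0.0))
        assert surf.total_area == pytest.approx(2 * math.pi * 10 * 40, rel=1e-9)
        r = np.hypot(surf.points[:, 0], surf.points[:, 1])
        assert np.allclose(r, 10.0)


class TestPeakSystole:
    def _field_with_lv_speeds(self, speeds):
        nt = len(speeds)
        data = np.zeros((4, 4, 4, nt, 3))
        data[1:3, 1:3, 1:3, :, 2] = np.asarray(speeds)
        return VelocityField4D(
            data=data,
            spacing=np.ones(3),
            frame_duration=600.0 / nt,
            venc=2.0,
            rr_interval=600.0,
        ), np.s_[1:3, 1:3, 1:3]

    def test_first_half_restriction_excludes_late_peak(self):
        field, sl = self._field_with_lv_speeds([0.2, 0.8, 0.5, 0.3, 0.9, 0.1])
        mask = np.zeros((4, 4, 4), bool)
        mask[sl] = True
        # frame 4 has the global peak but lies in the second half
        assert find_peak_systole(field, mask) == 1

    def test_constant_series_ties_to_frame_zero(self):
        field, sl = self._field_with_lv_speeds([0.5, 0.5, 0.5, 0.5])
        mask = np.zeros((4, 4, 4), bool)
        mask[sl] = True
        assert find_peak_systole(field, mask) == 0

    def test_phantom_waveform_peak_found(self, cfg, waveform):
        spec = tube_spec(10.0, 1.5 * waveform, noise_frac=0.02, seed=3)
        field, _, masks, truth = make_tube_phantom(spec, cfg)
        assert find_peak_systole(field, masks.lv) == truth.peak_systole_frame_true

    def test_result_always_in_first_half(self, cfg):
        rng = np.random.default_rng(0)
        for nt in (5, 6, 24):
            data = rng.normal(0, 1, size=(4, 4, 4, nt, 3))
            field = VelocityField4D(
                data=data, spacing=np.ones(3), frame_duration=1000.0 / nt,
                venc=5.0, rr_interval=1000.0,
            )
            mask = np.ones((4, 4, 4), bool)
            assert find_peak_systole(field, mask) < first_half_frames(nt)

    def test_empty_mask_rejected(self, small_field):
        with pytest.raises(ValidationError):
            find_peak_systole(small_field, np.zeros((6, 6, 6), bool))
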