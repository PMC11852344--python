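"""Wall shear stress, kinetic energy, peak velocity, Bernoulli and strain."""

import numpy as np
import pytest

from flow4d import (
    VelocityField4D,
    bernoulli_gradient,
    compute_wss,
    kinetic_energy_density,
    longitudinal_strain,
    peak_velocity,
)
from flow4d.errors import SurfaceCoverageError, ValidationError
from flow4d.phantom import make_tube_phantom, tube_spec
from flow4d.segmentation import analytic_cylinder_surface, extract_wall_surface
import flow4d.phantom as ph


def _cyl_surface(spec):
    _, z0, z1 = ph._tube_geometry(spec)
    dx, dy, dz = spec.spacing
    nx, ny, _ = spec.shape
    return analytic_cylinder_surface(
        spec.radius, ((z0 + 2) * dz, (z1 - 3) * dz),
        ((nx // 2) * dx, (ny // 2) * dy),
    )


class TestWSS:
    def test_parabolic_oracle_on_exact_surface(self, cfg, parabolic_phantom):
        spec, field, _, _, truth = parabolic_phantom
        wss = compute_wss(field, truth.peak_systole_frame_true,
                          _cyl_surface(spec), cfg)
        assert wss.summary == pytest.approx(0.64, rel=0.10)

    def test_zero_field_gives_zero_wss(self, cfg, parabolic_phantom):
        spec, field, _, _, _ = parabolic_phantom
        zero = VelocityField4D(
            data=np.zeros_like(field.data), spacing=field.spacing,
            frame_duration=field.frame_duration, venc=field.venc,
            rr_interval=field.rr_interval,
        )
        wss = compute_wss(zero, 5, _cyl_surface(spec), cfg)
        assert np.all(wss.magnitudes == 0.0)
        assert wss.summary == 0.0

    def test_linear_in_viscosity(self, cfg, parabolic_phantom):
        spec, field, _, _, truth = parabolic_phantom
        surf = _cyl_surface(spec)
        frame = truth.peak_systole_frame_true
        base = compute_wss(field, frame, surf, cfg)
        doubled = compute_wss(field, frame, surf, cfg.replace(mu=2 * cfg.mu))
        assert np.allclose(doubled.magnitudes, 2 * base.magnitudes, rtol=1e-12)

    def test_linear_in_peak_velocity(self, cfg, waveform):
        surfs = {}
        for scale in (1.0, 1.5):
            spec = tube_spec(10.0, scale * waveform, profile_exponent=2.0)
            field, _, _, truth = make_tube_phantom(spec, cfg)
            surfs[scale] = compute_wss(
                field, truth.peak_systole_frame_true, _cyl_surface(spec), cfg
            ).summary
        assert surfs[1.5] == pytest.approx(1.5 * surfs[1.0], rel=1e-6)

    def test_error_shrinks_with_grid_refinement(self, cfg, waveform):
        def rel_err(spacing):
            spec = tube_spec(10.0, 1.0 * waveform, profile_exponent=2.0,
                             spacing=spacing)
            field, _, masks, truth = make_tube_phantom(spec, cfg)
            surf = extract_wall_surface(masks.aorta, spec.spacing,
                                        drop_caps_axis=2, cap_margin_mm=6.0)
            got = compute_wss(field, truth.peak_systole_frame_true, surf, cfg)
            return abs(got.summary / truth.wss_true - 1)

        assert rel_err((1.2, 1.2, 1.25)) < rel_err((2.4, 2.4, 2.5))

    def test_summary_is_area_weighted_mean(self, cfg, parabolic_phantom):
        spec, field, _, _, truth = parabolic_phantom
        wss = compute_wss(field, truth.peak_systole_frame_true,
                          _cyl_surface(spec), cfg)
        expected = np.sum(wss.area_weights * wss.magnitudes) / np.sum(wss.area_weights)
        assert wss.summary == pytest.approx(expected, rel=1e-12)

    def test_surface_outside_volume_raises_coverage_error(self, cfg, small_field):
        surf = analytic_cylinder_surface(30.0, (2.0, 8.0), (6.0, 6.0))
        with pytest.raises(SurfaceCoverageError):
            compute_wss(small_field, 0, surf, cfg)


class TestPeakVelocity:
    def test_vector_norm_of_uniform_field(self):
        data = np.zeros((4, 4, 4, 2, 3))
        data[..., 0] = 0.3
        data[..., 1] = 0.4
        field = VelocityField4D(data=data, spacing=np.ones(3),
                                frame_duration=200.0, venc=2.0, rr_interval=400.0)
        assert peak_velocity(field, 0, np.ones((4, 4, 4), bool)) == pytest.approx(0.5)

    def test_zero_field(self):
        field = VelocityField4D(data=np.zeros((4, 4, 4, 2, 3)), spacing=np.ones(3),
                                frame_duration=200.0, venc=2.0, rr_interval=400.0)
        assert peak_velocity(field, 1, np.ones((4, 4, 4), bool)) == 0.0

    def test_noise_free_phantom_peak_is_exact(self, cfg, waveform):
        spec = tube_spec(10.0, 1.53 * waveform, profile_exponent=2.0)
        field, _, masks, truth = make_tube_phantom(spec, cfg)
        vp = peak_velocity(field, truth.peak_systole_frame_true, masks.lv)
        assert vp == pytest.approx(1.53, abs=1e-12)

    def test_peak_bounds_mean_speed(self, cfg, waveform):
        spec = tube_spec(10.0, 1.5 * waveform, noise_frac=0.02, seed=7)
        field, _, masks, truth = make_tube_phantom(spec, cfg)
        frame = truth.peak_systole_frame_true
        vp = peak_velocity(field, frame, masks.lv)
        assert vp >= field.speed()[masks.lv][:, frame].mean()

    def test_empty_mask_rejected(self, small_field):
        with pytest.raises(ValidationError):
            peak_velocity(small_field, 0, np.zeros((6, 6, 6), bool))


class TestKineticEnergy:
    def test_uniform_speed_closed_form(self, cfg):
        data = np.zeros((4, 4, 4, 2, 3))
        data[..., 2] = 1.0
        field = VelocityField4D(data=data, spacing=np.ones(3),
                                frame_duration=200.0, venc=2.0, rr_interval=400.0)
        ke = kinetic_energy_density(field, 0, np.ones((4, 4, 4), bool), cfg)
        assert ke == pytest.approx(530.0)

    def test_parabolic_phantom_matches_analytic_factor(self, cfg, waveform):
        spec = tube_spec(12.5, 1.53 * waveform, profile_exponent=2.0)
        field, _, masks, truth = make_tube_phantom(spec, cfg)
        ke = kinetic_energy_density(field, truth.peak_systole_frame_true,
                                    masks.lv, cfg)
        assert ke == pytest.approx(413.6, rel=0.05)

    def test_zero_field(self, cfg):
        field = VelocityField4D(data=np.zeros((4, 4, 4, 2, 3)), spacing=np.ones(3),
                                frame_duration=200.0, venc=2.0, rr_interval=400.0)
        assert kinetic_energy_density(field, 0, np.ones((4, 4, 4), bool), cfg) == 0.0

    def test_invariant_under_rigid_rotation(self, cfg, small_field):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        mask = np.ones((6, 6, 6), bool)
        before = kinetic_energy_density(small_field, 2, mask, cfg)
        rotated = VelocityField4D(
            data=small_field.data @ rot.T, spacing=small_field.spacing,
            frame_duration=small_field.frame_duration, venc=small_field.venc,
            rr_interval=small_field.rr_interval,
        )
        after = kinetic_energy_density(rotated, 2, mask, cfg)
        assert after == pytest.approx(before, rel=1e-12)


class TestBernoulli:
    @pytest.mark.parametrize(
        "series, frames, dp_mean, dp_max",
        [
            ([1.0, 1.0, 1.0], [0, 1, 2], 4.0, 4.0),
            ([1.63], [0], 4 * 1.63**2, 4 * 1.63**2),
            ([1.0, 2.0], [0, 1], 10.0, 16.0),
        ],
    )
    def test_simplified_bernoulli_values(self, series, frames, dp_mean, dp_max):
        got_mean, got_max = bernoulli_gradient(series, frames)
        assert got_mean == pytest.approx(dp_mean)
        assert got_max == pytest.approx(dp_max)

    def test_max_never_below_mean(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.uniform(0.1, 3.0, size=8)
            dp_mean, dp_max = bernoulli_gradient(v, range(8))
            assert dp_max >= dp_mean

    def test_empty_systole_rejected(self):
        with pytest.raises(ValidationError):
            bernoulli_gradient([1.0, 2.0], [])


class TestStrain:
    @pytest.mark.parametrize(
        "lengths, expected",
        [
            ([50, 47, 44, 46, 50], -12.0),
            ([40, 40, 40], 0.0),
            ([40, 44], 0.0),  # lengthening only: minimum stays at frame 0
        ],
    )
    def test_contour_strain(self, lengths, expected):
        assert longitudinal_strain(lengths) == pytest.approx(expected)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValidationError):
            longitudinal_strain([50, 0, 40])
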