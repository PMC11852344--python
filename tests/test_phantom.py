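"""Closed-form oracles, calibration inverses and the phantom generator."""

import numpy as np
import pytest

from flow4d import AnalysisConfig
from flow4d.errors import (
    DomainError,
    InfeasibleTargetError,
    ResolutionError,
)
from flow4d.phantom import (
    calibrate_segment,
    calibrate_stroke_volume,
    calibrate_velocity_ke,
    default_waveform,
    draw_matched_targets,
    make_cohort,
    make_tube_phantom,
    mean_velocity_factor,
    phantom_truth,
    poiseuille_wall_shear,
    powerlaw_mean_ke_density,
    profile_shape_factor,
    tube_spec,
)


class TestClosedForms:
    def test_parabolic_wall_shear(self):
        assert poiseuille_wall_shear(1.0, 0.01, 0.0032, 2) == pytest.approx(0.64)

    def test_wall_shear_rejects_nonpositive_input(self):
        with pytest.raises(DomainError):
            poiseuille_wall_shear(0.0, 0.01, 0.0032, 2)

    def test_parabolic_ke_density(self):
        # g(2) = 1/3 → ½·1060/3
        assert powerlaw_mean_ke_density(1.0, 1060, 2) == pytest.approx(
            1060 / 6, rel=1e-12
        )

    def test_plug_flow_ke_limit(self):
        # n → ∞: the profile approaches plug flow, g → 1, KE → ½ρv²
        assert powerlaw_mean_ke_density(1.0, 1060, 1e6) == pytest.approx(530.0, rel=1e-4)

    def test_ke_density_at_table_peak_velocity(self):
        assert powerlaw_mean_ke_density(1.53, 1060, 2) == pytest.approx(413.6, abs=0.1)

    def test_shape_factor_monotone_increasing(self):
        n = np.linspace(1, 20, 200)
        g = np.array([profile_shape_factor(x) for x in n])
        assert np.all(np.diff(g) > 0)
        assert g[0] == pytest.approx(1 / 6)


class TestCalibration:
    def test_aorta_table_column_inversion(self, cfg):
        vmax, n = calibrate_segment(0.73, 480.8, 0.0125, cfg)
        assert n == pytest.approx(1.53, abs=0.01)
        assert vmax == pytest.approx(1.86, abs=0.01)
        # plugging back into the closed form reproduces the WSS target
        assert poiseuille_wall_shear(vmax, 0.0125, cfg.mu, n) == pytest.approx(
            0.73, rel=1e-2
        )

    def test_inverse_of_forward_identity(self, cfg):
        wss = poiseuille_wall_shear(1.0, 0.01, cfg.mu, 2.0)
        ke = powerlaw_mean_ke_density(1.0, cfg.rho, 2.0)
        vmax, n = calibrate_segment(wss, ke, 0.01, cfg)
        assert vmax == pytest.approx(1.0, rel=1e-6)
        assert n == pytest.approx(2.0, rel=1e-6)

    def test_velocity_ke_inverse_of_forward(self, cfg):
        ke = powerlaw_mean_ke_density(1.5, cfg.rho, 3.7)
        vmax, n = calibrate_velocity_ke(1.5, ke, cfg)
        assert (vmax, n) == (pytest.approx(1.5), pytest.approx(3.7, rel=1e-6))

    def test_infeasible_targets_raise_with_bound(self, cfg):
        with pytest.raises(InfeasibleTargetError):
            calibrate_segment(1000.0, 0.001, 0.0125, cfg)

    def test_stroke_volume_amplitude_scales_linearly(self, waveform):
        v1 = calibrate_stroke_volume(45.0, 0.0125, waveform, 1000 / 24)
        v2 = calibrate_stroke_volume(90.0, 0.0125, waveform, 1000 / 24)
        assert v2 == pytest.approx(2 * v1, rel=1e-12)


class TestWaveform:
    def test_peak_frame_and_flow_free_diastole(self):
        w = default_waveform(24, peak_frame=5, systole_end=11)
        assert int(np.argmax(w)) == 5
        assert w.max() == pytest.approx(1.0)
        assert np.all(w[11:] == 0)


class TestTubePhantom:
    def test_uncorrupted_voxels_equal_analytic_profile(self, cfg, waveform):
        spec = tube_spec(10.0, 1.2 * waveform, profile_exponent=2.0)
        field, _, masks, truth = make_tube_phantom(spec, cfg)
        nx, ny, _ = spec.shape
        dx, dy, _ = spec.spacing
        # centre voxel sits on the axis: velocity = vmax(t) exactly
        ci, cj = nx // 2, ny // 2
        zmid = spec.shape[2] // 2
        assert np.array_equal(
            field.data[ci, cj, zmid, :, 2], 1.2 * waveform
        )
        # an off-axis lumen voxel matches the profile exactly
        r = 2 * dx
        expected = 1.2 * waveform * (1 - (r / 10.0) ** 2)
        assert np.allclose(field.data[ci + 2, cj, zmid, :, 2], expected, atol=1e-15)
        # in-plane components are exactly zero without corruption
        assert np.all(field.data[..., :2] == 0)

    def test_same_seed_bit_identical(self, cfg, waveform):
        spec = tube_spec(10.0, waveform, noise_frac=0.03, alias=True, seed=5)
        f1, m1, k1, t1 = make_tube_phantom(spec, cfg)
        f2, m2, k2, t2 = make_tube_phantom(spec, cfg)
        assert np.array_equal(f1.data, f2.data)
        assert np.array_equal(m1.data, m2.data)

    def test_truth_independent_of_noise_seed(self, cfg, waveform):
        t1 = phantom_truth(tube_spec(10.0, waveform, noise_frac=0.05, seed=1), cfg)
        t2 = phantom_truth(tube_spec(10.0, waveform, noise_frac=0.05, seed=2), cfg)
        assert t1.wss_true == t2.wss_true
        assert t1.stroke_volume_true == t2.stroke_volume_true

    def test_waveform_peak_sets_truth_peak_frame(self, cfg):
        w = default_waveform(24, peak_frame=5)
        spec = tube_spec(10.0, 1.5 * w)
        _, _, _, truth = make_tube_phantom(spec, cfg)
        assert truth.peak_systole_frame_true == 5

    def test_corruptions_apply_in_noise_offset_wrap_order(self, cfg, waveform):
        coeffs = np.zeros((3, 10))
        coeffs[2, 0] = 0.4
        kw = dict(profile_exponent=2.0, venc=1.5, seed=3)
        clean, *_ = make_tube_phantom(tube_spec(10.0, 1.7 * waveform, **kw), cfg)
        noisy, *_ = make_tube_phantom(
            tube_spec(10.0, 1.7 * waveform, noise_frac=0.02, **kw), cfg
        )
        full, *_ = make_tube_phantom(
            tube_spec(
                10.0, 1.7 * waveform, noise_frac=0.02, offset_coeffs=coeffs,
                alias=True, **kw,
            ),
            cfg,
        )
        from flow4d.phantom import wrap_velocity

        noise = noisy.data - clean.data
        expected = wrap_velocity(clean.data + noise + coeffs[:, 0][None, None, None, None, :] * 0
                                 + np.array([0, 0, 0.4]), 1.5)
        assert np.allclose(full.data, expected, atol=1e-12)
        # disabling all corruption yields the pure analytic field
        again, *_ = make_tube_phantom(tube_spec(10.0, 1.7 * waveform, **kw), cfg)
        assert np.array_equal(again.data, clean.data)

    def test_underresolved_tube_rejected(self, waveform):
        with pytest.raises(ResolutionError):
            tube_spec(5.0, waveform)  # radius < 3 voxels at 2.4 mm

    def test_stroke_volume_truth_closed_form(self, cfg, waveform):
        spec = tube_spec(12.5, 1.0 * waveform, profile_exponent=2.0)
        truth = phantom_truth(spec, cfg)
        area = np.pi * 0.0125**2
        sv = (area * 1.0 * waveform * mean_velocity_factor(2.0)
              * (spec.frame_duration / 1000)).sum() * 1e6
        assert truth.stroke_volume_true == pytest.approx(sv, rel=1e-12)


class TestCohort:
    def test_zero_sd_targets_give_identical_truths_at_group_mean(self, cfg):
        targets = {"vpeak_lvot": (1.25, 0.0), "ke_lvot": (345.4, 0.0)}
        subjects = make_cohort(
            "healthy_control", 3, cfg, segments=("lvot",), seed=0,
            targets=targets, noise_frac=0.0, offsets=False, alias=False,
        )
        vps = [s.true_targets["vpeak_lvot"] for s in subjects]
        assert vps == [1.25] * 3
        kes = [s.true_targets["ke_lvot"] for s in subjects]
        assert kes == [345.4] * 3

    def test_drawn_targets_moment_match_the_column(self, cfg):
        subjects = make_cohort("isolated_myectomy", 3, cfg,
                               segments=("aorta",), seed=42)
        wss = np.array([s.true_targets["wss_aorta"] for s in subjects])
        assert wss.mean() == pytest.approx(0.73, rel=1e-9)
        assert wss.std(ddof=1) == pytest.approx(0.1, rel=1e-9)

    def test_fixed_seed_reproduces_cohort(self, cfg):
        a = make_cohort("myectomy_amvle", 2, cfg, segments=("lvot",), seed=9)
        b = make_cohort("myectomy_amvle", 2, cfg, segments=("lvot",), seed=9)
        for sa, sb in zip(a, b):
            assert sa.true_targets == sb.true_targets
            assert np.array_equal(
                sa.segments["lvot"].field.data, sb.segments["lvot"].field.data
            )

    def test_healthy_cohort_mean_peak_velocity_matches_table(self, cfg):
        subjects = make_cohort("healthy_control", 3, cfg, segments=("lvot",), seed=1)
        mean_vp = np.mean([s.true_targets["vpeak_lvot"] for s in subjects])
        assert mean_vp == pytest.approx(1.25)


class TestMatchedDraws:
    def test_sample_moments_exact(self):
        rng = np.random.default_rng(3)
        x = draw_matched_targets(rng, 10.0, 2.0, 5)
        assert x.mean() == pytest.approx(10.0)
        assert x.std(ddof=1) == pytest.approx(2.0)
        assert np.all(x > 0)

    def test_degenerate_cases(self):
        rng = np.random.default_rng(3)
        assert np.array_equal(draw_matched_targets(rng, 5.0, 0.0, 3), [5.0] * 3)
        assert np.array_equal(draw_matched_targets(rng, 5.0, 2.0, 1), [5.0])
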