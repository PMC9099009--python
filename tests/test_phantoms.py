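"""Phantom generator: analytic ground truths, rasterisation, determinism."""
import math

import numpy as np
import pytest

import tortuflow as tf
from tortuflow.errors import PhantomSpecError


class TestMakeCurve:
    @pytest.mark.parametrize(
        "family, params, expect",
        [
            ("straight", {"length": 100.0},
             dict(al=100.0, dl=100.0, ti=1.0, bl=0.0, n=0)),
            ("semicircle", {"radius": 20.0},
             dict(al=math.pi * 20, dl=40.0, ti=math.pi / 2, bl=20.0, n=0)),
            ("helix", {"radius": 10.0, "pitch": 20.0, "n_turns": 2},
             dict(al=2 * math.hypot(2 * math.pi * 10, 20), dl=40.0, n=0)),
        ],
    )
    def test_closed_form_truths(self, family, params, expect):
        ct = tf.make_curve(tf.CurveSpec(family, params))
        assert ct.al_true == pytest.approx(expect["al"], rel=1e-9)
        assert ct.dl_true == pytest.approx(expect["dl"], rel=1e-6)
        if "ti" in expect:
            assert ct.ti_true == pytest.approx(expect["ti"], rel=1e-6)
        if "bl" in expect:
            assert ct.bl_true == pytest.approx(expect["bl"], abs=1e-3)
        assert ct.n_true == expect["n"]

    def test_sinusoid_truth_against_quadrature_and_sign_change_oracle(self):
        A, lam, n_per = 10.0, 50.0, 2.0
        ct = tf.make_curve(tf.CurveSpec("sinusoid",
                                        {"amplitude": A, "wavelength": lam, "n_periods": n_per}))
        # independent trapezoid oracle for the arc length
        k = 2 * math.pi / lam
        z = np.linspace(0, lam * n_per, 400001)
        al_oracle = np.trapezoid(np.sqrt(1 + (A * k * np.cos(k * z)) ** 2), z)
        assert ct.al_true == pytest.approx(al_oracle, rel=1e-7)
        # interior zero crossings of the second derivative on dense samples
        d2 = -A * k * k * np.sin(k * z[1:-1])
        signs = np.sign(d2[np.abs(d2) > 1e-12])
        n_oracle = int(np.sum(signs[1:] * signs[:-1] < 0))
        assert ct.n_true == n_oracle == 3
        assert ct.bl_true == pytest.approx(A, rel=1e-4)

    @pytest.mark.parametrize("n_per, expected_n", [(1, 1), (2, 3), (3, 5), (1.5, 2), (2.5, 4)])
    def test_sinusoid_inflection_counts(self, n_per, expected_n):
        ct = tf.make_curve(tf.CurveSpec("sinusoid",
                                        {"amplitude": 8.0, "wavelength": 40.0, "n_periods": n_per}))
        assert ct.n_true == expected_n

    @pytest.mark.parametrize("family, params", [
        ("unknown", {"length": 1.0}),
        ("straight", {"length": 0.0}),
        ("semicircle", {"radius": -5.0}),
        ("sinusoid", {"amplitude": 5.0, "wavelength": 30.0, "n_periods": 0.25}),
    ])
    def test_invalid_specs_rejected(self, family, params):
        with pytest.raises(PhantomSpecError):
            tf.make_curve(tf.CurveSpec(family, params))

    def test_ti_at_least_one_with_equality_iff_straight(self):
        for family, params in [
            ("straight", {"length": 80.0}),
            ("semicircle", {"radius": 15.0}),
            ("sinusoid", {"amplitude": 6.0, "wavelength": 25.0, "n_periods": 2}),
            ("helix", {"radius": 8.0, "pitch": 15.0, "n_turns": 1.5}),
            ("composite", {"amplitude": 6.0, "wavelength": 40.0, "n_periods": 2,
                           "amplitude2": 2.0, "wavelength2": 13.0}),
        ]:
            ct = tf.make_curve(tf.CurveSpec(family, params))
            if family == "straight":
                assert ct.ti_true == pytest.approx(1.0, abs=1e-12)
            else:
                assert ct.ti_true > 1.0

    def test_axis_orientation_permutes_points_only(self):
        pz = tf.make_curve(tf.CurveSpec("sinusoid", {"amplitude": 5, "wavelength": 30, "n_periods": 2}, axis="z"))
        px = tf.make_curve(tf.CurveSpec("sinusoid", {"amplitude": 5, "wavelength": 30, "n_periods": 2}, axis="x"))
        assert px.al_true == pz.al_true and px.n_true == pz.n_true
        assert np.allclose(px.points[:, 0], pz.points[:, 2])


class TestRasterizeTube:
    def test_true_mask_volume_matches_analytic_cylinder(self):
        spec = tf.TubePhantomSpec(curve=tf.CurveSpec("straight", {"length": 100.0}),
                                  tube_radius=2.0, voxel_spacing=(1.0, 1.0, 1.0),
                                  noise_sd=0.0, seed=0)
        ph = tf.rasterize_tube(spec)
        analytic = math.pi * 2.0 ** 2 * 100.0  # pi r^2 L, unit voxel volume
        assert ph.true_mask.n_voxels == pytest.approx(analytic, rel=0.05)

    def test_mask_volume_converges_with_resolution(self):
        spec_fn = lambda s: tf.TubePhantomSpec(
            curve=tf.CurveSpec("straight", {"length": 60.0}), tube_radius=2.0,
            voxel_spacing=(s, s, s), noise_sd=0.0, seed=0)
        analytic = math.pi * 4.0 * 60.0
        errs = []
        for s in (1.0, 0.5):
            ph = tf.rasterize_tube(spec_fn(s))
            errs.append(abs(ph.true_mask.n_voxels * s ** 3 - analytic) / analytic)
        assert errs[1] < errs[0]

    def test_noiseless_volume_has_exactly_two_intensities(self):
        spec = tf.TubePhantomSpec(curve=tf.CurveSpec("straight", {"length": 40.0}),
                                  voxel_spacing=(1.0, 1.0, 1.0),
                                  fg_intensity=200.0, bg_mean=100.0, noise_sd=0.0, seed=0)
        ph = tf.rasterize_tube(spec)
        assert set(np.unique(ph.volume.data)) == {100.0, 200.0}

    def test_same_seed_bit_reproducible(self):
        spec = tf.TubePhantomSpec(curve=tf.CurveSpec("straight", {"length": 40.0}),
                                  voxel_spacing=(1.0, 1.0, 1.0), seed=7)
        a = tf.rasterize_tube(spec)
        b = tf.rasterize_tube(spec)
        assert np.array_equal(a.volume.data, b.volume.data)
        assert np.array_equal(a.true_mask.data, b.true_mask.data)

    def test_curve_exceeding_grid_rejected(self):
        spec = tf.TubePhantomSpec(curve=tf.CurveSpec("straight", {"length": 100.0}),
                                  voxel_spacing=(1.0, 1.0, 1.0), grid_dims=(20, 20, 20))
        with pytest.raises(PhantomSpecError, match="grid"):
            tf.rasterize_tube(spec)


class TestPcPhantom:
    def test_peak_phase_is_linear_in_vmax(self):
        pair, _ = tf.make_pc_phantom(tf.FlowPhantomSpec(v_max=40.0, venc=80.0, noise_sd=0.0))
        assert pair.phase.max() == pytest.approx(math.pi / 2, rel=1e-12)

    def test_zero_velocity_gives_zero_phase_and_flux(self):
        pair, truth = tf.make_pc_phantom(tf.FlowPhantomSpec(v_max=0.0, noise_sd=0.0))
        assert np.all(pair.phase == 0)
        assert truth.flux_true == 0

    def test_flux_truth_closed_form_and_numeric_integral(self):
        spec = tf.FlowPhantomSpec(vessel_radius_px=10, v_max=40.0, pixel_size=0.45)
        _, truth = tf.make_pc_phantom(spec)
        r_mm = 10 * 0.45
        closed = math.pi * (r_mm / 10.0) ** 2 * (40.0 / 2.0) * 60.0  # cm^2 * cm/s * 60
        assert truth.flux_true == pytest.approx(closed, rel=1e-12)
        # numeric area integral of the continuous profile (polar rule)
        r = np.linspace(0, r_mm / 10.0, 200001)
        v = 40.0 * (1 - (r / (r_mm / 10.0)) ** 2)
        numeric = np.trapezoid(2 * math.pi * r * v, r) * 60.0
        assert truth.flux_true == pytest.approx(numeric, rel=1e-6)

    def test_wrap_rejected(self):
        with pytest.raises(PhantomSpecError, match="wrap"):
            tf.FlowPhantomSpec(v_max=100.0, venc=80.0)


class TestScanRescan:
    def test_no_noise_no_shift_identical(self):
        spec = tf.TubePhantomSpec(curve=tf.CurveSpec("straight", {"length": 40.0}),
                                  voxel_spacing=(1.0, 1.0, 1.0), noise_sd=0.0)
        a, b = tf.make_scan_rescan(spec, seed_pair=(0, 0), shift_mm=(0, 0, 0))
        assert np.array_equal(a.volume.data, b.volume.data)

    def test_seeded_pair_reproducible(self):
        spec = tf.TubePhantomSpec(curve=tf.CurveSpec("straight", {"length": 40.0}),
                                  voxel_spacing=(1.0, 1.0, 1.0), noise_sd=5.0)
        a1, b1 = tf.make_scan_rescan(spec, seed_pair=(3, 4))
        a2, b2 = tf.make_scan_rescan(spec, seed_pair=(3, 4))
        assert np.array_equal(a1.volume.data, a2.volume.data)
        assert np.array_equal(b1.volume.data, b2.volume.data)

    def test_oversized_shift_rejected(self):
        spec = tf.TubePhantomSpec(curve=tf.CurveSpec("straight", {"length": 40.0}),
                                  voxel_spacing=(1.0, 1.0, 1.0))
        with pytest.raises(PhantomSpecError, match="shift"):
            tf.make_scan_rescan(spec, seed_pair=(0, 1), shift_mm=(3.0, 0, 0))


class TestCohort:
    def test_deterministic_under_seed(self):
        a = tf.make_cohort(12, seed=9)
        b = tf.make_cohort(12, seed=9)
        assert [s.age for s in a] == [s.age for s in b]
        assert [s.tube_spec.curve.params["amplitude"] for s in a] == \
               [s.tube_spec.curve.params["amplitude"] for s in b]

    def test_minimum_size_enforced(self):
        with pytest.raises(PhantomSpecError):
            tf.make_cohort(5, seed=0)

    def test_zero_slopes_give_null_generated_trend(self):
        slopes = tf.CohortSlopes(amplitude_slope=0.0, vmax_slope=0.0)
        subjects = tf.make_cohort(100, slopes=slopes, seed=17)
        ages = [s.age for s in subjects]
        amps = [s.tube_spec.curve.params["amplitude"] for s in subjects]
        assert abs(tf.pearson_r(ages, amps)) < 0.3

    def test_positive_amplitude_slope_in_generated_specs(self):
        subjects = tf.make_cohort(100, seed=17)
        ages = [s.age for s in subjects]
        amps = [s.tube_spec.curve.params["amplitude"] for s in subjects]
        vmaxes = [s.flow_spec.v_max for s in subjects]
        assert tf.pearson_r(ages, amps) > 0.5
        assert tf.pearson_r(ages, vmaxes) < -0.5
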