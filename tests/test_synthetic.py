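"""Ground-truth cohort generator: cap geometry, scan simulation, determinism."""

import numpy as np
import pytest

from drusenkit.quantify import MeasureConfig, measure_eye
from drusenkit.synthetic import (
    SPECTRALIS_DENSE,
    DrusenBump,
    RpdLesion,
    SimCohortConfig,
    UnknownStageError,
    analytic_drusen_volume,
    build_cohort,
    build_eye,
    simulate_scan,
)

from conftest import clean_device, make_eye


def grid_coords(eye, device):
    ys = eye.fovea_y_um + (
        np.arange(device.n_bscans) - (device.n_bscans - 1) / 2
    ) * device.bscan_spacing_um
    n = device.n_ascans
    xs = eye.fovea_x_um + (np.arange(n) - (n - 1) / 2) * device.ascan_pitch_um
    return np.meshgrid(xs, ys)


class TestAnalyticVolume:
    def test_no_bumps_is_zero(self):
        assert analytic_drusen_volume(make_eye(), 5.0) == 0.0

    def test_single_cap_closed_form(self):
        # V = (pi h / 6)(3 a^2 + h^2), a = 250 um, h = 60 um
        eye = make_eye([DrusenBump(0, 0, 500.0, 60.0)])
        expected = np.pi * 60 / 6 * (3 * 250**2 + 60**2) / 1e9
        assert analytic_drusen_volume(eye, 5.0) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.006004, abs=5e-7)

    def test_cap_outside_circle_is_zero(self):
        eye = make_eye([DrusenBump(5000.0, 0, 500.0, 60.0)])
        assert analytic_drusen_volume(eye, 5.0) == 0.0

    def test_straddling_cap_clipped_numerically(self):
        # cap centered on the circle boundary: roughly half its volume
        eye = make_eye([DrusenBump(2500.0, 0, 500.0, 60.0)])
        v = analytic_drusen_volume(eye, 5.0)
        full = DrusenBump(0, 0, 500.0, 60.0).volume_mm3
        assert 0.4 * full < v < 0.6 * full

    def test_rotation_invariance(self, rng):
        bumps = [
            DrusenBump(rng.uniform(-1500, 1500), rng.uniform(-1500, 1500),
                       rng.uniform(100, 400), rng.uniform(20, 45))
            for _ in range(6)
        ]
        eye = make_eye(bumps)
        v0 = analytic_drusen_volume(eye, 5.0)
        theta = 1.1
        rot = [
            DrusenBump(
                b.center_x_um * np.cos(theta) - b.center_y_um * np.sin(theta),
                b.center_x_um * np.sin(theta) + b.center_y_um * np.cos(theta),
                b.base_diameter_um, b.height_um,
            )
            for b in bumps
        ]
        v1 = analytic_drusen_volume(make_eye(rot), 5.0)
        assert v1 == pytest.approx(v0, rel=1e-3)


class TestBuildEye:
    def test_unknown_stage_rejected(self, rng):
        with pytest.raises(UnknownStageError):
            build_eye("late_amd", rng, SimCohortConfig())

    def test_zero_bump_distribution_yields_empty(self, rng):
        config = SimCohortConfig()
        config.stage_models = dict(config.stage_models)
        from drusenkit.synthetic import StageModel

        config.stage_models["no_amd"] = StageModel(p_any=0.0)
        eye = build_eye("no_amd", rng, config)
        assert eye.bumps == []

    def test_stage_diameter_invariants(self, rng):
        config = SimCohortConfig()
        for _ in range(300):
            eye = build_eye("eamd", rng, config)
            dmax = max(b.base_diameter_um for b in eye.bumps)
            assert 63 < dmax <= 125
        for _ in range(100):
            eye = build_eye("iamd", rng, config)
            assert max(b.base_diameter_um for b in eye.bumps) > 125
        for _ in range(100):
            eye = build_eye("no_amd", rng, config)
            if eye.bumps:
                assert max(b.base_diameter_um for b in eye.bumps) <= 63

    def test_bumps_inside_field(self, rng):
        config = SimCohortConfig()
        for _ in range(50):
            eye = build_eye("iamd", rng, config)
            for b in eye.bumps:
                assert abs(b.center_x_um) <= config.field_x_um / 2
                assert abs(b.center_y_um) <= config.field_y_um / 2

    def test_same_stream_state_reproduces_eye(self):
        config = SimCohortConfig()
        e1 = build_eye("iamd", np.random.default_rng(3), config, rpd_present=True)
        e2 = build_eye("iamd", np.random.default_rng(3), config, rpd_present=True)
        assert e1.bumps == e2.bumps
        assert e1.rpd == e2.rpd
        assert np.array_equal(e1.bm_coeffs, e2.bm_coeffs)

    def test_stage_monotonic_mean_volume(self):
        # mean analytic 5-mm volume must rise across no AMD < eAMD < iAMD
        config = SimCohortConfig()
        rng = np.random.default_rng(0)
        means = []
        for stage in ("no_amd", "eamd", "iamd"):
            vols = [
                analytic_drusen_volume(build_eye(stage, rng, config), 5.0)
                for _ in range(200)
            ]
            means.append(np.mean(vols))
        assert means[0] < means[1] < means[2]


class TestSimulateScan:
    def test_identity_sampling(self, rng):
        # noise 0, slope 1, intercept 0: RPE - BM - offset equals the
        # analytic cap height at every node
        eye = make_eye([DrusenBump(200.0, -300.0, 600.0, 70.0)])
        device = clean_device(100.0)
        s = simulate_scan(eye, device, rng)
        xx, yy = grid_coords(eye, device)
        expected = eye.drusen_elevation(xx, yy)
        np.testing.assert_allclose(s.rpe_um - s.bm_um - 35.0, expected, atol=1e-9)

    def test_bias_slope_halves_volume(self, rng, single_cap_eye):
        device = clean_device(10.0, bias_slope=0.5)
        s = simulate_scan(single_cap_eye, device, rng)
        m = measure_eye(s, "bm_offset", MeasureConfig(min_height_px=0))
        truth = analytic_drusen_volume(single_cap_eye, 5.0)
        assert m.volume_5mm_mm3 == pytest.approx(0.5 * truth, rel=0.05)

    def test_rpd_never_captured_matches_rpd_free_eye(self):
        bumps = [DrusenBump(0, 0, 400.0, 50.0)]
        rpd = [RpdLesion(500.0, 500.0, 800.0, 40.0)]
        device = clean_device(100.0, rpd_capture_prob=0.0, surface_noise_sd_um=2.0)
        s_with = simulate_scan(make_eye(bumps, rpd), device, np.random.default_rng(5))
        s_without = simulate_scan(make_eye(bumps), device, np.random.default_rng(5))
        np.testing.assert_array_equal(s_with.rpe_um, s_without.rpe_um)
        np.testing.assert_array_equal(s_with.bm_um, s_without.bm_um)

    def test_device_field_must_fit(self, rng, single_cap_eye):
        big = clean_device(100.0, field=12000.0)
        with pytest.raises(ValueError, match="field"):
            simulate_scan(single_cap_eye, big, rng)


class TestBuildCohort:
    def test_counts_and_scans(self, small_cohort_config):
        cohort = build_cohort(small_cohort_config)
        assert len(cohort) == 11
        stages = [eye.stage for eye, _ in cohort]
        assert stages.count("no_amd") == 3
        assert stages.count("eamd") == 3
        assert stages.count("iamd") == 5
        for _, scans in cohort:
            assert set(scans) == {d.name for d in small_cohort_config.devices}

    def test_rpd_fraction_one_flags_all_iamd(self):
        config = SimCohortConfig(
            n_per_stage={"no_amd": 0, "eamd": 0, "iamd": 8},
            rpd_fraction_iamd=1.0,
            rng_seed=2,
        )
        cohort = build_cohort(config)
        assert all(eye.rpd_present for eye, _ in cohort)

    def test_seed_reproducibility_bit_for_bit(self, small_cohort_config):
        c1 = build_cohort(small_cohort_config)
        c2 = build_cohort(small_cohort_config)
        for (e1, s1), (e2, s2) in zip(c1, c2):
            assert e1.bumps == e2.bumps and e1.rpd == e2.rpd
            for name in s1:
                assert s1[name].rpe_um.tobytes() == s2[name].rpe_um.tobytes()
                assert s1[name].bm_um.tobytes() == s2[name].bm_um.tobytes()

    def test_empty_device_list_rejected(self):
        with pytest.raises(ValueError, match="device"):
            build_cohort(SimCohortConfig(devices=()))


def test_cap_height_geometry_invariant():
    # height <= base radius is required by spherical-cap geometry
    with pytest.raises(ValueError):
        DrusenBump(0, 0, 100.0, 60.0)
    b = DrusenBump(0, 0, 100.0, 50.0)  # hemisphere is the limit case
    assert b.volume_mm3 == pytest.approx(2 / 3 * np.pi * 50**3 / 1e9, rel=1e-9)


def test_default_profiles_match_scan_patterns():
    assert SPECTRALIS_DENSE.n_bscans == 241
    assert SPECTRALIS_DENSE.bscan_spacing_um == pytest.approx(30, abs=1)
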