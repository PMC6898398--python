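"""The hopping-mode protocol: detection, self-referencing, scan variants."""

import dataclasses

import numpy as np
import pytest

import sicmph as s
from sicmph.exceptions import CollisionError, ConfigurationError, NoSurfaceError
from tests.conftest import make_flat_scene


def small_config(**overrides) -> s.ScanConfig:
    kw = dict(nx=4, ny=4, pitch=1e-6, seed=1)
    kw.update(overrides)
    return s.ScanConfig(**kw)


class TestDetectSurface:
    def test_noiseless_crossing_at_one_radius(self):
        fb, geom = s.FeedbackModel(), s.ProbeGeometry()
        z = np.linspace(5e-6, 1e-9, 4000)
        trace = np.asarray(s.approach_current(fb, geom, z))
        z_det, _ = s.detect_surface(trace, z, 0.01, 3)
        assert z_det / geom.inner_radius == pytest.approx(1.0, rel=0.05)

    def test_subthreshold_noise_never_triggers(self):
        rng = np.random.default_rng(0)
        trace = 1.0 + 0.003 * rng.standard_normal(5000)
        trace = np.clip(trace, 0.991, None)  # amplitude below the 1% setpoint
        z = np.linspace(5e-6, 1e-9, 5000)
        with pytest.raises(NoSurfaceError):
            s.detect_surface(trace, z, 0.01, 3)

    def test_debounce_reduces_false_positives(self):
        # white noise occasionally dips below threshold; a 3-sample debounce
        # must fire strictly less often than a 1-sample one
        z = np.linspace(5e-6, 1e-9, 2000)
        hits = {1: 0, 3: 0}
        for seed in range(200):
            rng = np.random.default_rng(seed)
            trace = 1.0 + 0.005 * rng.standard_normal(z.size)
            for db in (1, 3):
                try:
                    s.detect_surface(trace, z, 0.01, db)
                    hits[db] += 1
                except NoSurfaceError:
                    pass
        assert hits[1] > hits[3]


class TestSelfReference:
    def test_zero_drift_is_direct_subtraction(self, noiseless_probe):
        fit = noiseless_probe.calibration
        sen = noiseless_probe.sensor
        bulk = np.full(20, s.sensor_current(sen, sen.working_bias, 7.4))
        surf = np.full(20, s.sensor_current(sen, sen.working_bias, 6.9))
        r_bulk, r_surf, dph = s.self_reference(bulk, surf, fit)
        assert dph == pytest.approx(r_surf.pH - r_bulk.pH)
        assert dph == pytest.approx(-0.5, abs=1e-9)

    def test_constant_offset_cancels_exactly(self, noiseless_probe):
        fit = noiseless_probe.calibration
        sen = noiseless_probe.sensor
        bulk = np.full(20, s.sensor_current(sen, sen.working_bias, 7.4))
        surf = np.full(20, s.sensor_current(sen, sen.working_bias, 6.9))
        _, _, dph0 = s.self_reference(bulk, surf, fit)
        offset = 3.3e-11
        _, _, dph1 = s.self_reference(bulk, surf, fit,
                                      drift=(np.full(20, offset),
                                             np.full(20, offset)))
        assert dph1 == pytest.approx(dph0, abs=1e-12)

    def test_missing_window_rejected(self, noiseless_probe):
        with pytest.raises(ValueError):
            s.self_reference(np.array([]), np.ones(20),
                             noiseless_probe.calibration)


class TestHoppingScan:
    def test_flat_scene_noiseless_accuracy(self, noiseless_probe):
        scene = make_flat_scene(z0=2e-6)
        cfg = small_config()
        res = s.run_hopping_scan(scene, noiseless_probe, cfg)
        # corrected topography within one descent sample of the truth
        step = cfg.descent_step
        assert np.abs(res.topography - 2e-6).max() <= 2 * step + 1e-12
        # raw detected z keeps the setpoint-crossing offset
        raw = np.array([r.z_surface for r in res.records])
        d_set = s.setpoint_distance(noiseless_probe.feedback,
                                    noiseless_probe.geometry)
        assert np.abs(raw - 2e-6 - d_set).max() <= 2 * step + 1e-12
        np.testing.assert_array_equal(res.dpH_map, 0.0)

    def test_flat_scene_default_noise_topography(self, default_probe):
        scene = make_flat_scene(z0=2e-6)
        res = s.run_hopping_scan(scene, default_probe, small_config())
        rms = np.sqrt(np.mean((res.topography - 2e-6) ** 2))
        assert rms <= 50e-9

    def test_seed_determinism_bitwise(self, default_probe):
        scene = make_flat_scene()
        cfg = small_config(seed=42)
        r1 = s.run_hopping_scan(scene, default_probe, cfg)
        r2 = s.run_hopping_scan(scene, default_probe, cfg)
        np.testing.assert_array_equal(r1.topography, r2.topography)
        np.testing.assert_array_equal(r1.dpH_map, r2.dpH_map)
        assert r1.to_frame().equals(r2.to_frame())

    def test_acidic_patch_dpH_accuracy(self, default_probe):
        # measured dpH at the patch pixel matches the self-referenced ground
        # truth to 0.02 pH on average under the default noise model
        scene = s.make_cell_scene(n_cells=1, extent=(12e-6, 12e-6),
                                  dome_radius=5e-6, dome_height=3e-6,
                                  patches_per_cell=1,
                                  target_mask_mean_dpH=-0.5, seed=2)
        cfg_base = s.ScanConfig(nx=6, ny=6, pitch=2e-6, seed=0)
        truth = scene.surface_dpH_grid(
            6, 6, 2e-6, height=150e-9,
            reference_height=150e-9 + cfg_base.hop_amplitude)
        m = scene.mask(6, 6, 2e-6)
        errs = []
        for seed in range(5):
            res = s.run_hopping_scan(scene, default_probe,
                                     dataclasses.replace(cfg_base, seed=seed))
            errs.append(np.nanmean((res.dpH_map - truth)[m]))
        assert abs(np.mean(errs)) < 0.02

    def test_out_of_reach_pixel_flagged(self, noiseless_probe):
        scene = make_flat_scene(z0=2e-6)
        cfg = small_config(hop_amplitude=1e-6, hop_ceiling="absolute")
        res = s.run_hopping_scan(scene, noiseless_probe, cfg)
        assert all(r.no_surface for r in res.records)
        assert np.isnan(res.topography).all()

    def test_drift_invariance_of_dpH(self, default_probe):
        # 0.1 pH-equivalent per 100 s of sensor drift; the dpH map may move
        # only by the drift accrued within one hop cycle (well under 1e-3)
        scene = make_flat_scene(z0=2e-6)
        cfg = small_config(seed=9)
        rate_pH = 0.1 / 100.0
        slope = default_probe.calibration.slope
        drift = lambda t: rate_pH * slope * np.asarray(t)
        r0 = s.run_hopping_scan(scene, default_probe, cfg)
        r1 = s.run_hopping_scan(scene, default_probe, cfg, drift=drift)
        assert np.nanmax(np.abs(r1.dpH_map - r0.dpH_map)) < 1e-3


class TestSingleBarrelArtefact:
    def test_ball_artefact_over_active_source(self, artefact_scene):
        cfg = s.ScanConfig(nx=5, ny=5, pitch=1e-6, seed=2)
        db = s.run_hopping_scan(artefact_scene,
                                s.Probe.double_barrel().calibrated(), cfg)
        sb = s.run_single_barrel_scan(artefact_scene,
                                      s.Probe.single_barrel().calibrated(),
                                      cfg)
        # apparent bump at the source pixel in single-barrel mode
        assert sb.topography[2, 2] - db.topography[2, 2] > 100e-9
        # double-barrel topography is unaffected by the pH field (flat truth)
        assert np.nanmax(np.abs(db.topography)) < 50e-9

    def test_artefact_absent_when_source_gated_off(self, artefact_scene_off):
        cfg = s.ScanConfig(nx=5, ny=5, pitch=1e-6, seed=2)
        sb = s.run_single_barrel_scan(artefact_scene_off,
                                      s.Probe.single_barrel().calibrated(),
                                      cfg)
        assert abs(sb.topography[2, 2]) < 50e-9

    def test_neutral_scene_matches_double_barrel(self, noiseless_probe):
        scene = make_flat_scene(z0=1e-6)
        cfg = small_config(nx=3, ny=3)
        db = s.run_hopping_scan(scene, noiseless_probe, cfg)
        sb_probe = dataclasses.replace(
            s.Probe.single_barrel(),
            sensor=dataclasses.replace(noiseless_probe.sensor),
            feedback=dataclasses.replace(s.Probe.single_barrel().feedback,
                                         noise_fraction=0.0)).calibrated()
        sb = s.run_single_barrel_scan(scene, sb_probe, cfg)
        # the sealed membrane's first-order lag delays detection by at most
        # fall_rate * tau (~17 nm); beyond that the two modes must agree
        lag = cfg.fall_rate * sb_probe.sensor.time_constant
        np.testing.assert_allclose(sb.topography, db.topography,
                                   atol=lag + 2 * cfg.descent_step)

    def test_double_barrel_topography_independent_of_field(
            self, artefact_scene, artefact_scene_off):
        # bitwise identical in the noiseless case, per the decoupling design
        probe = s.Probe.double_barrel()
        probe = dataclasses.replace(
            probe,
            sensor=dataclasses.replace(probe.sensor, noise_rms=0.0),
            feedback=dataclasses.replace(probe.feedback,
                                         noise_fraction=0.0)).calibrated()
        cfg = s.ScanConfig(nx=3, ny=3, pitch=1.5e-6, seed=0)
        r_on = s.run_hopping_scan(artefact_scene, probe, cfg)
        r_off = s.run_hopping_scan(artefact_scene_off, probe, cfg)
        np.testing.assert_array_equal(r_on.topography, r_off.topography)


class TestConstantHeight:
    def test_uniform_scene_reads_bulk(self, noiseless_probe):
        scene = make_flat_scene(z0=0.5e-6)
        cfg = small_config(mode="constant_height", constant_height_z=2e-6)
        res = s.run_constant_height_scan(scene, noiseless_probe, cfg)
        np.testing.assert_allclose(res.dpH_map, 0.0, atol=1e-9)

    def test_peak_sits_over_the_source(self, noiseless_probe, artefact_scene):
        cfg = s.ScanConfig(nx=5, ny=5, pitch=1e-6, seed=0,
                           mode="constant_height", constant_height_z=1.5e-6)
        res = s.run_constant_height_scan(artefact_scene, noiseless_probe, cfg)
        iy, ix = np.unravel_index(np.argmax(np.abs(res.dpH_map)),
                                  res.dpH_map.shape)
        assert (ix, iy) == (2, 2)  # source at (2 um, 2 um)

    def test_contrast_attenuates_with_height(self, noiseless_probe,
                                             artefact_scene):
        maxima = []
        for z in (1.5e-6, 3e-6, 6e-6):
            cfg = s.ScanConfig(nx=5, ny=5, pitch=1e-6, seed=0,
                               mode="constant_height", constant_height_z=z)
            res = s.run_constant_height_scan(artefact_scene, noiseless_probe,
                                             cfg)
            maxima.append(np.abs(res.dpH_map).max())
        assert maxima[0] > maxima[1] > maxima[2]

    def test_collision_detected(self, noiseless_probe):
        scene = make_flat_scene(z0=2e-6)
        cfg = small_config(mode="constant_height", constant_height_z=1e-6)
        with pytest.raises(CollisionError):
            s.run_constant_height_scan(scene, noiseless_probe, cfg)


class TestConfigValidation:
    def test_invariants_enforced(self):
        with pytest.raises(ConfigurationError):
            s.ScanConfig(nx=4, ny=4, pitch=1e-6, hop_amplitude=50e-9)
        with pytest.raises(ConfigurationError):
            s.ScanConfig(nx=4, ny=4, pitch=1e-6, setpoint_fraction=1.5)
        with pytest.raises(ConfigurationError):
            s.ScanConfig(nx=4, ny=4, pitch=1e-6, fs=3e3, f_c=2e3)
        with pytest.raises(ConfigurationError):
            s.ScanConfig(nx=4, ny=4, pitch=1e-6, mode="iceberg")
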