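"""Sensor electrical model, calibration, approach curve, recording chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sicmph as s
from sicmph.exceptions import CalibrationError, ConfigurationError, EstimationError


class TestSensorCurrent:
    def test_ohmic_at_zero_bias_and_neutral_pH(self, noiseless_sensor):
        sen = noiseless_sensor
        for ph in (4.0, 7.0, 9.0):
            assert s.sensor_current(sen, 0.0, ph) == 0.0
        v = 0.31
        assert s.sensor_current(sen, v, sen.neutral_pH) == pytest.approx(
            sen.base_conductance * v)

    def test_slope_at_working_bias(self, noiseless_sensor):
        sen = noiseless_sensor
        i1 = s.sensor_current(sen, sen.working_bias, 6.0)
        i2 = s.sensor_current(sen, sen.working_bias, 7.0)
        expected = (sen.base_conductance * 0.6 * sen.rectification
                    * math.tanh(0.6 / sen.rectification_voltage_scale))
        assert i2 - i1 == pytest.approx(expected, rel=1e-12)
        assert sen.pH_slope == pytest.approx(expected, rel=1e-12)

    def test_rectification_flips_across_neutral(self, noiseless_sensor):
        sen = noiseless_sensor
        # ratio |I(+V)|/|I(-V)| crosses 1 at pH0 with opposite asymmetry
        def ratio(ph):
            return abs(s.sensor_current(sen, 0.6, ph)) / abs(
                s.sensor_current(sen, -0.6, ph))
        assert ratio(sen.neutral_pH) == pytest.approx(1.0)
        assert (ratio(5.0) - 1.0) * (ratio(9.0) - 1.0) < 0

    def test_affine_in_pH_over_full_domain(self, noiseless_sensor):
        sen = noiseless_sensor
        ph = np.linspace(0.5, 13.5, 40)
        i = np.asarray(s.sensor_current(sen, sen.working_bias, ph))
        resid = np.polyfit(ph, i, 1, full=True)[1]
        assert float(resid[0]) < 1e-40


class TestCvSweep:
    def test_cycle_duration(self, noiseless_sensor):
        trace = s.cv_sweep(noiseless_sensor, 7.0)
        assert trace.time_s.iloc[-1] == pytest.approx(2 * 1.2 / 0.65,
                                                      abs=1e-3)

    def test_straight_line_at_neutral(self, noiseless_sensor):
        trace = s.cv_sweep(noiseless_sensor, noiseless_sensor.neutral_pH)
        np.testing.assert_allclose(
            trace.current_A,
            noiseless_sensor.base_conductance * trace.voltage_V, rtol=1e-12)

    def test_traces_differ_most_at_extreme_bias(self, noiseless_sensor):
        t4 = s.cv_sweep(noiseless_sensor, 4.0)
        t9 = s.cv_sweep(noiseless_sensor, 9.0)
        diff = np.abs(t4.current_A - t9.current_A)
        assert abs(t4.voltage_V[diff.idxmax()]) == pytest.approx(0.6,
                                                                 abs=0.01)

    def test_invalid_window(self, noiseless_sensor):
        with pytest.raises(ConfigurationError):
            s.cv_sweep(noiseless_sensor, 7.0, v_min=0.6, v_max=-0.6)


class TestCalibration:
    def test_noiseless_fit_is_exact(self, noiseless_sensor):
        fit = s.default_calibration(noiseless_sensor)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(noiseless_sensor.pH_slope,
                                          rel=1e-10)
        assert fit.valid_range == (4.0, 9.0)

    def test_noisy_linearity_monte_carlo(self, noiseless_sensor):
        # six points pH 4..9, noise 1% of full-scale span, 100 seeds
        sen = noiseless_sensor
        ph = np.linspace(4.0, 9.0, 6)
        clean = np.asarray(s.sensor_current(sen, sen.working_bias, ph))
        span = np.ptp(clean)
        rng = np.random.default_rng(12345)
        r2 = []
        for _ in range(100):
            noisy = clean + rng.normal(0.0, 0.01 * span, size=clean.shape)
            r2.append(s.fit_calibration(np.column_stack([ph, noisy])).r_squared)
        assert np.mean(r2) >= 0.96

    def test_slope_sign_follows_rectification(self):
        for rho in (-0.08, 0.08):
            sen = s.SensorModel(rectification=rho, noise_rms=0.0)
            fit = s.default_calibration(sen)
            assert math.copysign(1, fit.slope) == math.copysign(1, rho)

    def test_insufficient_points_rejected(self):
        with pytest.raises(CalibrationError):
            s.fit_calibration([(7.0, 1e-9), (8.0, 2e-9)])
        with pytest.raises(CalibrationError):
            s.fit_calibration([(7.0, 1e-9), (7.0, 2e-9), (7.0, 3e-9)])


class TestCurrentToPH:
    def test_round_trip(self, noiseless_sensor):
        fit = s.default_calibration(noiseless_sensor)
        cur = s.sensor_current(noiseless_sensor,
                               noiseless_sensor.working_bias, 6.5)
        reading = s.current_to_pH(fit, cur)
        assert reading.pH == pytest.approx(6.5, abs=1e-9)
        assert not reading.out_of_range

    def test_out_of_range_flag(self, noiseless_sensor):
        fit = s.default_calibration(noiseless_sensor)
        cur = s.sensor_current(noiseless_sensor,
                               noiseless_sensor.working_bias, 10.5)
        assert s.current_to_pH(fit, cur).out_of_range

    def test_zero_slope_rejected(self):
        fit = s.CalibrationFit(slope=0.0, intercept=0.0, r_squared=1.0,
                               residual_sd=0.0, valid_range=(4.0, 9.0))
        with pytest.raises(CalibrationError):
            s.current_to_pH(fit, 1e-9)


class TestReversalPotential:
    def test_zero_at_neutral(self, noiseless_sensor):
        assert s.reversal_potential(noiseless_sensor,
                                    noiseless_sensor.neutral_pH) == 0.0

    def test_fitted_slope_in_selectivity_window(self, noiseless_sensor):
        ph = np.array([5.0, 6.0, 7.0, 8.0])
        slope = np.polyfit(ph, s.reversal_potential(noiseless_sensor, ph),
                           1)[0]
        assert 15.0 <= slope <= 20.0

    def test_span_over_three_units(self, noiseless_sensor):
        span = (s.reversal_potential(noiseless_sensor, 8.0)
                - s.reversal_potential(noiseless_sensor, 5.0))
        assert span == pytest.approx(52.5)


class TestTipScaling:
    def test_anchor_values(self):
        i100 = s.bulk_current_for_tip(s.ProbeGeometry(inner_radius=50e-9))
        i2500 = s.bulk_current_for_tip(s.ProbeGeometry(inner_radius=1.25e-6))
        assert i100 == pytest.approx(-0.8e-9, rel=1e-9)
        assert i2500 == pytest.approx(-70e-9, rel=1e-9)

    def test_power_law_interpolation(self):
        i = s.bulk_current_for_tip(s.ProbeGeometry(inner_radius=0.25e-6))
        assert i == pytest.approx(-7.5e-9, rel=0.01)

    def test_extrapolation_warns(self):
        with pytest.warns(UserWarning):
            s.bulk_current_for_tip(s.ProbeGeometry(inner_radius=10e-6))


class TestApproachCurve:
    def test_limits(self):
        fb, geom = s.FeedbackModel(), s.ProbeGeometry()
        assert s.approach_current(fb, geom, 1.0) == pytest.approx(1.0,
                                                                  abs=1e-6)
        assert s.approach_current(fb, geom, 0.1 * geom.inner_radius) == \
            pytest.approx(1.0 / 1.101, rel=1e-4)
        with pytest.raises(ValueError):
            s.approach_current(fb, geom, 0.0)

    def test_default_setpoint_at_one_radius(self):
        fb, geom = s.FeedbackModel(), s.ProbeGeometry()
        d = s.setpoint_distance(fb, geom)
        assert d / geom.inner_radius == pytest.approx(1.0, rel=0.001)

    @given(st.floats(min_value=1e-9, max_value=1e-5),
           st.floats(min_value=1.1, max_value=10.0))
    @settings(deadline=None, max_examples=50)
    def test_strictly_increasing(self, d, factor):
        fb, geom = s.FeedbackModel(), s.ProbeGeometry()
        assert s.approach_current(fb, geom, d * factor) > \
            s.approach_current(fb, geom, d)

    def test_decoupled_feedback_ignores_pH(self, noiseless_sensor):
        fb = s.FeedbackModel(pH_coupled=False)
        geom = s.ProbeGeometry()
        a = s.approach_current(fb, geom, 1e-7, local_pH=5.0,
                               sensor=noiseless_sensor)
        b = s.approach_current(fb, geom, 1e-7, local_pH=9.0,
                               sensor=noiseless_sensor)
        assert a == b

    def test_coupled_feedback_tracks_pH(self, noiseless_sensor):
        fb = s.FeedbackModel(pH_coupled=True)
        geom = s.ProbeGeometry()
        a = s.approach_current(fb, geom, 1e-7, local_pH=5.0,
                               sensor=noiseless_sensor, reference_pH=7.4)
        b = s.approach_current(fb, geom, 1e-7, local_pH=9.0,
                               sensor=noiseless_sensor, reference_pH=7.4)
        assert a != b


class TestRecordingChain:
    def test_passthrough_without_lag_noise_filter(self, noiseless_sensor):
        import dataclasses
        sen = dataclasses.replace(noiseless_sensor, time_constant=0.0)
        x = np.sin(np.linspace(0, 5, 200))
        np.testing.assert_array_equal(
            s.sensor_readout(x, sen, 20e3, None), x)

    def test_constant_input_constant_output(self, noiseless_sensor):
        x = np.full(100, 2.5e-9)
        y = s.sensor_readout(x, noiseless_sensor, 20e3, 2e3)
        np.testing.assert_allclose(y, 2.5e-9, rtol=1e-9)

    def test_deterministic_under_seed(self):
        sen = s.SensorModel()
        x = np.full(200, 1e-9)
        y1 = s.sensor_readout(x, sen, 20e3, 2e3, seed=7)
        y2 = s.sensor_readout(x, sen, 20e3, 2e3, seed=7)
        np.testing.assert_array_equal(y1, y2)

    def test_step_response_reaches_95_at_3tau(self):
        sen = s.SensorModel(time_constant=2e-3, noise_rms=0.0)
        fs = 100e3
        step = np.concatenate([np.zeros(50), np.ones(4000)])
        y = s.sensor_readout(step, sen, fs, None)
        assert np.all(np.diff(y) >= -1e-15)
        t = s.response_time(y, fs)
        assert t == pytest.approx(3 * 2e-3, rel=0.05)

    def test_nyquist_guard(self, noiseless_sensor):
        with pytest.raises(ConfigurationError):
            s.sensor_readout(np.zeros(10), noiseless_sensor, 1e3, 2e3)


class TestResponseTime:
    def test_default_chain_is_two_milliseconds(self, noiseless_sensor):
        fs = 20e3
        step = np.concatenate([np.zeros(40), np.ones(200)])
        y = s.sensor_readout(step, noiseless_sensor, fs, 2e3)
        assert s.response_time(y, fs) == pytest.approx(2e-3, rel=0.25)

    def test_instantaneous_sensor_one_sample(self):
        import dataclasses
        sen = s.SensorModel(time_constant=0.0, noise_rms=0.0)
        fs = 20e3
        step = np.concatenate([np.zeros(40), np.ones(100)])
        y = s.sensor_readout(step, sen, fs, None)
        assert s.response_time(y, fs) == pytest.approx(1.0 / fs)

    def test_flat_trace_rejected(self):
        with pytest.raises(EstimationError):
            s.response_time(np.ones(100), 20e3)
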