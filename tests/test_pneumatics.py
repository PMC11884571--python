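"""Waveforms, lag response, rate statistics and derived quantities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stretchfield.pneumatics import (
    PressureTrace,
    RateStats,
    WaveformSpec,
    acquisition_schedule,
    cycles_in_duration,
    fit_second_order,
    frequency,
    generate_setpoint,
    implied_strain_rate,
    pressure_rate,
    pressure_to_vacuum,
    rate_peaks,
    simulate_response,
    vacuum_to_pressure,
)


class TestConversion:
    @pytest.mark.parametrize(
        "vac,bar", [(35.0, 0.65), (0.0, 1.0), (50.0, 0.5), (100.0, 0.0)]
    )
    def test_vacuum_pressure_pairs(self, vac, bar):
        assert vacuum_to_pressure(vac) == pytest.approx(bar)
        assert pressure_to_vacuum(bar) == pytest.approx(vac)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            vacuum_to_pressure(101.0)
        with pytest.raises(ValueError):
            pressure_to_vacuum(1.5)

    @settings(max_examples=25, deadline=None)
    @given(st.floats(0, 100))
    def test_roundtrip(self, vac):
        assert pressure_to_vacuum(vacuum_to_pressure(vac)) == pytest.approx(vac, abs=1e-9)


class TestSetpoint:
    def test_zero_vacuum_constant_atmosphere(self):
        trace = generate_setpoint(WaveformSpec(vacuum_fraction=0.0, duration=10.0))
        assert np.all(trace.pressure == 1.0)

    def test_rectangular_plateau_occupies_half_period(self):
        trace = generate_setpoint(WaveformSpec(duration=20.0))
        at_vacuum = np.isclose(trace.pressure, 0.65)
        # 10 s stretched and 10 s relaxed per 20 s period (minus ramp samples)
        assert at_vacuum.sum() * trace.dt == pytest.approx(10.0, abs=0.1)

    def test_ramp_duration_matches_slope(self):
        # 0.35 bar at 17.5 bar/s -> 0.02 s = 2 samples at 10 ms
        trace = generate_setpoint(WaveformSpec(duration=1.0))
        falling = np.nonzero(np.diff(trace.pressure) < 0)[0]
        assert len(falling) == 2

    def test_sinusoidal_bounds(self):
        trace = generate_setpoint(WaveformSpec(shape="sinusoidal", duration=40.0))
        assert trace.pressure.max() == pytest.approx(1.0, abs=1e-9)
        assert trace.pressure.min() == pytest.approx(0.65, abs=1e-9)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            WaveformSpec(period=0.0)
        with pytest.raises(ValueError):
            WaveformSpec(vacuum_fraction=1.5)
        with pytest.raises(ValueError):
            WaveformSpec(setpoint_slope=-2.0)


class TestResponse:
    def test_zero_step_constant_output(self):
        trace = generate_setpoint(WaveformSpec(vacuum_fraction=0.0, duration=5.0))
        out = simulate_response(trace, tau=0.1)
        assert np.allclose(out.pressure, 1.0, atol=1e-9)

    def test_first_order_reaches_95pct_at_3tau(self):
        t = np.arange(0, 2, 0.001)
        step = np.where(t >= 0.5, 0.65, 1.0)
        out = simulate_response(PressureTrace(t, step), tau=0.1)
        idx = np.searchsorted(t, 0.5 + 0.3)
        progress = (1.0 - out.pressure[idx]) / 0.35
        assert progress == pytest.approx(1 - np.exp(-3), abs=0.01)

    def test_default_model_evacuation_time_and_settling(self):
        # 0 -> 35% vacuum: target first reached ~300 ms after the set-point
        # step, settled within ±2% of the step well before 1.5 s
        trace = generate_setpoint(WaveformSpec(duration=20.0))
        out = simulate_response(trace)
        t, p = out.times, out.pressure
        t_step = t[np.argmax(trace.pressure < trace.pressure[0])]  # set-point leaves atmosphere
        seg = t < 10.0
        t_cross = t[seg][np.argmax(p[seg] <= 0.65)] - t_step
        assert t_cross == pytest.approx(0.300, rel=0.05)
        late = (t > t_step + 1.5) & (t < 10.0)
        assert np.abs(p[late] - 0.65).max() < 0.02 * 0.35
        assert p[seg].min() < 0.65 - 0.005  # overshoot is present

    def test_overdamped_second_order_monotone(self):
        t = np.arange(0, 5, 0.001)
        step = np.where(t >= 0.5, 0.65, 1.0)
        out = simulate_response(PressureTrace(t, step), omega_n=8.0, zeta=1.5)
        assert out.pressure.min() >= 0.65 - 1e-6  # no overshoot

    def test_nonuniform_sampling_rejected(self):
        with pytest.raises(ValueError):
            PressureTrace(np.array([0.0, 0.1, 0.3]), np.ones(3))

    def test_bad_params_rejected(self):
        trace = generate_setpoint(WaveformSpec(duration=1.0))
        with pytest.raises(ValueError):
            simulate_response(trace, tau=-1.0)

    def test_fit_settles_in_band(self):
        omega_n, zeta = fit_second_order()
        assert zeta < 1  # underdamped: overshoot exists
        assert np.exp(-zeta * omega_n * 1.5) / np.sqrt(1 - zeta**2) < 0.02


class TestRates:
    def test_constant_trace_zero_rate(self):
        t = np.arange(0, 1, 0.01)
        assert np.allclose(pressure_rate(PressureTrace(t, np.full(t.size, 0.8))), 0.0)

    def test_linear_ramp_exact(self):
        t = np.arange(0, 1, 0.01)
        rate = pressure_rate(PressureTrace(t, 1.0 - 2.0 * t))
        assert np.allclose(rate, -2.0, atol=1e-9)

    def test_sinusoid_amplitude(self):
        t = np.arange(0, 10, 0.01)
        w = 2 * np.pi * 0.2
        rate = pressure_rate(PressureTrace(t, 0.8 + 0.1 * np.sin(w * t)))
        assert rate.max() == pytest.approx(0.1 * w, rel=1e-3)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pressure_rate(PressureTrace(np.array([0.0, 0.01]), np.array([1.0, 1.0])))

    def test_identical_periods_sem_zero(self):
        trace = generate_setpoint(WaveformSpec(duration=400.0))
        out = simulate_response(trace)
        stats = rate_peaks(out, 20.0)
        assert stats.n_periods == 20
        assert stats.evacuation_rate_sem < 1e-9
        assert stats.venting_rate_sem < 1e-9

    def test_peaks_match_brute_force(self):
        trace = generate_setpoint(WaveformSpec(duration=100.0))
        out = simulate_response(trace, tau=0.1)
        stats = rate_peaks(out, 20.0)
        rate = np.gradient(out.pressure, out.times)
        brute = [
            rate[(out.times >= 20 * k) & (out.times < 20 * (k + 1))].min()
            for k in range(5)
        ]
        assert stats.evacuation_rate_mean == pytest.approx(np.mean(brute))
        assert stats.n_periods == 5

    def test_trace_shorter_than_period_rejected(self):
        t = np.arange(0, 5, 0.01)
        with pytest.raises(ValueError):
            rate_peaks(PressureTrace(t, np.ones(t.size)), period=20.0)


class TestDerived:
    @pytest.mark.parametrize("rate,expected", [(2.0, 46.0), (1.3, 30.0)])
    def test_implied_strain_rate_printed_values(self, rate, expected):
        assert implied_strain_rate(8.0, 0.35, rate) == expected

    def test_implied_strain_rate_unrounded(self):
        assert implied_strain_rate(8.0, 0.35, 2.0, rounded=False) == pytest.approx(45.714, abs=0.001)

    def test_zero_rate(self):
        assert implied_strain_rate(8.0, 0.35, 0.0) == 0.0

    def test_linearity_in_rate(self):
        a = implied_strain_rate(8.0, 0.35, 1.0, rounded=False)
        b = implied_strain_rate(8.0, 0.35, 3.0, rounded=False)
        assert b == pytest.approx(3 * a)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            implied_strain_rate(8.0, 0.0, 2.0)

    def test_cycles_and_frequency(self):
        assert cycles_in_duration(18 * 3600, 20.0) == 3240
        assert frequency(20.0) == pytest.approx(0.05)
        assert cycles_in_duration(5.0, 20.0) == 0

    def test_acquisition_schedule_timing(self):
        pairs = acquisition_schedule(period=20.0, settle_delay=3.0, pair_interval=20.0, duration=40.0)
        # relaxed at +3 s, stretched 3 s after the half-period transition
        assert pairs[0] == (3.0, 13.0)

    def test_acquisition_schedule_18h_protocol(self):
        pairs = acquisition_schedule()
        assert len(pairs) == 109  # initial pair + 108 at 10-min intervals

    def test_acquisition_empty_and_invalid(self):
        assert acquisition_schedule(duration=0.0) == []
        with pytest.raises(ValueError):
            acquisition_schedule(settle_delay=15.0)
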