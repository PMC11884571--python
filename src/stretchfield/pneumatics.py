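"""Pneumatic actuation: set-point waveforms, lag response, rate statistics.

Vacuum is expressed in gauge percent (v% of atmosphere) and converted to
absolute pressure as p = (1 - v/100) * 1 bar, so 35% vacuum is 0.65 bar and
0% is atmosphere. Set-point waveforms (rectangular / trapezoidal /
sinusoidal) are slewed at a finite slope and sampled at a fixed rate,
mirroring a DAQ-driven proportional valve; the plant response is modeled as
a linear time-invariant lag — first order, or underdamped second order when
the measured response overshoots before settling.

Rate analysis differentiates the pressure trace by central differences and
extracts the per-period extreme rates: the most negative rate during
evacuation (pull to vacuum) and the most positive during venting (return to
atmosphere), summarised as mean ± SEM over periods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "WaveformSpec",
    "PressureTrace",
    "RateStats",
    "vacuum_to_pressure",
    "pressure_to_vacuum",
    "generate_setpoint",
    "simulate_response",
    "fit_second_order",
    "pressure_rate",
    "rate_peaks",
    "implied_strain_rate",
    "cycles_in_duration",
    "frequency",
    "acquisition_schedule",
]

ATM_BAR = 1.0


@dataclass(frozen=True)
class WaveformSpec:
    """Set-point waveform for cyclic vacuum actuation.

    Defaults follow the characterised operating point: rectangular waveform,
    20 s period (0.05 Hz), 35% vacuum depth, a 17.5 bar/s set-point slope
    and 10 ms sampling.
    """

    shape: str = "rectangular"  # rectangular | trapezoidal | sinusoidal
    period: float = 20.0  # s
    vacuum_fraction: float = 0.35  # 0..1 (35% vacuum -> 0.65 bar)
    setpoint_slope: float = 17.5  # bar/s
    sample_dt: float = 0.010  # s
    duration: float = 400.0  # s
    ramp_time: float | None = None  # s; trapezoidal ramp duration

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if not 0 <= self.vacuum_fraction <= 1:
            raise ValueError("vacuum_fraction must be in [0, 1]")
        if self.sample_dt <= 0:
            raise ValueError("sample_dt must be positive")
        if self.shape not in ("rectangular", "trapezoidal", "sinusoidal"):
            raise ValueError(f"unknown waveform shape {self.shape!r}")
        if self.shape in ("rectangular", "trapezoidal") and self.setpoint_slope <= 0:
            raise ValueError("setpoint_slope must be positive for ramped shapes")


@dataclass
class PressureTrace:
    """Uniformly sampled absolute pressure (bar)."""

    times: np.ndarray  # s
    pressure: np.ndarray  # bar

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.times.shape != self.pressure.shape:
            raise ValueError("times and pressure must have equal length")
        if len(self.times) >= 2:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("pressure trace must be uniformly sampled")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class RateStats:
    evacuation_rate_mean: float  # bar/s (negative: pressure falls)
    evacuation_rate_sem: float
    venting_rate_mean: float  # bar/s (positive)
    venting_rate_sem: float
    n_periods: int


def vacuum_to_pressure(vacuum_percent: float) -> float:
    """Absolute pressure (bar) for a gauge vacuum percentage: 35% -> 0.65 bar."""
    v = np.asarray(vacuum_percent, dtype=float)
    if np.any(v < 0) or np.any(v > 100):
        raise ValueError("vacuum percentage must be in [0, 100]")
    out = (1.0 - v / 100.0) * ATM_BAR
    return float(out) if out.ndim == 0 else out


def pressure_to_vacuum(pressure_bar: float) -> float:
    """Inverse conversion: 0.65 bar -> 35% vacuum."""
    p = np.asarray(pressure_bar, dtype=float)
    if np.any(p < 0) or np.any(p > ATM_BAR):
        raise ValueError("absolute pressure must be in [0, 1] bar for vacuum operation")
    out = (1.0 - p / ATM_BAR) * 100.0
    return float(out) if out.ndim == 0 else out


def _slew(target: np.ndarray, dt: float, slope: float, start: float) -> np.ndarray:
    """Slew-rate-limit a sampled target signal (max |dp/dt| = slope).

    Sample 0 holds the resting value; the output moves toward the target
    from sample 1 on, so a trace always opens at its pre-trigger state.
    """
    out = np.empty_like(target)
    out[0] = prev = start
    max_step = slope * dt
    for i, t in enumerate(target[1:], start=1):
        prev = prev + np.clip(t - prev, -max_step, max_step)
        out[i] = prev
    return out


def generate_setpoint(spec: WaveformSpec) -> PressureTrace:
    """Sampled set-point pressure trace for the requested waveform.

    Rectangular: 50% duty cycle — each period opens with the evacuation to
    the vacuum target (stretched plateau, half a period) and vents back to
    atmosphere for the second half — with transitions slewed at
    ``setpoint_slope``. Trapezoidal: like rectangular but ramped over
    ``ramp_time``. Sinusoidal: offset sine between atmosphere and the vacuum
    target.
    """
    n = int(round(spec.duration / spec.sample_dt))
    t = np.arange(n) * spec.sample_dt
    p_low = vacuum_to_pressure(100 * spec.vacuum_fraction)
    if spec.vacuum_fraction == 0:
        return PressureTrace(t, np.full(n, ATM_BAR))
    phase = np.mod(t, spec.period)
    if spec.shape == "sinusoidal":
        mid = (ATM_BAR + p_low) / 2
        amp = (ATM_BAR - p_low) / 2
        p = mid + amp * np.cos(2 * np.pi * t / spec.period)
        return PressureTrace(t, p)
    # square target: vacuum (stretched) first half, atmosphere second half,
    # so every period contains one evacuation and one venting transition
    target = np.where(phase < spec.period / 2, p_low, ATM_BAR)
    if spec.shape == "trapezoidal":
        ramp = spec.ramp_time if spec.ramp_time else (ATM_BAR - p_low) / spec.setpoint_slope
        slope = (ATM_BAR - p_low) / ramp
    else:
        slope = spec.setpoint_slope
    p = _slew(target, spec.sample_dt, slope, ATM_BAR)
    return PressureTrace(t, p)


def fit_second_order(
    crossing_time: float = 0.300, settle_time: float = 1.5, settle_band: float = 0.02
) -> tuple[float, float]:
    """Natural frequency and damping for the underdamped lag model.

    Chooses damping 0.5 and sets the natural frequency so the step response
    first reaches its final value at ``crossing_time`` (the measured
    evacuation time); verifies the envelope is inside ``settle_band`` of the
    step by ``settle_time``. Returns (omega_n rad/s, zeta).
    """
    zeta = 0.5
    omega_d_t = math.pi - math.acos(zeta)  # first crossing: sin(wd t + phi) = 0
    omega_n = omega_d_t / (crossing_time * math.sqrt(1 - zeta**2))
    envelope = math.exp(-zeta * omega_n * settle_time) / math.sqrt(1 - zeta**2)
    if envelope > settle_band:
        raise ValueError("model cannot settle within the requested band")
    return omega_n, zeta


def simulate_response(
    setpoint: PressureTrace,
    tau: float | None = None,
    omega_n: float | None = None,
    zeta: float | None = None,
) -> PressureTrace:
    """Apply the LTI lag model to a set-point trace.

    Pass ``tau`` for a first-order lag (no overshoot), or ``omega_n`` and
    ``zeta`` for a second-order model; ``zeta < 1`` produces the
    overshoot-then-stabilize response seen at the valve. With no parameters,
    the second-order model fitted to the measured 300 ms evacuation /
    1.5 s settling is used. Output sampling matches the input exactly.
    """
    if len(setpoint.times) < 2:
        raise ValueError("setpoint trace too short")
    if tau is not None:
        if tau <= 0:
            raise ValueError("time constant must be positive")
        system = signal.lti([1.0], [tau, 1.0])
    else:
        if omega_n is None or zeta is None:
            omega_n, zeta = fit_second_order()
        if omega_n <= 0 or zeta <= 0:
            raise ValueError("omega_n and zeta must be positive")
        system = signal.lti([omega_n**2], [1.0, 2 * zeta * omega_n, omega_n**2])
    # simulate deviation from the initial value so the trace starts at rest
    p0 = setpoint.pressure[0]
    _, y, _ = signal.lsim(system, setpoint.pressure - p0, setpoint.times)
    return PressureTrace(setpoint.times, y + p0)


def pressure_rate(trace: PressureTrace) -> np.ndarray:
    """dp/dt (bar/s) by central differences (one-sided at the ends)."""
    if len(trace.times) < 3:
        raise ValueError("need at least three samples to differentiate")
    return np.gradient(trace.pressure, trace.times)


def rate_peaks(trace: PressureTrace, period: float) -> RateStats:
    """Per-period extreme pressure-change rates, mean ± SEM over periods.

    Evacuation is the most negative rate in each complete period, venting the
    most positive. SEM uses the sample standard deviation (ddof=1); it is
    reported as 0 for a single period or identical periods.
    """
    rate = pressure_rate(trace)
    t = trace.times
    # the trace covers n_samples * dt of signal time
    n_periods = int(np.floor((t[-1] - t[0] + trace.dt) / period + 1e-9))
    if n_periods < 1:
        raise ValueError("trace shorter than one period")
    evac, vent = [], []
    for k in range(n_periods):
        sel = (t >= t[0] + k * period) & (t < t[0] + (k + 1) * period)
        if not sel.any():
            continue
        evac.append(rate[sel].min())
        vent.append(rate[sel].max())
    evac = np.asarray(evac)
    vent = np.asarray(vent)
    if len(evac) == 0 or (np.all(evac == 0) and np.all(vent == 0)):
        raise ValueError("no rate peaks detected")

    def sem(x):
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    return RateStats(
        evacuation_rate_mean=float(evac.mean()),
        evacuation_rate_sem=sem(evac),
        venting_rate_mean=float(vent.mean()),
        venting_rate_sem=sem(vent),
        n_periods=len(evac),
    )


def implied_strain_rate(
    strain_at_vacuum_percent: float,
    vacuum_depth_bar: float,
    rate_bar_per_s: float,
    rounded: bool = True,
) -> float:
    """Strain rate (%/s) implied by a pressure-change rate.

    Uses the linear strain–vacuum relation: a strain of s% reached at a
    vacuum depth of d bar gives sensitivity s/d %/bar, so a pressure-change
    rate r bar/s implies a strain rate (s/d)*|r| %/s. With the characterised
    8% strain at 0.35 bar, rates of 2 and 1.3 bar/s imply 46 and 30 %/s
    (rounded to integers, as conventionally reported).
    """
    if vacuum_depth_bar <= 0:
        raise ValueError("vacuum depth must be positive")
    rate = strain_at_vacuum_percent / vacuum_depth_bar * abs(rate_bar_per_s)
    return float(round(rate)) if rounded else float(rate)


def cycles_in_duration(duration_s: float, period_s: float) -> int:
    """Number of complete stretch cycles: floor(duration / period).

    18 h at a 20 s period is 3240 cycles.
    """
    if period_s <= 0:
        raise ValueError("period must be positive")
    return int(np.floor(duration_s / period_s + 1e-9))


def frequency(period_s: float) -> float:
    """Cyclic frequency in Hz (20 s period -> 0.05 Hz)."""
    if period_s <= 0:
        raise ValueError("period must be positive")
    return 1.0 / period_s


def acquisition_schedule(
    period: float = 20.0,
    settle_delay: float = 3.0,
    pair_interval: float = 600.0,
    duration: float = 64800.0,
) -> list[tuple[float, float]]:
    """Image trigger times for relaxed/stretched pair acquisition.

    Each period starts relaxed and switches to stretched at the half period;
    the relaxed image is triggered ``settle_delay`` s after the period start
    and the stretched image ``settle_delay`` s after the transition (to let
    the pneumatic overshoot stabilize). Pairs are emitted every
    ``pair_interval`` s for ``duration`` s. Defaults give the 18 h / 10 min
    stability protocol: 109 pairs (the initial pair plus 108).
    """
    if settle_delay >= period / 2:
        raise ValueError("settle_delay must be shorter than half a period")
    if pair_interval < period:
        raise ValueError("pair_interval must be at least one period")
    if pair_interval % period != 0:
        raise ValueError("pair_interval must be a whole number of periods")
    if duration < period:
        return []
    # pair periods start at multiples of pair_interval, from 0 through the
    # duration inclusive (acquisition runs *for* the duration, so the pair
    # whose period opens exactly at the end point is still triggered)
    n = int(np.floor(duration / pair_interval + 1e-9)) + 1
    return [
        (k * pair_interval + settle_delay, k * pair_interval + period / 2 + settle_delay)
        for k in range(n)
    ]
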