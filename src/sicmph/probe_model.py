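"""Electrical and dynamic model of single- and double-barrel nanoprobes.

The pH-sensitive barrel is a nanopipette sealed by a zwitterionic
nanomembrane whose ion-current rectification depends on pH: the membrane
passes anions preferentially in acid and cations in base, so the I-V curve
is asymmetric and the asymmetry flips sign around a neutral point pH0.  The
simplest functional form with those properties is

    I(V, pH) = G0 * V * [1 + rho * (pH - pH0) * tanh(V / V_T)]

which is ohmic at pH0 and exactly affine in pH at any fixed bias - the
basis of the linear current-pH calibration at the +600 mV working bias.

The open (SICM) barrel supplies distance feedback through the classical
approach-curve drop of the ion current near a surface,

    I(d) / I_bulk = 1 / (1 + alpha * r_i / d),

with the default alpha placing the 1% setpoint crossing at one inner tip
radius.  A first-order sensor lag, additive white noise and a single-pole
anti-alias filter model the recording chain (20 kHz sampling, 2 kHz
low-pass by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import signal, stats

from .exceptions import CalibrationError, ConfigurationError, EstimationError

__all__ = [
    "ProbeGeometry",
    "SensorModel",
    "FeedbackModel",
    "CalibrationFit",
    "PHReading",
    "Probe",
    "sensor_current",
    "cv_sweep",
    "fit_calibration",
    "default_calibration",
    "current_to_pH",
    "reversal_potential",
    "bulk_current_for_tip",
    "approach_current",
    "setpoint_distance",
    "sensor_readout",
    "response_time",
]

# Anchors of the tip-size/current scaling at -0.6 V bias:
# 100 nm inner diameter -> -0.8 nA; 2.5 um -> -70 nA.
_TIP_ANCHOR_D = 1.0e-7           # m, diameter
_TIP_ANCHOR_I = -0.8e-9          # A
_TIP_ANCHOR_BIAS = -0.6          # V
_TIP_EXPONENT = math.log(70.0 / 0.8) / math.log(25.0)   # ~1.389

#: Default base conductance: |I| = 0.8 nA at -0.6 V for a 100 nm tip.
_G0_DEFAULT = abs(_TIP_ANCHOR_I / _TIP_ANCHOR_BIAS)     # 1.333e-9 S


@dataclass(frozen=True)
class ProbeGeometry:
    """Tip geometry. ``membrane_thickness`` is documentation only."""

    inner_radius: float = 50e-9
    radius_ratio: float = 1.5
    membrane_thickness: float = 200e-9
    barrels: int = 2

    def __post_init__(self) -> None:
        if self.inner_radius <= 0:
            raise ConfigurationError("inner_radius must be > 0")
        if self.radius_ratio <= 1:
            raise ConfigurationError("outer/inner radius ratio must be > 1")
        if self.barrels not in (1, 2):
            raise ConfigurationError("barrels must be 1 or 2")

    @property
    def inner_diameter(self) -> float:
        return 2.0 * self.inner_radius


@dataclass(frozen=True)
class SensorModel:
    """Rectification-based pH sensor with lag and noise.

    ``rectification`` (rho) is the fractional asymmetry per pH unit;
    its negative default makes the current at +600 mV decrease with pH.
    ``noise_rms`` defaults to 0.5% of the bulk working-bias current.
    ``time_constant`` is set so the 95%-band response time of the full
    recording chain is about 2 ms.
    """

    base_conductance: float = _G0_DEFAULT
    rectification: float = -0.08
    rectification_voltage_scale: float = 0.3
    neutral_pH: float = 7.0
    working_bias: float = 0.600
    linear_range: tuple[float, float] = (4.0, 9.0)
    time_constant: float = 0.67e-3
    noise_rms: float = 0.005 * _G0_DEFAULT * 0.600
    reversal_slope: float = 17.5     # mV per pH unit

    def __post_init__(self) -> None:
        if self.base_conductance <= 0:
            raise ConfigurationError("base_conductance must be > 0")
        if self.rectification_voltage_scale <= 0:
            raise ConfigurationError("rectification_voltage_scale must be > 0")
        if self.time_constant < 0 or self.noise_rms < 0:
            raise ConfigurationError("time_constant and noise_rms must be >= 0")
        lo, hi = self.linear_range
        if not lo < hi:
            raise ConfigurationError("linear_range must be increasing")

    @property
    def pH_slope(self) -> float:
        """dI/dpH at the working bias, A per pH unit (exact for the model)."""
        v = self.working_bias
        return (self.base_conductance * v * self.rectification
                * math.tanh(v / self.rectification_voltage_scale))


@dataclass(frozen=True)
class FeedbackModel:
    """SICM distance-feedback barrel at the feedback bias (default -200 mV).

    ``pH_coupled`` marks a single-barrel pH probe serving as its own
    feedback sensor, which couples topography detection to the local pH.
    ``noise_fraction`` is the white-noise RMS relative to the bulk current.
    """

    bulk_current: float = _TIP_ANCHOR_I * (0.2 / 0.6)   # ohmic scale to -0.2 V
    bias: float = -0.200
    approach_constant: float = 0.0101
    setpoint_fraction: float = 0.01
    pH_coupled: bool = False
    noise_fraction: float = 0.002
    time_constant: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.setpoint_fraction < 1.0:
            raise ConfigurationError("setpoint_fraction must lie in (0, 1)")
        if self.approach_constant <= 0:
            raise ConfigurationError("approach_constant must be > 0")
        if self.noise_fraction < 0 or self.time_constant < 0:
            raise ConfigurationError("noise parameters must be >= 0")


class PHReading(NamedTuple):
    """A pH value plus a flag for extrapolation outside the calibrated range."""

    pH: float
    out_of_range: bool


@dataclass(frozen=True)
class CalibrationFit:
    """Ordinary-least-squares current-vs-pH calibration line."""

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    valid_range: tuple[float, float]

    def predict(self, pH: float) -> float:
        return self.slope * pH + self.intercept

    def in_range(self, pH: float) -> bool:
        lo, hi = self.valid_range
        return lo <= pH <= hi


@dataclass(frozen=True)
class Probe:
    """A nanoprobe: geometry + pH sensor + feedback barrel + calibration."""

    geometry: ProbeGeometry = field(default_factory=ProbeGeometry)
    sensor: SensorModel = field(default_factory=SensorModel)
    feedback: FeedbackModel = field(default_factory=FeedbackModel)
    calibration: CalibrationFit | None = None

    @classmethod
    def double_barrel(cls, **overrides) -> "Probe":
        """Theta pipette: open SICM barrel decoupled from the pH barrel."""
        probe = cls(**overrides)
        return replace(probe, feedback=replace(probe.feedback, pH_coupled=False))

    @classmethod
    def single_barrel(cls, **overrides) -> "Probe":
        """One membrane-sealed barrel doing both feedback and pH sensing."""
        geometry = overrides.pop("geometry", ProbeGeometry(barrels=1))
        probe = cls(geometry=geometry, **overrides)
        fb = replace(probe.feedback, pH_coupled=True,
                     noise_fraction=0.005,
                     time_constant=probe.sensor.time_constant)
        return replace(probe, feedback=fb)

    def calibrated(self, n_points: int = 6) -> "Probe":
        """Attach a noiseless calibration over the sensor's linear range."""
        return replace(self, calibration=default_calibration(self.sensor,
                                                             n_points))


# ---------------------------------------------------------------------------
# Electrical model
# ---------------------------------------------------------------------------

def sensor_current(sensor: SensorModel, V, pH):
    """Membrane current I(V, pH) = G0 V [1 + rho (pH - pH0) tanh(V/V_T)], A."""
    pH_arr = np.asarray(pH, dtype=float)
    if np.any(pH_arr <= 0.0) or np.any(pH_arr >= 14.0):
        raise ValueError("pH out of the (0, 14) domain")
    V = np.asarray(V, dtype=float)
    out = sensor.base_conductance * V * (
        1.0 + sensor.rectification * (pH_arr - sensor.neutral_pH)
        * np.tanh(V / sensor.rectification_voltage_scale))
    return float(out) if out.ndim == 0 else out


def cv_sweep(sensor: SensorModel, pH: float, v_min: float = -0.6,
             v_max: float = 0.6, rate: float = 0.650, fs: float = 20e3,
             seed=None) -> pd.DataFrame:
    """One triangular cyclic-voltammetry cycle sampled at ``fs``.

    The schedule ramps v_min -> v_max -> v_min at the stated scan rate, so a
    full cycle spans 2 (v_max - v_min) / rate seconds.  Currents come from
    :func:`sensor_current` plus the sensor's white noise.
    """
    if rate <= 0:
        raise ConfigurationError("scan rate must be > 0")
    if v_min >= v_max:
        raise ConfigurationError("v_min must be < v_max")
    duration = 2.0 * (v_max - v_min) / rate
    t = np.arange(0.0, duration, 1.0 / fs)
    half = duration / 2.0
    v = np.where(t < half, v_min + rate * t, v_max - rate * (t - half))
    i = np.asarray(sensor_current(sensor, v, pH), dtype=float)
    if sensor.noise_rms > 0:
        rng = np.random.default_rng(seed)
        i = i + rng.normal(0.0, sensor.noise_rms, size=i.shape)
    return pd.DataFrame({"time_s": t, "voltage_V": v, "current_A": i})


def fit_calibration(points) -> CalibrationFit:
    """OLS line through (pH, current-at-working-bias) calibration points.

    ``points`` is a sequence of (pH, current_A) pairs or an (n, 2) array.
    Requires at least three distinct pH values.
    """
    arr = np.asarray(list(points) if not isinstance(points, np.ndarray)
                     else points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise CalibrationError("need >= 3 (pH, current) calibration points")
    ph, cur = arr[:, 0], arr[:, 1]
    if np.unique(ph).size < 3 or np.ptp(ph) == 0.0:
        raise CalibrationError("calibration points must span >= 3 distinct pH")
    res = stats.linregress(ph, cur)
    resid = cur - (res.slope * ph + res.intercept)
    dof = max(arr.shape[0] - 2, 1)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        residual_sd=float(np.sqrt(np.sum(resid ** 2) / dof)),
        valid_range=(float(ph.min()), float(ph.max())),
    )


def default_calibration(sensor: SensorModel, n_points: int = 6) -> CalibrationFit:
    """Noiseless calibration on an even pH grid over the linear range."""
    lo, hi = sensor.linear_range
    ph = np.linspace(lo, hi, n_points)
    cur = sensor_current(sensor, sensor.working_bias, ph)
    return fit_calibration(np.column_stack([ph, cur]))


def current_to_pH(fit: CalibrationFit, current: float) -> PHReading:
    """Invert the calibration line; flags readings outside the fitted range."""
    if fit.slope == 0.0:
        raise CalibrationError("cannot invert a zero-slope calibration")
    ph = (float(current) - fit.intercept) / fit.slope
    return PHReading(pH=ph, out_of_range=not fit.in_range(ph))


def reversal_potential(sensor: SensorModel, pH) -> float:
    """Zero-current (reversal) potential in mV: E_rev = s_rev (pH - pH0)."""
    pH = np.asarray(pH, dtype=float)
    out = sensor.reversal_slope * (pH - sensor.neutral_pH)
    return float(out) if out.ndim == 0 else out


def bulk_current_for_tip(geometry: ProbeGeometry, bias: float = -0.6) -> float:
    """Bulk current for a tip of given size, A (log-log interpolation).

    Anchored at (100 nm diameter, -0.8 nA) and (2.5 um, -70 nA) at -0.6 V;
    other biases scale ohmically.  Diameters outside [50 nm, 5 um] trigger
    an extrapolation warning.
    """
    d = geometry.inner_diameter
    if not 50e-9 <= d <= 5e-6:
        warnings.warn("tip diameter outside the anchored 50 nm - 5 um range; "
                      "extrapolating the power law", stacklevel=2)
    mag = abs(_TIP_ANCHOR_I) * (d / _TIP_ANCHOR_D) ** _TIP_EXPONENT
    return math.copysign(mag, bias) * abs(bias / _TIP_ANCHOR_BIAS) * (
        1.0 if bias != 0 else 0.0)


def approach_current(feedback: FeedbackModel, geometry: ProbeGeometry, d,
                     local_pH=None, sensor: SensorModel | None = None,
                     reference_pH: float | None = None):
    """Normalized feedback current I(d)/I_bulk = 1/(1 + alpha r_i / d).

    Strictly increasing in d and -> 1 far from the surface.  When the
    feedback is ``pH_coupled`` (single-barrel probe) the bulk current is
    additionally scaled by the sensor's rectification response at the
    feedback bias, so the normalized current depends on ``local_pH``
    relative to ``reference_pH`` (defaults to the sensor neutral point).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0.0):
        raise ValueError("tip-surface distance d must be > 0")
    out = 1.0 / (1.0 + feedback.approach_constant * geometry.inner_radius / d)
    if feedback.pH_coupled and local_pH is not None:
        if sensor is None:
            raise ConfigurationError(
                "pH-coupled feedback needs the sensor model")
        ref = sensor.neutral_pH if reference_pH is None else reference_pH
        g_loc = sensor_current(sensor, feedback.bias, local_pH)
        g_ref = sensor_current(sensor, feedback.bias, ref)
        out = out * np.asarray(g_loc) / g_ref
    return float(out) if out.ndim == 0 else out


def setpoint_distance(feedback: FeedbackModel,
                      geometry: ProbeGeometry) -> float:
    """Tip-surface distance at which the setpoint drop occurs, m.

    Solves 1/(1 + alpha r_i/d) = 1 - s for the uncoupled approach curve:
    d = alpha r_i (1 - s)/s.  With the defaults (alpha = 0.0101, s = 1%)
    this is one inner radius - the feedback sensing range.
    """
    s = feedback.setpoint_fraction
    return feedback.approach_constant * geometry.inner_radius * (1.0 - s) / s


# ---------------------------------------------------------------------------
# Recording chain
# ---------------------------------------------------------------------------

def _one_pole(x: np.ndarray, pole: float) -> np.ndarray:
    """y[n] = (1-a) x[n] + a y[n-1], initialised at equilibrium with x[0]."""
    b, a = [1.0 - pole], [1.0, -pole]
    zi = np.array([pole * x[0]])
    y, _ = signal.lfilter(b, a, x, zi=zi)
    return y


def sensor_readout(true_signal, sensor: SensorModel, fs: float,
                   f_c: float | None = 2e3, seed=None,
                   noise_rms: float | None = None,
                   time_constant: float | None = None) -> np.ndarray:
    """Pass a true signal through the sensor's recording chain.

    First-order sensor lag (``time_constant``), additive white Gaussian
    noise, then a single-pole low-pass at ``f_c`` (``None`` disables the
    filter), all at sampling rate ``fs``.  Deterministic under a fixed
    ``seed`` (an int or a Generator).  ``noise_rms``/``time_constant``
    override the sensor's values, e.g. for the feedback barrel.
    """
    x = np.asarray(true_signal, dtype=float).copy()
    if x.ndim != 1:
        raise ValueError("true_signal must be a 1-D time series")
    if f_c is not None and fs <= 2.0 * f_c:
        raise ConfigurationError("need fs > 2 f_c")
    tau = sensor.time_constant if time_constant is None else time_constant
    rms = sensor.noise_rms if noise_rms is None else noise_rms
    if tau > 0:
        x = _one_pole(x, math.exp(-1.0 / (fs * tau)))
    if rms > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        x = x + rng.normal(0.0, rms, size=x.shape)
    if f_c is not None:
        x = _one_pole(x, math.exp(-2.0 * math.pi * f_c / fs))
    return x


def response_time(trace, fs: float, band: float = 0.05,
                  sustain: int = 5) -> float:
    """Response time of a recorded step trace, s.

    Defined as the time from the step onset to the first *sustained* entry
    (``sustain`` consecutive samples) into the +/- ``band`` fraction of the
    step amplitude around the final plateau.  The onset is located at the
    steepest sample-to-sample change.
    """
    y = np.asarray(trace, dtype=float)
    if y.size < sustain + 2:
        raise EstimationError("trace too short to contain a step")
    onset = int(np.argmax(np.abs(np.diff(y)))) + 1
    baseline = y[0] if onset <= 1 else float(np.median(y[:onset]))
    tail = y[-max(sustain, y.size // 10):]
    plateau = float(np.mean(tail))
    amplitude = plateau - baseline
    if amplitude == 0.0:
        raise EstimationError("trace contains no step")
    if np.std(tail) > band * abs(amplitude):
        raise EstimationError("trace has not settled to a plateau")
    inside = np.abs(y - plateau) <= band * abs(amplitude)
    inside[:onset] = False
    run = np.convolve(inside.astype(int), np.ones(sustain, dtype=int),
                      mode="valid")
    hits = np.flatnonzero(run == sustain)
    if hits.size == 0:
        raise EstimationError("no sustained entry into the settling band")
    first = int(hits[0])
    return (first - onset + 1) / fs
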