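"""The virtual SICM: hopping-mode self-referencing scans of synthetic scenes.

Implements the four-step per-pixel protocol used for simultaneous
topography / extracellular-pH mapping with a double-barrel nanoprobe:

1. withdraw the probe to the hop ceiling (~10 um above the last detected
   surface);
2. hold for 1 ms while the stage moves to the new pixel, recording the
   *bulk* pH-barrel current (the self-referencing baseline) and refreshing
   the feedback reference current;
3. descend at a constant fall rate (25 nm/ms) while sampling the feedback
   barrel through the recording chain; declare the surface at the first
   debounced crossing of the setpoint (a 0.5-1% current drop) and record Z;
4. withdraw 100 nm and record the *surface* pH-barrel current for 1 ms.

The pixel's pH gradient is dpH = pH_surface - pH_bulk, which cancels any
additive sensor drift that is slow compared with one hop cycle.  Variants:
``single_barrel_hopping`` routes the pH-sensitive membrane current into the
feedback loop (reproducing the ball-like topographic artefact over strong
pH gradients) and ``constant_height`` rasters the pH barrel at a fixed Z
with no feedback at all.

Topography maps are reported with the deterministic setpoint-crossing
distance (about one tip radius) subtracted; the raw detected Z is kept in
each :class:`PixelRecord`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator

import numpy as np
import pandas as pd

from .exceptions import (CollisionError, ConfigurationError, NoSurfaceError)
from .probe_model import (CalibrationFit, PHReading, Probe, current_to_pH,
                          sensor_current, sensor_readout, setpoint_distance)

__all__ = [
    "ScanConfig",
    "PixelRecord",
    "ScanResult",
    "run_hopping_scan",
    "run_single_barrel_scan",
    "run_constant_height_scan",
    "self_reference",
    "detect_surface",
    "serpentine_order",
]

_D_FLOOR = 5e-11  # m; descent samples stop this far above the true surface


@dataclass(frozen=True)
class ScanConfig:
    """Hopping-mode protocol parameters (SI units)."""

    nx: int
    ny: int
    pitch: float
    hop_amplitude: float = 10e-6
    fall_rate: float = 25e-9 / 1e-3          # 25 nm/ms
    withdraw_after_detect: float = 100e-9
    dwell: float = 1e-3
    fs: float = 20e3
    f_c: float = 2e3
    setpoint_fraction: float = 0.01
    debounce_samples: int = 3
    mode: str = "hopping_self_ref"
    constant_height_z: float | None = None
    hop_ceiling: str = "relative"            # or "absolute"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1 or self.pitch <= 0:
            raise ConfigurationError("need nx, ny >= 1 and pitch > 0")
        if not self.hop_amplitude > self.withdraw_after_detect > 0:
            raise ConfigurationError(
                "need hop_amplitude > withdraw_after_detect > 0")
        if self.fall_rate <= 0:
            raise ConfigurationError("fall_rate must be > 0")
        if self.fs <= 2.0 * self.f_c:
            raise ConfigurationError("need fs > 2 f_c")
        if not 0.0 < self.setpoint_fraction < 1.0:
            raise ConfigurationError("setpoint_fraction must lie in (0, 1)")
        if self.debounce_samples < 1:
            raise ConfigurationError("debounce_samples must be >= 1")
        if self.mode not in ("hopping_self_ref", "constant_height",
                             "single_barrel_hopping"):
            raise ConfigurationError(f"unknown scan mode {self.mode!r}")
        if self.hop_ceiling not in ("relative", "absolute"):
            raise ConfigurationError("hop_ceiling must be relative|absolute")

    @property
    def n_dwell(self) -> int:
        return max(1, int(round(self.dwell * self.fs)))

    @property
    def descent_step(self) -> float:
        """Vertical distance per descent sample, m (fall_rate / fs)."""
        return self.fall_rate / self.fs


@dataclass(frozen=True)
class PixelRecord:
    """Per-pixel measurement. ``z_surface`` is the raw detected Z."""

    ix: int
    iy: int
    x: float
    y: float
    z_surface: float
    pH_bulk: float
    pH_surface: float
    delta_pH: float
    no_surface: bool = False
    out_of_range: bool = False


@dataclass
class ScanResult:
    """Assembled maps (row-major [iy, ix], pixel (0,0) at the scan origin)."""

    topography: np.ndarray
    dpH_map: np.ndarray
    abs_pH_map: np.ndarray
    config: ScanConfig
    records: list[PixelRecord] = field(default_factory=list)
    scene: object | None = None
    setpoint_offset: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-pixel table (ix, iy, x_m, y_m, z_m, pH columns, flags)."""
        return pd.DataFrame(
            {
                "ix": [r.ix for r in self.records],
                "iy": [r.iy for r in self.records],
                "x_m": [r.x for r in self.records],
                "y_m": [r.y for r in self.records],
                "z_m": [r.z_surface for r in self.records],
                "pH_bulk": [r.pH_bulk for r in self.records],
                "pH_surface": [r.pH_surface for r in self.records],
                "dpH": [r.delta_pH for r in self.records],
                "no_surface": [r.no_surface for r in self.records],
                "out_of_range": [r.out_of_range for r in self.records],
            }
        )


def serpentine_order(nx: int, ny: int) -> Iterator[tuple[int, int]]:
    """Row-major serpentine raster: even rows left-to-right, odd reversed."""
    for iy in range(ny):
        xs = range(nx) if iy % 2 == 0 else range(nx - 1, -1, -1)
        for ix in xs:
            yield ix, iy


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------

def detect_surface(normalized_trace, z_positions, setpoint_fraction: float,
                   debounce_samples: int) -> tuple[float, int]:
    """Surface Z from a filtered, normalized descent trace.

    Returns (z, index) of the first sample at which the normalized current
    stays below (1 - setpoint_fraction) for ``debounce_samples`` consecutive
    samples.  Raises :class:`NoSurfaceError` when no qualifying run exists.
    """
    trace = np.asarray(normalized_trace, dtype=float)
    z = np.asarray(z_positions, dtype=float)
    if trace.shape != z.shape:
        raise ValueError("trace and z_positions must have the same length")
    below = trace < (1.0 - setpoint_fraction)
    if debounce_samples > 1:
        run = np.convolve(below.astype(int),
                          np.ones(debounce_samples, dtype=int), mode="valid")
        hits = np.flatnonzero(run == debounce_samples)
    else:
        hits = np.flatnonzero(below)
    if hits.size == 0:
        raise NoSurfaceError("descent trace never crossed the setpoint")
    idx = int(hits[0])
    return float(z[idx]), idx


def self_reference(bulk_currents, surface_currents, fit: CalibrationFit,
                   drift=None) -> tuple[PHReading, PHReading, float]:
    """Convert the two dwell windows of one hop into (pH_bulk, pH_surface, dpH).

    Each window's current is averaged, then inverted through the
    calibration line.  ``drift`` optionally injects an additive current
    series into both windows (pair of arrays, or one array split in two) to
    exercise the drift-cancellation property: any offset that is constant
    within one hop cycle cancels exactly in the difference.
    """
    bulk = np.asarray(bulk_currents, dtype=float)
    surf = np.asarray(surface_currents, dtype=float)
    if bulk.size == 0 or surf.size == 0:
        raise ValueError("both dwell windows must be present")
    if drift is not None:
        d_bulk, d_surf = drift
        bulk = bulk + np.asarray(d_bulk, dtype=float)
        surf = surf + np.asarray(d_surf, dtype=float)
    r_bulk = current_to_pH(fit, float(bulk.mean()))
    r_surf = current_to_pH(fit, float(surf.mean()))
    return r_bulk, r_surf, r_surf.pH - r_bulk.pH


# ---------------------------------------------------------------------------
# Scan engine
# ---------------------------------------------------------------------------

class _Engine:
    """Shared state for one scan: probe, scene, rng, clock, filters."""

    def __init__(self, scene, probe: Probe, config: ScanConfig,
                 drift: Callable[[np.ndarray], np.ndarray] | None = None):
        self.scene = scene
        self.probe = probe if probe.calibration else probe.calibrated()
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.t = 0.0
        self.drift = drift
        fb = self.probe.feedback
        self.single = config.mode == "single_barrel_hopping" or fb.pH_coupled
        self.fb_bulk = (
            sensor_current(self.probe.sensor, fb.bias, scene.medium.bulk_pH)
            if self.single else fb.bulk_current)
        self.fb_noise = fb.noise_fraction * abs(self.fb_bulk)

    # -- measurement primitives ------------------------------------------

    def _window_times(self, n: int) -> np.ndarray:
        times = self.t + np.arange(n) / self.config.fs
        self.t += n / self.config.fs
        return times

    def measure_pH_window(self, point: np.ndarray) -> np.ndarray:
        """Raw pH-barrel current samples for one dwell window at ``point``."""
        cfg, sensor = self.config, self.probe.sensor
        true_pH = float(self.scene.ground_truth.pH(point, self.t))
        true_pH = min(max(true_pH, 1e-3), 14.0 - 1e-3)
        i_true = float(sensor_current(sensor, sensor.working_bias, true_pH))
        times = self._window_times(cfg.n_dwell)
        trace = sensor_readout(np.full(cfg.n_dwell, i_true), sensor,
                               cfg.fs, cfg.f_c, seed=self.rng)
        if self.drift is not None:
            trace = trace + np.asarray(self.drift(times), dtype=float)
        return trace

    def measure_feedback_reference(self, point: np.ndarray,
                                   d: float) -> float:
        """Mean feedback current over one dwell at the hop ceiling."""
        cfg, fb = self.config, self.probe.feedback
        geom = self.probe.geometry
        f = 1.0 / (1.0 + fb.approach_constant * geom.inner_radius / d)
        i_true = self._feedback_current(np.array([point[2]]), point, f)[0]
        trace = sensor_readout(np.full(cfg.n_dwell, i_true),
                               self.probe.sensor, cfg.fs, cfg.f_c,
                               seed=self.rng, noise_rms=self.fb_noise,
                               time_constant=fb.time_constant)
        self.t += cfg.n_dwell / cfg.fs
        return float(trace.mean())

    def _feedback_current(self, z: np.ndarray, point: np.ndarray, f):
        """Model feedback current at heights ``z`` (coupling aware)."""
        if self.single:
            sensor, fb = self.probe.sensor, self.probe.feedback
            pts = np.column_stack([np.full(z.size, point[0]),
                                   np.full(z.size, point[1]), z])
            ph = np.clip(np.asarray(self.scene.ground_truth.pH(pts, self.t),
                                    dtype=float), 1e-3, 14.0 - 1e-3)
            return np.atleast_1d(np.asarray(sensor_current(sensor, fb.bias, ph)) * f)
        return np.atleast_1d(self.fb_bulk * np.asarray(f, dtype=float))

    def descend(self, point: np.ndarray, z_top: float, z_true: float,
                i_ref: float) -> tuple[float, int]:
        """Step-3 descent; returns (raw detected z, sample index)."""
        cfg, fb, geom = self.config, self.probe.feedback, self.probe.geometry
        # physically the descent continues until the current drops; the trace
        # is generated down to just above the true surface, where the
        # approach-curve falloff makes a crossing certain in the noiseless case
        z_floor = max(z_true + _D_FLOOR, 0.0)
        n = int(math.floor((z_top - z_floor) / cfg.descent_step)) + 1
        z = z_top - cfg.descent_step * np.arange(n)
        d = np.maximum(z - z_true, _D_FLOOR)
        f = 1.0 / (1.0 + fb.approach_constant * geom.inner_radius / d)
        i_model = self._feedback_current(z, point, f)
        trace = sensor_readout(i_model, self.probe.sensor, cfg.fs, cfg.f_c,
                               seed=self.rng, noise_rms=self.fb_noise,
                               time_constant=fb.time_constant)
        norm = trace / i_ref
        z_det, idx = detect_surface(norm, z, cfg.setpoint_fraction,
                                    cfg.debounce_samples)
        self.t += (idx + 1) / cfg.fs
        return z_det, idx


def run_hopping_scan(scene, probe: Probe, config: ScanConfig,
                     drift: Callable[[np.ndarray], np.ndarray] | None = None
                     ) -> ScanResult:
    """Execute the four-step hopping-mode self-referencing scan.

    ``drift`` optionally injects an additive pH-barrel current drift as a
    function of absolute scan time (vectorized over sample times), used to
    verify that self-referencing cancels slow sensor drift.  Deterministic
    under a fixed ``config.seed``.
    """
    eng = _Engine(scene, probe, config, drift)
    cfg = config
    fit = eng.probe.calibration
    d_set = setpoint_distance(eng.probe.feedback, eng.probe.geometry)

    nx, ny = cfg.nx, cfg.ny
    topo = np.full((ny, nx), np.nan)
    dph = np.full((ny, nx), np.nan)
    records: list[PixelRecord] = []
    last_surface = 0.0

    for ix, iy in serpentine_order(nx, ny):
        x, y = ix * cfg.pitch, iy * cfg.pitch
        z_true = float(scene.topography(x, y))
        z_top = (last_surface + cfg.hop_amplitude
                 if cfg.hop_ceiling == "relative" else cfg.hop_amplitude)
        if z_top <= z_true:
            records.append(PixelRecord(ix, iy, x, y, math.nan, math.nan,
                                       math.nan, math.nan, no_surface=True))
            continue
        top_point = np.array([x, y, z_top])

        # step 2: bulk reference windows (pH barrel + feedback reference)
        bulk_window = eng.measure_pH_window(top_point)
        i_ref = eng.measure_feedback_reference(top_point, z_top - z_true)

        # step 3: feedback-controlled descent
        try:
            z_det, _ = eng.descend(top_point, z_top, z_true, i_ref)
        except NoSurfaceError:
            records.append(PixelRecord(ix, iy, x, y, math.nan, math.nan,
                                       math.nan, math.nan, no_surface=True))
            continue

        # step 4: withdraw 100 nm, surface pH window
        z_meas = z_det + cfg.withdraw_after_detect
        eng.t += cfg.withdraw_after_detect / cfg.fall_rate
        surf_window = eng.measure_pH_window(np.array([x, y, z_meas]))

        r_bulk, r_surf, delta = self_reference(bulk_window, surf_window, fit)
        flag_range = r_bulk.out_of_range or r_surf.out_of_range
        records.append(PixelRecord(ix, iy, x, y, z_det, r_bulk.pH, r_surf.pH,
                                   delta, out_of_range=flag_range))
        topo[iy, ix] = z_det - d_set
        dph[iy, ix] = delta
        last_surface = z_det

    abs_map = scene.medium.bulk_pH + dph
    return ScanResult(topography=topo, dpH_map=dph, abs_pH_map=abs_map,
                      config=cfg, records=records, scene=scene,
                      setpoint_offset=d_set)


def run_single_barrel_scan(scene, probe: Probe, config: ScanConfig,
                           drift=None) -> ScanResult:
    """Hopping scan with a pH-coupled single-barrel probe.

    Identical protocol, but the feedback current is the membrane current of
    the pH sensor, so strong pH gradients perturb the detected topography
    (the ball-like artefact over an active H+ source).
    """
    if not probe.feedback.pH_coupled:
        probe = replace(probe, feedback=replace(probe.feedback,
                                                pH_coupled=True,
                                                noise_fraction=0.005))
    config = replace(config, mode="single_barrel_hopping")
    return run_hopping_scan(scene, probe, config, drift)


def run_constant_height_scan(scene, probe: Probe,
                             config: ScanConfig) -> ScanResult:
    """Lateral raster of the pH barrel at a fixed height (no feedback).

    Reports dpH relative to the medium's bulk pH; the topography plane of
    the result is all-NaN since no surface detection takes place.  Raises
    :class:`CollisionError` if the plane intersects the sample.
    """
    if config.constant_height_z is None:
        raise ConfigurationError("constant_height mode needs constant_height_z")
    z = config.constant_height_z
    eng = _Engine(scene, probe, replace(config, mode="hopping_self_ref"))
    fit = eng.probe.calibration
    nx, ny = config.nx, config.ny
    dph = np.full((ny, nx), np.nan)
    records: list[PixelRecord] = []
    for ix, iy in serpentine_order(nx, ny):
        x, y = ix * config.pitch, iy * config.pitch
        if z <= float(scene.topography(x, y)):
            raise CollisionError(
                f"constant height {z} m is below the sample at pixel "
                f"({ix}, {iy})")
        window = eng.measure_pH_window(np.array([x, y, z]))
        reading = current_to_pH(fit, float(window.mean()))
        delta = reading.pH - scene.medium.bulk_pH
        dph[iy, ix] = delta
        records.append(PixelRecord(ix, iy, x, y, math.nan, scene.medium.bulk_pH,
                                   reading.pH, delta,
                                   out_of_range=reading.out_of_range))
    topo = np.full((ny, nx), np.nan)
    return ScanResult(topography=topo, dpH_map=dph,
                      abs_pH_map=scene.medium.bulk_pH + dph,
                      config=config, records=records, scene=scene)
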