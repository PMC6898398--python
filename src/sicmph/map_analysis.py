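"""Quantification of scan outputs.

Per-cell pericellular-pH statistics, spatial-resolution estimates from
line profiles, and stationary-probe time courses.  The "pHe gradient" of a
cell group is operationalised as the mask-mean surface dpH versus bulk
(the minimum is reported alongside as a conservative alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EstimationError
from .probe_model import Probe, current_to_pH, sensor_current, sensor_readout
from .scan_controller import ScanResult

__all__ = [
    "MapStats",
    "map_statistics",
    "resolution_estimate",
    "timecourse_extract",
]


@dataclass(frozen=True)
class MapStats:
    """Summary statistics of a dpH map under a cell mask."""

    mask_mean_dpH: float
    mask_min_dpH: float
    mask_sd_dpH: float
    background_mean_dpH: float
    n_pixels: int

    def as_dict(self) -> dict:
        return {
            "mask_mean_dpH": self.mask_mean_dpH,
            "mask_min_dpH": self.mask_min_dpH,
            "mask_sd_dpH": self.mask_sd_dpH,
            "background_mean_dpH": self.background_mean_dpH,
            "n_pixels": self.n_pixels,
        }


def map_statistics(result, mask) -> MapStats:
    """Mask statistics of a dpH map (a :class:`ScanResult` or a 2-D array).

    Flagged (NaN) pixels are excluded; the background mean is computed over
    the mask complement.  ``mask_sd_dpH`` is the heterogeneity index.
    """
    dph = np.asarray(result.dpH_map if isinstance(result, ScanResult)
                     else result, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dph.shape:
        raise ValueError("mask shape must match the map shape")
    valid = np.isfinite(dph)
    sel = mask & valid
    if not sel.any():
        raise ValueError("mask contains no unflagged pixels")
    inside = dph[sel]
    outside = dph[~mask & valid]
    return MapStats(
        mask_mean_dpH=float(inside.mean()),
        mask_min_dpH=float(inside.min()),
        mask_sd_dpH=float(inside.std(ddof=1)) if inside.size > 1 else 0.0,
        background_mean_dpH=float(outside.mean()) if outside.size else float("nan"),
        n_pixels=int(inside.size),
    )


def resolution_estimate(positions, values, noise_floor: float | None = None
                        ) -> float:
    """Full width at half maximum of a background-subtracted line profile, m.

    The background is the median of the outer 20% of the profile; the peak
    must rise at least 3x above the noise level (estimated from the same
    outer region unless ``noise_floor`` is given).  Half-height crossings
    are located by linear interpolation.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape or x.size < 5:
        raise ValueError("need matching position/value arrays of length >= 5")
    n_edge = max(2, x.size // 10)
    edges = np.concatenate([y[:n_edge], y[-n_edge:]])
    background = float(np.median(edges))
    work = np.abs(y - background)
    noise = float(np.std(edges)) if noise_floor is None else float(noise_floor)
    peak_idx = int(np.argmax(work))
    peak = work[peak_idx]
    if peak <= max(3.0 * noise, 1e-15):
        raise EstimationError("no peak above 3x the noise level")
    half = peak / 2.0

    def cross(idx_range, reverse: bool) -> float:
        seq = idx_range[::-1] if reverse else idx_range
        prev = peak_idx
        for i in seq:
            if work[i] < half:
                x0, x1 = x[i], x[prev]
                y0, y1 = work[i], work[prev]
                return x0 + (half - y0) * (x1 - x0) / (y1 - y0)
            prev = i
        raise EstimationError("profile does not fall below half maximum")

    left = cross(list(range(0, peak_idx)), reverse=True)
    right = cross(list(range(peak_idx + 1, x.size)), reverse=False)
    return float(abs(right - left))


def timecourse_extract(scene, probe: Probe, position=None,
                       duration: float = 300.0, cadence: float = 1.0,
                       dwell: float = 1e-3, fs: float = 20e3,
                       f_c: float = 2e3, seed: int = 0) -> pd.DataFrame:
    """pH(t) monitored by a stationary probe held at ``position``.

    At each cadence point the pH-barrel current is recorded for one dwell
    window through the full readout chain and inverted through the probe's
    calibration; defaults to the scene's configured observation point
    (e.g. 1 um above a secreting cell).  Returns a (time_s, pH) frame.
    """
    if position is None:
        position = scene.observation_point
    if position is None:
        raise ValueError("no observation position given or configured")
    probe = probe if probe.calibration else probe.calibrated()
    sensor, fit = probe.sensor, probe.calibration
    rng = np.random.default_rng(seed)
    n_dwell = max(1, int(round(dwell * fs)))
    pt = np.asarray(position, dtype=float)
    times = np.arange(0.0, duration + 0.5 * cadence, cadence)
    out = np.empty_like(times)
    for i, t in enumerate(times):
        true_pH = float(np.clip(scene.ground_truth.pH(pt, float(t)),
                                1e-3, 14.0 - 1e-3))
        i_true = float(sensor_current(sensor, sensor.working_bias, true_pH))
        trace = sensor_readout(np.full(n_dwell, i_true), sensor, fs, f_c,
                               seed=rng)
        out[i] = current_to_pH(fit, float(trace.mean())).pH
    return pd.DataFrame({"time_s": times, "pH": out})
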