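"""Synthetic living-cell scenes with exact ground truth attached.

A :class:`Scene` bundles a smooth topography, a set of gated proton
sources, a buffered medium and the closed-form ground-truth pH field those
ingredients imply.  The generators emulate the instrument's biological
preparations:

* ``make_cell_scene`` - groups of dome-shaped cells carrying acid-efflux
  surface patches (cancer-cell scenes; a zero-flux variant stands in for
  non-cancerous control cells);
* ``make_delivery_pipette_scene`` - a voltage-gated point H+ source over a
  flat substrate (the artificial-gradient test bed);
* ``make_parietal_scene`` - a single acid-secreting cell whose flux rises
  after a stimulus and decays after a pump inhibitor;
* ``make_diatom_scene`` - a large alkalinising cell whose surface sink is
  gated by a light schedule.

Source strengths for the presets are *calibrated*: they are back-computed
from target pH-change anchors through the closed-form field (the
biological fluxes themselves are not known), and scale linearly, so
regenerating a scene from its stored parameters and seed reproduces the
ground truth bitwise.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .chem_field import (BufferSpecies, Medium, PhField, ProtonSource,
                         calibrate_point_source)
from .exceptions import ConfigurationError

__all__ = [
    "Scene",
    "make_cell_scene",
    "make_delivery_pipette_scene",
    "make_parietal_scene",
    "make_diatom_scene",
    "add_buffer",
    "preset_scene",
    "PRESETS",
    "unbuffered_medium",
    "hbss_medium",
    "quarter_hbss_medium",
    "low_buffered_seawater_medium",
    "hepes_species",
]


# ---------------------------------------------------------------------------
# Media presets
# ---------------------------------------------------------------------------

def unbuffered_medium(bulk_pH: float = 7.4) -> Medium:
    """Pure electrolyte: no reactive buffer, infinite screening length."""
    return Medium(species=(), bulk_pH=bulk_pH)


def _hbss_species(scale: float = 1.0) -> tuple[BufferSpecies, ...]:
    # HBSS buffering: 5 mM bicarbonate + 0.8 mM phosphate.
    return (
        BufferSpecies("bicarbonate", 5.0 * scale, pKa=6.1,
                      diffusivity=1.18e-9),
        BufferSpecies("phosphate", 0.8 * scale, pKa=7.21,
                      diffusivity=0.88e-9),
    )


def hbss_medium(bulk_pH: float = 7.4) -> Medium:
    """Hanks' balanced salt solution buffering (5 mM bicarbonate,
    0.8 mM phosphate), pH 7.4."""
    return Medium(species=_hbss_species(), bulk_pH=bulk_pH)


def quarter_hbss_medium(bulk_pH: float = 7.4) -> Medium:
    """Low-buffered imaging medium: HBSS species at quarter concentration
    in saline (the composition that preserves pericellular pH gradients)."""
    return Medium(species=_hbss_species(0.25), bulk_pH=bulk_pH)


def low_buffered_seawater_medium(bulk_pH: float = 7.65) -> Medium:
    """Low-buffered artificial seawater: 1/10 PBS phosphate (1 mM) in a
    0.5 M NaCl background, pH 7.65."""
    return Medium(
        species=(BufferSpecies("phosphate", 1.0, pKa=7.21,
                               diffusivity=0.88e-9),),
        bulk_pH=bulk_pH,
    )


def hepes_species(concentration_mM: float = 10.0) -> BufferSpecies:
    """HEPES zwitterionic buffer (pKa 7.5) at the given concentration."""
    return BufferSpecies("HEPES", float(concentration_mM), pKa=7.5,
                         diffusivity=0.60e-9)


# ---------------------------------------------------------------------------
# Scene container
# ---------------------------------------------------------------------------

@dataclass
class Scene:
    """Topography + sources + medium + exact ground truth.

    ``topography`` maps (x, y) in metres to a height z >= 0 (vectorized);
    ``mask_fn`` labels cell footprint points; ``config`` holds everything
    needed to regenerate the scene (ground truth is always derived, never
    hand-edited).
    """

    topography: Callable
    sources: tuple[ProtonSource, ...]
    medium: Medium
    ground_truth: PhField
    mask_fn: Callable
    seed: int
    extent: tuple[float, float]
    transport_mode: str
    config: dict = field(default_factory=dict)
    observation_point: tuple[float, float, float] | None = None

    def mask(self, nx: int, ny: int, pitch: float) -> np.ndarray:
        """Rasterized cell mask, shape (ny, nx), row-major like scan maps."""
        x = np.arange(nx) * pitch
        y = np.arange(ny) * pitch
        xx, yy = np.meshgrid(x, y)
        return np.asarray(self.mask_fn(xx, yy), dtype=bool)

    def topography_grid(self, nx: int, ny: int, pitch: float) -> np.ndarray:
        x = np.arange(nx) * pitch
        y = np.arange(ny) * pitch
        xx, yy = np.meshgrid(x, y)
        return np.asarray(self.topography(xx, yy), dtype=float)

    def surface_dpH_grid(self, nx: int, ny: int, pitch: float,
                         height: float = 100e-9,
                         reference_height: float | None = None,
                         t: float | None = None) -> np.ndarray:
        """Ground-truth dpH sampled ``height`` above the surface, (ny, nx).

        With ``reference_height`` given, returns the *self-referenced*
        quantity the hopping protocol reports: the field at ``height`` minus
        the field at ``reference_height`` above the surface (the hop-top
        bulk reading).
        """
        x = np.arange(nx) * pitch
        y = np.arange(ny) * pitch
        xx, yy = np.meshgrid(x, y)
        zz = np.asarray(self.topography(xx, yy), dtype=float)
        pts = np.stack([xx, yy, zz + height], axis=-1)
        out = np.asarray(self.ground_truth.delta_pH(pts, t))
        if reference_height is not None:
            ref = np.stack([xx, yy, zz + reference_height], axis=-1)
            out = out - np.asarray(self.ground_truth.delta_pH(ref, t))
        return out


def _dome_topography(centres: np.ndarray, heights: np.ndarray,
                     radii: np.ndarray) -> Callable:
    """Sum of C1 cosine-taper bumps: h cos^2(pi r / (2 R)) inside r < R."""

    def topo(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = np.zeros(np.broadcast(x, y).shape)
        for (cx, cy), h, rad in zip(centres, heights, radii):
            r = np.hypot(x - cx, y - cy)
            inside = r < rad
            z = z + np.where(inside,
                             h * np.cos(math.pi * r / (2.0 * rad)) ** 2, 0.0)
        return z if z.ndim else float(z)

    return topo


def _dome_mask(centres: np.ndarray, radii: np.ndarray) -> Callable:
    def mask(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.zeros(np.broadcast(x, y).shape, dtype=bool)
        for (cx, cy), rad in zip(centres, radii):
            out |= np.hypot(x - cx, y - cy) < rad
        return out

    return mask


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def make_cell_scene(n_cells: int = 3,
                    dome_height: float = 4e-6,
                    dome_radius: float = 8e-6,
                    medium: Medium | None = None,
                    seed: int = 0,
                    extent: tuple[float, float] = (40e-6, 40e-6),
                    patches_per_cell: int = 2,
                    patch_radius: float = 2.5e-6,
                    target_mask_mean_dpH: float | None = -0.7,
                    flux_sigma: float = 0.3,
                    measure_height: float = 100e-9,
                    reference_height: float = 10e-6,
                    boundary_layer: float | None = 15e-6,
                    transport_mode: str = "mobile_buffer") -> Scene:
    """A group of dome-shaped cells with acid-efflux surface patches.

    Patch positions and relative fluxes are drawn from ``seed``
    (log-normal heterogeneity of width ``flux_sigma``); the absolute flux
    scale is calibrated so that the *measured* mask-mean dpH - the field
    ``measure_height`` above the surface referenced against the hop-top
    reading ``reference_height`` above it, exactly what the self-referencing
    protocol reports - equals ``target_mask_mean_dpH`` (0 or None gives an
    inactive, control-cell scene).  ``boundary_layer`` bounds the
    pericellular gradient to the unstirred layer of the bath (see
    :class:`~sicmph.chem_field.Medium`).  Domes must fit in the field of
    view without overlapping.
    """
    medium = quarter_hbss_medium() if medium is None else medium
    if boundary_layer is not None:
        medium = dataclasses.replace(medium, unstirred_layer=boundary_layer)
    rng = np.random.default_rng(seed)
    ex, ey = extent
    if n_cells < 1:
        raise ConfigurationError("need at least one cell")

    # dome centres on a jittered grid; reject overlaps
    ncol = int(math.ceil(math.sqrt(n_cells)))
    nrow = int(math.ceil(n_cells / ncol))
    centres = []
    for i in range(n_cells):
        cx = (i % ncol + 0.5) / ncol * ex
        cy = (i // ncol + 0.5) / nrow * ey
        jitter = rng.uniform(-0.05, 0.05, size=2) * min(ex, ey)
        centres.append((cx + jitter[0], cy + jitter[1]))
    centres = np.asarray(centres)
    for i in range(n_cells):
        for j in range(i + 1, n_cells):
            if np.hypot(*(centres[i] - centres[j])) < 1.6 * dome_radius:
                raise ConfigurationError("cell domes overlap beyond tolerance")
    heights = np.full(n_cells, dome_height)
    radii = np.full(n_cells, dome_radius)
    topo = _dome_topography(centres, heights, radii)
    mask_fn = _dome_mask(centres, radii)

    sources: list[ProtonSource] = []
    active = target_mask_mean_dpH is not None and target_mask_mean_dpH != 0.0
    rel_fluxes = np.exp(rng.normal(0.0, flux_sigma,
                                   size=n_cells * patches_per_cell))
    if active:
        area = math.pi * patch_radius ** 2
        k = 0
        for (cx, cy), h, rad in zip(centres, heights, radii):
            for _ in range(patches_per_cell):
                rho = rng.uniform(0.0, 0.6) * rad
                ang = rng.uniform(0.0, 2.0 * math.pi)
                px, py = cx + rho * math.cos(ang), cy + rho * math.sin(ang)
                pz = float(topo(px, py))
                sources.append(ProtonSource((px, py, pz),
                                            strength=rel_fluxes[k],
                                            kind="patch", area=area))
                k += 1

    field_unit = PhField(medium=medium, sources=tuple(sources),
                         transport_mode=transport_mode)
    if active and sources:
        # calibrate absolute flux so the measured (self-referenced)
        # mask-mean anchor is hit exactly; linear in the common flux scale
        ngrid = 48
        pitch = min(ex, ey) / ngrid
        x = np.arange(ngrid) * pitch
        y = np.arange(ngrid) * pitch
        xx, yy = np.meshgrid(x, y)
        m = mask_fn(xx, yy)
        zz = np.asarray(topo(xx, yy))
        pts = np.stack([xx, yy, zz + measure_height], axis=-1)
        ref = np.stack([xx, yy, zz + measure_height + reference_height],
                       axis=-1)
        dpH_unit = (np.asarray(field_unit.delta_pH(pts))
                    - np.asarray(field_unit.delta_pH(ref)))
        mean_unit = float(dpH_unit[m].mean())
        scale = target_mask_mean_dpH / mean_unit
        sources = [replace(s, strength=s.strength * scale) for s in sources]

    gt = PhField(medium=medium, sources=tuple(sources),
                 transport_mode=transport_mode)
    cfg = dict(kind="cell", n_cells=n_cells, dome_height=dome_height,
               dome_radius=dome_radius, seed=seed, extent=extent,
               patches_per_cell=patches_per_cell, patch_radius=patch_radius,
               target_mask_mean_dpH=target_mask_mean_dpH,
               flux_sigma=flux_sigma, measure_height=measure_height,
               reference_height=reference_height,
               boundary_layer=boundary_layer,
               transport_mode=transport_mode)
    return Scene(topography=topo, sources=tuple(sources), medium=medium,
                 ground_truth=gt, mask_fn=mask_fn, seed=seed, extent=extent,
                 transport_mode=transport_mode, config=cfg)


def make_delivery_pipette_scene(position=(10e-6, 10e-6, 1e-6),
                                Q: float | None = None,
                                gate=None,
                                medium: Medium | None = None,
                                target_dpH: float = -1.0,
                                target_r: float = 1e-6,
                                extent: tuple[float, float] = (20e-6, 20e-6),
                                transport_mode: str | None = None,
                                seed: int = 0) -> Scene:
    """A gated point H+ source (delivery pipette tip) over a flat substrate.

    The gate follows the deliver/retain voltage semantics: intervals are the
    periods with the +0.5 V delivery voltage applied; outside them the
    retaining voltage keeps the source off (negative control).  ``Q`` is
    back-computed from ``target_dpH`` at ``target_r`` when not given.
    """
    medium = unbuffered_medium() if medium is None else medium
    if transport_mode is None:
        transport_mode = "free_proton" if not medium.species else "mobile_buffer"
    if Q is None:
        Q = calibrate_point_source(medium, target_dpH, target_r,
                                   transport_mode)
    if Q == 0.0:
        raise ConfigurationError("delivery source strength must be non-zero")
    src = ProtonSource(tuple(position), strength=Q, gate=gate, kind="point")
    gt = PhField(medium=medium, sources=(src,), transport_mode=transport_mode)

    def topo(x, y):
        z = np.zeros(np.broadcast(np.asarray(x), np.asarray(y)).shape)
        return z if z.ndim else 0.0

    def mask_fn(x, y):
        return np.hypot(np.asarray(x) - position[0],
                        np.asarray(y) - position[1]) < 2e-6

    cfg = dict(kind="pipette", position=tuple(position), Q=Q,
               gate=gate, target_dpH=target_dpH, target_r=target_r,
               extent=extent, transport_mode=transport_mode, seed=seed)
    return Scene(topography=topo, sources=(src,), medium=medium,
                 ground_truth=gt, mask_fn=mask_fn, seed=seed, extent=extent,
                 transport_mode=transport_mode, config=cfg,
                 observation_point=(position[0], position[1],
                                    position[2] + target_r))


def make_parietal_scene(stimulus_time: float = 60.0,
                        inhibitor_time: float = 240.0,
                        peak_flux: float | None = None,
                        medium: Medium | None = None,
                        rise_tau: float = 15.0,
                        decay_tau: float = 30.0,
                        peak_dpH: float = -0.5,
                        seed: int = 0) -> Scene:
    """A single gastric parietal cell secreting HCl after a stimulus.

    Surface flux is zero before ``stimulus_time``, rises with time constant
    ``rise_tau`` toward ``peak_flux`` after the stimulus, and decays with
    ``decay_tau`` after the pump inhibitor is applied.  The scene's
    observation point sits 1 um above the secreting patch, matching the
    stationary-probe monitoring geometry.  ``peak_flux`` defaults to the
    strength producing ``peak_dpH`` at 1 um.
    """
    if not stimulus_time < inhibitor_time:
        raise ConfigurationError("stimulus must precede the inhibitor")
    medium = hbss_medium() if medium is None else medium
    transport_mode = "mobile_buffer"
    if peak_flux is None:
        peak_flux = calibrate_point_source(medium, peak_dpH, 1e-6,
                                           transport_mode)

    level_at_inhibitor = 1.0 - math.exp(-(inhibitor_time - stimulus_time)
                                        / rise_tau)

    def modulation(t: float) -> float:
        if t < stimulus_time:
            return 0.0
        if t < inhibitor_time:
            return 1.0 - math.exp(-(t - stimulus_time) / rise_tau)
        return level_at_inhibitor * math.exp(-(t - inhibitor_time) / decay_tau)

    extent = (30e-6, 30e-6)
    centre = np.array([[15e-6, 15e-6]])
    h, rad = np.array([5e-6]), np.array([10e-6])
    topo = _dome_topography(centre, h, rad)
    patch_r = 1e-6
    src = ProtonSource((15e-6, 15e-6, float(h[0])), strength=peak_flux,
                       kind="patch", area=math.pi * patch_r ** 2,
                       modulation=modulation)
    gt = PhField(medium=medium, sources=(src,), transport_mode=transport_mode)
    cfg = dict(kind="parietal", stimulus_time=stimulus_time,
               inhibitor_time=inhibitor_time, peak_flux=peak_flux,
               rise_tau=rise_tau, decay_tau=decay_tau, peak_dpH=peak_dpH,
               seed=seed)
    return Scene(topography=topo, sources=(src,), medium=medium,
                 ground_truth=gt, mask_fn=_dome_mask(centre, rad), seed=seed,
                 extent=extent, transport_mode=transport_mode, config=cfg,
                 observation_point=(15e-6, 15e-6, float(h[0]) + 1e-6))


def make_diatom_scene(light_schedule=((0.0, 200.0),),
                      amplitude_target: float = 0.3,
                      medium: Medium | None = None,
                      seed: int = 0) -> Scene:
    """A large photosynthesising diatom whose surface alkalinises in light.

    The cell carries a surface H+ *sink* gated by ``light_schedule``
    (illuminated intervals); the sink strength is calibrated so the steady
    pH change 1 um above the surface equals +``amplitude_target``.  Kept in
    low-buffered artificial seawater by default.
    """
    if amplitude_target <= 0:
        raise ConfigurationError("amplitude target must be > 0")
    medium = low_buffered_seawater_medium() if medium is None else medium
    transport_mode = "mobile_buffer"
    q = calibrate_point_source(medium, +amplitude_target, 1e-6,
                               transport_mode)  # negative Q (sink)
    extent = (100e-6, 100e-6)
    centre = np.array([[50e-6, 50e-6]])
    h, rad = np.array([8e-6]), np.array([35e-6])
    topo = _dome_topography(centre, h, rad)
    patch_r = 0.5e-6
    src = ProtonSource((50e-6, 50e-6, float(h[0])), strength=q,
                       gate=tuple(light_schedule), kind="patch",
                       area=math.pi * patch_r ** 2)
    gt = PhField(medium=medium, sources=(src,), transport_mode=transport_mode)
    cfg = dict(kind="diatom", light_schedule=tuple(light_schedule),
               amplitude_target=amplitude_target, seed=seed)
    return Scene(topography=topo, sources=(src,), medium=medium,
                 ground_truth=gt, mask_fn=_dome_mask(centre, rad), seed=seed,
                 extent=extent, transport_mode=transport_mode, config=cfg,
                 observation_point=(50e-6, 50e-6, float(h[0]) + 1e-6))


def add_buffer(scene: Scene, species: BufferSpecies) -> Scene:
    """Return the scene with ``species`` added to the medium.

    Source strengths are kept (they model the cells, not the medium), and
    the ground truth is regenerated, so the pericellular |dpH| shrinks as
    the added buffer raises the capacity - the numerical analogue of
    clamping the gradient with 10 mM HEPES.
    """
    if species.total_concentration == 0.0:
        return scene
    new_medium = scene.medium.with_species(species)
    gt = PhField(medium=new_medium, sources=scene.sources,
                 transport_mode=scene.transport_mode)
    cfg = dict(scene.config)
    cfg.setdefault("added_buffers", [])
    cfg["added_buffers"] = list(cfg["added_buffers"]) + [
        (species.name, species.total_concentration, species.pKa)]
    return replace(scene, medium=new_medium, ground_truth=gt, config=cfg)


# ---------------------------------------------------------------------------
# Named presets
# ---------------------------------------------------------------------------

def _mcf7_minus_e2(seed: int = 0) -> Scene:
    """Estradiol-deprived CD44-high breast-cancer-like group: strong
    acidification (mask-mean dpH anchor -0.7)."""
    return make_cell_scene(n_cells=3, target_mask_mean_dpH=-0.7,
                           flux_sigma=0.3, seed=seed)


def _a375m(seed: int = 0) -> Scene:
    """Melanoma-like group: weaker but heterogeneous acidification
    (mask-mean dpH anchor -0.2)."""
    return make_cell_scene(n_cells=3, target_mask_mean_dpH=-0.2,
                           patches_per_cell=3, flux_sigma=0.6, seed=seed)


def _melanocyte(seed: int = 0) -> Scene:
    """Non-cancerous control: same morphology, zero acid efflux."""
    return make_cell_scene(n_cells=3, target_mask_mean_dpH=None, seed=seed)


PRESETS: dict[str, Callable[..., Scene]] = {
    "pipette": make_delivery_pipette_scene,
    "parietal": make_parietal_scene,
    "diatom": make_diatom_scene,
    "mcf7": _mcf7_minus_e2,
    "melanoma": _a375m,
    "melanocyte": _melanocyte,
}


def preset_scene(name: str, seed: int = 0, **overrides) -> Scene:
    """Build one of the named demo scenes."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return factory(seed=seed, **overrides)
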