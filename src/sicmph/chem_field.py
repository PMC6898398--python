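"""Ground-truth extracellular proton fields.

Models the fate of protons released (or consumed) near a cell surface in a
buffered aqueous medium.  Two transport regimes are exposed explicitly:

``free_proton``
    The excess *free* proton concentration around a point source obeys a
    screened diffusion equation; reaction with the basic form of the buffer
    gives an exponential screening length ``lambda = sqrt(D_H / sum(k_on *
    [B-]))``.  In physiological buffer this is of order 10 nm; with no
    reactive buffer the screening length is infinite and the perturbation
    decays only as 1/r, so an acid source remains detectable hundreds of
    micrometres away.

``mobile_buffer``
    On micrometre scales the buffer itself carries acid away from the
    source.  The *total acid* perturbation spreads diffusively with the
    concentration-weighted mobile-buffer diffusivity and is converted to a
    pH change through the buffer capacity ``beta``.

Both regimes have closed-form steady point-source solutions; a
finite-difference transient solver provides the numeric realisation for
gated/time-varying sources and serves as an independent cross-check of the
closed forms.

Units: positions and lengths in metres, concentrations in mol/m^3
(1 mM == 1 mol/m^3) unless a variable is explicitly molar (suffix ``_M``),
rates k_on in M^-1 s^-1, source strengths in mol/s, time in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .exceptions import ConfigurationError

__all__ = [
    "BufferSpecies",
    "Medium",
    "ProtonSource",
    "PhField",
    "SampledPhField",
    "proton_concentration",
    "pH_from_concentration",
    "buffer_capacity",
    "screening_length",
    "steady_point_source_dpH",
    "calibrate_point_source",
    "detectability_radius",
    "solve_transient_field",
    "D_H_DEFAULT",
    "K_ON_DEFAULT",
]

LN10 = math.log(10.0)

#: Free-proton (hydronium) diffusivity in water, m^2/s.
D_H_DEFAULT = 9.3e-9

#: Diffusion-limited protonation rate constant, M^-1 s^-1.
K_ON_DEFAULT = 1.0e10

#: Water ion product (taken pH/T independent here).
KW = 1.0e-14

_H_FLOOR_M = 1.0e-13  # numerical floor for [H+] when summing perturbations


def _hoc_kernel() -> np.ndarray:
    """Compact 27-point (Mehrstellen) Laplacian stencil, units of 1/h^2.

    Far more isotropic near a point source than the 7-point stencil, which
    is what lets the discrete steady state track the 1/(4 pi D r) Green's
    function to a few percent already two cells from the source.  The
    kernel sums to zero, so zero-flux (replicated-edge) boundaries conserve
    the integrated perturbation exactly.
    """
    w = np.empty((3, 3, 3))
    weight = {0: -128.0, 1: 14.0, 2: 3.0, 3: 1.0}
    for i in range(3):
        for j in range(3):
            for k in range(3):
                w[i, j, k] = weight[abs(i - 1) + abs(j - 1) + abs(k - 1)] / 30.0
    return w


_HOC_KERNEL = _hoc_kernel()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BufferSpecies:
    """One acid/base buffer pair dissolved in the medium.

    Parameters
    ----------
    name : str
        Label ("HEPES", "phosphate", ...).
    total_concentration : float
        Total (acid + base form) concentration, mol/m^3.
    pKa : float
        Acid dissociation constant exponent, 0 < pKa < 14.
    k_on : float
        Association rate of H+ with the basic form, M^-1 s^-1.
    diffusivity : float
        Diffusivity of the buffer pair, m^2/s.
    mobile : bool
        Whether the species carries acid by diffusion (immobilised buffers
        contribute to capacity and screening but not to transport).
    """

    name: str
    total_concentration: float
    pKa: float
    k_on: float = K_ON_DEFAULT
    diffusivity: float = 1.0e-9
    mobile: bool = True

    def __post_init__(self) -> None:
        if self.total_concentration < 0:
            raise ConfigurationError("total_concentration must be >= 0")
        if not 0.0 < self.pKa < 14.0:
            raise ConfigurationError("pKa must lie in (0, 14)")
        if self.k_on <= 0:
            raise ConfigurationError("k_on must be > 0")
        if self.diffusivity < 0:
            raise ConfigurationError("diffusivity must be >= 0")

    def basic_fraction(self, pH: float) -> float:
        """Fraction of the species in the basic (H+-accepting) form."""
        ka = 10.0 ** (-self.pKa)
        h = 10.0 ** (-pH)
        return ka / (ka + h)

    def basic_concentration(self, pH: float) -> float:
        """Basic-form concentration at the given pH, mol/m^3."""
        return self.total_concentration * self.basic_fraction(pH)


@dataclass(frozen=True)
class Medium:
    """Buffered aqueous environment: buffer species, bulk pH, diffusivities."""

    species: tuple[BufferSpecies, ...] = ()
    bulk_pH: float = 7.4
    proton_diffusivity: float = D_H_DEFAULT
    temperature: float = 26.0
    #: Unstirred-layer thickness (m) bounding mobile-buffer transport: beyond
    #: this radius convective mixing clamps the medium to bulk, giving the
    #: classic steady profile Q/(4 pi D) (1/r - 1/delta).  None = unbounded
    #: diffusion (pure 1/r).
    unstirred_layer: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if not 0.0 < self.bulk_pH < 14.0:
            raise ConfigurationError("bulk_pH must lie in (0, 14)")
        if self.proton_diffusivity <= 0:
            raise ConfigurationError("proton_diffusivity must be > 0")
        if self.unstirred_layer is not None and self.unstirred_layer <= 0:
            raise ConfigurationError("unstirred_layer must be > 0 or None")

    def reaction_rate(self, pH: float | None = None) -> float:
        """Pseudo-first-order H+ consumption rate sum(k_on*[B-]), s^-1."""
        pH = self.bulk_pH if pH is None else pH
        return sum(
            sp.k_on * sp.basic_concentration(pH) / 1.0e3 for sp in self.species
        )

    def mobile_buffer_diffusivity(self) -> float:
        """Concentration-weighted diffusivity of mobile buffers, m^2/s."""
        mobile = [sp for sp in self.species if sp.mobile and sp.total_concentration > 0]
        if not mobile:
            raise ConfigurationError(
                "medium has no mobile buffer; mobile_buffer transport undefined"
            )
        ctot = sum(sp.total_concentration for sp in mobile)
        return sum(sp.total_concentration * sp.diffusivity for sp in mobile) / ctot

    def bulk_proton_molar(self) -> float:
        return 10.0 ** (-self.bulk_pH)

    def with_species(self, *extra: BufferSpecies) -> "Medium":
        return replace(self, species=self.species + tuple(extra))


@dataclass(frozen=True)
class ProtonSource:
    """A gated H+ source (Q > 0, acidifying) or sink (Q < 0, alkalinising).

    ``gate`` is an ordered tuple of non-overlapping (t_on, t_off) intervals in
    seconds; ``None`` means always on.  ``modulation`` optionally scales the
    strength with time (values in [0, 1]), e.g. for a secretion profile that
    ramps up after a stimulus.  ``kind`` is ``"point"`` or ``"patch"``; patch
    sources carry a finite ``area`` (m^2) and their near field saturates at
    the equivalent-disc radius instead of diverging.
    """

    position: tuple[float, float, float]
    strength: float
    gate: tuple[tuple[float, float], ...] | None = None
    kind: str = "point"
    area: float | None = None
    modulation: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", tuple(float(v) for v in self.position))
        if len(self.position) != 3:
            raise ConfigurationError("position must be a 3-vector")
        if self.kind not in ("point", "patch"):
            raise ConfigurationError(f"unknown source kind {self.kind!r}")
        if self.kind == "patch":
            if self.area is None or self.area <= 0:
                raise ConfigurationError("patch sources require a finite area")
        if self.gate is not None:
            gate = tuple((float(a), float(b)) for a, b in self.gate)
            object.__setattr__(self, "gate", gate)
            prev_end = -math.inf
            for a, b in gate:
                if b <= a:
                    raise ConfigurationError("gate intervals must have t_off > t_on")
                if a < prev_end:
                    raise ConfigurationError(
                        "gate intervals must be ordered and non-overlapping"
                    )
                prev_end = b

    @property
    def effective_radius(self) -> float:
        """Equivalent-disc radius of a patch source (0 for a point)."""
        if self.kind == "patch" and self.area:
            return math.sqrt(self.area / math.pi)
        return 0.0

    def is_on(self, t: float) -> bool:
        if self.gate is None:
            return True
        return any(a <= t < b for a, b in self.gate)

    def activity(self, t: float | None) -> float:
        """Fractional activity in [0, 1] at time ``t`` (1 when t is None)."""
        if t is None:
            return 1.0
        if not self.is_on(t):
            return 0.0
        if self.modulation is not None:
            return float(np.clip(self.modulation(t), 0.0, 1.0))
        return 1.0


# ---------------------------------------------------------------------------
# Scalar chemistry
# ---------------------------------------------------------------------------

def proton_concentration(pH):
    """Free proton concentration [H+] = 10^-pH in mol/L.

    Strictly decreasing in pH; ``pH_from_concentration`` is its inverse.
    """
    pH = np.asarray(pH, dtype=float)
    if np.any(pH <= 0.0) or np.any(pH >= 14.0):
        raise ValueError("pH out of the (0, 14) domain")
    out = 10.0 ** (-pH)
    return float(out) if out.ndim == 0 else out


def pH_from_concentration(conc_M):
    """Inverse of :func:`proton_concentration` (conc in mol/L)."""
    conc_M = np.asarray(conc_M, dtype=float)
    if np.any(conc_M <= 0.0):
        raise ValueError("concentration must be positive")
    out = -np.log10(conc_M)
    return float(out) if out.ndim == 0 else out


def buffer_capacity(medium: Medium, pH: float | None = None) -> float:
    """Buffer capacity beta in mol/m^3 per pH unit.

    beta = ln(10) * ([H+] + [OH-] + sum_i C_i * Ka_i [H+] / (Ka_i + [H+])^2),
    the classical Van Slyke expression with water terms included.
    """
    pH = medium.bulk_pH if pH is None else float(pH)
    if not 0.0 < pH < 14.0:
        raise ValueError("pH out of the (0, 14) domain")
    h = 10.0 ** (-pH)          # M
    oh = KW / h                # M
    total = (h + oh) * 1.0e3   # water contribution, mol/m^3
    for sp in medium.species:
        ka = 10.0 ** (-sp.pKa)
        total += sp.total_concentration * ka * h / (ka + h) ** 2
    return LN10 * total


def screening_length(medium: Medium) -> float:
    """Free-proton screening length lambda = sqrt(D_H / sum(k_on [B-])), m.

    Infinite when the medium has no reactive buffer; strictly decreasing in
    every buffer concentration.
    """
    rate = medium.reaction_rate()
    if rate <= 0.0:
        return math.inf
    return math.sqrt(medium.proton_diffusivity / rate)


# ---------------------------------------------------------------------------
# Steady point-source solutions
# ---------------------------------------------------------------------------

def _steady_delta_conc(medium: Medium, Q: float, r, mode: str,
                       r_min: float = 0.0):
    """Concentration perturbation (mol/m^3) of a steady point source.

    free_proton: d[H+] = Q/(4 pi D_H r) * exp(-r/lambda)
    mobile_buffer: d[TA] = Q/(4 pi D_buf r)
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0.0):
        raise ValueError("r must be > 0 (point-source singularity at r = 0)")
    r_eff = np.maximum(r, r_min) if r_min > 0 else r
    if mode == "free_proton":
        lam = screening_length(medium)
        out = Q / (4.0 * math.pi * medium.proton_diffusivity * r_eff)
        if math.isfinite(lam):
            out = out * np.exp(-r_eff / lam)
    elif mode == "mobile_buffer":
        d_buf = medium.mobile_buffer_diffusivity()
        out = Q / (4.0 * math.pi * d_buf * r_eff)
        if medium.unstirred_layer is not None:
            delta = medium.unstirred_layer
            offset = Q / (4.0 * math.pi * d_buf * delta)
            inside = r_eff < delta
            out = np.where(inside, out - offset, 0.0)
            if out.ndim == 0:
                out = float(out)
    else:
        raise ConfigurationError(f"unknown transport_mode {mode!r}")
    return out


def _delta_conc_to_dpH(medium: Medium, dconc, mode: str):
    """Convert a concentration perturbation (mol/m^3) to a pH change."""
    dconc = np.asarray(dconc, dtype=float)
    if mode == "free_proton":
        h_new = medium.bulk_proton_molar() + dconc / 1.0e3
        h_new = np.clip(h_new, _H_FLOOR_M, None)
        out = -np.log10(h_new) - medium.bulk_pH
    else:
        beta = buffer_capacity(medium)
        out = -dconc / beta
    return float(out) if out.ndim == 0 else out


def steady_point_source_dpH(medium: Medium, source: ProtonSource, r,
                            transport_mode: str = "free_proton",
                            t: float | None = None):
    """Steady-state pH perturbation at distance ``r`` from a point source.

    ``t`` selects the source activity (gate/modulation); ``None`` means fully
    on.  Patch sources saturate at their equivalent-disc radius.  The decay
    is monotone in r in both transport modes.
    """
    q_eff = source.strength * source.activity(t)
    if q_eff == 0.0:
        r = np.asarray(r, dtype=float)
        if np.any(r <= 0.0):
            raise ValueError("r must be > 0")
        out = np.zeros_like(r)
        return float(out) if out.ndim == 0 else out
    dconc = _steady_delta_conc(medium, q_eff, r, transport_mode,
                               r_min=source.effective_radius)
    return _delta_conc_to_dpH(medium, dconc, transport_mode)


def calibrate_point_source(medium: Medium, target_dpH: float, r: float,
                           transport_mode: str = "free_proton") -> float:
    """Source strength Q (mol/s) that yields ``target_dpH`` at distance r.

    Inverts the steady closed form; used to back-compute preset fluxes from
    anchor pH perturbations.
    """
    if r <= 0:
        raise ValueError("r must be > 0")
    if transport_mode == "free_proton":
        h_bulk = medium.bulk_proton_molar()
        h_new = 10.0 ** (-(medium.bulk_pH + target_dpH))
        dconc = (h_new - h_bulk) * 1.0e3  # mol/m^3
        lam = screening_length(medium)
        q = dconc * 4.0 * math.pi * medium.proton_diffusivity * r
        if math.isfinite(lam):
            q *= math.exp(r / lam)
        return q
    if transport_mode == "mobile_buffer":
        beta = buffer_capacity(medium)
        dconc = -target_dpH * beta
        d_buf = medium.mobile_buffer_diffusivity()
        if medium.unstirred_layer is not None:
            if r >= medium.unstirred_layer:
                raise ConfigurationError(
                    "calibration point lies outside the unstirred layer")
            geom = 1.0 / r - 1.0 / medium.unstirred_layer
            return dconc * 4.0 * math.pi * d_buf / geom
        return dconc * 4.0 * math.pi * d_buf * r
    raise ConfigurationError(f"unknown transport_mode {transport_mode!r}")


def detectability_radius(medium: Medium, source: ProtonSource,
                         sensitivity: float,
                         transport_mode: str = "free_proton",
                         r_cap: float = 10.0) -> float:
    """Largest distance at which |dpH| >= ``sensitivity`` (m); 0 if never.

    Root-bracketed numerically on the monotone steady solution.  ``r_cap``
    bounds the search (defaults to 10 m, effectively unbounded for any
    laboratory geometry).
    """
    if sensitivity <= 0:
        raise ValueError("sensitivity must be > 0")
    if source.strength == 0.0:
        return 0.0

    def excess(r: float) -> float:
        return abs(float(steady_point_source_dpH(
            medium, source, r, transport_mode))) - sensitivity

    r_lo = max(source.effective_radius, 1.0e-12)
    if excess(r_lo) < 0.0:
        return 0.0
    r_hi = max(2.0 * r_lo, 1.0e-9)
    while excess(r_hi) > 0.0:
        r_hi *= 10.0
        if r_hi > r_cap:
            return r_cap
    return float(brentq(excess, r_lo, r_hi, xtol=1e-12, rtol=1e-12))


# ---------------------------------------------------------------------------
# Field objects
# ---------------------------------------------------------------------------

@dataclass
class PhField:
    """Quasi-static ground-truth pH field from superposed steady sources.

    Concentration perturbations of the individual sources superpose (the
    transport equations are linear); the summed perturbation is converted to
    pH once.  Time enters only through the source gates/modulations
    (quasi-static approximation: diffusion over the relevant micrometre
    distances relaxes in milliseconds, much faster than the gate schedules).
    """

    medium: Medium
    sources: tuple[ProtonSource, ...] = ()
    transport_mode: str = "free_proton"

    def __post_init__(self) -> None:
        self.sources = tuple(self.sources)
        if self.transport_mode not in ("free_proton", "mobile_buffer"):
            raise ConfigurationError(
                f"unknown transport_mode {self.transport_mode!r}")

    def delta_conc(self, points, t: float | None = None):
        """Summed concentration perturbation (mol/m^3) at ``points`` (...,3)."""
        pts = np.asarray(points, dtype=float)
        total = np.zeros(pts.shape[:-1], dtype=float)
        for src in self.sources:
            q_eff = src.strength * src.activity(t)
            if q_eff == 0.0:
                continue
            r = np.linalg.norm(pts - np.asarray(src.position), axis=-1)
            r = np.maximum(r, 1.0e-12)
            total += _steady_delta_conc(self.medium, q_eff, r,
                                        self.transport_mode,
                                        r_min=src.effective_radius)
        return total

    def delta_pH(self, points, t: float | None = None):
        return _delta_conc_to_dpH(self.medium, self.delta_conc(points, t),
                                  self.transport_mode)

    def pH(self, points, t: float | None = None):
        """Absolute pH at ``points`` (...,3) and time ``t`` (s)."""
        out = self.medium.bulk_pH + np.asarray(self.delta_pH(points, t))
        return float(out) if out.ndim == 0 else out


@dataclass
class SampledPhField:
    """pH field sampled on a uniform grid at discrete times by the FD solver."""

    medium: Medium
    transport_mode: str
    origin: tuple[float, float, float]
    spacing: float
    t_points: np.ndarray
    delta_conc_grids: np.ndarray  # (nt, nx, ny, nz), mol/m^3

    def _time_index(self, t: float | None) -> int:
        if t is None:
            return len(self.t_points) - 1
        return int(np.argmin(np.abs(self.t_points - t)))

    def delta_pH_grid(self, t: float | None = None) -> np.ndarray:
        return np.asarray(_delta_conc_to_dpH(
            self.medium, self.delta_conc_grids[self._time_index(t)],
            self.transport_mode))

    def pH(self, points, t: float | None = None):
        from scipy.interpolate import RegularGridInterpolator

        grid = self.delta_pH_grid(t)
        axes = [self.origin[i] + self.spacing * np.arange(grid.shape[i])
                for i in range(3)]
        interp = RegularGridInterpolator(axes, grid, bounds_error=False,
                                         fill_value=0.0)
        pts = np.asarray(points, dtype=float)
        out = self.medium.bulk_pH + interp(pts.reshape(-1, 3)).reshape(
            pts.shape[:-1])
        return float(out) if out.ndim == 0 else out

    def total_mass(self, t: float | None = None) -> float:
        """Integrated perturbation (mol) on the grid at time ``t``."""
        cell = self.spacing ** 3
        return float(self.delta_conc_grids[self._time_index(t)].sum() * cell)


# ---------------------------------------------------------------------------
# Transient finite-difference solver
# ---------------------------------------------------------------------------

def solve_transient_field(medium: Medium,
                          sources: Sequence[ProtonSource],
                          spacing: float,
                          extent: Sequence[tuple[float, float]],
                          t_points: Sequence[float],
                          transport_mode: str = "free_proton",
                          cfl_safety: float = 0.15) -> SampledPhField:
    """Explicit finite-difference solution of the perturbation field.

    Solves dc/dt = D lap(c) - k c + s(x, t) on a uniform Cartesian grid with
    zero-flux (Neumann) boundaries, where ``c`` is the free-proton excess
    (``free_proton`` mode; k = sum(k_on [B-]) at bulk pH) or the total-acid
    excess (``mobile_buffer`` mode; k = 0, D the mobile-buffer diffusivity).
    Sources deposit into their nearest cell.  The time step is the stable
    explicit bound ``cfl_safety * dx^2 / D`` (and <= 0.2/k for the reaction
    term); the initial condition is the unperturbed bulk.  The solver models
    unbounded diffusion inside the box: a medium's ``unstirred_layer`` (a
    closed-form convective cutoff) is not represented here.
    """
    if spacing <= 0:
        raise ConfigurationError("grid spacing must be > 0")
    if not 0 < cfl_safety <= 1.0 / 6.0:
        raise ConfigurationError(
            "cfl_safety must lie in (0, 1/6] for a stable 3-D explicit step")
    extent = [(float(a), float(b)) for a, b in extent]
    shape = tuple(max(2, int(round((b - a) / spacing)) + 1) for a, b in extent)
    origin = tuple(a for a, _ in extent)

    if transport_mode == "free_proton":
        diff = medium.proton_diffusivity
        k = medium.reaction_rate()
    elif transport_mode == "mobile_buffer":
        diff = medium.mobile_buffer_diffusivity()
        k = 0.0
    else:
        raise ConfigurationError(f"unknown transport_mode {transport_mode!r}")

    dt = cfl_safety * spacing ** 2 / diff
    if k > 0:
        dt = min(dt, 0.2 / k)
    t_points = np.asarray(sorted(float(t) for t in t_points))
    if t_points.size == 0:
        raise ConfigurationError("t_points must be non-empty")

    cell_vol = spacing ** 3
    src_cells = []
    for src in sources:
        idx = tuple(int(round((src.position[i] - origin[i]) / spacing))
                    for i in range(3))
        if not all(0 <= idx[i] < shape[i] for i in range(3)):
            raise ConfigurationError("source lies outside the grid extent")
        src_cells.append((idx, src))

    c = np.zeros(shape, dtype=float)
    grids = np.empty((t_points.size, *shape), dtype=float)
    inv_dx2 = 1.0 / spacing ** 2
    t = 0.0
    out_i = 0
    # record any t_points at/before t=0
    while out_i < t_points.size and t_points[out_i] <= 0.0:
        grids[out_i] = c
        out_i += 1
    t_end = float(t_points[-1])
    while out_i < t_points.size:
        step = min(dt, t_end - t)
        lap = ndimage.correlate(c, _HOC_KERNEL, mode="nearest") * inv_dx2
        dc = diff * lap - k * c
        for idx, src in src_cells:
            q_eff = src.strength * src.activity(t)
            if q_eff != 0.0:
                dc[idx] += q_eff / cell_vol
        c = c + step * dc
        t += step
        while out_i < t_points.size and t >= t_points[out_i] - 0.5 * dt:
            grids[out_i] = c
            out_i += 1

    return SampledPhField(medium=medium, transport_mode=transport_mode,
                          origin=origin, spacing=spacing,
                          t_points=t_points, delta_conc_grids=grids)
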