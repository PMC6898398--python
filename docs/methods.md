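# Methods

This note documents the physical models behind `sicmph`, the defaults and
why they were chosen, what the synthetic scenes do and do not emulate, and
the numerical choices that matter when interpreting its output.

## Proton transport and buffering

Extracellular acid spreads from a cellular source through two distinct
channels, and the package deliberately exposes them as separate
`transport_mode` values rather than one unified kinetic model, because each
has a clean closed form and they dominate on different length scales.

**Free protons (`free_proton`).** A proton released into a buffered medium
survives only until it meets the basic form of a buffer. Linearising the
reaction–diffusion balance around bulk gives a screened point-source
steady state

    Δ[H⁺](r) = Q / (4π D_H r) · exp(−r/λ),  λ = √(D_H / Σᵢ k_on,ᵢ[Bᵢ⁻]),

with the basic-form concentrations evaluated at bulk pH. With the default
D_H = 9.3×10⁻⁹ m²/s and a diffusion-limited k_on = 10¹⁰ M⁻¹s⁻¹ (standard
literature values; the medium composition, not these constants, is the
experimental variable), 10 mM of reactive base gives λ ≈ 9.6 nm — free
protonic charge is confined to nanometres in physiological buffer, while in
unbuffered solution (λ = ∞) a source calibrated to −1 pH at 1 µm remains
above a 0.01-pH sensitivity out to ≈ 386 µm. ΔpH is obtained by exact log
conversion of the perturbed concentration; no activity corrections.

**Buffer-carried acid (`mobile_buffer`).** On micrometre scales the
protons ride the buffer: the *total acid* perturbation diffuses with the
concentration-weighted mobile-buffer diffusivity D_buf and converts to pH
through the buffer capacity

    β(pH) = ln10 · ([H⁺] + [OH⁻] + Σᵢ Cᵢ Kₐᵢ[H⁺]/(Kₐᵢ+[H⁺])²),

so ΔpH(r) = −Q / (4π D_buf r β). This is the regime that produces the
micrometre-scale pericellular gradients the instrument maps in low-buffered
media, and it is why adding 10 mM HEPES (β up ~25-fold in quarter-HBSS)
collapses the measured gradient by >90%.

**Unstirred layer.** A `Medium` may carry an optional unstirred-layer
thickness δ. Beyond δ, convective mixing clamps the bath to bulk, giving
the classical bounded-diffusion profile Δ[TA] ∝ (1/r − 1/δ), zero outside.
The closed-form operations default to δ = None (pure 1/r, the analytically
testable form); the cell scenes set δ = 15 µm so that the hop-top reference
10 µm above the surface reads near-bulk, as it does in a stirred dish.
Without this cutoff a cell group acidified by 0.7 pH at its surface would
still read ≈ −0.4 at the hop ceiling, and the self-referencing protocol
would systematically under-report the gradient. 15 µm is at the low end of
laboratory unstirred layers; the value is a scene default, not a claim.

**Transient solver.** `solve_transient_field` integrates
∂c/∂t = D∇²c − kc + s(x,t) explicitly on a uniform grid with zero-flux
boundaries (c is the free-proton excess with k = Σ k_on[B⁻], or the total
acid with k = 0). The Laplacian is the compact 27-point Mehrstellen
stencil: its discrete Green's function is isotropic enough to match
1/(4πDr) within 1% two cells from a point source, where the 7-point
stencil errs by ~13%. The stencil sums to zero, so with replicated-edge
boundaries the integrated perturbation is conserved to round-off once
sources gate off. The time step is 0.15·Δx²/D (inside the 3-D explicit
stability bound Δx²/6D and the 0.2/k reaction bound). Sources deposit into
their nearest cell; fields are second-order accurate away from that cell.
The solver models sealed boxes — a medium's unstirred layer is a
closed-form construct and is not represented in it.

## The probe

**Rectification sensor.** The membrane's I–V response is modelled as

    I(V, pH) = G₀ · V · [1 + ρ·(pH − pH₀)·tanh(V/V_T)],

the simplest form that is ohmic at the neutral point pH₀, flips its
rectification asymmetry across pH₀, and is *exactly* affine in pH at any
fixed bias — which is what makes a linear six-point calibration at the
+600 mV working bias and its OLS inverse well posed. Defaults: pH₀ = 7.0,
V_T = 0.3 V, ρ = −0.08 /pH (sign configurable; the direction of the pH
response at positive bias is an assumption), G₀ = 1.33 nS so that a 100 nm
tip passes −0.8 nA at −0.6 V. Tip-size scaling interpolates a power law
(exponent ≈ 1.39) between the (100 nm, −0.8 nA) and (2.5 µm, −70 nA)
anchors, ohmic in bias. Ion selectivity is summarised by a reversal
potential E_rev = s_rev·(pH − pH₀) with s_rev = 17.5 mV/pH, the midpoint of
the 15–20 mV/pH selectivity window.

**Approach curve and feedback.** The normalized SICM current follows
I(d)/I∞ = 1/(1 + α·rᵢ/d). α = 0.0101 places the 1% setpoint crossing at
exactly one inner radius (d = α rᵢ(1−s)/s), the probe's stated sensing
range; no geometric formula for α is implied. Topography maps subtract
this deterministic crossing distance; the raw detected Z is kept per pixel.
With `pH_coupled` feedback (single-barrel probe) the feedback current is
the membrane current at the −200 mV feedback bias, which couples surface
detection to the local pH and reproduces the ball-like topographic
artefact over an active H⁺ source; the double-barrel configuration is
decoupled by construction.

**Recording chain and noise.** Sensor dynamics are a first-order lag
(τ = 0.67 ms, set so the 95%-band response time of the full chain at
20 kHz sampling with the 2 kHz single-pole low-pass is ≈ 2 ms; the
response time, not τ, is the observable), additive white Gaussian noise,
then the low-pass. The pH barrel's noise defaults to 0.5% RMS of its bulk
working-bias current (≈ 4 pA). The open feedback barrel is quieter,
0.2% of its bulk current; when a single-barrel pH probe serves as its own
feedback sensor the 0.5% figure applies. These fractions are model
choices (no noise figure is specified by the sensing principle); the
sensitivity and topography-fidelity tests are run against them. The
response-time estimator reports the time from step onset (steepest sample)
to the first 5 consecutive samples inside ±5% of the step amplitude about
the final plateau.

## The scan protocol

Each pixel runs the four-step hopping cycle in order: withdraw to the hop
ceiling (10 µm above the last detected surface — the reference current is
re-measured there every hop, so the setpoint tracks slow drift); dwell
1 ms (20 samples) while translating laterally and record the bulk pH
reading; descend kinematically at 25 nm/ms sampling the feedback barrel
through the full recording chain, declaring the surface at the first
3-sample debounced drop below (1 − setpoint); withdraw 100 nm and record
the surface pH for 1 ms. Dwell windows are averaged with the mean
(variance-predictable under Gaussian noise). ΔpH = pH_surface − pH_bulk;
any additive sensor drift constant over one hop cycle (≈ 0.3–0.5 s,
dominated by the descent) cancels in the difference, which is the point of
self-referencing. Piezo dynamics, overshoot and creep are not modelled —
the 100 nm withdraw is honoured as pure protocol. Raster order is
row-major serpentine with pixel (0,0) at the scan origin; maps are stored
row-major `[iy, ix]`. Both ΔpH and absolute (bulk + ΔpH) maps are emitted,
labelled explicitly. All stochastic draws come from one seeded generator,
so identical config + seed gives bitwise-identical results.

Degenerate cases: a pixel whose surface lies above the hop ceiling, or
whose descent never crosses the setpoint, is flagged `no_surface` (NaN in
the maps); pH readings outside the calibration range carry an
`out_of_range` flag but are still reported.

## Synthetic scenes

Scenes are built from C¹ cosine-taper domes (smooth at the rim, so descent
detection stays well posed at patch edges), surface efflux patches,
gated/modulated point sources, and media presets: quarter-HBSS
(1.25 mM bicarbonate pKa 6.1 + 0.2 mM phosphate pKa 7.21, pH 7.4),
full HBSS, low-buffered artificial seawater (1 mM phosphate in 0.5 M NaCl,
pH 7.65), unbuffered saline, and a HEPES additive (pKa 7.5).

No biological flux magnitudes are assumed anywhere. Every preset's source
strength is *calibrated* through the closed-form field to a pH anchor:
the cancer-cell presets to a mask-mean self-referenced reading of −0.7
(breast-cancer-like, estradiol-deprived) or −0.2 (melanoma-like, with
larger patch-to-patch log-normal flux spread) — calibrating on the
self-referenced quantity (surface reading minus hop-top reference) rather
than the raw surface field, because that is the quantity the instrument
reports; the delivery pipette to −1.0 pH at 1 µm; the parietal cell to
−0.5 pH at 1 µm at peak secretion; the diatom sink to +0.3 pH at 1 µm
under light. Efflux patches default to 2.5 µm radius: micrometre-scale
efflux regions keep the surface field smooth at scan pitch and the
patch-centre pH inside the sensor's 4–9 calibration range. Patch placement
and flux heterogeneity consume only the scene seed, and ground truth is
always regenerated from the configuration — never stored — so rebuilding a
scene reproduces it bitwise.

Scene ground truths are quasi-static: gates and secretion profiles
modulate the steady closed form, valid because micrometre-scale diffusion
relaxes in milliseconds while the schedules change over seconds. The FD
solver provides the genuinely transient realisation where that matters
(gate-toggle relaxation, settling via the erfc(r/√4Dt) law).

What the scenes do **not** emulate: mechanistic pump kinetics, open-system
CO₂/bicarbonate exchange, electro-migration in the delivery field, cell
movement or shape change during a scan, convection (beyond the unstirred-
layer cutoff), and fluorescence channels. Passing tests therefore
demonstrate that the *instrument model* recovers known synthetic fields
through its full measurement chain — not that real cells behave like the
presets.

## Analysis conventions

The "pHe gradient" of a cell group is operationalised as the mask-mean
ΔpH (surface versus bulk reference) over unflagged cell-footprint pixels;
the mask minimum is reported alongside as a conservative alternative, and
the mask SD serves as the heterogeneity index. Spatial resolution is the
FWHM of a background-subtracted line profile (background = median of the
outer 20%, half-height crossings by linear interpolation, peak required to
exceed 3× the edge noise).

## Problem sizes and tolerances

Defaults used by the test suite and demos: 16×16 to 64×64-pixel scans
(a 64×64 preset scan takes a few seconds), FD grids of ~30³ cells at
0.2–0.4 µm spacing integrated over a few milliseconds, 100-seed Monte
Carlo for calibration linearity. Solver-vs-oracle agreement is asserted at
5% for radii ≥ 2 grid cells; mass conservation at 10⁻⁶ relative; noiseless
scan topography at ≤ 2 descent samples (2.5 nm); noisy topography RMS at
≤ 50 nm; measured-vs-truth ΔpH accuracy at 0.02 pH averaged over seeds
(one pixel's ΔpH has σ ≈ 0.02 under the default noise, so the single-draw
value is noise-, not bias-, limited).

## Known limitations

* The rectification functional form is phenomenological; only its
  fixed-bias affinity in pH and the asymmetry flip are anchored.
* The approach curve ignores tilt, surface charge and pipette geometry
  beyond the single α·rᵢ/d parameter.
* The quasi-static ground truth ignores the finite diffusion time between
  a gate toggle and field establishment (milliseconds at micrometre
  scale).
* `mobile_buffer` transport assumes a single effective buffer diffusivity
  and a pH-independent β evaluated at bulk; strong perturbations
  (|ΔpH| ≳ 1) stretch the linearisation.
* The unstirred-layer cutoff is a steady-state construct; the FD solver
  does not include it.
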