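# Methods

## Scope and model reduction

`basilar` studies one question: how does a passively placed CI electrode,
parameterized by its insertion angle, change the traveling-wave mechanics
of the chinchilla cochlea? The full 3-D problem (three fluid chambers,
elastic membranes, a coiled bony labyrinth, a solid electrode with
fluid–structure interfaces) is reduced to a 1-D two-duct transmission line
along the BM midline. The reduction keeps exactly the physics the question
needs — graded partition impedance, duct fluid inertia, occlusion of the
scala tympani — and drops what it does not: Reissner's membrane is
mechanically inert (the scala media is lumped with the scala vestibuli),
the bony walls are rigid, the vestibular system is carried in the material
table but never solved, and there is no middle ear, no active amplifier,
and no insertion trauma. The quantity every downstream analysis consumes
is the 1-D displacement profile u(x) along the midline, so nothing the
pipeline needs is lost by the reduction.

## Geometry

The synthetic geometry replaces a scan-derived mesh. A logarithmic spiral
(default three turns, 1080°; taper rate 0.08/rad) provides the centerline
and the angle ↔ arc-length maps; the whole construction is scaled by one
factor so the BM midline is exactly 18.3 mm, the chinchilla average. BM
thickness tapers linearly 16.5 → 5 µm (a smooth exponential alternative is
config-selectable; both pin the same endpoints). Because profiles are
functions of relative position, the build is invariant to the pre-scale
spiral size, which a property test enforces.

Width and duct areas are not printed anywhere authoritative and are
**calibrated stand-ins**: BM width 0.08 → 0.25 mm, chosen so the basal
characteristic frequency (~29 kHz) sits in the chinchilla's upper audible
range and the model's tuning map tracks the species' Greenwood function;
duct areas 1.1 → 0.35 mm² per duct, at chinchilla scala scale. This
calibration was done once against the Greenwood benchmark and frozen; the
values are plain config fields for sensitivity runs and must not be read
as measurements. With a textbook-typical width of 0.125 mm the
basal resonance would fall near 12 kHz and the highest stimulus (10 kHz)
would peak almost on the basal boundary with a truncated wave-buildup
region.

## Materials

All inner-ear structures are tabulated with exact constants
(densities, moduli, β damping, fluid viscosity, speed of sound), including
structures the solver never uses (bone, cupulae, maculae, membranous
labyrinth) so the table is complete for audit. Two recorded conflicts are
deliberately left unresolved: the bone modulus appears both as 13.4×10¹⁰ Pa
(table) and 14.1 GPa (text) — irrelevant under rigid walls — and the fluid
bulk modulus 2.6×10⁹ Pa is inconsistent with the speed of sound 1498 m/s at
ρ = 1000 kg/m³ (sqrt(K/ρ) = 1612 m/s). Construction surfaces the latter as
a warning; the solver treats c as primary.

The graded laws take x in **millimetres**: E_bm = 7.1e4·e^(−0.21x) Pa,
β_bm = 2.3e-8·e^(0.52x) s, E_rm = 1e4·x Pa (floored at x = 0.1 mm so the
basal value is nonzero), β_rm = 6e-6·e^(0.158x) s. In metres the exponents
would make the laws effectively constant over 18.3 mm, which cannot carry a
tonotopic gradient; in millimetres they give a 47× modulus drop, the
physiologically sensible reading.

### Partition reduction

The BM strip (width w, thickness t, clamped at both edges, uniform
trans-partition pressure q) has the classical deflection profile
y(ξ) = q ξ²(w−ξ)²/(24 D_plate). Its *mean* deflection is q w⁴/(720 D), so
the stiffness per unit area defined against the mean deflection — the
quantity that carries volume velocity in a transmission line — is

    K(x) = 720·D/w⁴ = 60·E(x)·t(x)³ / ((1−ν²)·w(x)⁴).

The plate constant C = 60 is therefore a derived convention, not a free
parameter; it is still config-exposed (32 recovers the midpoint-deflection
convention, 16/3 a simply supported strip). Mass per unit area is ρ_bm·t.
β enters as a complex stiffness K(1+iωβ), the standard harmonic-analysis
meaning of stiffness-proportional Rayleigh damping.

### Longitudinal bending

A purely locally reacting partition with the basal damping law above has
loss factors ωβ ~ 10⁻³ near the base: its resonances are needles a few
micrometres wide supporting arbitrarily short waves — an artifact of the
1-D reduction, since the real BM (and any 3-D shell model of it) has
longitudinal bending stiffness that cuts such waves off. The partition
equation therefore retains the strip's longitudinal flexural rigidity
D = E t³/12(1−ν²) per unit width (same constants, complex with the same β),
discretized variationally with free ends. This imposes a physical
short-wavelength cutoff λ_c ≈ 1.2·w ≈ 0.1 mm at the base and makes the
solution grid-convergent at practical resolutions. Switching
`longitudinal_coupling` off recovers the pure transmission line (used by
the closed-form oracle tests).

## Fluid line

Series impedance per unit length: Z' = iωρ(1/A_sv + 1/A_st,eff), with
A_st,eff = A_st(1−φ) under occlusion. Two optional physical terms are on by
default:

- **Viscous wall drag**: the Stokes boundary layer of the tabulated
  viscosity adds (1+i)·sqrt(ωρµ/2)·P/A² per duct (P = circular-equivalent
  wetted perimeter). Relative to the fluid inertia this scales as ω^(−1/2),
  so it damps low frequencies hardest — part of why apical peaks are lower.
- **Compressibility** (`formulation: acoustic`): adds the fast-wave shunt
  iω·A_h/(2ρc²) with the tabulated speed of sound. Its effect on the slow
  wave is small (peaks move < 0.1 mm), which a test pins.

Boundary conditions: prescribed oval-window volume velocity
U_s = iω·u_s·A_fp at the base (stapes footplate area default 0.8 mm²; the
round-window pressure release is what closes this single-loop circuit), and
a helicotrema impedance at the apex, by default matched to the local
characteristic impedance sqrt(Z'/Y') so the unabsorbed remnant of the wave
leaves without reflection. The stapes drive defaults to a flat 10 nm at
90 dB label; all reported quantities are normalized by stapes displacement,
so only the footplate area (not the amplitude table) matters even in
principle, and neither affects normalized results.

## Electrode

A tapered body (defaults 0.55 → 0.25 mm diameter — a long lateral-wall
array scaled to chinchilla dimensions, not measured values) lies in the
scala tympani from the round-window entry to the insertion angle θ ≤ 900°.
Because the thin distal end leads during insertion, the diameter seen at
position x for a partial insertion is interpolated along the array from its
tip; deeper insertions are therefore supersets both in span and pointwise
occlusion (a tested invariant). Occlusion ramps to zero over one grid cell
at the tip. Default mechanical coupling is occlusion plus a compliant shunt
branch iωC_e/(1+iωβ_e), C_e = a_e/E_e, which carries the electrode's
modulus, and silicone loss factor into the system at its physically
correct — negligible — magnitude. An optional `mass_loading` mode adds
ρ_e·a_e/w to the partition mass for sensitivity studies. The wetted-surface
viscous drag of the electrode is deliberately excluded from the default
(it belongs to the same boundary layer already attributed to the walls,
and double-counting it roughly triples the low-frequency peak shift).

## Discretization and numerics

Uniform grid on the midline, default dx = 0.025 mm (733 nodes): four to
five nodes per bending-cutoff wavelength, inside the convergent regime —
halving dx moves peak locations by < 0.1% of L and smoothed peak
magnitudes by < 1%. A 0.05 mm grid is accepted and fast but sits at the
edge of resolving λ_c. Fluid continuity is discretized by second-order
finite volumes (half cells at the ends carry the source and termination),
the bending operator by the variational square of the second difference
(natural free-end conditions). The assembled complex system — tridiagonal
for the locally reacting case, 2×2-block sparse with bending — is solved
directly; the normwise backward error is checked against the configured
tolerance (default 1e-10, surfaced in diagnostics). The finite-volume
fluxes make the discrete power balance exact: stapes input equals
partition + electrode + viscous + helicotrema dissipation to solver
precision, and each solve reports the balance. Ties in peak finding break
toward the base; displacement sign is positive toward the scala vestibuli.

## Analysis pipeline

Per frequency: normalize |u(x)| by the stapes displacement, smooth with a
centered moving average over 0.2 mm (reflective edges; sum-then-divide so
constants are preserved bit-exactly), take the global maximum. The 0.2 mm
local filter suppresses the short-wavelength interference ripple that
collects near and beyond the peaks, where neighbouring frequencies'
wavelengths overlap. Greenwood comparison inverts F(x̃) = A(10^{a x̃} − k)
(chinchilla preset A = 163.5, a = 2.1, k = 0.85; x̃ measured from the
apex); out-of-range frequencies are flagged NaN rather than fatal. The
frozen regression bound for the healthy model is RMS location error
< 5% of L (measured: 2.0%).

Residual-hearing deltas compare implanted vs healthy tuning per frequency
and angle: peak shift Δx in mm and magnitude change in dB
(20·log₁₀ ratio). "Minimal effect" is operationalized by frozen default
thresholds |Δx| ≤ 0.1 mm and |ΔdB| ≤ 3 dB. The location threshold is a
fixed physical tolerance (two steps of the coarse 0.05 mm reference grid,
~0.5% of BM length), not a multiple of the run grid: a tolerance that
tightens under grid refinement would penalize better resolution for the
same physics. Measured at defaults: ≤ 0.075 mm and ≤ 0.19 dB across all
angles and frequencies.

## What the synthetic model does and does not show

The generator emulates the study conditions — BM length and thickness
taper, coil with ≥ 900° of electrode room, two ducts with a compliant
partition, graded laws, stapes drive, 180°-stepped insertion sweep — but
its width, duct areas and spiral parameters are calibrated plausibilities,
and the solver is a 1-D reduction of a 3-D problem. Passing tests
therefore show that *under this model class* tonotopy is preserved and the
occlusion effect of an atraumatic insertion is small; they do not
constitute evidence about trauma, fibrosis, round-window stiffening, or
any mechanism the reduction omits. Known limitations: no active
(outer-hair-cell) amplification, so tuning is broad and passive; no
short-wave 3-D fluid loading (the bending cutoff stands in for it); the
helicotrema impedance is idealized as matched; Reissner's membrane carries
no load; absolute displacement levels inherit the flat stapes table and
should only be read normalized.

## Problem sizes

Default runs: 733 nodes × 7 frequencies; the full sweep is 6 solves
(healthy + 5 angles), ~40 sparse solves of order ≤ 1466 in total, well
under a second of linear algebra. The test suite's convergence checks use
up to 1465 nodes.
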