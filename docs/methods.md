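# Methods

`mrsim` models the self-assembly of liquid micro-reflectors around
micron-scale fluorescent beads and their effect on fluorescence
collection, and implements the time-lapse analysis used to measure that
effect.  The chain is: vapor-condensation kinetics → equilibrium meniscus
shapes → ray-traced collection enhancement → (optionally) enhancement
versus time; a separate module generates and analyzes synthetic
time-lapse image stacks.

## Condensation kinetics (`mrsim.condensation`)

After a critical nucleus forms at the bead/substrate/vapor triple
junction (fast, treated as instantaneous), the reflector volume grows by
condensation onto its liquid-vapor surface:

    dV/dt = J · V1 · A_lv(V)

* `J` — kinetic-theory impingement flux `n0 · sqrt(k T_sat / 2 π m1)`
  (molecules m⁻² s⁻¹), the one-sided Maxwell-Boltzmann wall flux.  The
  model assumes steady state (constant vapor density, transient heating
  neglected) and a sticking coefficient of 1.
* `m1 = 4.69 × 10⁻²⁵ kg`, `V1 = m1/ρ = 4.15 × 10⁻²⁸ m³` — mass and
  liquid-phase volume of one PEG molecule.  The nominal condensate is
  PEG 300, modeled as the pure hexamer HO–(C₂H₄O)₆–H (282.3 Da; the
  "300" is the commercial mixture's average).
* Initial condition: a monolayer ring at the triple junction,
  `V0 = π D V1^(2/3)` — circumference `π D` times a molecular
  cross-section `V1^(2/3)`.

Saturated vapor pressure of the oligomer: no single published Antoine
fit covers PEG oligomers, so the package uses a two-parameter-per-M
Clausius–Clapeyron correlation,

    ln(P/P_atm) = −(ΔH(M)/R) (1/T − 1/T_b(M)),
    ΔH(M) = (23.5 + 15.0·M) kJ/mol,   T_b(M) = (450 + 35·M) K,

calibrated to literature boiling points (518/558/587 K) and vaporization
enthalpies (≈52/71/84 kJ/mol) of di-, tri- and tetraethylene glycol and
extrapolated linearly in the monomer count M.  For M = 6 it predicts a
boiling point of ≈387 °C and P_vap(100 °C) ≈ 0.013 Pa, which puts the
reflector-formation timescale for a 100–120 °C reservoir at tens of
seconds to minutes — the right order for vapor-deposited micro-optics,
though the extrapolated pressure itself is uncertain to well over a
factor of two.  The correlation is declared valid for 20–250 °C; outside
that window a warning is logged and the value extrapolated.  The
saturation temperature for a given vapor density n0 inverts this curve
through the ideal-gas closure `P = n0 k T` (Brent root find, converged
to ≪ 0.01 K).  Temperatures are SI kelvin everywhere; the correlation's
Celsius form is converted at the function boundary.

Material defaults (overridable via `PEGProperties` or the TOML config):
ρ = 1130 kg/m³, γ = 43.5 mN/m, n = 1.46.  These literature values
reproduce the stated V1 from the stated m1 to 0.1%.

The growth ODE is integrated with an adaptive explicit Runge–Kutta
method (rtol 1e-8).  `A_lv(V)` comes from the meniscus shape family; if
the requested volume leaves the family's tabulated range the curve is
truncated there and flagged.

## Meniscus shapes (`mrsim.meniscus`)

The liquid-air interface satisfies the Young–Laplace balance
`Δp − ρ g h = 2 γ K_m`.  The solver integrates the axisymmetric
arc-length form

    dr/ds = cos φ,  dh/ds = sin φ,  dφ/ds = ±(Δp − ρgh)/γ − sin φ / r

(the sign fixed by which side of the curve holds the liquid), which —
unlike the graph form h(r) — handles vertical tangents that occur for
large menisci.  A profile is shot from a contact point on the bead at
polar angle α (from the bead-substrate tangency point) with launch
direction set by the particle contact angle θ_p against the local bead
tangent, and integrated until it reaches the substrate plane; failures
(re-entry into the bead, pinch-off at the axis, runaway without a
substrate crossing) are classified and reported distinctly.  A 1-D root
search over α then matches the achieved substrate contact angle to θ_s
within 0.3° (the scan uses cheap low-tolerance shots; matched profiles
are re-integrated at rtol 1e-9).  Internally everything is
nondimensionalized by the bead radius R: pressure κ = Δp·R/γ, gravity
as the Bond number ρgR²/γ (~3 × 10⁻⁵ at 10 μm — negligible, but the
term is retained).

At fixed Δp up to two menisci satisfy the same contact-angle pair (a
small pendular-ring branch at strongly negative Δp and a large drop-like
branch in a narrow band of small positive Δp); the family builder
collects both branches over a composite Δp grid (log-spaced negative
side κ ∈ [−60, −0.005], fine linear positive side κ ∈ [0.005, 0.6]),
sorts by volume, and returns `n_shapes` profiles spaced approximately
uniformly in log-volume.  Default contact angles are θ_s = 30°,
θ_p = 60° (the experimentally-matched pair); the sensitivity grid
{30°, 35°} × {55°, 60°, 65°} is one constructor argument away.

Geometry: volumes are boundary-circulation (Green's theorem) integrals
of π r² dh along the generatrix plus a closed-form spherical-segment
term for the wetted bead cap; areas are ∫ 2π r ds.  Both are evaluated
with composite Simpson quadrature on a 2001-point sampling of the dense
ODE solution (cap/catenoid oracles pass at ≤1e-8); the stored
generatrix is resampled to 400 equal-arc-length points, which is what
the ray tracer consumes (a 4× finer surface changes detector totals by
less than the Monte-Carlo scatter).

## Ray tracing (`mrsim.raytrace`)

Non-sequential Monte-Carlo tracing with intensity splitting.  The scene
is watertight: polystyrene bead (n = 1.61, resting tangent on the
substrate), optional meniscus volume (n = 1.46) bounded by the bead cap
below the contact circle, the wetted substrate disk and the meniscus
surface of revolution, a laterally infinite coverslip slab (n = 1.5,
180 μm), and air.  Emitters are placed uniformly inside the bead; each
ray carries a relative intensity and is split at every interface into a
reflected and a refracted child with unpolarized Fresnel power
coefficients (mean of s and p; no interference, absorption or
wavelength dependence — geometric-optics regime, incoherent unpolarized
fluorescence).  Total internal reflection spawns a single full-intensity
child.  Termination: escape to the far field (binned by the polar angle
of the final direction, signed by the x-component, 1° bins from −80° to
80° per hemisphere; steeper rays are ledgered as outside-aperture),
relative intensity below the cutoff (default 1e-4, ledgered as
truncated), or split depth beyond the maximum (default 12, ledgered as
trapped).  The ledger must conserve the emitted intensity to 1e-6 —
violations raise.  The default budget is 2000 emitters × 5000 rays; the
`fast` profile (200 × 2000) is used for desk-scale runs and acceptance.
The per-ray depth-first walk is a numba kernel; meniscus intersection
treats each generatrix segment as a conical frustum with
bounding-cylinder and z-window prefilters.

Sampling design: emitter coordinates (radius³, cos θ, azimuth) and each
emitter's ray directions (cos θ, azimuth) are jittered-Latin-hypercube
stratified with independent random stratum orderings, so every marginal
distribution is exactly uniform-in-ball / isotropic while the
clustering variance that dominates small budgets is suppressed.  All
draws come from one seeded generator in a fixed order (emitters, then
each emitter's direction block), so two scenes traced with the same
seed share identical rays — enhancement ratios use these common random
numbers.

For the bare perfect sphere the trapped fraction is computed by
classifying each ray once by its first internal incidence angle against
the critical angle (in a perfect sphere the incidence angle repeats
forever, so super-critical rays never escape).  The estimate is
cross-checked against a 1-D quadrature over emitter radius — for
emitter radius fraction x the trapped solid-angle fraction is
√(1 − (s_c/x)²), s_c = 1/n — whose closed form is (1 − 1/n²)^{3/2}
≈ 0.481 for n = 1.61, i.e. the "about half the light is trapped"
baseline.  Real beads are rougher and trap less; the model deliberately
keeps the perfect sphere.

## Enhancement analysis (`mrsim.enhancement`)

Collection within a numerical aperture sums detector bins inside
arcsin(NA) on the chosen side (default: lower, through the coverslip,
matching the inverted detection geometry), weighting the boundary bin
by its fractional angular overlap (arcsin 0.13 = 7.47° is mid-bin;
nearest-bin rounding would bias the headline ratio).  The enhancement
of a shape is its in-cone collection divided by the bare-bead in-cone
collection from the same rays.  Composing enhancement(V) with the
growth law V(t) gives enhancement against time.  By reciprocity the
reflector concentrates excitation like it redirects emission, so the
predicted total signal enhancement is the collection enhancement
squared; symmetrically, `experimental_adjustment` divides a measured
intensity series by its minimum (taking the smoothed, freshly-coated
bead as reference) and takes the square root to isolate the collection
component.

Monte-Carlo uncertainty at the fast budget: the NA-0.13 cone receives
only ~0.2% of the emitted intensity for the bare bead, so the
peak-enhancement estimate (a maximum over 20 shapes sharing one ray
set) scatters by roughly ±10% between seeds even with stratification
and common random numbers; at a 2-million-ray budget the peak of the
default family converges to ≈2.45–2.50.  The headline check therefore
fixes the seed; `scripts/acceptance.py` recomputes both headline
numbers for any seed.

## Image pipeline (`mrsim.imaging`)

Per frame: background = median, robust σ = 1.4826·MAD (floored at one
count so noiseless integer frames keep a meaningful threshold),
detection threshold = background + 5σ, 8-connected labeling, minimum
region area 4 px.  Each region's intensity is the background-subtracted
sum over the region expanded by 3 px (`skimage.segmentation.expand_labels`,
which cannot merge neighbors); the expansion captures the faint spot
skirt so the measured flux tracks the true flux to ~1% across the
brightness range instead of varying with the threshold contour.
Segmentation is redone every frame, so the growing apparent bead size as
the reflector redirects light next to the bead is included in the
measured total.  Clusters are rejected once, on frame 0, as regions
larger than 1.8× the median region area.  Tracking: nearest-neighbor
linking around positions predicted with a global drift estimate (median
displacement of the previous frame's matches), links refused beyond one
median bead diameter, beads unmatched for more than 3 frames marked
lost, double-claimed regions flagged merged.  Per-bead curves are
normalized either to frame 0 or by the min-then-sqrt convention; cohort
mean ± sd is reported across retained beads.

The synthetic generator renders beads as Gaussian spots (σ = 2 px)
whose integrated flux follows a dip-then-rise profile (defaults: dip to
0.5 of the initial value at 120 s, peak at 2.8× at 420 s — the
characteristic shape of reflector formation around a 10 μm bead with
frames every 2 s), with global linear drift (default ~0.2 px/frame,
emulating thermal expansion of the holder), small per-bead jitter,
Poisson shot noise, Gaussian read noise (2 counts) over a 10-count
background, and a configurable fraction of touching bead pairs placed
one bead diameter (≈5σ) apart.  The default amplitude of 400 counts
gives peak SNR ≈ 20.  What the generator does *not* emulate: spatially
varying illumination, photobleaching, the stochastic blinking of the
smallest beads (droplet coalescence), PSF asymmetries, or
camera-specific noise; passing the recovery tests therefore shows the
pipeline is correct and drift/cluster-robust at realistic SNR, not that
it is robust to every artifact of real microscope data.

## Numerical choices and limitations

* Shooting integration: RK45, rtol 1e-9 (1e-6 for scan shots), events
  for substrate crossing, pinch-off, bead re-entry and runaway escape.
* Volume/area quadrature: composite Simpson on 2001 points (exactly
  additive at even split indices).
* Ray self-hit exclusion: 1e-12 m path offset; detection is by final
  direction (far field), the nominal 10 cm detector distance is
  cosmetic.
* The splitting cutoff (1e-4) and depth cap (12) leave ≲1e-4 of the
  intensity in the truncated/trapped ledger entries for meniscus
  scenes; in such scenes "trapped" means terminated inside a medium by
  the depth cap, which includes light waveguided laterally in the slab.
* Out of scope by design: coherent whispering-gallery physics and
  surface roughness (invoked only qualitatively for the initial
  intensity dip of real beads), droplet coalescence, contact-angle
  hysteresis, non-axisymmetric menisci, heater/chamber heat transfer.
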