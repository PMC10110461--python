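# Methods

## Physical model

Each fluorophore is a rigid dipole at orientation Ω = (θ, φ) carrying a
photo-state: OFF (dark, ground state of the switched-off chromophore), ON
(fluorescent), and optionally a dark shelving INTERMEDIATE and an
irreversibly BLEACHED state.  The system state is a density n_s(Ω, t) per
photo-state over the unit sphere; all observables are linear functionals of
these densities, so concentration and absolute molecule number only set an
overall photon scale.

**Photoselection.** Every light-driven rate follows the one-photon law.
For a beam of power density P (W/cm²) with peak rate constant k (1/s per
W/cm², the value for a dipole parallel to the field):

- linear polarization along ê: rate(Ω) = k·P·(μ̂·ê)²;
- circular polarization in the plane ⊥ ẑ: rate(Ω) = k·P·(1−μ̂_z²)/2.

405-nm light drives OFF→ON; 488-nm light drives ON→OFF and simultaneously
excites fluorescence (rate constant k_exc, same angular kernel).  Because
emission and OFF-switching are driven by the same beam, the expected number
of photons an ON molecule emits before switching off is
brightness·k_exc/k_off independent of its orientation history — which is
why a population that starts 100% ON yields exactly 10× the photons of a
10% photoselected start under identical readout (the scheme-2 advantage).

**Rotation.** Isotropic rotational diffusion with coefficient D_r; the
spherical-harmonic mode of degree l decays at l(l+1)·D_r, so the anisotropy
(an l = 2 moment) of a free sphere decays with τ_rot = 1/(6·D_r).  A
`static_fraction` models an immobile sub-population (D_r = 0) and adds a
constant anisotropy component.  The Stokes–Einstein–Debye relation
τ_rot = π·η·d³/(6·k_B·T) converts between correlation time and hydrodynamic
diameter; it assumes rigid spheres, stick boundary conditions and uniform
solvent viscosity, so fitted diameters are *apparent* sizes.

**Detection.** Emission from a dipole μ̂_em is projected on two analyzers
x̂ (parallel) and ŷ (perpendicular) with weights
w = (1 + 2·P₂(cos β)·P₂(μ̂·ê))/2, where β is the absorption–emission dipole
angle (β = 0, collinear, by default; the azimuthally averaged P₂(cos β)
factor is the standard depolarization correction).  The normalization makes
an isotropic emitter split its `brightness` photons equally between the
channels, so r = 0 exactly for isotropic populations and r₀ = 0.4 for
cos²-photoselected ones.  High-NA depolarization is not modelled.  A
polarization-insensitive mode (each channel collects half of every photon,
orientation-independent) represents single-detector readout and is the
default for the two-pulse scheme's total-count observable.

**Detector.** Gain imbalance G multiplies the parallel channel; cross-talk
background and dark counts are independent Poisson streams at constant
rates per channel.  `calibrate_g` recovers G as the channel-count ratio of
an isotropic, circularly excited record.  The cross-talk level is estimated
from the tail of the OFF-switching reset segment and subtracted from both
channels before computing r.

## Numerical engine

The reference solver discretizes the sphere on a Gauss–Legendre (cos θ) ×
uniform (φ) grid, 64 × 128 by default (band limit l = 63).  Quadrature is
exact for the polynomial kernels involved, which is why the photoselection
identities (r₀ = 0.4, equal-channel symmetry) hold to machine precision on
the grid.  One time step is Strang-split:

1. diffuse dt/2 — exact per retained mode, by filtering the
   spherical-harmonic spectrum with exp(−l(l+1)·D_r·dt/2); unconditionally
   stable, mass-conserving, uniform fields are exact fixed points;
2. react dt — the per-cell linear kinetics (switching, shelving, bleaching,
   emission) have constant coefficients within a step and are advanced with
   closed-form solutions, including analytic time-integrals of the ON
   population for bin-exact expected photon counts;
3. diffuse dt/2.

Step control: within detecting segments the step never exceeds the bin
width nor 0.1/max(rate); segments during which the rotor barely moves
(6·D_r·Δt < 0.02) are taken in a single exact reaction step, since
splitting error only arises from the rotation–reaction interleaving.
Spectral truncation can produce negative undershoots of order the solver
tolerance; these are clamped to zero.

An independent axially symmetric solver (`LegendreModeSolver`) expands the
densities in Legendre modes about a common beam axis and integrates the
coupled switching/diffusion ODEs exactly with a matrix exponential —
no grid and no splitting.  For schemes with all beams linear along one
axis the two engines agree to ~2·10⁻⁴ relative on channel fluxes; this
dual-route check is part of the test suite.  The published description of
the underlying multi-state analytical model was not available in full, so
the orientation-resolved engine here is a numerically equivalent
construction, not a transcription of that algebra.

**Intermediate state.** With `intermediate_rate` g set, OFF-switching
shelves ON molecules into a dark ground-state intermediate that decays at
g with equal branching back to ON and on to OFF.  At high probe power this
makes the observed fluorescence decay bi-exponential: a dominant fast
component at the shelving rate and a weak slow tail at ≈ g/2 (so
g = 4·10⁴ 1/s gives the ~50 µs slow component seen for rsEGFP2 at high
488-nm intensity).  The equal branching ratio is a modelling choice; the
state graph of the real photocycle is richer.

## Pulse schemes and defaults

All defaults are package operating points chosen to mirror the published
experiments; every one can be overridden.

- **Scheme 1**: 250-ns linear 405-nm pulse whose fluence is calibrated by
  root-finding so the orientation-averaged ON fraction is 10%; probe 1 ms
  circular 488 nm at 100 W/cm²; storage bins 2 µs (a 10-ns hardware-like
  floor on bin width is enforced; sub-µs storage bins are unnecessary for
  µs–ms rotors).  The probe mildly OFF-switches the selected population
  (~25% over 500 µs at defaults), which is the main source of the ~3%
  upward bias of fitted correlation times.
- **Scheme 2**: the circular activation is ideal by default (cycle starts
  100% ON, isotropic); probe linear 488 nm.  Early-time r equals the
  conventional steady-state photoselection value 0.4, then decays only if
  OFF-switching outcompetes rotation.
- **Scheme 3**: two identical 50-ns linear 405-nm pulses (default first-
  pulse ON fraction 50%), delays 0.2–500 µs, readout by a strong circular
  488-nm probe (2000 W/cm², 1 ms) that depletes the ON population
  essentially completely, so the total count reports the switched-ON number
  itself and the single-pulse-normalized signal is exactly 1 when the
  second pulse is absent.  The default observable is polarization-summed
  (single-detector readout); a polarization-resolved variant is available.
  `analyze_method3` fits F(Δ) = F∞ − (F∞−F₀)·exp(−Δ/τ_eff) and maps τ_eff
  to τ_rot through a forward-model calibration table, because hole
  refilling mixes the l = 2 and l = 4 diffusion modes and τ_eff is ~10%
  below τ_rot.

Multi-cycle acquisitions propagate one cycle and scale expectations by the
cycle count, assuming the trailing reset (strong circular 488-nm pulse, ~20
mean switching times) restores the initial state; the residual ON mass is
recorded in the metadata.  Poisson sampling happens at the bin level on the
accumulated expectations, with named, independent substreams (signal,
background, dark, per-delay) derived from one seed so adding a stage never
perturbs the draws of another.

## Fluorophore presets

`rsEGFP2` and `DronpaM159T` presets ship as JSON with explicit provenance
flags: the peak rates per W/cm² are order-of-magnitude values derived from
typical absorption cross-sections and switching quantum yields, not
calibrated measurements.  They set realistic ratios (ON-switching much
faster than OFF-switching per unit power; ~0.02 detected photons per
excitation) and are sufficient for scheme design and pipeline testing, but
absolute power densities should be recalibrated against any real
instrument.

## Analysis pipeline

Anisotropy is computed per bin after background subtraction and G
correction; bins whose corrected denominator is not positive are flagged
invalid, never silently dropped.  The 95% confidence band propagates
Poisson variance (Var = N) through the anisotropy formula to first order
(delta method, z = 1.96); a seeded parametric bootstrap is provided as a
cross-check and agrees with the delta method within 15% of interval width
for ≥100 counts per bin.

Decay fits minimize weighted least squares (weights 1/σ² from the CI band;
noiseless expectation curves are fitted unweighted) with a multi-start over
a logarithmic τ grid — the offset and amplitude are solved linearly at each
start — followed by Levenberg–Marquardt polish in log τ.  Models:
r(t) = r_static + A·exp(−t/τ) and the stretched variant
r(t) = r_static + A·exp(−(t/τ)^β), β ∈ (0.05, 1], compared by AICc.  A
curve with no resolvable decay (chi-square gain below the ~95% threshold
for the extra parameters) returns the static fit with τ flagged
unconstrained rather than an arbitrary number.  τ intervals are transformed
to diameter intervals through the cube-root Stokes–Einstein map endpoint by
endpoint (the cubic nonlinearity makes the diameter interval asymmetric).

Imaging: records are (y, x, t) photon stacks per channel (row-major,
0-based, half-open time bins), stored as two multi-page 16-bit TIFFs plus a
JSON sidecar with bit-exact round-trip.  Segmentation normalizes the
time-integrated intensity by the maximum of its 3×3-median-filtered version
(hot-pixel guard; the filter size is a package choice) and labels pixels by
half-open bands (lo, hi] — the cell-data preset uses (0.05, 0.30] for
cytosol and (0.50, 1] for bright clusters; a generic Otsu two-class split
covers nucleus-style segmentation, whose threshold is otherwise
unspecified.  Region decays are exact integer photon sums; per-pixel
anisotropy maps mask pixels below a count threshold.

## Synthetic data: what it does and does not show

The fixture generator produces bead series (30/60/100 nm), a two-population
particle scenario (a constrained slow rotor with a high anisotropy plateau
vs a fast free rotor), a cell-like field with bright clusters
(τ = 22.2 µs) over cytosol (τ = 8.1 µs), and a static reference — each as
curve-mode CSV and image-mode TIFF records with ground truth.  It emulates
cos² photoselection, tunable OFF-switching, Poisson shot noise, detector
imbalance and cross-talk background.  It does **not** emulate high-NA
depolarization, scanning/timing artifacts, detector dead time or
afterpulsing, homo-FRET between densely packed fluorophores, or spatial
heterogeneity of viscosity.  Passing the recovery tests therefore
demonstrates the correctness and statistical efficiency of the pipeline
under the stated model, not instrument-level accuracy on real samples.

## Problem sizes used in tests

The test suite runs the engine at 32×64 (some cross-checks at 48×96 and the
scheme-3 sweep at the default 64×128), probes of 50–500 µs with 1–2 µs
bins, and photon budgets up to 10⁷ — sizes chosen so the full suite
completes in well under a minute while every tolerance is met with margin.
Recovery accuracy at these settings: fitted diameters within ~2% of truth
at 10⁷ photons (the stated acceptance band is 15%), 60 vs 70 nm separated
at 95% confidence, matching the ~10-nm size discrimination the method
claims at high photon budget.

## Known limitations

- Two-analyzer detection with an orientation-dependent total collection;
  no unpolarized total-intensity correction for scheme 1/2 observables.
- The scheme-2 quantitative inverse problem (extracting τ from the
  OFF-switching/rotation competition) is provided only as closed-loop
  fitting against this package's own forward model.
- No mass↔diameter conversion is offered; cubic scaling between mass and
  hydrodynamic size is too assumption-laden to bundle.
- The Legendre-mode accelerator is valid only for axially symmetric beam
  geometries and the two-state model.
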