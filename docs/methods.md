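# Methods

## Scope and model

`pmmc` implements a macro Monte Carlo (local-to-global) dose engine for
protons in voxelized geometries, together with the two auxiliary engines it
needs: a slab *pre-simulator* that builds the macro-step parameter database,
and a full condensed-history *reference* Monte Carlo used as the built-in
benchmark.  All three engines share one set of compiled micro-physics
kernels, so a comparison between the macro transport and the reference
isolates the macro-step approximation rather than differences in physics
tables.  This internal-consistency design is deliberate: the package makes
no claim of parity with general-purpose Monte Carlo codes or with measured
data — its validation surface is "macro transport versus its own reference
under identical physics".

### Stopping power and range

A single analytic model is used throughout:

    R_CSDA(E) = a_csda · E · (E + 2 MeV)      [cm]
    S(E)      = 1 / (a_csda (2E + 2))         [MeV/cm]
    E(R)      = −1 + sqrt(1 + R / a_csda)     [MeV]

with the material-dependent coefficient `a_csda` (cm/MeV²) taken from the
CT ramp.  The three functions are exact closed-form inverses, which keeps
energy book-keeping bit-exact: per-history ledgers close to ~1e-15 relative.
Mean energy loss over any step is evaluated through the range algebra (no
step-size error), so step-size convergence is governed by scattering and
binning only.

### CT ramp

Seven node materials (air, lung, adipose, muscle, spongiosa, cortical bone,
teeth) with HU value, mass density, mass stopping power ratio (mSPR) and
`a_csda`.  HU between nodes defines a *mixed material* by linear-in-HU
interpolation of all properties; HU outside the ramp clamps to the end
nodes.  Linear-in-HU interpolation was chosen (over, e.g., linear-in-density)
as the simplest scheme consistent with a piecewise-linear calibration curve;
the difference is second order within a band.  The ramp additionally carries
a `scatter_ratio` column, X0(water)/X0(material) per g/cm² (≈1 for soft
tissue, 2.17 for cortical bone, 2.55 for enamel): multiple scattering per
unit mass is much stronger in mineralized tissue, and a density-only scaling
would understate it badly — precisely the effect the lateral-interface
scenario probes.  Users may supply their own ramp (YAML, same schema; the
column is optional and defaults to 1).

### Condensed-history micro physics (presim + reference)

Per micro step (default 0.01 cm):

* **Energy loss** — closed-form mean plus Gaussian (Bohr-like) straggling,
  σ² = 0.087 MeV²cm²/g · ρ · Δs.  The fluctuation is truncated to a window
  *symmetric about the mean* (also bounded by [0, E]); a plain
  clamp-at-zero would bias the mean upward by ~1% per range at this step
  size because σ ≈ mean/2 per step.
* **Multiple Coulomb scattering** — Highland:
  θ₀ = 14.1 MeV/(pv) · sqrt(t) · (1 + log₁₀(t)/9), t = path·ρ·sc/X0_water.
  Because the log-corrected variance is not additive over sub-steps, the
  per-step variance *telescopes* on the proton's cumulative
  radiation-length path; at constant energy the summed variance then equals
  the Highland value for the full traversed path exactly.
* **Nuclear interactions** — simplified two-channel model with macroscopic
  cross-sections 0.012 cm⁻¹ (inelastic) and 0.006 cm⁻¹ (elastic) at unit
  density, flat above 100 MeV and ramping linearly to zero at 8 MeV.
  Elastic: Rayleigh-distributed deflection with σ = 30 MeV/pv and a 2%
  local recoil deposit.  Inelastic: one secondary proton carrying a uniform
  30–80% (mean 55%) of the available energy with a broad angular spread
  (σ = 0.35 rad), a 20% neutron share that escapes without depositing, and
  the remainder (heavy ions / de-excitation) deposited locally.  These are
  *not* fitted nuclear data; they are documented constants applied
  identically in all engines.
* Protons below 2 MeV deposit their remaining energy locally (residual
  range < 100 µm).

The pre-simulator transports protons through homogeneous slabs and stores,
per (material, energy, thickness): a 64-bin ΔE histogram, a 32×32 joint
(exit polar angle, lateral displacement) histogram, elastic/inelastic
interaction probabilities with a 32-bin interaction-depth histogram
(accumulated analytically with survival weighting, which removes the
sampling noise from these small probabilities), and the stopping fraction.
Protons stopping inside a slab are recorded with ΔE equal to their full
energy.

### Database

Defaults: energies 10→250 MeV in 10 MeV steps (the benchmark scripts use
10→150, which covers the beams they simulate), slab sizes
{0.05, 0.1, 0.2, 0.5, 1, 2} cm, 10⁴–2·10⁴ histories per record.  A slab is
recorded when its thickness does not exceed 60% of the CSDA range at the
record energy; the smallest slab is recorded unconditionally so that every
(material, energy) pair has a fallback.  Storage is HDF5
(`/material/<name>/E<MeV>/t<mm>`), with the physics-config hash checked on
load.

### Macro transport

Per macro step (flow):

1. If E < E_min (= lowest database energy, 10 MeV): deposit the residual
   energy along the current direction via CSDA and stop.
2. Raytrace the distance *d* to the next material interface (boundary
   between voxels whose HU values are separated by a ramp node; a shared
   boundary node does not separate).  *d* is capped at the grid exit and at
   the largest slab size.
3. Scan a cylinder of radius 0.5 mm around the intended step for voxels of
   a different material band (sampled at half the smallest voxel pitch).
   If an interface lies closer than 0.5 mm, force the smallest available
   slab; otherwise choose the available slab closest to *d* (ties toward
   the smaller slab).  Availability = recorded for both bracketing ramp
   nodes at the nearest grid energy and within 60% of the residual range.
   The non-adaptive mode instead caps the slab at the distance to the next
   voxel boundary with *any* HU change.
4. Represent the slab content by the *path-averaged* material along the
   intended step (length-weighted HU and scattering density, harmonic-mean
   `a_csda` since stopping powers add along the path).  Using the entry
   voxel alone aliases badly when the slab length is commensurate with the
   phantom's HU-cycle period and produced centimeter-scale range errors in
   the mixed-band phantom.
5. Sample the record of one bracketing node (probability = mix weight).
   ΔE is *mean-shifted* (not scaled) to the closed-form loss of the actual
   material/energy, preserving the energy-independent straggling width;
   a closed-form correction adds the stopping cost of the telescoped excess
   wiggle path (slab records accumulate scattering from a zero history,
   the proton's cumulative Highland variance grows faster).  Angle and
   displacement are scaled by sqrt(ρ·sc ratio) and the pv ratio at
   *mid-slab residual energies* (low-energy records lose a large energy
   fraction inside the slab, so start-of-slab pv would misrepresent them),
   then rescaled to the cumulative-path Highland variance.  Interaction
   probabilities are rescaled by the analytic cross-section ratio.
6. Build the hinge track (hinge at 30% of the slab size along the entry
   direction, then straight to the sampled exit point) and walk it through
   the voxels.  If the track crosses a material interface the step is
   truncated there: the closed-form partial energy loss for the traversed
   slab fraction is deposited and the proton resumes toward the sampled
   exit point from the crossing (a plain linear-fraction rescale is
   available via `TransportConfig(closed_form_partial=False)`; the measured
   difference is negligible).  If a hard interaction was sampled, the step
   is truncated at the sampled interaction depth, the direction is
   interpolated between entry and exit directions by path fraction, and
   secondaries are handled with the same rules as the reference engine.
7. Deposit ΔE over the traversed voxel cuts with the SPA: linear
   stopping-power profile (slope from the semi-empirical 0.8 MeV cm⁻²
   formula, S₀,₀ clamped at zero with the slope re-fit to preserve the
   track mean), weighted by local ρ·mSPR, and renormalized by a single
   factor so the deposits sum to ΔE exactly (the printed formula alone
   does not guarantee conservation once the density ratio varies).

The azimuth of the exit direction equals the displacement azimuth plus a
Gaussian spread of 0.6 rad — a modeling constant standing in for the
angle–displacement azimuthal correlation the histograms do not store.

### Scoring

Deposits accumulate per history through a stamp/touched-list scheme, giving
history-by-history Σx/Σx² per voxel *and* 10 batch sums in one pass; both
uncertainty estimators are exposed.  Dose is energy/mass with the mass from
the HU-interpolated density.  The 1-D gamma on depth-dose curves uses cubic
sub-voxel interpolation of the test curve (linear interpolation cannot reach
a peaked maximum between samples and falsely fails the Bragg-peak bin); the
3-D gamma searches a 3×-refined lattice within 3·DTA with trilinear
interpolation, against a retained brute-force oracle.  Efficiency is
ε = 1/(T·σ²) plus the hardware-independent mean-macro-steps-per-history
proxy.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `hinge_fraction` | 0.30 | hinge position as fraction of slab size |
| `lateral_threshold` | 0.05 cm | force smallest slab below this lateral distance |
| `e_min` | 10 MeV | switch to CSDA deposition |
| `micro_step` | 0.01 cm | condensed-history step (presim + reference) |
| `straggling_coefficient` | 0.087 MeV²cm²/g | Bohr straggling |
| availability fraction | 0.6 | max slab / residual range |
| energy grid | 10–250 MeV, 10 MeV steps | database records |
| slab sizes | 0.05…2 cm | database records |

`micro_step` was set to 0.01 cm (not 0.02) because at 0.02 the reference
engine's Bragg-peak amplitude still moves by ~1% when the step is halved,
violating the package's own convergence requirement (<0.5% above 10% of the
maximum, which 0.01 satisfies).

## What the phantoms emulate — and what they do not

The academic phantoms reproduce the validation geometry class: an
adipose–muscle mixture with layer-by-layer (1 mm) varying HU plus lung and
cortical-bone blocks in series (interfaces perpendicular to the beam) or
adjacent (parallel to the beam); the benchmark suite runs them at half the
published voxel counts (50×50×200 at 0.2×0.2×0.1 cm³) with 10⁵ histories,
which keeps depth-dose noise well below the 1% criterion while fitting a
desk-scale compute budget.  The synthetic patient-like head (ellipsoidal
soft tissue, bone shell, air cavities, teeth) exercises the full HU span on
the published grid dimensions but is *not* a real CT: passing tests show
the transport handles realistic HU heterogeneity and grid sizes, not that
clinical dose distributions are reproduced.  Block positions inside the
academic phantoms are package defaults (series: lung 4–8 cm, bone 12–16 cm
depth; adjacent: split at the beam axis), as the published figures do not
dimension them.

## Numerical choices and degenerate inputs

Ray traversal is Amanatides–Woo with half-open voxels and 0-based indices;
points exactly on the far face are outside.  Two voxels sharing only a ramp
node value are not an interface (tie-break).  Track truncation nudges the
resume point 10 nm into the next voxel.  Zero-length tracks deposit into
the containing voxel.  S₀,₀ < 0 (steep-gradient steps near the peak) clamps
to zero with the slope re-fit; an all-zero SPA profile falls back to
path-length·ρ·mSPR weighting.  Empty gamma ROIs raise; out-of-grid starts
raise.  Reproducibility: every history seeds its own substream derived from
the run seed, so results are independent of batching and bit-identical
across runs.

## Known limitations

* The nuclear model is a two-channel caricature (no fragment spectra, no
  angular correlations from cascade physics); it is shared between engines,
  so validation is blind to its absolute accuracy.
* Neutrons deposit nothing; the ~2% of energy they carry simply escapes in
  both engines.
* The scattering model scales water's radiation length by density and a
  per-material constant; it is not a Molière calculation.
* The lateral-interface stress test (125 MeV pencil 0.1 mm from bone/lung,
  restriction disabled) degrades to a maximum depth-dose discrepancy of
  ~2.6% of the curve maximum in this implementation — clearly worse than
  the ~0.8% with the restriction enabled, but smaller than the >5%
  published for the Geant4-referenced original.  Two reasons: the
  environment-breaking rescaling here is closed-form (more forgiving of
  oversized steps), and the simplified nuclear/scattering stand-ins soften
  the bone/lung contrast.  The qualitative conclusion — the lateral
  restriction is required below 0.5 mm — is reproduced.
* History-by-history variance tracking skips voxels beyond a 200k
  touched-voxel cap per history (never reached in practice; energy is still
  conserved).
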