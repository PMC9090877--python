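# Methods

`ecsdiff` simulates the transport of charged nanoparticles (NPs) through
the extracellular space (ECS) of brain white matter (WM) and estimates
their effective diffusion coefficient *D* from ensemble trajectories.
This note records the model, its assumptions, the numerical choices, and
the places where the design was genuinely open.

## Geometry: a stochastic WM cross-section

In WM, axons run in parallel; a transverse cross-section is well
approximated by a dense random packing of circles.  `generate_rve` builds
an 18 × 18 µm square (closed domain, coordinates in µm, origin at a
corner) filled with non-overlapping disks subject to four simultaneous
constraints:

| constraint | default | note |
|---|---|---|
| extracellular porosity | 0.30 ± 0.01 | area fraction not covered by axons |
| mean axon diameter | 1.0 µm ± 5 % | diameters truncated-lognormal in [0.2, 2.0] µm |
| minimum axon–axon gap | 0.1 µm (hard) | sets the ~100 nm typical ECS channel width |
| containment | hard | disks lie fully inside the box (no periodic wrap) |

The diameter *law* is not uniquely determined by the constraints; we use
a lognormal (right-skewed, as axon-caliber histograms are) truncated to
configurable bounds, with `sigma_log = 0.6` by default, affinely rescaled
so the sample mean diameter and the covered area are met exactly.  The
effective packing fraction — disks inflated by half the hard gap — is
≈ 0.82–0.84, beyond random-sequential-addition (RSA) saturation, so the
generator works in three phases: RSA seeding at shrunken radii, a
growth-and-relaxation loop (pairwise overlap pushes), and a FIRE
energy minimization on the soft-disk overlap energy to drain the last
near-jamming overlaps.  A small slack inflation (0.5 % of the gap) turns
the hard tolerance into a soft one: any residual overlap below twice the
slack still satisfies the true gap constraint.  If a draw does not settle
(packability varies between diameter draws near jamming), the generator
resamples and retries; every returned geometry passes a brute-force
O(n²) audit of all constraints.

Because axon diameters reach 2 µm, a release square at the domain centre
would land inside an axon in most realizations; geometries intended for
central-release simulations therefore carve a small keep-out disk
(`clear_radius = 0.25 µm`, 0.06 % of the domain) at the centre.

A mean axon length (15 µm) is carried in the configuration for
completeness but plays no role in a 2-D cross-section.

## Charge model: Zeta potential → particle charge

The only measurable proxy for a particle's charge state is its Zeta
potential ζ.  The Gouy–Chapman solution of the 1-D Poisson–Boltzmann
equation maps ζ to an effective surface charge density

δ_eff = √(8 c N_A ε k_B T) · sinh(e ζ / 2 k_B T),

with the ion concentration c in mol/m³ (the configuration accepts mol/L:
normal saline, 0.154 mol/L).  The particle's total charge is
q = δ_eff · π d_p² (sphere area), treated as a point charge at the
centre — adequate when inter-particle distances are large compared with
d_p.  δ_eff is used directly as the surface charge density; a hook
(`ParticleSpec.fixed_charge`) accepts an externally supplied charge when
a material-specific effective-to-real correction is available.  The
mapping is exactly invertible (`flat_plate_potential`), odd and strictly
monotone in ζ, and gives q ∝ d_p² at fixed ζ — the mechanism behind the
size–*D* relationship of charged particles.

Constants are fixed at the study's values (k_B = 1.38×10⁻²³ J/K,
e = 1.60×10⁻¹⁹ C, N_A = 6.02×10²³ mol⁻¹, ε₀ = 8.85×10⁻¹² C/Vm,
ε_NS = 6.55×10⁻¹⁰ C/Vm, T = 310 K).

## Forces

Four contributions act on each particle:

1. **Brownian forcing.**  White noise with per-component amplitude
   √(12 π k_B µ T r_p / Δt) for the bare Stokes drag; inside the
   integrator the amplitude carries an extra 1/√C_slip so that
   fluctuation–dissipation is exact for the slip-corrected drag (below).
2. **Stokes drag with slip.**  F_D = 6 π µ r_p (v_flow − v_p)/C_slip with
   the Cunningham factor C_slip = 1 + 2K_n(1.257 + 0.4 e^(−1.1/2K_n)),
   K_n = 0.025 (C_slip ≈ 1.063).  The fluid is static (v_flow = 0): the
   goal is a self-diffusion coefficient.
   Buoyancy and gravity are negligible at these sizes and are omitted.
3. **Pairwise Coulomb repulsion.**  Direct O(n²) sum
   F_i = Σ_j q² (r_i−r_j)/(4 π ε |r_i−r_j|³) over the live ensemble.
   ε is the **medium's** absolute permittivity (normal saline,
   6.55×10⁻¹⁰ C/Vm): a Coulomb interaction inside an electrolyte is
   reduced by the solvent's dielectric response, and only with the medium
   permittivity do the published magnitudes (headline *D* values,
   millisecond residence times) follow from this model.  A `vacuum` mode
   (ε₀) is retained for sensitivity analysis, as is a Debye-`screened`
   Yukawa mode (the default is unscreened: Debye-screened interactions at
   0.154 M would extinguish the charge effects the study reports).
   Hard particle–particle collisions are neglected (dilute suspension);
   instead the pair distance is clamped at one particle diameter, which
   caps the force and prevents singularities.
4. **Membrane DLVO force.**  Near an axon surface (treated as a flat
   plate; the particle is 10–100× smaller than the axon), the particle
   feels F = −∂/∂h (U_edl + U_vdw) along the surface normal, with
   U_vdw = −A_H d_p/(12 h) (sphere–plate van der Waals; Hamaker constant
   A_H configurable, default 10⁻²⁰ J, a typical polymer/water/lipid
   scale) and U_edl = q ζ_m e^(−κh) — the particle's charge in the
   membrane's Debye-screened Gouy–Chapman surface potential
   (ζ_m = −20 mV; κ⁻¹ ≈ 0.77 nm in normal saline).  This choice of U_edl
   is a deliberate repair: equating the electrostatic term directly with
   the surface potential would add volts to joules.  The force is cut off
   beyond 10 nm and h is clamped at h_min = 1 nm (standing in for Born
   repulsion).  Only the nearest membrane contributes.

## Equation of motion

At nanoparticle scales the Stokes number is ≪ 1: inertia relaxes in
picoseconds.  The integrator is therefore overdamped — drag balances the
other forces instantaneously:

v = v_flow + C_slip (F_C + F_mem)/(6 π µ r_p),
Δr = v Δt + √(2 D₀ Δt) Φ,  D₀ = C_slip k_B T/(6 π µ r_p).

This is the unique reading under which free diffusion reproduces the
slip-corrected Stokes–Einstein coefficient exactly, which the
free-solution validation rows then confirm by measurement.

Numerics:

- **Time step.** Base Δt = 10⁻⁷ s; for uncharged runs the step is chosen
  so the RMS Brownian step is ≈ 12 nm (well below the 100 nm channels).
  For charged runs an adaptive cap shortens Δt whenever the fastest
  deterministic displacement would exceed `dx_max` = 10 nm (halving the
  cap to 5 nm changes the strongly driven estimates by < 5 %; 20 nm does
  not resolve them).
- **Collisions.** Continuous segment–circle detection against axon disks
  inflated by the particle radius (a uniform-grid disk index makes the
  candidate set O(1)), so fast particles cannot tunnel through thin
  gaps.  On contact the particle undergoes **diffuse scattering**: it is
  placed at the contact point and re-emitted in a cosine-weighted
  (Lambertian) direction about the outward normal — the standard meaning
  of diffuse scattering in particle tracing — with the remaining path
  length preserved.  Up to 8 reflections per step; if a concave corner
  still traps the segment, the step is rejected (particle stays put).
- **Boundaries.** Particles crossing the domain edge are removed and
  time-stamped; they no longer contribute forces or statistics.
- **Determinism.** One seeded RNG stream per run; identical
  (configuration, geometry, seed) reproduce bit-identical trajectories.
  Kernel seeds are mixed through a `SeedSequence` because the legacy
  MT19937 seeding produces visibly correlated streams for numerically
  related seeds.

## From trajectories to D

The ensemble MSD ⟨R²⟩(t) (displacements from each particle's release
point, averaged over particles still alive at t) shows three stages: a
release transient dominated by particle–particle interactions (I), a
statistically stable linear regime (II), and a depletion-driven noisy
tail as particles exit (III).  *D* is the stage-II slope:
D_x = slope(⟨R_x²⟩)/2 per axis, averaged over x and y (the cross-section
is statistically isotropic; the estimate is the perpendicular component
of the diffusivity tensor).  The fit keeps a free intercept — the
transient shifts the line but not its slope.

Stage II is found by a sliding-window rule: the longest window in which
(a) a linear fit reaches R² ≥ 0.995, (b) the slopes of the two window
halves agree with the full window within 10 %, and (c) the alive
fraction stays ≥ 0.8.  All thresholds live in the configuration.  For
strongly driven ensembles the expansion can decelerate continuously
(the Coulomb drive dilutes as the cloud spreads) and no slope-stable
window exists; the experiment layer then falls back to fitting from the
end of the release transient (first 15 % of the pre-depletion span) to
depletion onset, and flags the row (`status = "fallback-window"`).
Survivorship averaging (alive particles only) is unbiased when removal
is independent of displacement and is a known mild downward-bias source
near stage III; the fit window never extends there.

## Study conditions and problem sizes

The published release protocol is 900 particles from a central
0.2 × 0.2 µm square.  Two profiles bundle the run sizes: `paper`
(900 particles) and `desk` (200 particles, shorter horizons) for
interactive work and CI.  Quantities that depend on the *total* ensemble
charge — the headline *D* of 98 nm particles at −5 mV and the
Zp-amplification fold — are measured at the paper profile; threshold
*locations* (peak size, peak Zp) and uncharged coefficients are
insensitive to the ensemble size and are measured at desk scale with
≥ 3 replicate seeds.  The reproduction script
(`scripts/acceptance.py`) states the ensemble size it used for every
quantity in its output.

The free-solution validation rows run at the dilute-agarose viscosity
(6.9152×10⁻⁴ Pa·s — water at 310 K).  NP simulations in WM use the
measured interstitial-fluid viscosity (3.5×10⁻³ Pa·s), which lumps the
unmodelled microenvironment (ECM fibres, osmotic effects, local flows)
into a single viscous parameter.  The 2.0 nm WM validation row is the
exception: that tracer is a small hydrophilic CSF contrast agent whose
measured free-solution diffusivity (~3.8×10⁻¹⁰ m²/s at 37 °C)
corresponds to water viscosity, and only at water viscosity is the
published hindered value even reachable (the free-solution ceiling at IF
viscosity is 6.9×10⁻¹¹ m²/s, below the published 16.4×10⁻¹¹).  The row
therefore defaults to the aqueous viscosity; `run_table2(wm_mu=...)`
overrides it.

## What the synthetic fixtures do and do not show

`make_free_diffusion_record` draws ideal random walks with a known *D*
(no integrator involved) — it validates the estimator, not the physics.
`make_staged_msd_record` plants a ballistic transient, a clean diffusive
window and a depleting tail at known changepoints — it validates the
stage-II detector's window placement.  `make_toy_packing` exercises the
full constraint set on a 6 µm domain.  Passing these shows the analysis
chain is correct on data with known truth; it does not show that real
brain tissue behaves like the model (the geometry is an idealized
transverse section: no ECM obstacles, no longitudinal tortuosity, no
regional variability).

## Known limitations

- The 2-D cross-section measures only the perpendicular diffusivity;
  parallel transport (1.3–1.9× faster) is out of scope.
- The effective-to-real surface-charge correction for specific materials
  is not built in; with the identity mapping, charge grows as d_p²
  uncorrected, which likely overstates the drive of the largest
  particles at strongly negative ζ.
- The published decline of *D* for 98 nm particles beyond |ζ| = 30 mV is
  **not reproduced**: its published explanation is kinetic (faster
  particles waste more collisions), and an overdamped model has no
  kinetic energy to store — the pair drive (∝ q²) outgrows the membrane
  barrier (∝ q) monotonically.  The size threshold at 90 nm, which is
  steric/electrostatic rather than kinetic, *is* reproduced.
- Hydrodynamic inter-particle coupling, lubrication near walls, adhesion
  and endocytosis are not modelled.
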