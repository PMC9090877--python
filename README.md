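# ecsdiff

Brownian-dynamics tracing of charged nanoparticles in the extracellular
space of brain white matter.

Nanoparticle (NP) drugs and carriers must diffuse through the brain's
extracellular space (ECS) — the ~100 nm fluid channels between axons —
to reach their targets, and the two design knobs a formulator controls,
particle size and surface charge (characterized by the Zeta potential,
Zp), change the effective diffusion coefficient *D* by orders of
magnitude.  `ecsdiff` is a simulation framework for quantifying those
effects: it builds a stochastic two-dimensional cross-section of white
matter (WM) as a dense packing of circular axons, traces an ensemble of
NPs through the fluid between them under Brownian, drag, inter-particle
Coulomb and particle–membrane DLVO forces, and estimates *D* from the
linear (stage-II) regime of the ensemble mean-squared displacement
(MSD).  It is aimed at researchers in nanomedicine and brain drug
delivery who want to decouple size and charge effects that experiments
can only vary together.

## Model in brief

- **Geometry.**  Axons are non-overlapping disks in an 18 × 18 µm box:
  porosity 0.30, mean diameter 1 µm (truncated lognormal), hard minimum
  gap 0.1 µm.  Packing is RSA seeding + growth/relaxation + FIRE settling,
  audited exhaustively.
- **Charge.**  Gouy–Chapman: δ_eff = √(8cN_Aεk_BT)·sinh(eζ/2k_BT),
  q = δ_eff·πd_p² — so charge grows with the particle surface.
- **Dynamics.**  Overdamped: v = C_slip·F/(6πµr_p),
  Δr = vΔt + √(2D₀Δt)·Φ with D₀ = C_slip·k_BT/(6πµr_p) (Cunningham slip
  factor C_slip at K_n = 0.025).  F sums the unscreened pairwise Coulomb
  force at the medium's permittivity and the DLVO membrane force
  (screened double-layer repulsion + van der Waals attraction).
  Particles scatter diffusely (cosine law) off membranes and are removed
  at the domain boundary.
- **Estimation.**  D = slope(⟨R_x²⟩ vs t)/2 per axis over the detected
  stage-II window, x/y-averaged.

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

```python
from ecsdiff import generate_rve, porosity, audit_geometry
from ecsdiff.experiments import measure_D

geom = generate_rve(seed=42)
print(f"axons: {geom.n_disks}, porosity: {porosity(geom):.3f}, "
      f"mean diameter: {geom.achieved_mean_diameter():.3f} um, "
      f"audit: {audit_geometry(geom)[1]}")

neutral = measure_D(40.0, zeta_mV=0.0, medium="WM", seed=7, geometry_seed=42)
charged = measure_D(40.0, zeta_mV=-5.0, medium="WM", seed=7, geometry_seed=42)
print(f"D(40 nm,  0 mV) = {neutral['D']:.3g} m^2/s   ({neutral['status']})")
print(f"D(40 nm, -5 mV) = {charged['D']:.3g} m^2/s   ({charged['status']})")
print(f"fold increase   = {charged['D'] / neutral['D']:.0f}x")
```

prints

```
axons: 234, porosity: 0.300, mean diameter: 1.000 um, audit: ok
D(40 nm,  0 mV) = 1.76e-12 m^2/s   (ok)
D(40 nm, -5 mV) = 5.49e-10 m^2/s   (ok)
fold increase   = 313x
```

An uncharged 40 nm particle diffuses at ~1.8×10⁻¹² m²/s — the
Stokes–Einstein value at interstitial-fluid viscosity, reduced by the
tortuosity of the packed cross-section.  Charging the same particle to
just −5 mV switches transport to Coulomb-driven spreading and raises the
measured coefficient by two to three orders of magnitude at this
200-particle scale (over four orders at the full 900-particle release).
`status` reports how the stage-II window was found.

## Command line

```sh
ecsdiff generate-geometry --size 18 --porosity 0.3 --min-gap 0.1 \
        --mean-diameter 1.0 --seed 1 --out geom.json
ecsdiff simulate --config run.yaml --geometry geom.json --out traj.h5
ecsdiff analyze --traj traj.h5 --out report/
ecsdiff run-table2 --profile desk
ecsdiff run-sweep --sizes 20,40,60,80,90,98 --zetas -20 --out sweep/
```

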