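# flywind

A numerical wind tunnel for flapping-wing insect flight: an immersed-boundary
incompressible Navier–Stokes solver with prescribed fruit-fly wing kinematics,
aerodynamic force/power quantification, and convection-dominated odor
transport (Lagrangian tracers and antenna odor-mass-flux probes), plus
reproducible experiment drivers for a reduced-frequency sweep and a
trailing-edge wing-clip comparison.

## What's inside

| module | purpose |
|---|---|
| `flywind.geometry` | synthetic fly morphology: parametric wing planform (area 2.59 mm², span 2.87 mm), trailing-edge clipping (→ 2.09 mm², ≈20% removed), ellipsoid body, flat-plate wing meshes, 2-D sagittal sections |
| `flywind.kinematics` | Euler-angle flapping schedules (ϕ = ½Φcos 2πft, feathering plateaus ±α with sinusoidal reversal blending), rigid wing transforms, dimensionless groups (Re, k, Sc, Pe) |
| `flywind.grid` | nonuniform Cartesian grids: uniform refined box + geometrically stretched outer regions (ratio ≤ 1.2) |
| `flywind.solver` | fractional-step solver (AB2 convection, Crank–Nicolson diffusion, approximate projection with face fluxes) with ghost-cell immersed boundaries for moving rigid bodies; wind-tunnel or periodic boundaries; 2-D and 3-D |
| `flywind.forces` | surface traction integration, lift/thrust/power, coefficient definitions (C_L, C_T, C_F, C_PW) |
| `flywind.odor` | RK2 particle tracing with origin tags, odor-mass-flux probes (C′·ρ_odor·U* at 0.03R above landmarks, antenna triplet averaging), optional upwind scalar advection, capture statistics |
| `flywind.diagnostics` | Q-criterion, vorticity, patch/loop circulation (antenna vortex vs leading-edge vortex) |
| `flywind.experiments` | desk-scale 2-D sagittal analog, reduced-frequency sweep, wing-clip comparison, body-only baseline, coarse-3D anisotropy harness, hovering validation case, cluster-scale 3-D preset |
| `flywind.config` / `flywind.cli` | YAML run configuration (validated, unit-explicit, unknown keys rejected) and the `flywind` command |

Desk-scale runs use reduced grids and a 2-D analog; every result row carries a
`scale` tag (`desk`/`paper`). The full 3-D production configuration
(15R³ domain, Δ = 0.0125R, ~10⁷ grid points, eight cycles) is constructible via
`flywind.experiments.paper_scale_setup()` but is cluster-scale and the sweep
driver refuses to run it on a desk machine.

## CLI

```sh
flywind validate [config.yaml]      # schema check; empty config = nominal case
flywind fixtures --out fixtures     # STL/OBJ fly geometry, kinematics CSV, example config
flywind run --k 0.65 --cycles 4 --out runs/r1
flywind sweep --scale desk --out runs/sweep.csv
flywind clip-compare --k 0.65 --out runs/clip.csv
```

## Conventions

Nondimensionalization: lengths by wingspan R, velocities by the freestream
U∞, time by R/U∞; freestream along +x. In 2-D, vertical is +y; in 3-D the
sagittal plane is y = 0 and vertical is +z. Thrust is −F·x̂ (pushing the
flyer upstream). The feathering angle is measured from the stroke plane,
positive nose-up; the downstroke is the half-cycle with ϕ decreasing.
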