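# vescomp — mechanics of 2D crystals in fluid vesicle membranes

Giant unilamellar vesicles cooled through a lipid demixing transition grow a
single solid (crystalline) membrane domain inside the fluid bilayer.  The
shapes those crystals take — compact hexagons on small vesicles, many-petalled
flowers on large ones — are set by mechanics, not chemistry: the
near-inextensible solid expels Gaussian curvature (it stays developable),
forcing the fluid to carry all of the closed surface's topologically required
curvature, while thermal contraction and slow water permeation put large
vesicles under higher tension and inflation than small ones.

`vescomp` implements this composite fluid–solid vesicle model end to end:

- **Mesh geometry** (`vescomp.mesh`) — closed genus-0 triangulations with
  solid/fluid face labels; areas, enclosed volume, reduced volume
  v̄ = √(36π)V/A^(3/2), cotangent-Laplacian mean curvature, angle-deficit
  Gaussian curvature.
- **Shape synthesis** (`vescomp.flower`) — the 6-fold flower boundary
  r(θ) = r₀[1 + (a/2)cos6θ − (a/10)cos12θ] with petal ratio
  α = (5+2a)/(5−3a); vesicle meshes with a labelled solid patch and its
  planar rest state via equal-area projection; rigid-disk (effective core)
  variants.
- **Energies** (`vescomp.energy`) — Helfrich bending (B/2)∫(2H)², plate
  stretching Y/(2(1+ν))∫[Tr ε² + ν/(1−ν)(Tr ε)²] against the planar rest
  state, line energy σP, and the reduced elastic energy Ē = E/(8πB).
- **Minimizer** (`vescomp.minimize`) — L-BFGS relaxation of vertex positions
  at fixed phase areas and volume (quadratic penalties with stiffness
  continuation), exact gradients from a built-in reverse-mode autodiff of the
  discrete energies, Delaunay edge-flip mesh maintenance, rigid-core support.
- **Inflation analysis** (`vescomp.inflation`) — Ē(v̄) curves by warm-started
  continuation, tension τ = (12πB/A)v̄ ∂Ē/∂v̄, tension-free states v̄₀, the
  effective-core fit and closed-form maximal inflation v̄_max, relative
  inflation I, and the bending-vs-line-energy state map over (v̄, Rσ/B).
- **Tension dynamics** (`vescomp.thermal`) — steady-state tension
  τ_ss = (κρ/4𝒫)|dT/dt|R² from the thermal-contraction/permeation balance,
  the permeation law ∂V/∂t = −A(2τ/R)(𝒫/ρ), and a transient ODE with
  burst–reseal capping at the lysis tension.
- **I/O + CLI** (`vescomp.io`, `vescomp.cli`) — OFF/PLY with JSON sidecars
  (bit-exact round trips), VTK export of curvature fields, a manifest-writing
  pipeline; `vescomp build|minimize|sweep|coremodel|statemap|tension|pipeline`.

See `docs/methods.md` for the model, discretization and numerical choices.

## Worked example

```python
import numpy as np
from vescomp import (BuildSpec, MaterialParams, ThermalParams,
                     steady_state_tension, sweep_inflation,
                     zero_tension_volume, tension)

# steady-state tension of thermally contracting vesicles, 0.3 C/min cooling
for d_um in (10.0, 60.0):
    tau = steady_state_tension(ThermalParams(radius_um=d_um / 2))
    print(f"{d_um:.0f} um diameter: tau_ss = {tau:.3g} mN/m")

# energy-inflation curve of a phi = 0.14 flower crystal (alpha = 3)
curve = sweep_inflation(BuildSpec(alpha=3.0, phi=0.14, subdivisions=3, seed=1),
                        np.linspace(0.90, 0.995, 8))
print("vbar0 =", round(zero_tension_volume(curve), 3))
print("Ebar  =", np.round(curve.ebars, 3))
```

prints (a few minutes of minimization)

```
10 um diameter: tau_ss = 0.558 mN/m
60 um diameter: tau_ss = 20.1 mN/m
vbar0 = 0.986
Ebar  = [2.104 1.919 1.778 1.663 1.538 1.403 1.214 1.248]
```

The two tensions differ by exactly 36× (the R² scaling: large vesicles shed
water too slowly to relax contraction stress, which is why they stay inflated
and grow flowers).  The energy curve is non-monotonic in inflation: its
minimum v̄₀ ≈ 0.99 is the tension-free state, and the rise on either side is
what the membrane tension (slope) measures.  A compact disk (α = 1) has its
minimum lower, near v̄₀ ≈ 0.97, and a much higher energy near full inflation —
flowering pays line energy to relieve bending.

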