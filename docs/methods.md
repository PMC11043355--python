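# Methods

## The model

`vescomp` models a closed lipid vesicle whose membrane is a 2D fluid
containing a single solid (crystalline) domain of fixed area fraction φ.
The composite is treated as a purely elastic equilibrium problem at fixed
total area A, fixed phase areas, and fixed enclosed volume V:

- **Fluid phase** — Helfrich bending energy, E_fluid = (B/2) ∫ (2H)² dA,
  with bending modulus B.  The fluid shears freely, so it carries the
  vesicle's Gaussian curvature at no elastic cost.
- **Solid phase** — an elastic plate with the same bending term plus an
  isotropic in-plane stretching energy,
  E_stretch = Y/(2(1+ν)) ∫ dA [Tr ε² + ν/(1−ν)(Tr ε)²],
  with 2D Young's modulus Y, Poisson ratio ν, and strain ε measured against
  a *planar* rest configuration.  The modulus ratio defines the elastic
  thickness t = √(B/Y); at the default t/R = 8.3×10⁻⁵ the sheet is nearly
  inextensible, so in-plane elasticity acts as a developability constraint:
  the solid expels Gaussian curvature and bends only cylindrically/conically.
- **Line energy** — σP along the solid–fluid boundary of length P.  It
  enters only the morphology comparison (state map), not the shape
  relaxation at fixed domain shape, where it is constant.
- Gaussian-bending (saddle-splay) terms are omitted: with a developable
  solid and a continuous tangent at the phase boundary their integral over
  the closed surface is topologically fixed and shape independent.

The solid domain's planar outline is the 6-fold "flower"
r(θ) = r₀[1 + (a/2)cos 6θ − (a/10)cos 12θ], with petal-to-core ratio
α = r(0)/r(π/6) = (5+2a)/(5−3a); α = 1 is a disk, α ≳ 3.5 a serrated
flower.  Enclosed area is πr₀²(1 + a²/8 + a²/200) exactly, which fixes r₀
at given (a, φ).

About the printed arrangement of the two stretching invariants: the
transposed form (coefficients of Tr ε² and (Tr ε)² exchanged) is available
behind the `eq2_as_printed` toggle of `MaterialParams`.  At
t/R = 8.3×10⁻⁵ the strain energy is orders of magnitude below bending in
every relaxed state, so the arrangement has no measurable effect; the
default is the standard isotropic 2D form.

## Reduced units and key observables

Lengths are reduced by the equal-area-sphere radius (A = 4π, R = 1) and
energies by B.  In the near-inextensible (isometric) limit the elastic
energy depends only on the dimensionless state (v̄, φ, α, ν), not on
vesicle size; physical size re-enters only through the line term (∝ R) and
the tension scale (B/R²).

- Reduced volume v̄ = √(36π) V/A^{3/2} ∈ (0, 1]; 1 is the sphere.
- Reduced elastic energy Ē = (E_solid + E_fluid)/(8πB); 1 is a bare fluid
  sphere.
- Membrane tension τ = −(∂E/∂A)_V = (12πB/A) v̄ (∂Ē/∂v̄); the curve
  minimum v̄₀ is the tension-free state.  Physical conversion:
  τ_phys = τ̄ B/R² (with B = 25 k_BT this is ~10⁻⁶ mN/m per unit τ̄ at
  R = 10 μm).

## Discretization

The surface is a closed, oriented, genus-0 triangulation with per-face
phase labels.  Choices, all standard discrete differential geometry:

- Mean curvature: cotangent Laplace–Beltrami; for the *measured* per-vertex
  field, mixed Voronoi areas (Meyer's hybrid cells); for the *energy*,
  barycentric vertex areas — the energy must be smooth and cheaply
  differentiable, and both converge to (B/2)∫(2H)² under refinement
  (a unit icosphere at ~2.5k vertices evaluates to 8πB within 0.3%).
- Gaussian curvature: angle deficit over the vertex area.  The total
  deficit of any closed genus-0 triangulation is exactly 4π (a
  combinatorial identity — used as a self-check rather than a result).
- Stretching: constant-strain triangles.  Each solid face stores rest edge
  lengths from its planar layout; the Green–Lagrange strain comes from the
  pulled-back metric.  Strain-free ⇔ congruent to the rest triangle.
- Enclosed volume: signed tetrahedra (divergence theorem).

## Mesh synthesis

Vesicles are built from a subdivided icosahedron (default level 4, 2562
vertices; tests mostly use level 3, 642 vertices).  The flower is placed by
the inverse Lambert azimuthal equal-area projection about the +z pole:
faces whose projected centroids fall inside r(θ) are labelled solid, the
boundary loop is snapped to the *nearest point* of the curve (bounded
displacement — radial snapping folds triangles at petal notches),
redistributed uniformly by arclength, and the labelling is iterated on r₀
until the measured φ is within 0.5 %.  Equal-area projection makes the
patch area fraction equal the planar flower's by construction and minimizes
the built-in prestrain (the map is equal-area, not isometric, so a few
percent of projection strain remains for the relaxation to release).
Solid-interior vertices are smoothed in the rest plane, fluid vertices on
the sphere, and non-Delaunay edges are flipped (planar metric inside the
solid, embedded metric in the fluid); the final planar layout becomes the
rest state.  A seeded normal perturbation of amplitude 10⁻³ makes the
fold-pattern symmetry breaking explicit and reproducible.  Initial reduced
volumes below 1 are reached by an oblate z-scaling.

The rigid effective-core variant labels a polar cap of area fraction
Φ_core, flattens it onto the plane of its rim with its equal-area planar
coordinates (its rest layout), and flags it rigid.

## Constrained minimization

Vertex positions are relaxed with L-BFGS (scipy) on

E = E_bend + E_stretch + k·8πB·[(ΔA_solid/A_solid)² + (ΔA_fluid/A_fluid)² + (ΔV/V)²]

under a two-way continuation schedule: the penalty stiffness k rises
(2×10² → 2×10⁶) while the solid modulus ramps from ~10⁻⁷Y to Y, letting
the crystal first unbend and then flatten instead of fighting a stiff
landscape from the start.  Gradients are exact: the discrete energies are
expressed in a small reverse-mode automatic-differentiation layer
(`vescomp._adiff`, ~20 array operations with hand-written adjoints,
validated against finite differences).  Between stages, fluid-fluid edges
failing the Delaunay criterion are flipped when the minimum face angle
drops below 12° (the solid's topology, and hence its rest geometry, is
never touched); a stage that produces non-finite values or degenerate
faces is reverted.  Constraint residuals below 10⁻³ (relative) define
convergence; non-convergence is reported in the diagnostics, and raises
only on request.

Rigid cores are handled by holding the disk vertices fixed in their planar
layout — since the energy is invariant under rigid motions this costs no
generality and enforces planarity and in-plane rigidity exactly.

Solid area targets are taken from the *rest* geometry (the strain-free
area), not from the possibly squashed initial mesh: with a near-inextensible
solid, any mismatch between the two is unpayable strain.

## Inflation sweeps

Ē(v̄) is sampled over a grid (default 21 points on [0.86, 1.0]; analysis
runs here use 7–8 points on [0.88, 0.995] at 642 vertices — chosen as the
smallest meshes that resolve all four petal shapes with ≥ 8 boundary
vertices per petal) with warm-started continuation: the grid median is
minimized from scratch and *shake-annealed* (two seeded normal
perturbations of amplitude 5×10⁻³, keeping the lowest-energy relaxation)
to escape poor fold branches — fold patterns are degenerate and
seed-dependent, so energies, never patterns, are compared.  The remaining
points continue outward in both directions; an interior point landing
>15 % above both neighbours is re-relaxed from its better neighbour once.
For rigid cores the grid is truncated below the closed-form maximal
inflation.  v̄₀ comes from a parabola through the three samples around the
curve minimum; τ(v̄) differentiates a not-a-knot cubic spline of the
samples (exact on the parabolic neighbourhood of v̄₀).

## Effective core and state map

The effective-core reduction replaces the flower with the rigid disk whose
tension-free inflation matches: v̄₀(Φ_core) is monotone over the sampled
candidates, so the fit interpolates linearly; the RMS relative Ē mismatch
against the nearest sampled candidate over the common inflation window is
reported as a diagnostic.  The disk geometry caps inflation at the
bulb-on-disk shape: rim continuity plus the area split give
cos ψ = (1−3Φ)/(1−Φ) for the cap opening angle, hence a closed-form
v̄_max(Φ) with v̄_max → 1 as Φ → 0 (cross-checked against a brute-force
scan over cap angles to 10⁻⁶).  Relative inflation is
I = (v̄−v̄₀)/(v̄_max−v̄₀).

The state map minimizes 8πB Ē(v̄; α) + σ P(α) R over candidate α at each
(v̄, Rσ/B) grid point, with P(α) the planar flower perimeter at the
prescribed solid area (quadrature of the boundary arclength) — the
mesh-measured perimeter differs only by discretization noise.  Ties break
to the smallest α.  The physical right axis uses B = 25 k_BT and
B/σ = 25 nm.  Note one direction of this energy balance: because the
elastic part is size independent and the line part grows ∝ R, at *fixed*
inflation a larger vesicle favours the compact shape; the observed
larger-vesicle → flower correlation arises because larger vesicles sustain
higher inflation (next section), which moves them across the nearly
vertical compact/flowered boundary.

## Thermal-contraction tension dynamics

Cooling contracts the membrane area (κ = (1/A)(∂A/∂T)_τ = 0.005 °C⁻¹)
faster than the enclosed water; tension builds and drives efflux,
∂V/∂t = −A(2τ/R)(𝒫/ρ), with permeability 𝒫 = 2.8×10⁻¹⁶ s μm⁻¹ and water
density ρ = 1000 kg m⁻³ (ρ enters linearly and is exposed in the
parameters).  At constant cooling the rates balance at
τ_ss = (κρ/4𝒫)|dT/dt|R².  **R is the vesicle radius**; quoted vesicle
sizes are diameters, and the R² scaling makes the convention worth a
factor of 4.

The transient extension closes the balance with τ = K_A(A−A_rel)/A_rel on
a quasi-spherical vesicle, A_rel shrinking at rate κ|dT/dt|A_rel.  K_A (an
apparent area-stretch modulus, default 240 mN/m) sets only the approach
time: the steady state reduces exactly to τ_ss for any K_A, which the
tests verify over three decades.  An optional burst–reseal event vents
enclosed volume when τ reaches the lysis threshold (default 8.5 mN/m,
middle of the 7–10 mN/m band) and reseals at 90 % of it.

## What the synthetic generator does and does not emulate

The generator produces the *model system*: one 6-fold crystal per vesicle,
φ = 0.14, ν = 0.4, t/R = 8.3×10⁻⁵, prescribed α.  It does not emulate
crystal growth kinetics, anisotropic (Wulff) line energy, n-fold variation,
thermal undulations, multi-domain nucleation, or imaging noise — so
passing tests show the mechanics of the idealized composite, not fidelity
to raw micrographs.

## Numerical caveats and limitations

- Fold-pattern degeneracy makes relaxed energies weakly path- and
  seed-dependent (~1 % after annealing at 642 vertices); all comparisons
  are made on energies at matched conditions.
- The penalty formulation leaves ≤10⁻³ relative constraint slack; tension
  is extracted thermodynamically from Ē(v̄), never from penalty forces.
- At inflations approaching a shape's geometric maximum the minimizer may
  fail to meet constraints; such points truncate the sweep and are flagged.
- Coarse meshes under-resolve the fluid's curvature ridge at the solid rim,
  so Ē is resolution dependent at the few-percent level (tested: ≤2 %
  between 642 and 2562 vertices for the reference disk case).  Strongly
  serrated flowers (α ≈ 4) are the worst case: at 642 vertices their petal
  necks span only one or two elements, which over-stiffens the developable
  folding, leaves residual Gaussian curvature at the petal tips, and raises
  the whole Ē(v̄) curve by several tenths relative to the α ≤ 3 trend; the
  finer meshes that would cure this do not relax to comparable depth within
  practical schedules, so α = 4 results at this resolution should be read
  as upper bounds.
- Rigid-disk (effective-core) energies are extremely flat within ~0.01 of
  their maximal inflation at this resolution (the continuum divergence of
  rim curvature is cut off by the discrete kink), so the core model's
  tension-free inflation is determined only to about ±0.005.
- The transient tension closure (K_A relation) is this package's
  construction for connecting the steady-state balance to cooling
  histories; only its steady state is constrained by the balance law.
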