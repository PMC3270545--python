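# Methods

`wlsfem` solves the incompressible Navier–Stokes equations as a weighted
least-squares minimization, assimilating planar PIV velocity data weakly, on
domains that move with prescribed boundary motion.  This note records the
model, the numerical choices, what the synthetic data emulates, and the known
limitations.

## Governing equations and first-order reformulation

The flow is dimensionless, Newtonian and incompressible, in the scaling that
puts the Reynolds number on both the inertial and viscous terms:

    Re (∂v/∂t + v·∇v) = −∇p + (1/Re) ∇²v,      ∇·v = 0.

Two auxiliary unknowns turn this into a first-order system: the vorticity with
the sign convention ω = −∇×v, and the total-pressure gradient
r = ∇p + (Re/2)∇|v|² = ∇(p + (Re/2)|v|²).  The solved system is

    ∇×v + ω = 0
    ∇·v = 0
    (1/Re) ∇×ω − r − Re (v_c×ω + ∂v/∂t) = 0
    ∇·ω = 0                                    (3D only)
    ∇×r = 0
    (1/Re²) [ ∇·r − Re|ω|² − Re² v·r − Re³ v·∂v/∂t ] = 0

where v_c = v − v_mesh is the convective velocity with the mesh velocity
subtracted (the ALE correction on moving domains).  The last line — the
"pressure-link" closure — is the divergence of the momentum equation, derived
using ∇·(v×ω) = ω·(∇×v) − v·(∇×ω) and the momentum equation itself; the
1/Re² prefactor is a least-squares row weighting that keeps the row
commensurate with the momentum row at Re ~ 10³ (it does not change the
equation's zero set).  A `pressure_link` switch selects this consistent form
(default), a historical variant with Re instead of Re² on the v·r term
(`"verbatim"` — it is *not* satisfied by exact solutions unless v·r = 0 or
Re = 1, as a unit test demonstrates on plane channel flow), or `"off"`.

Pressure is not an unknown.  When requested, the total pressure is recovered
post hoc by a least-squares potential reconstruction (min ‖∇φ − r‖², one node
anchored) and p = φ − (Re/2)|v|²; this is post-processing, outside the
functional.

### 2D specialization

ω is scalar; ∇×v is the scalar curl ∂x v₂ − ∂y v₁; ∇×ω is the rotated
gradient (∂ω/∂y, −∂ω/∂x); v×ω means ω(v₂, −v₁); the ∇·ω equation and the
normal-vorticity boundary term are dropped (scalar ω has no divergence or
normal trace).

## The least-squares functional

    G(v, ω, r) = Σ ‖interior residuals‖²₀,Ω
               + (w_Γ/h) ‖v − g₁‖²₀,Γ  +  (w/h) ‖ω·n − g₂‖²₀,Γ
               + (w_PIV/h) ‖v − g_PIV‖²₀,Γ_PIV

The w/h-weighted boundary L² norm approximates the H^{1/2} trace norm while
de-emphasizing oscillatory (noisy) components; h is the **local** facet
diameter (length in 2D, √area in 3D), so nonuniform meshes weight
consistently.  For the PIV plane, h is the size of the mesh element containing
each plane quadrature point.  Weights follow the accuracy rule w ≈ 1/σ², with
optional normalization so the most accurate stream has weight 1.

The PIV misfit uses only the components the instrument measures: the two
in-plane components in 3D (mode `tangential`, default), or all stored
components for synthetic 3-component data.  Plane quadrature uses the data's
sample points with trapezoidal area weights; masked-out vectors contribute
nothing; sample points outside the mesh (a scan sector larger than the
chamber) are skipped.  In time, data is taken from the matching frame when one
exists, else interpolated linearly (configurable: `nearest`/`linear`/`none`).

An advisory utility flags vectors deviating more than k·σ (default k = 5) from
a 3×3 local median; nothing is filtered automatically — the validity mask is
under the caller's control.

## Discretization and solver

All unknowns share one tensor-product quadratic Lagrange basis (9-node
quadrilaterals, 27-node hexahedra) on an isoparametric geometric map; no
inf-sup condition constrains the pairing.  Quadrature is 3-point Gauss per
direction (exact for the degree-4 products of quadratic bases on affine
elements) and 4-point on the curved half-ellipsoid elements.

Time stepping is backward Euler: ∂v/∂t ≈ (v − v_prev)/dt inside the momentum
(and closure) residual, with nodal values following the moving mesh and the
mesh velocity subtracted from the convective term.

Each Gauss–Newton step linearizes the residuals about the current iterate
(classic Gauss–Newton: full first-order Jacobian, second-order terms dropped)
and solves the SPD normal equations A = JᵀWJ.  A halving line search (max 5)
guards against overshoot; convergence is declared at relative functional
change < 1e-8 (configurable) within 25 iterations, and a nonconverged step
returns the best iterate flagged.

The normal equations are solved by preconditioned conjugate gradients after a
symmetric diagonal (Jacobi) scaling that equilibrates the squared residual
rows — essential because the momentum row carries factors up to Re/dt, so the
raw normal matrix has condition numbers beyond 1e13 at Re = 10³.  The default
preconditioner is a strong incomplete LU factorization (SuperLU ILUTP,
drop 1e-12); on failure a near-complete factorization is retried.  Negative
curvature raises a distinct error (the SPD contract is falsified), near-zero
curvature reports a nullspace.  Assembly order is fixed by element index, so
repeated runs are bit-stable on one platform.

Gauss–Newton convergence caveat: on *steady* problems with large optimal
residual (coarse meshes at Re ≳ 100) Gauss–Newton converges only linearly and
the line search can stall near α ~ 1/32; the implicit time-stepping path, which
both scenarios use, regularizes each step and converges in a handful of
iterations.  The iteration-envelope test therefore pins the transient cavity
fixture.

## Moving domain: pseudosolid mapping

The deforming mesh is a fictitious compressible elastic solid,
λ∇(∇·u) + ∇²u = 0 (λ = 1 by default), rewritten first-order with U = ∇u:
U − ∇u = 0, λ∇(tr U) + ∇·U = 0, ∇×U = 0 (row-wise), minimized together with
(1/h)‖u − g_u‖²_Γ.  This is linear least squares: one normal-equation solve
per step.  Affine boundary data is reproduced exactly (the functional minimum
is zero), which the tests pin.

Each step solves on the **rest** mesh with cumulative boundary displacement
(total Lagrangian) — incremental solves would accumulate distortion.  Mesh
velocity is the backward difference of node positions, matching the flow
discretization.  Any nonpositive element Jacobian after motion is a hard
failure naming the worst element.

The printed source for the first-order elasticity system is typographically
garbled in its second line; the three-equation system above is the one
recoverable from the elasticity functional, and a possible boundary trace
condition involving n was unrecoverable and is omitted.

The flap is a zero-thickness interior surface: the box mesh is built
conforming to the rest flap, flap nodes strictly between the wall root and the
tip are duplicated on the two sides, and both sides carry the no-slip velocity
(the flap's displacement rate).  After each elasticity solve the duplicate
pairs' displacements are averaged so the deformed mesh stays watertight (the
least-squares solve makes them equal only to solver tolerance).

## Geometry

Boxes are structured quad/hex meshes.  The half-ellipsoid ventricle maps a
structured box through a smooth cube-to-ball volumetric map and scales by the
semi-axes: all-hex topology, positive Jacobians, no degenerate apex (this
apex treatment is this package's choice; the topology near the apex is not
prescribed by the source experiments).  The flat base carries disjoint
`inlet`/`outlet` sub-patches selected by configurable disks in base-plane
coordinates; `base` and `wall` partition the boundary.

Ventricular wall motion uses the family
X = (x(1+γz/c), y(1+γz/c), z(1+βγz/c)) (β = 0.5), which fixes every
base-plane point exactly and contracts the wall radially with depth; the
amplitude γ(t) is root-found against the closed-form deformed cavity volume so
that the volume tracks V_ED(1 − EF·phase(t)) — at end systole the change
equals the ejection fraction times end-diastolic volume.  Diastole is run in
reverse (filling from the end-systolic shape back to rest).

## Scenarios and desk scale

Both drivers run the full pipeline per step: pseudosolid solve → mesh update
and mesh velocity → implicit flow step with boundary and PIV terms →
diagnostics (CSV, optional legacy-VTK time series with quadratic cells
subdivided into linear sub-cells).

**Flap**: square section (side 7.0 jet diameters — a 15.4 cm tank scaled by
the 2.2 cm jet) of the tank, run 2D on the PIV plane itself at desk scale
(recorded in output metadata); Re = 1000, dt = 0.02 (20 ms at a 1 s convective
scale); paraboloid inlet jet on for 0.2 s; natural outflow on the right face;
no-slip elsewhere; flap deflection follows a 5th-order-polynomial-in-height
table, here a synthetic bow that tracks the jet and relaxes.  The
total-velocity diagnostic sums |v| over the mesh nodes on the PIV line.

**Left ventricle**: half-ellipsoid (a = b = 1, c = 1.5), Re = 1000,
dt = 0.05 (50 ms), six filling steps, ejection fraction 0.5, coarse 3D
resolution (~2.2k unknowns); wall no-slip at the wall-motion rate, fixed base,
natural outlet; the inlet speed is read from the PIV data near the base and
imposed as a paraboloid plug along a configurable direction.  The vortex
diagnostic is the peak in-plane curl of the in-plane velocity on the PIV
plane, sampled on a fixed grid.

## Synthetic PIV: what it emulates, and does not

The generator projects a velocity field onto a plane's measured components on
a rectangular grid at a frame rate (default 60 Hz), then adds Gaussian noise
σ, random dropout, and direction-randomized gross outliers (spurious
cross-correlation peaks).  Identical seeds give identical datasets; datasets
round-trip bit-stably through a long-format CSV with the plane frame in the
header.

The scenario fixtures are built for a model-data *mismatch*, mirroring what
real assimilation is for:

- **Flap**: the dataset is a data-free (w_PIV = 0) solver run sampled on the
  PIV line, amplified by 1.15, plus noise with σ = 10 % of the peak speed —
  data carrying energy the bare model underestimates.
- **Ventricle**: the dataset is a data-free run sampled on the long-axis
  plane *plus* an embedded Gaussian vortex that grows through diastole
  (strength 2.5, core radius 0.4a) and noise at σ = 2 % of peak — a valve-wake
  feature the bare model cannot produce.  A dynamically consistent background
  is essential: pure-vortex data conflicts with the momentum residual almost
  everywhere and is suppressed rather than assimilated.

What passing these fixtures shows: the weighted plane term moves the solution
toward the data by the expected amount, monotonically in w_PIV, with the
1/σ² calibration beating over-trusting weights, and data influence decaying
away from the plane.  What it does not show: performance on real echo PIV
(ultrasound artifacts, correlated noise, out-of-plane motion, wall-tracking
error), behavior at clinical mesh resolutions, or regimes where the flow is
turbulent.  At the coarse desk-scale resolution the interior residual terms at
Re = 10³ are stiff, so only a small fraction (~1 %) of a dynamically
inconsistent data feature transfers into the solution; the effect direction is
robust but its magnitude is resolution-limited.

## Verification

The manufactured study solves one implicit step of the 2D decaying Taylor
vortex (amplitude e^{−2k²t/Re²} in this scaling) with exact boundary data and
a manufactured previous state v(t₁) − dt·∂v/∂t(t₁), so the backward difference
is exact and spatial error is isolated.  Its default Re = 2 sits in the
well-resolved regime where the quadratic basis's optimal L² rate (~3) is
visible on affordable meshes; at Re = 10 the measured L² orders straddle 2.0
(2.15/1.71/2.03 over n = 4…32) because the functional norm only controls
H¹-type error.  The study reports per-pair orders and a least-squares fit.

Default problem sizes throughout (meshes of 4–16 elements per side in 2D, a
3-per-side half-ellipsoid in 3D, 6–8 time steps) are chosen so the full
verification and scenario pipeline runs on a laptop-class single core in
minutes.

## Known limitations

- Serial only; no distributed assembly or solve.
- Quadrilateral/hexahedral elements only; no tetrahedra, no CAD import.
- Weak boundary enforcement means boundary data is matched to O(√(G·h/w)),
  not exactly; strong imposition is deliberately absent.
- The Gauss–Newton path is not globalized beyond the halving line search;
  steady high-Re problems should be reached by time stepping.
- One-way coupling only: the flap and ventricle wall motions are prescribed,
  not computed from fluid load (no fluid–structure interaction, no valve
  model).
- The ventricle inlet projection (data speed → paraboloid plug) is a modeling
  choice; the inlet/outlet patch geometry is configurable because no standard
  exists.
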