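# Methods

`aortaflow` simulates pulsatile blood flow and blood residence time in
idealized aortic-root geometries to compare three surgical states under
identical boundary conditions: a baseline surgical valve replacement (SAVR),
an annular-enlargement root carrying a larger valve (Y-AAE), and a
transcatheter valve deployed inside the surgical valve (TAVR-in-SAVR,
"valve-in-valve").  This note records the model, its assumptions, the
numerical choices, and what the synthetic geometry does and does not
represent.

Everything is in the mm–g–s unit system, in which pressure lands natively in
Pa (1 Pa = 1 g/(mm·s²)) and the Windkessel resistance/compliance carry their
literature units (Pa·s/mm³, mm³/Pa) without conversion factors.

## Flow model

Blood is an incompressible Newtonian fluid (density ρ = 1.026 g/ml =
1.026·10⁻³ g/mm³, dynamic viscosity μ = 4·10⁻³ Pa·s) in a rigid lumen with
no-slip walls:

    ρ ∂v/∂t + ρ (v·∇)v − ∇·σ = 0,    ∇·v = 0,
    σ = μ (∇v + ∇vᵀ) − p I.

The Cauchy stress uses the standard incompressible sign convention (−pI).
Boundary conditions over each cardiac cycle (heart rate 70 bpm, stroke
volume 73.5 ml):

* **Systole** (valve open, default systolic fraction 0.35): a prescribed
  volumetric flux at the inflow (LVOT) plane, by default a half-sine pulse
  whose integral equals the stroke volume to round-off (the discrete plug
  profile is rescaled so the *facet-quadrature* flux matches the prescribed
  value exactly).  A trapezoidal pulse is available.
* **Diastole** (valve closed): a prescribed left-ventricular filling
  pressure at the inflow plane (linear ramp 8 → 12 mmHg by default; the
  magnitudes are modeling choices, not literature values).
* **Outflow**: traction −P n with P from a two-element Windkessel,
  C dP/dt = Q − P/R, with R = 0.121 Pa·s/mm³ and C = 9.37 mm³/Pa.  The ODE
  is advanced with the exact exponential propagator (unconditionally stable,
  exact for flux held constant over a step, second order with mid-step flux
  sampling) and is updated inside the nonlinear loop from the current
  iterate's outlet flux — an implicit coupling, sub-iterated to a relative
  pressure tolerance of 10⁻⁶.  The initial pressure is the steady value
  R × (mean cardiac output), which removes most of the start-up transient.
* **Coronary ostia**: a prescribed outflow of 4% of mean cardiac output,
  drawn during diastole only and split equally between the two ostia (the
  magnitude is a modeling choice; only the existence of a prescribed
  coronary flux is part of the modeled physiology).
* **Backflow stabilization**: Neumann boundaries carry the standard
  penalty −(ρ/2)(v·n)₋ v·w, which prevents divergence during the
  deceleration-phase flow reversal at the outlet.

### Orifice-plane valve

The valve is an orifice plane at the annulus that opens and closes
instantaneously at the systole boundaries (no leaflet kinematics).  The
geometric orifice area (GOA) is a disc whose diameter is the implanted
valve's internal diameter minus 6.0 mm.

A plane of pinned P1 velocity nodes cannot seal a stabilized equal-order
discretization: the PSPG term couples the pressure across the plane and
pumps mass through it like a porous layer (we measured a spurious ~5000
mm²/s diastolic leak in 2-D under the ~9 kPa transvalvular jump).  The mesh
is therefore **cracked** along the valve plane: the plane's nodes are
duplicated, cells above the plane reference the twin copies, and

* **closed**: both copies are pinned to zero velocity; no element spans the
  plane, the two chambers decouple exactly and the pressure jump is
  representable (the inlet-side flux vanishes to round-off);
* **open**: twin degrees of freedom (velocity and pressure) are tied by
  equality constraints, restoring a continuous field.

A consequence is that the valve-plane facets appear as *paired boundary*
facets of the cracked cell complex (both copies tagged VALVE_ORIFICE /
VALVE_ANNULUS); the watertightness check applies to the complex away from
the crack.

### Discretization and solver

Equal-order P1–P1 elements on triangles (planar 2-D mode) or tetrahedra
(revolved 3-D mode) with residual-based SUPG/PSPG stabilization and a
grad-div term, τ = [(2/Δt)² + (2‖a‖/h)² + (12ν/h²)²]^(−1/2) with the
element scale h = (d!·V)^(1/d), grad-div viscosity ρ‖a‖h/2·min(Re_h/3, 1).
Time stepping is backward Euler with Picard linearization of advection
(relative velocity-increment tolerance 10⁻³, at most 10 iterations; a step
fails only on divergence, with the increment history attached).  Each linear
system is solved with a sparse direct factorization, so runs are
deterministic on a platform.

Because inlet and coronary Dirichlet data are rescaled to match their target
fluxes in facet quadrature, and the PSPG terms vanish for the constant test
function, the global discrete mass balance ∮ v·n = 0 holds to round-off:
the per-cycle imbalance ∫(Q_in − Q_out − Q_cor)dt is ~10⁻¹² % of the stroke
volume in practice (the 1% acceptance bound is loose).

Cycle convergence uses a 5% criterion: a run is converged when the
final two cycles' peak velocity and mean TPG agree within 5%.  Three cycles
suffice on the idealized root (observed deltas ≲ 0.1%).

### 2-D planar mode

The `ci` fidelity profile solves a planar (unit-thickness) analogue whose
half-width follows the lumen radius profile.  Volumetric fluxes are scaled
by the width/area ratio of the annulus disc, 4/(π·d_ann), which preserves
mean velocities; the Windkessel is driven by the volumetric flux
reconstructed with the *same* reference diameter, so R and C produce
physiological pressures (≈ 60–115 mmHg over the cycle).  The annulus disc is
the single reference for both conversions; using per-boundary diameters
would make the Windkessel see a flux inflated by d_outlet/d_annulus.

## Residence time

The residence-time field φ obeys ∂φ/∂t + v·∇φ − ∇·(D∇φ) = 1 with φ = 0 on
the inflow and outflow planes, zero diffusive flux elsewhere (coronary
ostia included, configurable), and D = 0 by default.  The advective field
replays the stored final flow cycle periodically (linear interpolation in
time; the run aborts if the stored record's first/last snapshots disagree
by more than 25% in relative L2, since a non-periodic record invalidates
the replay).  The default residence-time step is 4× the flow step; each
phase's system matrix repeats every cycle and is factorized once.  The run
lasts 14 cycles and reports per-cycle volume-weighted mean φ; it is flagged
converged when the cycle-to-cycle change drops below 5%.  The relative
residence time is φ/T with T the total replayed time: 1 marks blood that
never left, 0 near-instant washout.

**Stabilization.**  For pure advection the consistent SUPG scheme is sharp
but not monotone: at the fresh-blood front entering the recirculating
sinuses we observed crosswind oscillations reaching 30× the admissible
bound, growing over the 14-cycle run.  The default scheme is therefore the
monotone low-order one: Galerkin advection plus edge-based artificial
diffusion d_ij = max(0, k_ij, k_ji) lumped onto the diagonal, with a lumped
mass matrix.  This guarantees the discrete maximum principle — φ stays in
[0, t] and the relative field in [0, 1] without clipping — at the price of
first-order smearing of fronts.  With v = 0 the formulation grows φ by
exactly Δt per step, and on the union-jack 2-D grids it reproduces the
plug-flow solution φ = x/U to machine precision.  SUPG remains available
(`RTConfig(stabilization="supg")`) for smooth-field accuracy studies;
under/overshoots are then clipped at output with the clipped fraction
reported.

On the cracked valve plane the twin nodes are always merged for the scalar,
so residence time advects through an open valve; during diastole the stored
velocity is zero across the sealed plane and no special casing is needed.

## Synthetic geometry

Patient CT anatomies are replaced by a parametric body of revolution: LVOT
tube (annulus diameter 23 mm native), sinus bulge (maximal radius 16.5 mm,
height 22 mm — the three sinuses collapsed to one axisymmetric bulge),
sinotubular junction (27 mm), and ascending aorta (30 mm diameter, long
enough that the pressure-measurement plane 30 mm downstream of the valve
always exists).  Two circular coronary ostia (3 mm) sit on the sinus wall.
Annular enlargement scales the annulus and sinus radii by the implanted/
native valve-diameter ratio (29/23 by default), leaving the junction and
aorta unchanged.  Sinus dimensions and ostia placement are modeling
choices; the native/implanted valve sizes (23 mm and 29 mm) are typical
clinical medians for enlargement candidates.

The TAVR insert is a funnel sealed against the LVOT wall 4 mm below the
surgical valve plane, converging to a throat whose area is 80% of the
surgical orifice (valve-in-valve deployments typically cut the orifice
area by roughly a fifth, hence the 20% default).  The skirt is 13 mm tall — the sealing-skirt height of the
self-expanding device family modeled here — which places the funnel
top inside the sinus and forms the neo-sinus pocket between funnel and
sinus wall.  The skirt volume between funnel and LVOT wall below the
surgical ring is excluded from the fluid domain (hardware volume), so the
insert strictly reduces lumen volume.

Meshes are mapped structured grids (alternating-diagonal triangles in 2-D;
Kuhn-split tetrahedra of the revolved grid in 3-D, which is the consistent
face-matching split), so the valve plane, orifice rim, funnel wall and the
30 mm measurement plane fall exactly on mesh layers and node columns.  The
generator is deterministic; the seed is provenance metadata only.
Boundary-layer meshing is not attempted (isotropic elements near walls).

### What the synthetic data do and do not show

The generator preserves the features the metrics depend on — orifice size,
sinus pockets, measurement planes, coronary withdrawal — so orifice-driven
quantities transfer well: enlargement lowers peak velocity by ~38% and mean
TPG by ~47% in 2-D CI runs (patient-specific CT anatomies show the same
directions, with even larger TPG contrasts), and the insert raises both.  The residence-time *pattern* also
transfers: the insert drives the neo-sinus and sinus relative RT up
(regional sinus mean ≈ +19%, maximum relative RT reaching 1.0).  However
the large *global* mean-RT increase seen in patient-specific
valve-in-valve simulations is not
robust in the planar idealization: a 2-D jet fills the width ratio rather
than the (smaller) area ratio of the lumen, sinus shielding is therefore
weak, and the long ascending aorta dominates the volume average — across
mesh resolutions the global mean-RT change sits within ±3%.  Passing tests
on the synthetic root demonstrate correct mechanics and the expected
directional physics where the idealization supports them, not
patient-specific magnitudes, which are out of scope.

A further idealization artifact worth knowing: the wedge of fluid between
the permanently blocked annulus ring and the lateral wall is sealed in
every scenario, so a handful of corner nodes legitimately accumulate
relative RT → 1 even pre-TAVR; clinical pre-TAVR maxima are lower.

## Fidelity profiles and problem sizes

* `ci` — planar 2-D, 1.6 mm edges, Δt = 2 ms, 3 flow cycles, 14 RT cycles
  (~1 700 nodes; a scenario runs in ~1–3 minutes on one core).  All
  regression and acceptance runs use this profile.
* `desk` — revolved 3-D at 2.5 mm edges, Δt = 2 ms.
* `paper` — revolved 3-D at 1.0 mm edges, Δt = 0.8 ms: publication-grade
  resolution, provided for completeness; such runs are HPC-scale.

Verification fixtures run at their own sizes: the Poiseuille pipe (radius
2 mm, length 20 mm, 500 mm³/s) at 1.6/0.8/0.4 mm edges shows the pressure
drop converging to the Hagen–Poiseuille value (15% → 3% → 0.6% error), and
the plane-Poiseuille start-up channel reaches 1.5× mean velocity at the
centreline within 5%.

## Numerical edge cases and conventions

* Valve schedule half-open interval [t_open, t_close): exactly at closure
  the inlet condition is the diastolic pressure.
* Forward-flow window for the mean TPG = valve-open steps; the TPG is the
  positive part of (inlet plane − 30 mm plane) area-averaged pressures, so
  it is invariant to a constant pressure offset.
* Peak velocity is taken over the lumen between the valve plane and the
  30 mm plane (the jet region an echo probe interrogates), over the final
  cycle.
* rt statistics: cell value = nodal average; mean is cell-volume weighted;
  the >0.2 volume fraction counts whole cells.
* Degenerate inputs (non-positive dimensions, orifice wider than the
  annulus, too-coarse edge length, systolic fraction outside (0.2, 0.5))
  raise parameter errors before any compute.

## Known limitations

Rigid walls and an instantaneous orifice-plane valve (deliberate
best-case simplifications for controlled comparisons); a single axisymmetric sinus bulge instead of three
lobes; no boundary-layer resolution at desk scale; first-order monotone
transport for residence time (stasis is if anything underestimated);
2-D planar default for routine runs, with the global mean-RT comparison
across scenarios at the edge of its resolution as described above.
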