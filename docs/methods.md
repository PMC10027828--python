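# Methods

## Scope and model

`aneuflow` simulates pulsatile blood flow in an idealized two-dimensional
side-wall saccular aneurysm on a straight parent vessel, with the option of
filling the sac with a porous medium that represents an endovascular coil
pack.  The governing equations are the unsteady incompressible
Navier–Stokes equations with a shear-thinning Casson viscosity and, inside
the coiled sac, a Darcy momentum sink:

    rho (du/dt + u·∇u) = -∇p + ∇·(mu(γ̇) ∇u) - (mu/k) χ_sac u + f
    ∇·u = 0

Flow is laminar and the walls are rigid; there is no fluid–structure
interaction and no thrombosis model.

**The 2D idealization is deliberate.**  Patient-specific aneurysm
hemodynamics is three-dimensional; every physical ingredient here
(rheology, porous sink, wall-index definitions, the solver itself) is
dimension-agnostic, and the planar case keeps the full pipeline — meshing,
three-cycle transients, parameter sweeps — runnable in CPU-minutes on a
desktop.  Absolute pressures, WSS magnitudes and OSI values of a real 3D
aneurysm are therefore *not* reproduction targets; qualitative trends
(effect of hematocrit and of coiling porosity) and all structural and
analytic-oracle properties are.

## Synthetic geometry

The domain is a channel of height `vessel_diameter` (default 3 mm, a
middle-cerebral-artery scale) and length 16 mm, carrying on its upper wall
a circular dome of diameter 5 mm attached through a neck of width 2.5 mm.
The dome circle is placed so that its chord on the wall line is exactly the
neck; everything above the wall line and inside the circle is the sac
region, and the arc above the wall is the sac wall.  Boundary tags:
`INLET`, `OUTLET`, `WALL_VESSEL`, `WALL_SAC`; cell regions `LUMEN`, `SAC`.

Meshing samples the boundary curves at `mesh_size` (graded ~3x finer
toward the reentrant neck corners), extrudes geometrically graded
boundary-layer point rows from both walls (default 3 rows, growth 1.3,
total thickness 0.6·`mesh_size`), fills the interior with a hex-packed
cloud, triangulates with Delaunay and trims triangles whose centroid falls
outside the domain.  Because an unconstrained Delaunay can route thin
triangles across the wall line at the reentrant corners, a repair pass
re-admits trimmed triangles adjacent to any boundary edge that does not
lie on a geometric curve (capped to the corner neighborhood); the
resulting corner rounding is below the local element size.  The mesh is
validated structurally (positive orientation, boundary partition by tags,
single connected sac adjacent to the sac wall) and the sac area converges
to the analytic circular-segment area within 1% for mesh sizes ≤ 0.2 mm.

## Inflow waveform

The inlet speed is `v(t) = m + a1 cos(ω(t−tp)) + a2 cos(2ω(t−tp))` with
`a2/a1 = 0.2`, so both harmonics peak together at peak systole
`tp = 0.3 T` and the waveform is strictly positive for the default mean
0.25 m/s and peak 0.5 m/s.  With the default period `T = 0.8 s` (a
sub-second resting cardiac cycle; configurable) peak systole falls at
t = 0.24 s and the early-diastole reporting phase at t = 0.54 s.  The
spatial inlet profile is parabolic (fully developed) scaled by `v(t)`;
`uniform` and `traction-free` inlets exist for verification runs.  A
`steady` profile (constant `m`) provides the control experiment in which
OSI must vanish.

## Rheology

Casson apparent viscosity `mu(γ̇) = (sqrt(τ_y/γ̇) + sqrt(μ∞))²`,
regularized with a shear-rate floor `γ̇_min = 1e-3 s⁻¹` (a viscosity
ceiling; simpler and monotone compared with a Papanastasiou exponential,
and adequate because stagnant-zone WSS is near zero anyway).  Hematocrit
dependence, used by the sweep driver:

    τ_y(H)  = 0.1 (0.625 H)³  Pa          (Merrill-type yield stress)
    μ∞(H)   = η_p (1−H)^−2.5  Pa·s        (Einstein-type suspension law)

with plasma viscosity η_p = 1.45 mPa·s.  At the normal hematocrit
H = 0.40 these give τ_y ≈ 1.6 mPa and μ∞ ≈ 5.2 mPa·s.  Both coefficients
are strictly increasing in H and can be overridden with explicit values in
the case config.  `τ_y = 0` short-circuits to the exact constant `μ∞`, so
a zero-yield run is bit-identical to a constant-viscosity Newtonian run.

## Coil model

A coil of wire diameter `d_w` and length `L_c` packed into sac volume
`V_sac` leaves porosity `ε = 1 − (π d_w² L_c/4)/V_sac`; the reference coil
(0.254 mm × 30 cm in 103.87 mm³) gives ε = 0.8536.  Permeability is
anchored at the two reference pairs (0.75, 3.7e−8 m²) and
(0.85, 5.4e−8 m²) and interpolated linearly in ε; the two anchors are kept
as data rather than re-derived from a Kozeny-type relation because no
single Kozeny constant reproduces both pairs.  `ε = 1` maps to infinite
permeability and an identically zero sink, bit-identical to running
without the porous model.  The sink is pure Darcy `−(μ/k)u` over the whole
sac region; no Forchheimer term is included (no inertial coefficient is
available for the reference coils, and sac-interior speeds are small), and
the sink is treated implicitly so arbitrarily small `k` is stable.

## Discretization and solution

Equal-order P1–P1 triangles with SUPG/PSPG stabilization; the element
parameter is

    τ_T = [(2ρ c_t)² + (2ρ|a|/h)² + (12 μ/h²)² + (μ/k)²]^(−1/2)

with `c_t` the transient coefficient and `a` the advection iterate.  The
viscous Galerkin term uses the gradient (Laplacian) form `μ ∇u:∇v`; its
natural boundary condition is the classical do-nothing outlet
`μ ∂u/∂n − p n = 0`, which reproduces channel flows exactly.  On the
fully developed verification flows the gradient and full-stress forms
coincide; wall shear stress is always post-processed from the full stress
tensor `μ(∇u + ∇uᵀ)`.  Prescribing velocity at *both* ends of an
incompressible domain is over-constrained, so the outlet is always
traction-free while the inlet carries the velocity profile.

Time stepping is implicit Euler (default, `dt = 2 ms` at production
resolution; BDF2 available).  Each step runs Picard outer iterations: the
viscosity and advection fields are frozen at the previous iterate, the
Darcy sink is implicit, and the coupled linear system is solved directly
(sparse LU).  This plays the role of the usual segregated pressure–velocity
coupling loop; a monolithic solve was chosen over a segregated SIMPLE sweep
because it reaches the 2% analytic-oracle bands robustly without
checkerboard or relaxation tuning, while keeping the same outer-iteration
contract (per-iteration momentum and continuity residual tests).
Residuals are normalized by the per-row sum of absolute term magnitudes
(|A||x| + |b|), a scale-free measure valid from quiescent to peak-systolic
states; both tolerances default to 1e−5.  If the momentum residual stops
decreasing (Picard can limit-cycle on convection-dominated meshes) the
update is automatically under-relaxed by 0.6.  The first solve of every
step is taken in full, so each later iterate is a convex blend of exact
solutions of the linearized system and the discrete global mass balance
(inflow = outflow) holds to ~1e−14 at every accepted step.

Runs start from rest; the first of the three default cycles acts as
washout and only the final cycle feeds the wall indices.  On the default
fixture the phase-matched velocity difference between cycles 2 and 3 is
~1e−8 relative — far inside the 5% periodicity band — because at these
scales (Womersley number ≈ 2–3) the flow has little cycle-to-cycle memory.

## Wall indices

For each wall facet the tangential traction `τ = (I − nnᵀ) σ_visc n` is
evaluated from the adjacent element's P1 gradient.  Over the stored final
cycle (trapezoidal quadrature on the snapshot times):

    TAWSS = (1/T) ∫‖τ‖ dt
    OSI   = ½ (1 − ‖∫τ dt‖ / ∫‖τ‖ dt) ∈ [0, ½]

`TAWSS ≥ ‖mean τ‖` is the triangle inequality of the quadrature and holds
exactly; a facet with identically zero shear gets OSI 0 and a `stagnant`
flag.  Region aggregates (sac wall, vessel wall) are facet maxima and
facet-length-weighted averages (the 2D surrogate of area weighting); wall
pressure maxima/averages are extracted at the peak-systole and
early-diastole snapshots of the final cycle.  OSI/TAWSS are whole-cycle
integrals over the final cycle (the averaging window is configurable in
principle by slicing the trajectory); an instantaneous "end-of-cycle"
reading is not used.

## Experiments

* **Grid study** — one full transient per element size; rows carry the
  sac-averaged TAWSS and a percent-change column *truncated* (not rounded)
  to two decimals, the convention that reproduces the reference study's
  printed column (17.59, 5.81, 0.25 %) from its printed WSS values; the
  first grid whose change is below 1% is selected.  On the 2D fixture the
  computed sac-averaged WSS (~0.1 Pa) is dominated by neck/sac resolution
  and converges *non-monotonically* at desk-scale meshes, so the run-based
  tests check the mechanics (element counts, change computation,
  selection), not monotone decrease.
* **Sweeps** — a hematocrit × porosity factorial (defaults {0.35, 0.40,
  0.45} × {0.75, 0.85, 1.0}) of full transients, summarized per cell by
  sac OSI/TAWSS/pressure statistics in a long-format table; cells execute
  in deterministic sorted order and per-cell failures are recorded without
  aborting.  The expected coiling effect (lower porosity → higher average
  sac OSI) is evaluated as a *soft* pass/warn report, because the planar
  fixture cannot guarantee the directionality seen in 3D patient
  geometry.  On the default fixture it passes: the open sac has
  essentially unidirectional shear (OSI ≈ 0) while the coil pack's damped,
  reversing near-wall flow raises the average sac OSI to ~0.02.

## Fixture sizes and defaults

The test suite and the acceptance script run the coarse fixture: 0.4 mm
mesh (~1.4k triangles), dt = 5 ms (160 steps/cycle), 3 cycles — chosen so
a full 3×3 sweep completes in a few CPU-minutes while leaving every
structural invariant and trend observable.  Production defaults (0.2 mm,
dt = 2 ms) are a straight config change.  Density defaults to
1060 kg/m³ (whole blood).

## Known limitations

* Planar geometry: no secondary (out-of-plane) flow, no patient-specific
  curvature or jet impingement; absolute wall-index magnitudes are not
  comparable to 3D values.
* The hematocrit correlation and the inflow harmonics are literature-style
  defaults, not patient measurements; both are configurable.
* P1 wall gradients converge first-order in the boundary layer; the
  graded wall rows keep the channel-oracle error within 2%, but very
  coarse meshes under-resolve sac WSS (see the grid-study note).
* The Darcy sink is isotropic and homogeneous over the sac; real coil
  packs are heterogeneous and induce thrombosis, which is out of scope.
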