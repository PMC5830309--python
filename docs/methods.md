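# Methods

This note documents the physical model, the discretization, the default
parameters and the deliberate design choices behind `stenoflow`, at the
level of detail a maintainer or reviewer needs to judge what the code
does and does not demonstrate.

## Physical model and assumptions

The blood vessel is a rigid, axisymmetric tube of radius R₀ with a
parametric stenosis: a linear converging ramp on the proximal half of the
narrowing and a cosine diverging ramp on the distal half, throat radius
R₀ − δ. A symmetric double-cosine variant is available behind a flag
(`geometry.symmetric`) for sensitivity studies; it is not the default
because the asymmetric profile is the primary configuration this package
targets. Flow is laminar, incompressible and axisymmetric with no swirl
(u_θ ≡ 0); the walls are rigid (no fluid–structure interaction).

**Rheology.** Carreau shear-thinning viscosity with the standard whole-
blood fit (μ₁ = 0.056 Pa·s, μ_∞ = 0.036 Pa·s, λ = 3.313 s, n = 0.3568).
The scalar shear rate is the second invariant γ̇ = √(2 D:D) of the
rate-of-strain tensor in axisymmetric cylindrical coordinates, including
the hoop strain u_r/r (with the symmetry limit ∂u_r/∂r on the axis).
The momentum equation uses the full variable-viscosity stress divergence
∇·(μ(∇V + ∇Vᵀ)): the transpose term matters when μ varies in space.
Setting `solver.full_stress: false` restores the literal constant-μ
Laplacian form μ∇²V for comparison.

**Magnetic coupling.** Low magnetic Reynolds number: the induced field is
neglected and J = σ(V×B). A uniform transverse field is incompatible
with exact axisymmetry, so the code adopts the standard biofluid-dynamics
reduction: the azimuthally averaged Lorentz force is the axial damping
−σB²(z)u_z and the Joule source is σB²(z)u_z² ≥ 0. This is the precise
momentum equation whose steady straight-tube solution is the
modified-Bessel Hartmann profile

    u(r) = (G R²)/(μ Ha²) · (1 − I₀(Ha·r/R)/I₀(Ha)),

which doubles as the validation oracle. The Hartmann number is referenced
to the high-shear plateau, Ha = B₀R₀√(σ/μ_∞), because μ_∞ governs the
thin near-wall layers where the field–viscosity competition happens. The
field occupies an axial window (default: from the throat to the outlet)
with C¹ cosine edge ramps of half-width 0.1·L₀.

Magnetization is linear and temperature-independent, M = χH, which makes
the magnetocaloric term μ₀T(∂M/∂T)DH/Dt identically zero; the term is
kept in the code as an explicit hook returning zero so a Curie-law
closure can be plugged in later. The Kelvin body force μ₀M∇H is
implemented and unit-tested but **χ defaults to 0**: realizing Ha = 1 in
a 1 cm vessel takes B₀ ≈ 21 T, and even blood's tiny susceptibility
(~10⁻⁶) times a 21 T field confined with a centimetre-scale gradient
yields a body force of order 10⁵ N/m³ — three orders of magnitude above
the ~5×10² Pa/m driving gradient, which would swamp the flow entirely.
The study conditions this package models express all field effects
through the Hartmann damping; users who want magnetophoresis set χ
explicitly.

**Energy.** ρc_p DT/Dt = k∇²T + σB²u_z² + μΦ with the axisymmetric
viscous dissipation Φ = 2[(∂u_r/∂r)² + (u_r/r)² + (∂u_z/∂z)²] +
(∂u_r/∂z + ∂u_z/∂r)² − ⅔(∇·V)². Electrical conductivity is
temperature-independent. Thermal conductivity k is not part of the
published constant set this package mirrors; the default 0.52 W/(m·K) is
the standard literature value for whole blood.

**Boundary conditions.** No slip on the stenosed wall r = r_wall(z)
(applied on the actual wall, not at r = R₀); symmetry on the axis —
automatic in this discretization because axis faces carry exactly zero
area per radian; pressure Dirichlet at both ends (pulsatile gauge
P(t) = P_m(1 + ε sin ω₀t) at the inlet, 0 at the outlet) with
zero-gradient velocity; temperature Dirichlet at the inlet, adiabatic
walls except an optionally cooled Dirichlet patch on the distal stenosis
half (z ∈ (throat, stenosis end]), zero-gradient outlet. Inlet
temperature defaults to the physiological 310 K; the literal 300 K
variant remains available via `solver.T_inlet` because both conventions
appear in the literature this model follows.

## Default driving parameters

The pulsatile driving constants are not part of the published constant
set, so the package fixes them once as its study conditions: ω₀ = 2π
rad/s (a 1 Hz heartbeat, making the five standard snapshots t = 0, 0.25,
0.5, 0.75, 1 s quarter-period instants), ε = 0.2 (a physiologic
pulse-to-mean ratio that keeps the gauge pressure positive), and
P_m = 34.6 Pa chosen so the straight-tube Newtonian (μ_∞) mean flow has
Re ≈ 100 — a representative small-artery regime. The
"low driving pressure" 60 % blockage preset uses 0.75·P_m: steady
parameter scans place the onset of post-throat separation near 0.7·P_m
on the 96×32 grid, so 0.75·P_m sits inside the recirculating regime that
case exists to exhibit while remaining below the base-case driving. All
of these are plain config fields.

## Discretization

**Mesh.** Structured body-fitted quadrilaterals in (z, η = r/r_wall(z)),
cell-centred, 0-based indexing, z from the inlet and r from the axis.
All areas and volumes are computed per unit radian (the 2π cancels in
every balance) as exact polygon integrals, so the metric identity —
outward face-area vectors plus the azimuthal hoop closure (0, −A_planar)
summing to zero — holds to round-off for every cell. Two refinement
modes exist because exact child-volume conservation and wall-curve
re-sampling are mutually exclusive on a curved wall: bilinear vertex
splitting (children partition the parent exactly) and geometric
re-sampling (used by the grid-convergence study).

**Spatial scheme.** Finite volumes with first-order upwind convection by
default and a Barth–Jespersen-limited linear-upwind option
(`solver.convection: linear-upwind`). Diffusion uses the over-relaxed
decomposition: implicit orthogonal part Γ|A|²/(A·d) plus an explicit
non-orthogonal remainder driven by cell gradients. Cell gradients are
Green–Gauss with boundary-condition-aware face values; on this smooth
structured grid they are second-order (verified by manufactured-field
refinement, observed order 2.0). The transpose part of the stress and
the r-momentum hoop term −2μu_r/r² are handled explicitly and
implicitly (diagonal), respectively.

**Pressure–velocity coupling.** Collocated variables with Rhie–Chow
momentum-weighted face fluxes to exclude checkerboard modes, SIMPLE
outer iterations with SIMPLEC-form correction coefficients
(d = V/(a_P/α_u + Σa_nb)), pressure-correction Poisson solve with
Dirichlet p′ = 0 on the pressure boundaries, direct sparse solves
(SuperLU) throughout. Under-relaxation defaults are α_u = 0.9,
α_p = 0.95; the classic SIMPLE pairing (0.7/0.3) converges to the same
states ~8× slower and remains available. Steady solves back off α_u by
0.75 and restart (up to three times) if the residual diverges — the
convection-dominated mildest-blockage cases need α_u ≈ 0.8. Outer
convergence requires the normalized mass residual < 10⁻⁶ (relative to
the inlet mass flux) and the normalized momentum residual < 10⁻⁵. A
divergence guard aborts with the residual history when the residual
grows 10⁴-fold over its best value for 50 consecutive iterations or
becomes non-finite.

**Time marching.** Backward Euler (first order, verified by a dt-halving
Richardson check), one SIMPLE loop per step followed by an implicit
energy solve using the converged face fluxes. The advective CFL is only
warned about (the implicit step is stable); the default dt = 0.01 s
resolves the 1 Hz pulse with 100 steps.

**Degenerate inputs.** Zero driving pressure converges immediately to
the quiescent state; δ = 0 is a straight tube; B₀ = 0 reproduces the
unmagnetized solver's fields bit-for-bit (the damping and Joule terms
vanish identically rather than approximately); zero flow makes the flow
resistance undefined and raises rather than returning infinities.

## Post-processing definitions

Wall shear stress is the one-sided gradient τ_w = μ_w·u_t/δ_n at each
wall face (tangential cell velocity over wall-normal centroid distance),
with μ_w re-evaluated from the wall shear rate when a Carreau law is
supplied. Flow resistance is Λ(z) = (p_in − p(z))/Q with p sampled along
a fixed-radius midline (default R₀/4, configurable) and Q the inlet flow
rate; the scalar total is Δp/Q. Recirculation is the contiguous block of
post-throat cell columns containing reverse axial flow below a relative
floor of 10⁻⁸·max|u_z|; its extent and strongest reverse velocity are
reported, and the descriptor is empty whenever min u_z ≥ 0. The
grid-convergence study reports |τ_max(level) − τ_max(finest)|/τ_max(finest)
over nested factor-2 meshes (24×8, 48×16, 96×32 by default).

The mechanical-energy audit compares boundary pressure power against
viscous dissipation + Joule dissipation + net kinetic-energy outflow;
the residual gap measures the scheme's numerical dissipation. With
first-order upwind on the 64×24 stenosed grid that gap is ~11 %, and it
is the limited linear-upwind scheme on 96×32 that brings it below 1 % —
this is why the energy-audit tests run the second-order scheme. The
thermal audit uses the same upwind face convention as the discrete
energy equation and closes to solver tolerance.

## Problem sizes used by the test battery

The suite runs steady validation tubes at 24×32, sweep cases at 64×24,
recirculation cases at 96×32, the convergence chain 24×8→96×32, and one
cardiac cycle of the cooled Joule case at 64×24 with dt = 0.02 s —
sizes at which every qualitative result (monotone Hartmann damping,
resistance growth with blockage, eddy growth with driving pressure,
decreasing grid-error sequence, sub-40 °C thermal bound) is already
established and the whole battery stays cheap on one CPU.

## What the validation does and does not show

The closed-form oracles (Poiseuille, Bessel-form Hartmann profile,
exponential advection–diffusion, manufactured fields, backward-Euler
decay) exercise every operator the stenosed transient case uses, but on
idealized configurations; the stenosed-case assertions are deliberately
qualitative (orderings, monotonicities, presence of separation) because
the corresponding published results are plots without digitized values
and the driving-pressure constants behind them are unprinted. Agreement
on the monotone trends at these grid sizes does not certify pointwise
accuracy of, e.g., the 85 % blockage jet at higher Reynolds numbers.
First-order upwind is robust but diffusive: separation extents at 64×24
are systematically shorter than at 96×32. The model also excludes 3-D
and non-axisymmetric effects, wall compliance, temperature-dependent
conductivity and magnetization, and turbulence — all outside the scope
of the reference configuration.

## Known limitations

* The transverse-field reduction is azimuthally averaged; true Hartmann
  side-layer anisotropy is not representable in an axisymmetric code.
* The explicit transpose-stress and non-orthogonal corrections are
  lagged one outer iteration, which can slow (never destabilize)
  convergence on strongly tapered cells at 85 % blockage.
* Pressure boundaries use momentum-extrapolated boundary fluxes; strong
  backflow through the outlet (not reached in the shipped presets) would
  call for a proper backflow-stabilized outlet condition.
* The energy equation freezes the velocity within each time step
  (one-way coupling per step); buoyancy and temperature-dependent
  viscosity are not modelled.
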