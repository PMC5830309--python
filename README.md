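# stenoflow

Transient axisymmetric finite-volume simulation of biomagnetic,
shear-thinning blood flow and heat transfer through a stenosed artery.

## The problem

A stenosis — a local narrowing of an artery — reshapes the blood flow
around it: the throat jet amplifies wall shear stress, a recirculating
eddy forms downstream at low driving pressures, and the hemodynamic
resistance Δp/Q grows explosively with blockage severity. When the vessel
additionally sits in a strong transverse magnetic field (magnetic drug
targeting, hyperthermia therapy), the moving conducting blood experiences
Lorentz damping and volumetric Joule heating, and keeping the blood below
40 °C becomes a design constraint for the therapy.

`stenoflow` is a small research CFD code for exactly this configuration:
an axisymmetric rigid vessel with a parametric stenosis, pulsatile
pressure driving, Carreau shear-thinning rheology, the azimuthally
averaged transverse-field magnetohydrodynamic (MHD) coupling, and an
energy equation with Joule and viscous-dissipation sources plus an
optionally cooled stenosis wall. It is written for students and
researchers in computational hemodynamics who want a transparent,
fully-testable reference implementation rather than a black-box solver.

## Model

Incompressible axisymmetric flow (u_θ = 0) in cylindrical coordinates
(z, r):

    ∇·V = 0
    ρ DV/Dt = −∇p + ∇·(μ(γ̇)(∇V + ∇Vᵀ)) − σB²(z) u_z ê_z + μ₀M∇H
    ρc_p DT/Dt = k∇²T + σB²(z) u_z² + μ(γ̇) Φ

with the Carreau viscosity

    μ(γ̇) = μ_∞ + (μ₁ − μ_∞)(1 + (λγ̇)²)^((n−1)/2),
    γ̇ = √(2 D:D),   D = ½(∇V + ∇Vᵀ)

using the standard blood constants μ₁ = 0.056 Pa·s, μ_∞ = 0.036 Pa·s,
λ = 3.313 s, n = 0.3568. The stenosis wall is a piecewise profile — a
linear converging ramp followed by a cosine diverging ramp — with the
throat radius R₀ − δ (blockage fraction δ/R₀). The flow is driven by a
pulsatile inlet gauge pressure P(t) = P_m(1 + ε sin ω₀t) against a
zero-gauge outlet. The applied transverse field enters through the
Hartmann number Ha = B₀R₀√(σ/μ_∞); a uniform transverse field is not
axisymmetric, so the code uses the standard biofluid reduction in which
the azimuthally averaged Lorentz force is the damping −σB²u_z and the
Joule source is σB²u_z² (whose exact straight-tube solution is the
modified-Bessel Hartmann profile used for validation).

Numerics: structured body-fitted quadrilateral grid in (z, η = r/r_wall(z)),
collocated finite volumes with Rhie–Chow momentum interpolation,
SIMPLE/SIMPLEC pressure–velocity coupling, first-order upwind (optionally
limited linear-upwind) convection, backward-Euler time marching, direct
sparse linear solves. See `docs/methods.md` for the full account.

## Worked example

`python examples/validate_pipe_flow.py` solves the steady pressure-driven
straight tube at four field strengths and compares with the closed-form
profiles:

```
Ha    u_centerline [m/s]   exact [m/s]   max rel error
 0.0          0.027663      0.027771      0.391 %
 1.0          0.023265      0.023345      0.340 %
 5.0          0.004277      0.004281      0.232 %
10.0          0.001111      0.001111      0.882 %
```

Each row is one steady solve on a 24×32 grid: the centreline velocity of
the computed profile, the exact Poiseuille (Ha = 0) or Bessel-form
Hartmann value, and the worst pointwise deviation across the radius. The
field visibly damps the core flow (0.0277 → 0.0011 m/s from Ha 0 to 10)
and the discretization tracks the analytic solutions to well under 1 %.

The other scripts in `examples/` each demonstrate one capability:
rheology (`carreau_rheology.py`), geometry and mesh metrics
(`stenosis_geometry_and_mesh.py`), a full pulsatile cardiac cycle
(`pulsatile_base_case.py`), the resistance-versus-blockage sweep
(`blockage_resistance_sweep.py`), post-stenotic recirculation and wall
shear stress (`recirculation_and_wss.py`), and Joule heating with wall
cooling (`joule_heating_and_cooling.py`). `examples/scenario_example.yaml`
is the annotated configuration schema.

A thin CLI wraps the same library calls:

```bash
stenoflow run --preset paper_case_50pct --outdir results/base
stenoflow sweep --preset blockage_sweep --outdir results/sweep
stenoflow validate
stenoflow converge --levels 3
```

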