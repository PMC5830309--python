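# Annotated scenario file for `stenoflow run --config ...` / load_scenario().
# Every key shown here is optional: an empty file reproduces the base case
# (50 % blockage, 7 cm vessel, pulsatile driving, no magnetic field).
# Quantities accept SI numbers or quoted values with unit suffixes
# (lengths: m/cm/mm; pressures: Pa/kPa/mmHg). Unknown keys are errors.

name: demo_case

geometry:
  R0: "1 cm"                 # unobstructed vessel radius
  L_vessel: "7 cm"           # vessel length
  stenosis_length: "2.824 cm"
  throat_z: "2 cm"           # place the profile minimum here
                             # (alternative: stenosis_onset)
  blockage_fraction: 0.5     # stenosis height / R0 (alternative: delta)
  symmetric: false           # true: double-cosine bump instead of the
                             # linear-converging / cosine-diverging profile

rheology:
  model: carreau             # carreau | newtonian (newtonian takes `mu`)
  mu1: 0.056                 # zero-shear viscosity, Pa.s
  mu_inf: 0.036              # infinite-shear viscosity, Pa.s
  lam: 3.313                 # relaxation time, s
  n: 0.3568                  # power index

fluid:
  rho: 1050.0                # density, kg/m^3
  cp: 3490.0                 # specific heat, J/(kg K)
  k: 0.52                    # thermal conductivity, W/(m K)
  sigma: 0.8                 # electrical conductivity, S/m

magnetics:
  Ha: 1.0                    # Hartmann number (alternative: B0 in tesla;
                             # give exactly one of the two)
  z_on: "2 cm"               # magnetized window start (default: throat)
  z_off: "7 cm"              # window end (default: outlet)
  ramp_len: "2.8 mm"         # C1 cosine edge smoothing
  chi: 0.0                   # susceptibility for the Kelvin force M grad H

pressure:
  Pm: 34.6                   # mean inlet gauge pressure, Pa
  eps: 0.2                   # pulsation amplitude ratio Ps/Pm
  omega0: 6.283185307179586  # angular frequency, rad/s (1 Hz heartbeat)

solver:
  dt: 0.01                   # time step, s
  t_end: 1.0                 # simulated time, s
  steady: false              # true: drop the transient term, iterate to steady
  outer_tol: 1.0e-6          # normalized mass-residual tolerance
  mom_tol: 1.0e-5            # normalized momentum-residual tolerance
  relax_u: 0.9               # velocity under-relaxation
  relax_p: 0.95              # pressure-correction relaxation
  convection: upwind         # upwind | linear-upwind (limited, 2nd order)
  full_stress: true          # false: literal constant-viscosity Laplacian
  T_inlet: 310.0             # inlet blood temperature, K (300.0: literal mode)
  cooled_wall: false         # Dirichlet patch on the distal stenosis half
  # T_cool: 310.0            # cooled-patch temperature (default: T_inlet)

mesh:
  nz: 96                     # axial cells
  nr: 32                     # radial cells (body-fitted, axis to wall)

output:
  snapshot_times: [0.0, 0.25, 0.5, 0.75, 1.0]
  probe_stations: [0.002, 0.02, 0.04]   # m; u_z(r) and T(r) traces
  # outdir: results/demo                # VTK + CSV + log destination
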