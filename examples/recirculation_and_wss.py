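"""Post-stenotic recirculation and wall shear stress at 60 % blockage.

Solves the low-driving-pressure 60 % case (the regime where a trailing
eddy forms behind the throat) at two driving pressures and reports the
reverse-flow extent and the wall-stress landmarks.
"""

import warnings
from dataclasses import replace

import numpy as np

from stenoflow import detect_recirculation, make_solver, preset, wall_shear_stress

base = preset("joule_60pct_lowdp")
for fac in (1.0, 1.5):
    sc = replace(
        base,
        solver=replace(base.solver, steady=True),
        pressure=replace(base.pressure, Pm=base.pressure.Pm * fac, eps=0.0),
    )
    solver = make_solver(sc, nz=96, nr=32)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        state, _ = solver.steady_solve()
    rz = detect_recirculation(state, solver.mesh)
    wp = wall_shear_stress(state, solver.mesh, sc.fluid.carreau)
    z_peak = wp.z[np.argmax(np.abs(wp.tau))]
    print(f"Pm = {sc.pressure.Pm:5.1f} Pa:")
    print(f"  recirculation present: {rz.present}")
    if rz.present:
        print(
            f"  extent z = {100 * rz.z_start:.2f} .. {100 * rz.z_end:.2f} cm "
            f"({100 * rz.extent:.2f} cm), max reverse velocity "
            f"{1000 * rz.max_reverse_velocity:.3f} mm/s"
        )
    print(f"  peak wall shear stress {wp.tau_max:.3f} Pa at z = {100 * z_peak:.2f} cm\n")

print(
    "The eddy sits just downstream of the throat and lengthens with the "
    "driving pressure; wall stress peaks at the throat and collapses in "
    "the separated region - the combination implicated in plaque rupture."
)
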