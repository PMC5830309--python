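"""Flow resistance versus stenosis severity.

Steady solves of the 6 cm vessel from mild (20 %) to severe (85 %)
blockage at a fixed driving pressure; prints the total hemodynamic
resistance Delta p / Q for each case.
"""

import warnings
from dataclasses import replace

from stenoflow import flow_resistance, make_solver, preset

print("blockage   resistance [Pa.s/m^3]   x mild-case")
lam0 = None
for sc in preset("blockage_sweep"):
    sc = replace(
        sc,
        solver=replace(sc.solver, steady=True),
        pressure=replace(sc.pressure, eps=0.0),
    )
    solver = make_solver(sc, nz=64, nr=24)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        state, _ = solver.steady_solve()
    _, _, lam = flow_resistance(state, solver.mesh, p_inlet=sc.pressure.Pm)
    lam0 = lam0 or lam
    print(f"  {100 * sc.geometry.blockage_fraction:4.0f} %    {lam:12.4g}          {lam / lam0:8.1f}")

print(
    "\nResistance climbs slowly up to ~60 % blockage and then explosively "
    "(throat radius enters as ~1/r^4): the hemodynamic signature of a "
    "severe stenosis."
)
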