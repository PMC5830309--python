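"""Shared fixtures: cached steady solves reused across the suite."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import stenoflow as sf

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

MU_REF = 0.036  # high-shear plateau used as the Newtonian reference viscosity
STRAIGHT_GEOM = sf.StenosisGeometry(R0=0.01, L_vessel=0.05, d=0.02, L0=0.01, delta=0.0)
STRAIGHT_PM = 2.0  # Pa; low-Re regime where the developed profile is exact


def straight_tube_solver(Ha: float, nr: int = 32, nz: int = 24, **cfg_over):
    """Newtonian straight-tube solver with a uniform axial damping field."""
    props = sf.FluidProps(carreau=sf.CarreauParams.newtonian(MU_REF))
    B0 = sf.b0_for_hartmann(Ha, STRAIGHT_GEOM.R0, props.sigma, MU_REF)
    mag = sf.MagneticConfig(B0=B0, z_on=-1.0, z_off=1.0, ramp_len=0.0, sigma=props.sigma)
    pp = sf.PulsatilePressure(Pm=STRAIGHT_PM, eps=0.0)
    cfg = sf.SolverConfig(steady=True, **cfg_over)
    mesh = sf.build_mesh(STRAIGHT_GEOM, nz, nr)
    return sf.SimpleSolver(mesh, props, mag, cfg, pp)


@pytest.fixture(scope="session")
def straight_tube_solutions():
    """Converged steady states of the straight tube at Ha = 0, 1, 5, 10."""
    out = {}
    for Ha in (0.0, 1.0, 5.0, 10.0):
        solver = straight_tube_solver(Ha)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state, report = solver.steady_solve()
        assert report.converged
        out[Ha] = (solver, state)
    return out


@pytest.fixture(scope="session")
def stenosis50_steady():
    """Steady 50 % blockage base case (constant driving pressure), 64x24."""
    from dataclasses import replace

    sc = sf.preset("paper_case_50pct")
    sc = replace(
        sc,
        solver=replace(sc.solver, steady=True),
        pressure=replace(sc.pressure, eps=0.0),
    )
    solver = sf.make_solver(sc, nz=64, nr=24)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        state, report = solver.steady_solve()
    assert report.converged
    return sc, solver, state


@pytest.fixture(scope="session")
def stenosis50_steady_ho():
    """Steady 50 % base case with second-order convection, 96x32.

    The low numerical dissipation of the linear-upwind scheme is needed
    for the mechanical-energy audit to resolve the physical dissipation.
    """
    from dataclasses import replace

    sc = sf.preset("paper_case_50pct")
    sc = replace(
        sc,
        solver=replace(sc.solver, steady=True, convection="linear-upwind"),
        pressure=replace(sc.pressure, eps=0.0),
    )
    solver = sf.make_solver(sc, nz=96, nr=32)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        state, report = solver.steady_solve()
    assert report.converged
    return sc, solver, state


@pytest.fixture(scope="session")
def poiseuille_exact():
    def _exact(r):
        G = STRAIGHT_PM / STRAIGHT_GEOM.L_vessel
        return sf.analytic_poiseuille(np.asarray(r), G, MU_REF, STRAIGHT_GEOM.R0)

    return _exact
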