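"""Scenario orchestration: build the solver, march in time, collect outputs."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .analytics import ProbeTrace, probe_trace
from .fields import SimState
from .geometry import AxiMesh, build_mesh
from .scenario import Scenario
from .solver import IterationReport, SimpleSolver

__all__ = ["SimulationResult", "make_solver", "run_simulation"]

log = logging.getLogger("stenoflow")


@dataclass
class SimulationResult:
    """Snapshots, probe traces and residual reports of one run."""

    scenario: Scenario
    mesh: AxiMesh
    snapshots: list[SimState] = field(default_factory=list)
    snapshot_times: list[float] = field(default_factory=list)
    probes: list[ProbeTrace] = field(default_factory=list)
    reports: list[IterationReport] = field(default_factory=list)

    @property
    def final_state(self) -> SimState:
        return self.snapshots[-1]


def make_solver(sc: Scenario, nz: int | None = None, nr: int | None = None) -> SimpleSolver:
    mesh = build_mesh(sc.geometry, nz or sc.mesh_nz, nr or sc.mesh_nr)
    return SimpleSolver(mesh, sc.fluid, sc.magnetics, sc.solver, sc.pressure)


def run_simulation(
    sc: Scenario,
    max_steps: int | None = None,
    nz: int | None = None,
    nr: int | None = None,
) -> SimulationResult:
    """Time-march one scenario and collect snapshots and probe traces.

    Snapshots are taken at the configured times (default: the five
    quarter-period instants 0, 0.25, ..., 1 s); probes record u_z(r) and
    T(r) at the configured axial stations at every snapshot.  Outputs are
    written under ``scenario.outputs.outdir`` when set.
    """
    t_start = time.perf_counter()
    solver = make_solver(sc, nz, nr)
    mesh = solver.mesh
    log.info(
        "run '%s': grid %dx%d, config hash %s",
        sc.name,
        mesh.nz,
        mesh.nr,
        sc.config_hash(),
    )
    result = SimulationResult(scenario=sc, mesh=mesh)
    state = solver.initial_state(0.0)

    snap_times = sorted(set(sc.outputs.snapshot_times))
    stations = [z for z in sc.outputs.probe_stations if z <= sc.geometry.L_vessel]

    def take_snapshot(st: SimState):
        result.snapshots.append(st.copy())
        result.snapshot_times.append(st.t)
        for z in stations:
            result.probes.append(probe_trace(st, mesh, z, "u_z"))
            result.probes.append(probe_trace(st, mesh, z, "T"))

    if snap_times and abs(snap_times[0]) < 1e-12:
        take_snapshot(state)
        pending = snap_times[1:]
    else:
        pending = snap_times

    n_steps = int(round(sc.solver.t_end / sc.solver.dt))
    if max_steps is not None:
        n_steps = min(n_steps, max_steps)
    for step in range(n_steps):
        state, report = solver.advance(state)
        result.reports.append(report)
        log.debug(
            "t=%.4f s: %d outer iterations, mass residual %.2e",
            state.t,
            report.outer_iterations,
            report.mass[-1] if report.mass else np.nan,
        )
        while pending and state.t >= pending[0] - 0.5 * sc.solver.dt:
            take_snapshot(state)
            pending.pop(0)
    # capped or oddly-timed runs: always keep the last computed state
    if not result.snapshots or result.snapshot_times[-1] < state.t - 1e-12:
        take_snapshot(state)

    if sc.outputs.outdir:
        _write_outputs(result)
    log.info(
        "run '%s' finished: %d steps, %.1f s wall time",
        sc.name,
        n_steps,
        time.perf_counter() - t_start,
    )
    return result


def _write_outputs(result: SimulationResult) -> None:
    from .output import write_probes, write_snapshot
    from .scenario import save_scenario

    outdir = Path(result.scenario.outputs.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for k, (st, t) in enumerate(zip(result.snapshots, result.snapshot_times)):
        write_snapshot(st, result.mesh, outdir / f"snapshot_{k:03d}_t{t:.3f}.vtk")
    if result.probes:
        write_probes(result.probes, outdir / "probes.csv")
    save_scenario(result.scenario, outdir / "scenario.yaml")
    with open(outdir / "residuals.log", "w") as fh:
        fh.write("# step  outer_iterations  final_mass_residual  final_momentum_residual\n")
        for k, rep in enumerate(result.reports):
            fh.write(
                f"{k} {rep.outer_iterations} "
                f"{rep.mass[-1] if rep.mass else float('nan'):.6e} "
                f"{rep.momentum[-1] if rep.momentum else float('nan'):.6e}\n"
            )
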