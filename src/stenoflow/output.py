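"""Structured outputs: legacy-VTK snapshots, CSV probe traces, run logs.

Snapshots are ASCII VTK unstructured grids (quad cells in the (z, r)
plane, azimuth collapsed) with point data for the velocity vector,
pressure, temperature and viscosity — readable by ParaView and VisIt.
Cell values are averaged to the vertices for the point data.  Field names
are part of the output contract and stay stable across versions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .analytics import ProbeTrace
from .fields import SimState
from .geometry import AxiMesh

__all__ = ["write_snapshot", "read_vtk_points", "write_probes", "PROBE_COLUMNS", "VTK_FIELDS"]

VTK_FIELDS = ("velocity", "pressure", "temperature", "viscosity")
PROBE_COLUMNS = ("t", "z_station", "r", "u_z", "T")


def _cells_to_points(mesh: AxiMesh, cell_vals: np.ndarray) -> np.ndarray:
    """Average adjacent cell values onto the (nz+1, nr+1) vertices."""
    nz, nr = mesh.nz, mesh.nr
    c = cell_vals.reshape(nz, nr)
    acc = np.zeros((nz + 1, nr + 1))
    cnt = np.zeros((nz + 1, nr + 1))
    for di in (0, 1):
        for dj in (0, 1):
            acc[di : nz + di, dj : nr + dj] += c
            cnt[di : nz + di, dj : nr + dj] += 1.0
    return acc / cnt


def write_snapshot(state: SimState, mesh: AxiMesh, path) -> None:
    """Write one legacy-VTK snapshot of the state on its mesh."""
    path = Path(path)
    nz, nr = mesh.nz, mesh.nr
    npts = (nz + 1) * (nr + 1)

    def pid(i, j):
        return i * (nr + 1) + j

    uz_p = _cells_to_points(mesh, state.u_z).ravel()
    ur_p = _cells_to_points(mesh, state.u_r).ravel()
    p_p = _cells_to_points(mesh, state.p).ravel()
    T_p = _cells_to_points(mesh, state.T).ravel()
    mu_p = _cells_to_points(mesh, state.mu).ravel()

    lines = [
        "# vtk DataFile Version 3.0",
        f"stenoflow snapshot t={state.t:.6g}",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {npts} double",
    ]
    zz = np.repeat(mesh.zv, nr + 1)
    rr = mesh.rv.ravel()
    lines.extend(f"{z:.12e} {r:.12e} 0.0" for z, r in zip(zz, rr))
    ncell = nz * nr
    lines.append(f"CELLS {ncell} {5 * ncell}")
    for i in range(nz):
        for j in range(nr):
            lines.append(f"4 {pid(i, j)} {pid(i + 1, j)} {pid(i + 1, j + 1)} {pid(i, j + 1)}")
    lines.append(f"CELL_TYPES {ncell}")
    lines.extend(["9"] * ncell)  # VTK_QUAD
    lines.append(f"POINT_DATA {npts}")
    lines.append("VECTORS velocity double")
    lines.extend(f"{a:.9e} {b:.9e} 0.0" for a, b in zip(uz_p, ur_p))
    for name, arr in (("pressure", p_p), ("temperature", T_p), ("viscosity", mu_p)):
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.9e}" for v in arr)
    path.write_text("\n".join(lines) + "\n")


def read_vtk_points(path) -> np.ndarray:
    """Read back the POINTS block of a legacy-VTK file (round-trip checks)."""
    toks = []
    reading = False
    n = 0
    for line in Path(path).read_text().splitlines():
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            reading = True
            continue
        if reading:
            toks.extend(float(x) for x in line.split())
            if len(toks) >= 3 * n:
                break
    return np.asarray(toks[: 3 * n]).reshape(n, 3)


def write_probes(traces: list[ProbeTrace], path) -> pd.DataFrame:
    """Write probe traces as CSV with the fixed column order."""
    rows = []
    for tr in traces:
        for r, v in zip(tr.r, tr.values):
            rows.append(
                {
                    "t": tr.t,
                    "z_station": tr.z,
                    "r": r,
                    "u_z": v if tr.name == "u_z" else np.nan,
                    "T": v if tr.name == "T" else np.nan,
                }
            )
    df = pd.DataFrame(rows, columns=list(PROBE_COLUMNS))
    # merge u_z and T rows sharing (t, z, r)
    df = df.groupby(["t", "z_station", "r"], as_index=False).first()
    df = df[list(PROBE_COLUMNS)]
    df.to_csv(path, index=False)
    return df
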