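"""Closed-form validation profiles and post-processing of solver states.

The analytic references are the exact steady solutions of the axisymmetric
momentum equation the solver discretizes in a straight tube:

* Poiseuille, ``u = G (R^2 - r^2) / (4 mu)``, for no applied field;
* the Hartmann-damped pipe profile
  ``u = (G R^2 / (mu Ha^2)) (1 - I0(Ha r/R) / I0(Ha))``
  for the transverse-field damping model, with ``I0`` the modified Bessel
  function of the first kind.

Post-processing covers wall shear stress along the stenosed wall, the
cumulative flow-resistance profile Lambda(z) = (p_in - p(z)) / Q, trailing
recirculation (reverse-flow) regions behind the throat, grid-convergence
sequences of the peak wall stress, and discrete energy audits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import i0, iv

from .discretization import Discretization
from .fields import SimState
from .geometry import AxiMesh
from .magnetics import joule_heating
from .rheology import carreau_viscosity

__all__ = [
    "ProbeTrace",
    "WallProfile",
    "RecirculationZone",
    "analytic_poiseuille",
    "analytic_mhd_pipe_profile",
    "probe_trace",
    "wall_shear_stress",
    "flow_rate_profile",
    "flow_resistance",
    "detect_recirculation",
    "grid_convergence_study",
    "mechanical_energy_audit",
    "thermal_energy_audit",
]


# --------------------------------------------------------------------- types
@dataclass(frozen=True)
class ProbeTrace:
    """Radial profile of one field at an axial station and time."""

    z: float
    r: np.ndarray
    values: np.ndarray
    name: str
    t: float

    def __post_init__(self):
        if self.r.size > 1 and np.any(np.diff(self.r) <= 0):
            raise ValueError("radial samples must be strictly increasing")


@dataclass(frozen=True)
class WallProfile:
    """Wall-face arc positions with shear stress and pressure."""

    s: np.ndarray  # arc length along the wall from the inlet, m
    z: np.ndarray  # axial position of each wall face, m
    tau: np.ndarray  # wall shear stress, Pa
    p: np.ndarray  # wall pressure, Pa

    @property
    def tau_max(self) -> float:
        return float(np.max(np.abs(self.tau)))


@dataclass(frozen=True)
class RecirculationZone:
    """Post-throat reverse-flow descriptor (empty when no u_z < 0)."""

    present: bool
    z_start: float = np.nan
    z_end: float = np.nan
    max_reverse_velocity: float = 0.0
    n_cells: int = 0

    @property
    def extent(self) -> float:
        return 0.0 if not self.present else float(self.z_end - self.z_start)


# ------------------------------------------------------------------- oracles
def analytic_poiseuille(r, G, mu, R):
    """Steady pressure-driven pipe flow: u = G (R^2 - r^2) / (4 mu)."""
    r = np.asarray(r, dtype=float)
    out = G * (R**2 - r**2) / (4.0 * mu)
    return float(out) if out.ndim == 0 else out


def analytic_mhd_pipe_profile(r, G, mu, R, Ha):
    """Hartmann-damped pipe flow of the axisymmetric damping model.

    Solves ``mu (1/r)(r u')' - (mu Ha^2 / R^2) u + G = 0`` with no slip:
    ``u = (G R^2 / (mu Ha^2)) (1 - I0(Ha r/R)/I0(Ha))``; Ha -> 0 recovers
    Poiseuille.
    """
    if Ha < 0:
        raise ValueError("Ha must be >= 0")
    if Ha == 0.0:
        return analytic_poiseuille(r, G, mu, R)
    r = np.asarray(r, dtype=float)
    out = (G * R**2 / (mu * Ha**2)) * (1.0 - iv(0, Ha * r / R) / i0(Ha))
    return float(out) if out.ndim == 0 else out


# ------------------------------------------------------------------- probes
def probe_trace(state: SimState, mesh: AxiMesh, z_station: float, field: str = "u_z") -> ProbeTrace:
    """Radial profile of ``field`` at the cell column nearest ``z_station``."""
    i = int(np.argmin(np.abs(mesh.zc[:, 0] - z_station)))
    r = mesh.rc[i, :]
    vals = getattr(state, field).reshape(mesh.nz, mesh.nr)[i, :]
    return ProbeTrace(z=float(mesh.zc[i, 0]), r=r.copy(), values=vals.copy(), name=field, t=state.t)


# ----------------------------------------------------------- wall quantities
def wall_shear_stress(state: SimState, mesh: AxiMesh, carreau=None) -> WallProfile:
    """One-sided wall shear stress tau_w = mu_w du_t/dn on every wall face.

    The tangential velocity of the wall-adjacent cell divided by its
    wall-normal distance gives the one-sided gradient; the wall viscosity
    is re-evaluated from that shear rate when a Carreau law is supplied,
    otherwise the adjacent-cell viscosity is used.
    """
    disc = Discretization(mesh)
    b = disc.boundaries["wall"]
    cells = b["cells"]
    Amag = np.hypot(b["Az"], b["Ar"])
    nz_hat = b["Az"] / Amag
    nr_hat = b["Ar"] / Amag
    # tangent oriented +z-ish
    tz, tr = nr_hat, -nz_hat
    flip = tz < 0
    tz = np.where(flip, -tz, tz)
    tr = np.where(flip, -tr, tr)
    u_t = state.u_z[cells] * tz + state.u_r[cells] * tr
    dn = b["dz"] * nz_hat + b["dr"] * nr_hat  # cell centre to wall distance
    gamma_w = np.abs(u_t) / dn
    if carreau is not None:
        mu_w = carreau_viscosity(gamma_w, carreau)
    else:
        mu_w = state.mu[cells]
    tau = mu_w * u_t / dn
    zf = b["cz"]
    ds = np.hypot(np.diff(mesh.zv), np.diff(mesh.rv[:, -1]))
    s = np.cumsum(ds) - 0.5 * ds
    return WallProfile(s=s, z=zf.copy(), tau=tau, p=state.p[cells].copy())


def flow_rate_profile(state: SimState, mesh: AxiMesh) -> tuple[np.ndarray, np.ndarray]:
    """Volumetric flow rate Q(z) through every constant-z plane, m^3/s.

    Integrates u_z over each interior z-plane (full 2*pi azimuth).
    Returns (z_planes, Q).
    """
    nz, nr = mesh.nz, mesh.nr
    uz = state.u_z.reshape(nz, nr)
    # interpolate axially onto planes 1..nz-1
    Q = np.empty(nz + 1)
    Az = mesh.zf_Az  # (nz+1, nr) per radian
    Q[1:nz] = 2.0 * np.pi * np.sum(0.5 * (uz[:-1, :] + uz[1:, :]) * Az[1:nz, :], axis=1)
    Q[0] = 2.0 * np.pi * np.sum(uz[0, :] * Az[0, :])
    Q[nz] = 2.0 * np.pi * np.sum(uz[-1, :] * Az[nz, :])
    return mesh.zv.copy(), Q


def flow_resistance(
    state: SimState,
    mesh: AxiMesh,
    p_inlet: float | None = None,
    midline_r: float | None = None,
    q_floor: float = 1.0e-15,
):
    """Cumulative resistance Lambda(z) = (p_in - p(z)) / Q and the total.

    ``p(z)`` is sampled along a midline at fixed radius (default: quarter
    radius, following the convention of plotting resistance along a line
    r = const inside the lumen).  ``Q`` is the instantaneous flow rate at
    the inlet plane.  Returns ``(z, Lambda(z), Lambda_total)``; raises
    ``FloatingPointError`` when |Q| is below ``q_floor`` (resistance
    undefined).
    """
    zpl, Q = flow_rate_profile(state, mesh)
    Q0 = float(Q[0])
    if abs(Q0) < q_floor:
        raise FloatingPointError("flow rate below threshold: resistance undefined")
    r_mid = 0.25 * mesh.geom.R0 if midline_r is None else midline_r
    nz, nr = mesh.nz, mesh.nr
    p2 = state.p.reshape(nz, nr)
    z_line = mesh.zc[:, 0].copy()
    p_line = np.empty(nz)
    for i in range(nz):
        j = int(np.argmin(np.abs(mesh.rc[i, :] - r_mid)))
        p_line[i] = p2[i, j]
    if p_inlet is None:
        p_in = p_line[0]
    else:
        p_in = p_inlet
    lam = (p_in - p_line) / Q0
    lam_total = (p_in - 0.0) / Q0 if p_inlet is not None else (p_in - p_line[-1]) / Q0
    return z_line, lam, float(lam_total)


def detect_recirculation(
    state: SimState, mesh: AxiMesh, u_floor_frac: float = 1.0e-8
) -> RecirculationZone:
    """Locate contiguous post-throat reverse axial flow.

    A cell counts as reversed when ``u_z < -u_floor_frac * max|u_z|``.
    Returns the axial extent of the contiguous block of columns (starting
    from the first reversed column past the throat) and the strongest
    reverse velocity; an empty descriptor when no cell is reversed.
    """
    nz, nr = mesh.nz, mesh.nr
    uz = state.u_z.reshape(nz, nr)
    floor = -u_floor_frac * max(float(np.max(np.abs(uz))), 1e-300)
    z_throat = mesh.geom.throat_z
    zcol = mesh.zc[:, 0]
    rev_col = np.any(uz < floor, axis=1) & (zcol > z_throat)
    if not np.any(rev_col):
        return RecirculationZone(present=False)
    idx = np.flatnonzero(rev_col)
    # contiguous block containing the first reversed column
    blocks = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    block = max(blocks, key=len)
    sel = np.zeros(nz, dtype=bool)
    sel[block] = True
    u_rev = uz[sel, :].min()
    n_cells = int(np.sum(uz[sel, :] < floor))
    return RecirculationZone(
        present=True,
        z_start=float(zcol[block[0]]),
        z_end=float(zcol[block[-1]]),
        max_reverse_velocity=float(-u_rev),
        n_cells=n_cells,
    )


# -------------------------------------------------------------- grid studies
def grid_convergence_study(run_fn, levels: int = 3, base_nz: int = 24, base_nr: int = 8):
    """Error-vs-finest sequence of the peak wall shear stress.

    ``run_fn(nz, nr) -> (state, mesh)`` must run the scenario on the given
    grid.  Grids are nested, doubling each direction per level (so the
    point count grows ~4x per level).  Returns ``(resolutions, tau_max,
    rel_errors)`` where the error of level k is
    ``|tau_max(k) - tau_max(finest)| / tau_max(finest)`` (zero at the
    finest level by construction).
    """
    if levels < 3:
        raise ValueError("need at least 3 levels")
    taus = []
    res = []
    for lev in range(levels):
        nz = base_nz * 2**lev
        nr = base_nr * 2**lev
        state, mesh = run_fn(nz, nr)
        wp = wall_shear_stress(state, mesh)
        taus.append(wp.tau_max)
        res.append((nz, nr))
        if not np.isfinite(taus[-1]) or taus[-1] <= 0:
            raise RuntimeError(f"non-convergent level {lev}: tau_max={taus[-1]}")
    taus = np.asarray(taus)
    errs = np.abs(taus - taus[-1]) / taus[-1]
    return res, taus, errs


def observed_order(errs: np.ndarray) -> float:
    """Observed convergence order from the last two nonzero errors
    of a factor-2 refinement sequence."""
    e = np.asarray(errs, dtype=float)
    e = e[e > 0]
    if e.size < 2:
        return np.nan
    return float(np.log2(e[-2] / e[-1]))


# ------------------------------------------------------------- energy audits
def mechanical_energy_audit(solver, state: SimState) -> dict[str, float]:
    """Steady mechanical-energy balance: pressure power vs dissipation.

    At steady state the pressure power injected through the boundaries
    equals the volume-integrated viscous dissipation plus Joule (Lorentz)
    dissipation plus the net kinetic-energy flux carried out of the domain
    (significant when the outlet jet is faster than the inlet profile).
    All powers per unit radian; the residual gap measures the scheme's
    numerical dissipation and discretization error.
    """
    d = solver.disc
    flux = solver._flux
    rho = solver.props.rho
    p_work = 0.0
    ke_out = 0.0
    from .fields import inlet_pressure

    p_vals = {"inlet": inlet_pressure(state.t, solver.pp), "outlet": 0.0}
    ke_cell = 0.5 * (state.u_z**2 + state.u_r**2)
    for name in ("inlet", "outlet"):
        mb = flux.boundary[name]
        cells = d.boundaries[name]["cells"]
        p_work -= p_vals[name] * np.sum(mb) / rho
        ke_out += np.sum(mb * ke_cell[cells])  # upwind-consistent face value
    visc = float(np.sum(solver.viscous_dissipation(state) * d.vol))
    joule = float(np.sum(joule_heating(state.u_z, solver.B_cell, solver.props.sigma) * d.vol))
    gap = abs(p_work - ke_out - visc - joule) / max(abs(p_work), 1e-300)
    return {
        "pressure_power": float(p_work),
        "kinetic_outflow": float(ke_out),
        "viscous": visc,
        "joule": joule,
        "rel_gap": float(gap),
    }


def thermal_energy_audit(solver, state: SimState) -> dict[str, float]:
    """Steady thermal balance: enthalpy outflow - inflow vs heat sources.

    Uses the solver's converged face fluxes with the same upwind convention
    as the discrete energy equation, plus the one-sided diffusive fluxes on
    Dirichlet boundaries; at steady state the gap closes to solver
    tolerance.  All powers per unit radian, W/rad.
    """
    d = solver.disc
    props = solver.props
    flux = solver._flux
    bcs = solver.bcs_temperature()
    gT = d.gradient(state.T, bcs)
    advect = 0.0
    conduct = 0.0
    for name, b in d.boundaries.items():
        cells = b["cells"]
        mb = flux.boundary[name]
        bc = bcs[name]
        mask = bc.dirichlet_mask(cells.size)
        vals = bc.values(cells.size)
        T_face = np.where(mb >= 0, state.T[cells], np.where(mask, vals, state.T[cells]))
        advect += props.cp * np.sum(mb * T_face)
        Db = np.where(mask, props.k * b["Eb"], 0.0)
        corr = np.where(mask, props.k * (gT[0][cells] * b["Tbz"] + gT[1][cells] * b["Tbr"]), 0.0)
        conduct += np.sum(Db * (vals - state.T[cells]) + corr)  # into the domain
    joule = float(np.sum(joule_heating(state.u_z, solver.B_cell, props.sigma) * d.vol))
    visc = float(np.sum(solver.viscous_dissipation(state) * d.vol))
    source = joule + visc
    gap = abs(advect - conduct - source) / max(abs(source), abs(advect), 1e-300)
    return {
        "enthalpy_net_outflow": float(advect),
        "boundary_conduction_in": float(conduct),
        "joule": joule,
        "viscous": visc,
        "rel_gap": float(gap),
    }
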