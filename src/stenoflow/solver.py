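"""Pressure-velocity coupling (SIMPLE) and time marching.

The incompressible axisymmetric momentum/energy system is advanced with
backward-Euler time steps; within each step SIMPLE outer iterations couple
the collocated velocity and pressure through momentum-weighted (Rhie-Chow)
face fluxes and a pressure-correction Poisson solve.  The flow is driven by
a pulsatile gauge pressure at the inlet against a zero-gauge outlet; walls
are no-slip at the stenosed radius, and the axis needs no explicit
condition because axis faces carry exactly zero area per radian.

Magnetic coupling follows the azimuthally averaged transverse-field model:
an implicit damping -sigma B(z)^2 u_z in axial momentum, the Kelvin
magnetization force mu0 chi H dH/dz, and the Joule source sigma B^2 u_z^2
in the energy equation.  The Carreau viscosity is refreshed from the
rate-of-strain invariant every outer iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .discretization import (
    BoundaryCondition,
    Discretization,
    FaceFlux,
    apply_boundary_conditions,
    discretize_transport,
)
from .fields import FluidProps, PulsatilePressure, SimState, SolverConfig, inlet_pressure
from .geometry import AxiMesh
from .magnetics import (
    MagneticConfig,
    field_envelope,
    field_envelope_gradient,
    joule_heating,
    magnetization_force,
    magnetocaloric_term,
)
from .rheology import carreau_viscosity, shear_rate_invariant

__all__ = ["SimpleSolver", "SolverDivergence", "IterationReport"]


class SolverDivergence(RuntimeError):
    """Raised when the outer-iteration residuals grow without bound."""

    def __init__(self, message: str, history: list | None = None):
        super().__init__(message)
        self.history = history or []


@dataclass
class IterationReport:
    """Residual history of one SIMPLE loop (one time level)."""

    mass: list[float] = field(default_factory=list)
    momentum: list[float] = field(default_factory=list)
    outer_iterations: int = 0
    converged: bool = False


class SimpleSolver:
    """Finite-volume SIMPLE solver bound to one mesh and one physics setup."""

    def __init__(
        self,
        mesh: AxiMesh,
        props: FluidProps,
        mag: MagneticConfig,
        cfg: SolverConfig,
        pp: PulsatilePressure,
    ):
        self.mesh = mesh
        self.disc = Discretization(mesh)
        self.props = props
        self.mag = mag
        self.cfg = cfg
        self.pp = pp

        d = self.disc
        self.B_cell = np.asarray(field_envelope(d.cell_z, mag), dtype=float).reshape(d.n)
        H = self.B_cell / mag.mu0_mag
        gH = (
            np.asarray(field_envelope_gradient(d.cell_z, mag), dtype=float).reshape(d.n)
            / mag.mu0_mag
        )
        self.kelvin_force = magnetization_force(H, gH, mag)
        self._sigma_B2 = props.sigma * self.B_cell**2

        # cooled Dirichlet patch on the distal stenosis half
        g = mesh.geom
        wall_z = d.boundaries["wall"]["cz"]
        self.cooled_mask = (wall_z > g.throat_z) & (wall_z <= g.d + g.L0 + 1e-12)
        self._T_cool = cfg.T_cool if cfg.T_cool is not None else cfg.T_inlet

    # ------------------------------------------------------------------ BCs
    def bcs_velocity(self):
        bc_uz = {
            "inlet": BoundaryCondition("zero_gradient"),
            "outlet": BoundaryCondition("zero_gradient"),
            "wall": BoundaryCondition("dirichlet", 0.0),
        }
        bc_ur = {
            "inlet": BoundaryCondition("dirichlet", 0.0),
            "outlet": BoundaryCondition("zero_gradient"),
            "wall": BoundaryCondition("dirichlet", 0.0),
        }
        return bc_uz, bc_ur

    def bcs_pressure(self, t: float):
        return {
            "inlet": BoundaryCondition("dirichlet", inlet_pressure(t, self.pp)),
            "outlet": BoundaryCondition("dirichlet", 0.0),
            "wall": BoundaryCondition("zero_gradient"),
        }

    def bcs_temperature(self):
        if self.cfg.cooled_wall:
            wall = BoundaryCondition(
                "mixed",
                value=self._T_cool,
                mask=self.cooled_mask,
            )
        else:
            wall = BoundaryCondition("zero_gradient")
        return {
            "inlet": BoundaryCondition("dirichlet", self.cfg.T_inlet),
            "outlet": BoundaryCondition("zero_gradient"),
            "wall": wall,
        }

    # ------------------------------------------------------------- utilities
    def initial_state(self, t: float = 0.0) -> SimState:
        """Quiescent start: zero velocity, axially linear pressure, inlet T."""
        d = self.disc
        st = SimState.zeros(d.n, self.props.carreau.mu1, self.cfg.T_inlet)
        p_in = inlet_pressure(t, self.pp)
        L = self.mesh.geom.L_vessel
        st.p = p_in * (1.0 - d.cell_z / L)
        st.t = t
        return st

    def velocity_gradients(self, state: SimState):
        bc_uz, bc_ur = self.bcs_velocity()
        gzz, gzr = self.disc.gradient(state.u_z, bc_uz)  # d u_z / dz, d u_z / dr
        grz, grr = self.disc.gradient(state.u_r, bc_ur)  # d u_r / dz, d u_r / dr
        return gzz, gzr, grz, grr

    def shear_rate(self, state: SimState, grads=None) -> np.ndarray:
        if grads is None:
            grads = self.velocity_gradients(state)
        gzz, gzr, grz, grr = grads
        return shear_rate_invariant(gzz, gzr, grz, grr, state.u_r, self.disc.cell_r)

    def update_viscosity(self, state: SimState, grads=None, relax: float | None = None):
        mu_new = carreau_viscosity(self.shear_rate(state, grads), self.props.carreau)
        a = self.cfg.relax_u if relax is None else relax
        state.mu = (1.0 - a) * state.mu + a * np.asarray(mu_new)
        return state.mu

    def viscous_dissipation(self, state: SimState, grads=None) -> np.ndarray:
        """mu * Phi, W/m^3, from the axisymmetric dissipation function."""
        if grads is None:
            grads = self.velocity_gradients(state)
        gzz, gzr, grz, grr = grads
        r = self.disc.cell_r
        hoop = np.where(r > 0, state.u_r / np.where(r > 0, r, 1.0), grr)
        divV = gzz + grr + hoop
        Phi = 2.0 * (grr**2 + hoop**2 + gzz**2) + (grz + gzr) ** 2 - (2.0 / 3.0) * divV**2
        return state.mu * np.maximum(Phi, 0.0)

    # ---------------------------------------------------------- SIMPLE parts
    def _momentum_systems(self, state, flux, t, dt, old: SimState | None):
        d, cfg = self.disc, self.cfg
        grads = self.velocity_gradients(state)
        gzz, gzr, grz, grr = grads
        self.update_viscosity(state, grads)
        mu = state.mu
        mu_f = d.face_interp(mu)
        mu_b = {name: mu[b["cells"]] for name, b in d.boundaries.items()}

        gp_z, gp_r = d.gradient(state.p, self.bcs_pressure(t))
        bc_uz, bc_ur = self.bcs_velocity()

        common = dict(
            Gamma_f=mu_f,
            flux=flux,
            dt=dt,
            rho_transient=self.props.rho if dt is not None else None,
            scheme=cfg.convection,
        )
        r = d.cell_r
        hoop_coeff = (2.0 if cfg.full_stress else 1.0) * mu / np.maximum(r, 1e-300) ** 2

        sys_z = discretize_transport(
            d,
            phi=state.u_z,
            phi_old=old.u_z if old is not None else None,
            S_P=-self._sigma_B2,
            S_c=self.kelvin_force,
            grad_phi=(gzz, gzr),
            **common,
        )
        sys_z.b -= gp_z * d.vol
        sys_r = discretize_transport(
            d,
            phi=state.u_r,
            phi_old=old.u_r if old is not None else None,
            S_P=-hoop_coeff,
            S_c=0.0,
            grad_phi=(grz, grr),
            **common,
        )
        sys_r.b -= gp_r * d.vol

        if cfg.full_stress:
            # explicit divergence of the transpose part of the stress tensor
            sys_z.b += d.divergence_explicit(mu * gzz, mu * grz)
            sys_r.b += d.divergence_explicit(mu * gzr, mu * grr)

        apply_boundary_conditions(sys_z, bcs=bc_uz, flux=flux, Gamma_b=mu_b, grad_phi=(gzz, gzr))
        apply_boundary_conditions(sys_r, bcs=bc_ur, flux=flux, Gamma_b=mu_b, grad_phi=(grz, grr))
        return sys_z, sys_r, (gp_z, gp_r)

    def face_fluxes(self, state: SimState, dvol: np.ndarray, grad_p, t: float) -> tuple:
        """Rhie-Chow mass fluxes and the pressure-correction coefficients."""
        d, rho = self.disc, self.props.rho
        gp_z, gp_r = grad_p
        uf_z = d.face_interp(state.u_z)
        uf_r = d.face_interp(state.u_r)
        mdot = rho * (uf_z * d.fAz + uf_r * d.fAr)
        dv_f = d.face_interp(dvol)
        cf = rho * dv_f * d.Ef
        gpz_f = d.face_interp(gp_z)
        gpr_f = d.face_interp(gp_r)
        mdot += cf * (
            (state.p[d.own] - state.p[d.nbr]) + gpz_f * d.fdz + gpr_f * d.fdr
        )

        bflux: dict[str, np.ndarray] = {}
        cb: dict[str, np.ndarray] = {}
        p_vals = {"inlet": inlet_pressure(t, self.pp), "outlet": 0.0}
        for name, b in d.boundaries.items():
            cells = b["cells"]
            if name == "wall":
                bflux[name] = np.zeros(cells.size)
                cb[name] = np.zeros(cells.size)
                continue
            m = rho * (state.u_z[cells] * b["Az"] + state.u_r[cells] * b["Ar"])
            c = rho * dvol[cells] * b["Eb"]
            p_b = p_vals[name]
            m = m + c * (
                (state.p[cells] - p_b) + gp_z[cells] * b["dz"] + gp_r[cells] * b["dr"]
            )
            bflux[name] = m
            cb[name] = c
        return FaceFlux(mdot, bflux), cf, cb

    def _pressure_correction(self, flux: FaceFlux, cf, cb):
        from .discretization import LinearSystem

        d = self.disc
        sysm = LinearSystem(d)
        sysm.diag += np.bincount(d.own, cf, minlength=d.n)
        sysm.diag += np.bincount(d.nbr, cf, minlength=d.n)
        sysm.off_own[:] -= cf
        sysm.off_nbr[:] -= cf
        for name in ("inlet", "outlet"):
            cells = d.boundaries[name]["cells"]
            np.add.at(sysm.diag, cells, cb[name])
        sysm.b = -flux.cell_divergence(d)
        return sysm.solve()

    def outer_iteration(self, state: SimState, t: float, dt, old: SimState | None):
        """One SIMPLE iteration in place; returns (mass_res, mom_res, flux)."""
        with np.errstate(over="ignore", invalid="ignore"):
            return self._outer_iteration(state, t, dt, old)

    def _outer_iteration(self, state: SimState, t: float, dt, old: SimState | None):
        d, cfg = self.disc, self.cfg

        # lagged fluxes for the momentum convection
        dvol0 = getattr(self, "_dvol", None)
        if dvol0 is None:
            dvol0 = np.zeros(d.n)  # no Rhie-Chow term before the first momentum solve
        gp = d.gradient(state.p, self.bcs_pressure(t))
        flux, cf, cb = self.face_fluxes(state, dvol0, gp, t)

        sys_z, sys_r, grad_p = self._momentum_systems(state, flux, t, dt, old)

        # normalized momentum residual before the solve
        res_z = sys_z.residual(state.u_z)
        res_r = sys_r.residual(state.u_r)
        scale = np.sum(np.abs(sys_z.diag * state.u_z)) + np.sum(np.abs(sys_z.b))
        mom_res = (np.sum(np.abs(res_z)) + np.sum(np.abs(res_r))) / max(scale, 1e-300)

        uz_star = sys_z.solve(cfg.relax_u, state.u_z)
        ur_star = sys_r.solve(cfg.relax_u, state.u_r)
        state.u_z, state.u_r = uz_star, ur_star

        if cfg.coupling == "simplec":
            # SIMPLEC: consistent with under-relaxation, allows relax_p ~ 1
            aP_z = sys_z.diag / cfg.relax_u + sys_z.offdiag_rowsum()
            aP_r = sys_r.diag / cfg.relax_u + sys_r.offdiag_rowsum()
        else:
            aP_z = sys_z.diag / cfg.relax_u
            aP_r = sys_r.diag / cfg.relax_u
        dvol = d.vol / np.maximum(0.5 * (aP_z + aP_r), 1e-300)
        self._dvol = dvol

        flux, cf, cb = self.face_fluxes(state, dvol, grad_p, t)
        div = flux.cell_divergence(d)
        m_ref = max(
            np.sum(np.abs(flux.boundary["inlet"])),
            np.sum(np.abs(flux.boundary["outlet"])),
        )
        mass_res = np.sum(np.abs(div)) / m_ref if m_ref > 1e-300 else np.sum(np.abs(div))

        p_prime = self._pressure_correction(flux, cf, cb)

        # corrections
        state.p = state.p + cfg.relax_p * p_prime
        bc_pp = {
            "inlet": BoundaryCondition("dirichlet", 0.0),
            "outlet": BoundaryCondition("dirichlet", 0.0),
            "wall": BoundaryCondition("zero_gradient"),
        }
        gpp_z, gpp_r = d.gradient(p_prime, bc_pp)
        state.u_z = state.u_z - dvol * gpp_z
        state.u_r = state.u_r - dvol * gpp_r
        flux.internal += cf * (p_prime[d.own] - p_prime[d.nbr])
        for name in ("inlet", "outlet"):
            cells = d.boundaries[name]["cells"]
            flux.boundary[name] += cb[name] * p_prime[cells]
        self._flux = flux
        return mass_res, mom_res, flux

    def simple_iterate(
        self, state: SimState, t: float, dt: float | None, old: SimState | None = None
    ) -> tuple[SimState, IterationReport]:
        """Iterate SIMPLE at one time level until the residuals drop.

        Converged when the normalized mass residual is below ``outer_tol``
        and the normalized momentum residual below ``mom_tol`` (both must
        have been evaluated at least twice so lagged coefficients settle).
        Raises :class:`SolverDivergence` if the residual grows by more than
        ``divergence_factor`` over its best value for ``divergence_patience``
        consecutive iterations.
        """
        cfg = self.cfg
        report = IterationReport()
        best = np.inf
        worse = 0
        for it in range(cfg.max_outer):
            mass_res, mom_res, _ = self.outer_iteration(state, t, dt, old)
            report.mass.append(float(mass_res))
            report.momentum.append(float(mom_res))
            report.outer_iterations = it + 1
            total = mass_res + mom_res
            if total < best:
                best = total
                worse = 0
            else:
                worse += 1
            if it >= 1 and mass_res < cfg.outer_tol and mom_res < cfg.mom_tol:
                report.converged = True
                break
            if (
                worse > cfg.divergence_patience
                and total > cfg.divergence_factor * max(best, 1e-300)
            ) or not np.isfinite(total):
                raise SolverDivergence(
                    f"SIMPLE diverged at t={t:.4g}: residual {total:.3e} "
                    f"(best {best:.3e}) after {it + 1} iterations",
                    history=report.mass,
                )
        return state, report

    # ---------------------------------------------------------------- energy
    def solve_energy(
        self, state: SimState, dt: float | None = None, T_old: np.ndarray | None = None
    ) -> np.ndarray:
        """Advance/solve the temperature with Joule + viscous-dissipation sources.

        Requires converged face fluxes from the last SIMPLE loop (uses
        lagged fluxes stored on the solver).  The magnetocaloric term is a
        hook that is identically zero for temperature-independent
        magnetization.
        """
        d, props = self.disc, self.props
        flux = getattr(self, "_flux", None)
        if flux is None:
            flux = FaceFlux(np.zeros(d.nf), {n: np.zeros(b["cells"].size) for n, b in d.boundaries.items()})
        cp = props.cp
        eflux = FaceFlux(flux.internal * cp, {k: v * cp for k, v in flux.boundary.items()})

        grads = self.velocity_gradients(state)
        S = joule_heating(state.u_z, self.B_cell, props.sigma)
        S = S + self.viscous_dissipation(state, grads)
        S = S + magnetocaloric_term(state.T, self.B_cell / self.mag.mu0_mag, 0.0, self.mag)

        bcs = self.bcs_temperature()
        gT = d.gradient(state.T, bcs)
        sysm = discretize_transport(
            d,
            phi=state.T,
            Gamma_f=props.k,
            flux=eflux,
            dt=dt,
            rho_transient=props.rho * cp if dt is not None else None,
            phi_old=T_old,
            S_c=S,
            scheme=self.cfg.convection,
            grad_phi=gT,
        )
        k_b = {name: props.k for name in d.boundaries}
        apply_boundary_conditions(sysm, bcs=bcs, flux=eflux, Gamma_b=k_b, grad_phi=gT)
        state.T = sysm.solve(self.cfg.relax_T, state.T)
        return state.T

    # ------------------------------------------------------------- stepping
    def advance(self, state: SimState) -> tuple[SimState, IterationReport]:
        """One backward-Euler step: SIMPLE loop then energy solve."""
        cfg = self.cfg
        dt = cfg.dt
        umax = float(np.max(np.hypot(state.u_z, state.u_r)))
        h = min(
            self.mesh.geom.L_vessel / self.mesh.nz,
            (self.mesh.geom.R0 - self.mesh.geom.delta) / self.mesh.nr,
        )
        cfl = umax * dt / h
        if cfl > 20.0:
            warnings.warn(
                f"advective CFL {cfl:.1f} is large; the implicit step remains "
                "stable but transients may be under-resolved",
                stacklevel=2,
            )
        old = state.copy()
        new = state.copy()
        t_new = state.t + dt
        new, report = self.simple_iterate(new, t_new, dt, old)
        self.solve_energy(new, dt=dt, T_old=old.T)
        new.t = t_new
        return new, report

    def steady_solve(self, state: SimState | None = None, t: float = 0.0, max_retries: int = 3):
        """Iterate to the steady state at frozen boundary pressure.

        Convection-dominated cases can destabilize aggressive
        under-relaxation factors; on divergence the solve restarts from
        rest with relax_u scaled by 0.75, up to ``max_retries`` times.
        """
        from dataclasses import replace as _replace

        cfg0 = self.cfg
        try:
            for attempt in range(max_retries + 1):
                st = state.copy() if state is not None else self.initial_state(t)
                try:
                    st, report = self.simple_iterate(st, t, dt=None, old=None)
                    self.solve_energy(st, dt=None)
                    st.t = t
                    return st, report
                except SolverDivergence:
                    if attempt == max_retries:
                        raise
                    self.cfg = _replace(
                        self.cfg,
                        relax_u=0.75 * self.cfg.relax_u,
                        relax_p=min(self.cfg.relax_p, 0.9),
                    )
                    self._dvol = None
                    warnings.warn(
                        f"steady solve diverged; retrying with relax_u="
                        f"{self.cfg.relax_u:.3f}",
                        stacklevel=2,
                    )
        finally:
            self.cfg = cfg0
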