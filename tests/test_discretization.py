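"""Generic convection-diffusion assembly against closed-form oracles."""

import numpy as np
import pytest

import stenoflow as sf
from stenoflow.discretization import (
    BoundaryCondition,
    Discretization,
    FaceFlux,
    apply_boundary_conditions,
    discretize_transport,
)
from stenoflow.rheology import shear_rate_invariant


def straight_disc(nz=24, nr=8, L=0.06, R=0.01):
    geom = sf.StenosisGeometry(R0=R, L_vessel=L, d=0.02, L0=0.01, delta=0.0)
    return Discretization(sf.build_mesh(geom, nz, nr))


def zero_flux(disc):
    return FaceFlux(
        np.zeros(disc.nf),
        {n: np.zeros(b["cells"].size) for n, b in disc.boundaries.items()},
    )


def axial_flux(disc, rho_u):
    """Uniform axial mass flux rho*u through every constant-z face."""
    mdot = rho_u * disc.fAz  # r-faces have fAz = 0 on a straight tube
    b = {}
    for name, bb in disc.boundaries.items():
        b[name] = rho_u * bb["Az"]
    return FaceFlux(mdot, b)


class TestDiffusionAssembly:
    def test_uniform_field_is_a_solution(self):
        disc = straight_disc()
        phi0 = 3.7
        phi = np.full(disc.n, phi0)
        sysm = discretize_transport(disc, phi=phi, Gamma_f=0.5, flux=None)
        bcs = {
            "inlet": BoundaryCondition("dirichlet", phi0),
            "outlet": BoundaryCondition("zero_gradient"),
            "wall": BoundaryCondition("zero_gradient"),
        }
        apply_boundary_conditions(sysm, bcs=bcs, Gamma_b={"inlet": 0.5})
        assert np.allclose(sysm.solve(), phi0, rtol=1e-12)

    def test_negative_diffusivity_rejected(self):
        disc = straight_disc(8, 4)
        with pytest.raises(ValueError):
            discretize_transport(disc, phi=np.zeros(disc.n), Gamma_f=-1.0, flux=None)

    def test_missing_boundary_condition_raises(self):
        disc = straight_disc(8, 4)
        sysm = discretize_transport(disc, phi=np.zeros(disc.n), Gamma_f=1.0, flux=None)
        with pytest.raises(KeyError):
            apply_boundary_conditions(sysm, bcs={"inlet": BoundaryCondition("zero_gradient")})


class TestTransientDecay:
    def test_backward_euler_pointwise_decay(self):
        # no flow, no diffusion, S_P = -c: phi_new = phi_old / (1 + c dt / rho)
        disc = straight_disc(8, 4)
        rho, c, dt = 1050.0, 4.0, 0.05
        rng = np.random.default_rng(0)
        phi_old = rng.uniform(1.0, 2.0, disc.n)
        sysm = discretize_transport(
            disc,
            phi=phi_old,
            Gamma_f=0.0,
            flux=None,
            rho_transient=rho,
            phi_old=phi_old,
            dt=dt,
            S_P=-c,
        )
        bcs = {n: BoundaryCondition("zero_gradient") for n in ("inlet", "outlet", "wall")}
        apply_boundary_conditions(sysm, bcs=bcs)
        expected = phi_old / (1.0 + c * dt / rho)
        assert np.allclose(sysm.solve(), expected, rtol=1e-12)


class TestAdvectionDiffusion:
    @staticmethod
    def solve_1d(disc, rho_u, Gamma):
        phi = np.zeros(disc.n)
        flux = axial_flux(disc, rho_u)
        sysm = discretize_transport(disc, phi=phi, Gamma_f=Gamma, flux=flux)
        bcs = {
            "inlet": BoundaryCondition("dirichlet", 0.0),
            "outlet": BoundaryCondition("dirichlet", 1.0),
            "wall": BoundaryCondition("zero_gradient"),
        }
        apply_boundary_conditions(sysm, bcs=bcs, flux=flux, Gamma_b={"inlet": Gamma, "outlet": Gamma})
        return sysm.solve()

    def test_exponential_profile_within_upwind_error(self):
        # steady 1D advection-diffusion: phi = (exp(Pe z/L)-1)/(exp(Pe)-1)
        L, R = 0.06, 0.01
        rho_u, Gamma = 2.0, 0.03
        errs = []
        for nz in (24, 48):
            disc = straight_disc(nz=nz, L=L, R=R)
            phi = self.solve_1d(disc, rho_u, Gamma)
            Pe = rho_u * L / Gamma
            exact = (np.exp(Pe * disc.cell_z / L) - 1.0) / (np.exp(Pe) - 1.0)
            errs.append(np.max(np.abs(phi - exact)))
            Pe_cell = rho_u * (L / nz) / Gamma
            assert errs[-1] < Pe_cell  # generous first-order bound
        assert errs[1] < errs[0] / 1.5  # first-order decrease under refinement


class TestGradients:
    def test_manufactured_field_gradient_second_order(self):
        errs = []
        for nz, nr in ((16, 8), (32, 16)):
            mesh, payload = sf.make_fixture("manufactured_field", seed=7, nz=nz, nr=nr)
            fld = payload["field"]
            disc = Discretization(mesh)

            def dirichlet_bcs(f):
                return {
                    n: BoundaryCondition("dirichlet", f(b["cz"], b["cr"]))
                    for n, b in disc.boundaries.items()
                }

            gzz, gzr = disc.gradient(payload["u_z"], dirichlet_bcs(fld.u_z))
            grz, grr = disc.gradient(payload["u_r"], dirichlet_bcs(fld.u_r))
            gd = shear_rate_invariant(gzz, gzr, grz, grr, payload["u_r"], disc.cell_r)
            exact = fld.shear_rate(disc.cell_z, disc.cell_r)
            interior = np.arange(disc.n).reshape(nz, nr)[2:-2, 2:-2].ravel()
            errs.append(
                np.sqrt(np.mean((gd[interior] - exact[interior]) ** 2)) / np.max(np.abs(exact))
            )
        order = np.log2(errs[0] / errs[1])
        assert order > 1.7  # nominally second order on the smooth grid

    def test_linear_field_gradient_exact_axially(self):
        disc = straight_disc(16, 8)
        a = 5.0
        phi = a * disc.cell_z
        bcs = {
            "inlet": BoundaryCondition("dirichlet", a * disc.boundaries["inlet"]["cz"]),
            "outlet": BoundaryCondition("dirichlet", a * disc.boundaries["outlet"]["cz"]),
            "wall": BoundaryCondition("zero_gradient"),
        }
        gz, gr = disc.gradient(phi, bcs)
        assert np.allclose(gz, a, rtol=1e-10)
        assert np.max(np.abs(gr)) < 1e-10 * a
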