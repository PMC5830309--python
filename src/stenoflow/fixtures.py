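"""Deterministic small meshes and manufactured fields for testing.

All randomness is seed-controlled; the solver itself is deterministic.
The manufactured field carries analytic velocity/temperature expressions
and their exact derivatives, so discrete operators (gradients, the
rate-of-strain invariant, dissipation) can be checked for their
convergence order under refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .geometry import AxiMesh, StenosisGeometry, build_mesh

__all__ = ["ManufacturedField", "make_fixture"]


@dataclass(frozen=True)
class ManufacturedField:
    """Smooth axisymmetric fields with exact in-plane derivatives."""

    u_z: Callable
    u_r: Callable
    T: Callable
    du_z_dz: Callable
    du_z_dr: Callable
    du_r_dz: Callable
    du_r_dr: Callable

    def shear_rate(self, z, r):
        """Analytic sqrt(2 D:D) at (z, r)."""
        gzz = self.du_z_dz(z, r)
        gzr = self.du_z_dr(z, r)
        grz = self.du_r_dz(z, r)
        grr = self.du_r_dr(z, r)
        ur = self.u_r(z, r)
        hoop = np.where(np.asarray(r) > 0, ur / np.where(np.asarray(r) > 0, r, 1.0), grr)
        return np.sqrt(2.0 * (grr**2 + hoop**2 + gzz**2) + (grz + gzr) ** 2)


def make_fixture(kind: str, seed: int = 0, nz: int | None = None, nr: int | None = None):
    """Small deterministic test inputs.

    * ``straight_tube`` — 16x8 untapered vessel mesh, quiescent fields.
    * ``tiny_stenosis`` — 24x8 mesh of the 50 % base-case stenosis.
    * ``manufactured_field`` — straight-tube mesh plus a
      :class:`ManufacturedField` whose amplitudes and wavenumbers derive
      from ``seed`` (identical seed, identical fixture).

    Returns ``(mesh, payload)`` where payload is a dict of flat cell
    arrays (and the ``ManufacturedField`` for the manufactured kind).
    """
    if kind == "straight_tube":
        geom = StenosisGeometry(R0=0.01, L_vessel=0.07, d=0.02, L0=0.02, delta=0.0)
        mesh = build_mesh(geom, nz or 16, nr or 8)
        zeros = np.zeros(mesh.n_cells)
        return mesh, {"u_z": zeros.copy(), "u_r": zeros.copy(), "T": np.full(mesh.n_cells, 310.0)}

    if kind == "tiny_stenosis":
        geom = StenosisGeometry(
            R0=0.01, L_vessel=0.07, d=0.02 - 0.01412, L0=0.02824, delta=0.005
        )
        mesh = build_mesh(geom, nz or 24, nr or 8)
        zeros = np.zeros(mesh.n_cells)
        return mesh, {"u_z": zeros.copy(), "u_r": zeros.copy(), "T": np.full(mesh.n_cells, 310.0)}

    if kind == "manufactured_field":
        rng = np.random.default_rng(seed)
        geom = StenosisGeometry(R0=0.01, L_vessel=0.07, d=0.02, L0=0.02, delta=0.0)
        mesh = build_mesh(geom, nz or 16, nr or 8)
        R, L = geom.R0, geom.L_vessel
        U0 = 0.1 * (1.0 + 0.5 * rng.random())
        V0 = 0.02 * (1.0 + 0.5 * rng.random())
        kz = np.pi / L * (1 + rng.integers(1, 3))
        T0, dT = 310.0, 2.0 * rng.random()

        # u_r ~ r near the axis (regularity) and smooth elsewhere
        fld = ManufacturedField(
            u_z=lambda z, r: U0 * np.cos(kz * z) * (1.0 - (r / R) ** 2),
            u_r=lambda z, r: V0 * np.sin(kz * z) * (r / R) * (1.0 - (r / R) ** 2),
            T=lambda z, r: T0 + dT * np.cos(kz * z) * (r / R) ** 2,
            du_z_dz=lambda z, r: -U0 * kz * np.sin(kz * z) * (1.0 - (r / R) ** 2),
            du_z_dr=lambda z, r: -2.0 * U0 * np.cos(kz * z) * r / R**2,
            du_r_dz=lambda z, r: V0 * kz * np.cos(kz * z) * (r / R) * (1.0 - (r / R) ** 2),
            du_r_dr=lambda z, r: V0 * np.sin(kz * z) * (1.0 / R) * (1.0 - 3.0 * (r / R) ** 2),
        )
        z, r = mesh.zc.ravel(), mesh.rc.ravel()
        payload = {
            "u_z": fld.u_z(z, r),
            "u_r": fld.u_r(z, r),
            "T": fld.T(z, r),
            "field": fld,
        }
        return mesh, payload

    raise ValueError(
        f"unknown fixture kind {kind!r}; "
        "available: straight_tube, tiny_stenosis, manufactured_field"
    )
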