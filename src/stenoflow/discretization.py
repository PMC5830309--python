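"""Finite-volume discretization on the body-fitted axisymmetric mesh.

Collocated cell-centred variables; face fluxes by momentum-weighted
(Rhie-Chow) interpolation are handled in :mod:`stenoflow.solver`.  This
module owns the mesh connectivity, Green-Gauss gradients, and the generic
convection-diffusion assembly used for momentum, pressure correction and
energy:

    rho_c d(phi)/dt + sum_f mdot_f phi_f = sum_f Gamma_f (grad phi . A)_f
                                           + (S_P phi + S_c) dV

Convection is first-order upwind with an optional deferred-correction
linear-upwind scheme (Barth-Jespersen limited).  Diffusion uses the
over-relaxed decomposition: an implicit orthogonal part Gamma |A|^2/(A.d)
and an explicit non-orthogonal remainder driven by cell gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import AxiMesh

__all__ = [
    "Discretization",
    "BoundaryCondition",
    "LinearSystem",
    "FaceFlux",
    "discretize_transport",
    "apply_boundary_conditions",
]

_ZERO_AREA = 1.0e-300


@dataclass(frozen=True)
class BoundaryCondition:
    """Boundary treatment for one scalar on one boundary group.

    kind : "dirichlet" | "zero_gradient" | "mixed"
        "mixed" is Dirichlet on faces selected by ``mask`` and zero-gradient
        elsewhere (used for the partially cooled wall).
    value : scalar or per-face array (Dirichlet value); ignored otherwise.
    """

    kind: str
    value: float | np.ndarray | None = None
    mask: np.ndarray | None = None

    def dirichlet_mask(self, n: int) -> np.ndarray:
        if self.kind == "dirichlet":
            return np.ones(n, dtype=bool)
        if self.kind == "mixed":
            return np.asarray(self.mask, dtype=bool)
        return np.zeros(n, dtype=bool)

    def values(self, n: int) -> np.ndarray:
        v = np.zeros(n)
        if self.value is not None:
            v[:] = self.value
        return v


class Discretization:
    """Connectivity and metric arrays derived from an :class:`AxiMesh`.

    Internal faces are the concatenation of constant-z faces (planes
    i = 1..nz-1) and sloped constant-eta faces (levels j = 1..nr-1).
    Boundary groups: "inlet" (z = 0), "outlet" (z = L), "wall" (j = nr).
    Axis faces have identically zero area and carry no flux.
    """

    def __init__(self, mesh: AxiMesh):
        self.mesh = mesh
        nz, nr = mesh.nz, mesh.nr
        self.n = nz * nr

        ii, jj = np.meshgrid(np.arange(nz), np.arange(nr), indexing="ij")
        self.cell_z = mesh.zc.ravel()
        self.cell_r = mesh.rc.ravel()
        self.vol = mesh.vol.ravel()
        self.area_planar = mesh.area_planar.ravel()

        # ---- internal faces -------------------------------------------------
        # z-faces between (i-1, j) and (i, j), i = 1..nz-1
        iz, jz = np.meshgrid(np.arange(1, nz), np.arange(nr), indexing="ij")
        own_z = ((iz - 1) * nr + jz).ravel()
        nbr_z = (iz * nr + jz).ravel()
        Az_z = mesh.zf_Az[1:-1, :].ravel()
        Ar_z = np.zeros_like(Az_z)
        cz_z = mesh.zf_cz[1:-1, :].ravel()
        cr_z = mesh.zf_cr[1:-1, :].ravel()
        # r-faces between (i, j-1) and (i, j), j = 1..nr-1
        ir, jr = np.meshgrid(np.arange(nz), np.arange(1, nr), indexing="ij")
        own_r = (ir * nr + (jr - 1)).ravel()
        nbr_r = (ir * nr + jr).ravel()
        Az_r = mesh.rf_Az[:, 1:-1].ravel()
        Ar_r = mesh.rf_Ar[:, 1:-1].ravel()
        cz_r = mesh.rf_cz[:, 1:-1].ravel()
        cr_r = mesh.rf_cr[:, 1:-1].ravel()

        self.own = np.concatenate([own_z, own_r])
        self.nbr = np.concatenate([nbr_z, nbr_r])
        self.fAz = np.concatenate([Az_z, Az_r])
        self.fAr = np.concatenate([Ar_z, Ar_r])
        self.fcz = np.concatenate([cz_z, cz_r])
        self.fcr = np.concatenate([cr_z, cr_r])
        self.nf = self.own.size

        dz = self.cell_z[self.nbr] - self.cell_z[self.own]
        dr = self.cell_r[self.nbr] - self.cell_r[self.own]
        self.fdz, self.fdr = dz, dr
        A_dot_d = self.fAz * dz + self.fAr * dr
        A2 = self.fAz**2 + self.fAr**2
        self.Ef = A2 / np.maximum(A_dot_d, _ZERO_AREA)  # orthogonal diffusion metric
        self.Tfz = self.fAz - self.Ef * dz  # non-orthogonal remainder vector
        self.Tfr = self.fAr - self.Ef * dr
        # linear interpolation weight of the OWN cell
        d_own = np.hypot(self.fcz - self.cell_z[self.own], self.fcr - self.cell_r[self.own])
        d_nbr = np.hypot(self.fcz - self.cell_z[self.nbr], self.fcr - self.cell_r[self.nbr])
        self.w = d_nbr / np.maximum(d_own + d_nbr, _ZERO_AREA)

        # ---- boundary groups ------------------------------------------------
        self.boundaries: dict[str, dict[str, np.ndarray]] = {}
        j_all = np.arange(nr)
        self._add_boundary(
            "inlet",
            cells=(0 * nr + j_all),
            Az=-mesh.zf_Az[0, :],
            Ar=np.zeros(nr),
            cz=mesh.zf_cz[0, :],
            cr=mesh.zf_cr[0, :],
        )
        self._add_boundary(
            "outlet",
            cells=((nz - 1) * nr + j_all),
            Az=mesh.zf_Az[-1, :],
            Ar=np.zeros(nr),
            cz=mesh.zf_cz[-1, :],
            cr=mesh.zf_cr[-1, :],
        )
        i_all = np.arange(nz)
        self._add_boundary(
            "wall",
            cells=(i_all * nr + (nr - 1)),
            Az=mesh.rf_Az[:, -1],
            Ar=mesh.rf_Ar[:, -1],
            cz=mesh.rf_cz[:, -1],
            cr=mesh.rf_cr[:, -1],
        )

        # fixed sparsity pattern: diagonal + one entry per internal face per side
        self._rows = np.concatenate([np.arange(self.n), self.own, self.nbr])
        self._cols = np.concatenate([np.arange(self.n), self.nbr, self.own])

    def _add_boundary(self, name, cells, Az, Ar, cz, cr):
        dz = cz - self.cell_z[cells]
        dr = cr - self.cell_r[cells]
        A_dot_d = Az * dz + Ar * dr
        A2 = Az**2 + Ar**2
        Eb = A2 / np.maximum(A_dot_d, _ZERO_AREA)
        self.boundaries[name] = {
            "cells": np.asarray(cells),
            "Az": np.asarray(Az, dtype=float),
            "Ar": np.asarray(Ar, dtype=float),
            "cz": np.asarray(cz, dtype=float),
            "cr": np.asarray(cr, dtype=float),
            "dz": dz,
            "dr": dr,
            "Eb": Eb,
            "Tbz": Az - Eb * dz,
            "Tbr": Ar - Eb * dr,
        }

    # ---- gradients ---------------------------------------------------------
    def gradient(self, phi: np.ndarray, bcs: dict[str, BoundaryCondition]):
        """Green-Gauss cell gradient (d(phi)/dz, d(phi)/dr).

        Boundary face values follow the supplied boundary conditions
        (Dirichlet value, or the cell value for zero-gradient faces).  The
        azimuthal hoop closure subtracts phi_P * Ap from the radial sum.
        """
        phif = self.w * phi[self.own] + (1.0 - self.w) * phi[self.nbr]
        gz = np.zeros(self.n)
        gr = np.zeros(self.n)
        np.add.at(gz, self.own, phif * self.fAz)
        np.add.at(gr, self.own, phif * self.fAr)
        np.add.at(gz, self.nbr, -phif * self.fAz)
        np.add.at(gr, self.nbr, -phif * self.fAr)
        for name, b in self.boundaries.items():
            bc = bcs.get(name)
            cells = b["cells"]
            vb = phi[cells].copy()
            if bc is not None:
                m = bc.dirichlet_mask(cells.size)
                vals = bc.values(cells.size)
                vb[m] = vals[m]
            np.add.at(gz, cells, vb * b["Az"])
            np.add.at(gr, cells, vb * b["Ar"])
        gr -= phi * self.area_planar
        return gz / self.vol, gr / self.vol

    def face_interp(self, phi: np.ndarray) -> np.ndarray:
        return self.w * phi[self.own] + (1.0 - self.w) * phi[self.nbr]

    def divergence_explicit(self, qz, qr, bz=None, br=None) -> np.ndarray:
        """Cell divergence of a vector field given at cell centres.

        Used for the explicit transpose-stress terms.  ``bz, br``: optional
        dict name -> per-face boundary vector components (default: cell value).
        """
        qzf = self.face_interp(qz)
        qrf = self.face_interp(qr)
        div = np.zeros(self.n)
        flux = qzf * self.fAz + qrf * self.fAr
        np.add.at(div, self.own, flux)
        np.add.at(div, self.nbr, -flux)
        for name, b in self.boundaries.items():
            cells = b["cells"]
            qzb = bz[name] if bz and name in bz else qz[cells]
            qrb = br[name] if br and name in br else qr[cells]
            np.add.at(div, cells, qzb * b["Az"] + qrb * b["Ar"])
        return div

    def csr(self, diag: np.ndarray, off: np.ndarray) -> sp.csr_matrix:
        vals = np.concatenate([diag, off])
        return sp.csr_matrix((vals, (self._rows, self._cols)), shape=(self.n, self.n))


@dataclass
class FaceFlux:
    """Mass fluxes (per radian, kg/s) through internal and boundary faces."""

    internal: np.ndarray  # outward from own -> nbr
    boundary: dict[str, np.ndarray]  # outward through each boundary group

    def cell_divergence(self, disc: Discretization) -> np.ndarray:
        div = np.zeros(disc.n)
        np.add.at(div, disc.own, self.internal)
        np.add.at(div, disc.nbr, -self.internal)
        for name, m in self.boundary.items():
            np.add.at(div, disc.boundaries[name]["cells"], m)
        return div

    def boundary_total(self, name: str) -> float:
        return float(np.sum(self.boundary[name]))


class LinearSystem:
    """One implicit transport system with the fixed mesh sparsity pattern.

    ``diag``: (n,) diagonal; ``off``: (2*nf,) off-diagonal values ordered
    [own-row entries, nbr-row entries]; ``b``: right-hand side.
    """

    def __init__(self, disc: Discretization):
        self.disc = disc
        self.diag = np.zeros(disc.n)
        self.off = np.zeros(2 * disc.nf)
        self.b = np.zeros(disc.n)

    @property
    def off_own(self) -> np.ndarray:  # entries A[own, nbr]
        return self.off[: self.disc.nf]

    @property
    def off_nbr(self) -> np.ndarray:  # entries A[nbr, own]
        return self.off[self.disc.nf :]

    def matrix(self) -> sp.csr_matrix:
        return self.disc.csr(self.diag, self.off)

    def offdiag_rowsum(self) -> np.ndarray:
        """Row sums of the off-diagonal entries (negative for M-matrices)."""
        s = np.bincount(self.disc.own, self.off_own, minlength=self.disc.n)
        s += np.bincount(self.disc.nbr, self.off_nbr, minlength=self.disc.n)
        return s

    def residual(self, phi: np.ndarray) -> np.ndarray:
        return self.b - self.matrix() @ phi

    def solve(self, relax: float = 1.0, phi_prev: np.ndarray | None = None) -> np.ndarray:
        """Direct sparse solve with implicit under-relaxation."""
        if relax < 1.0:
            if phi_prev is None:
                raise ValueError("under-relaxation requires the previous iterate")
            diag = self.diag / relax
            b = self.b + (1.0 - relax) / relax * self.diag * phi_prev
            A = self.disc.csr(diag, self.off)
            return spla.spsolve(A, b)
        return spla.spsolve(self.matrix(), self.b)


def _upwind_value(disc, phi, mdot):
    return np.where(mdot >= 0.0, phi[disc.own], phi[disc.nbr])


def _bj_limiter(disc, phi, gz, gr):
    """Barth-Jespersen scalar limiter per cell over the face stencil."""
    n = disc.n
    phimax = phi.copy()
    phimin = phi.copy()
    np.maximum.at(phimax, disc.own, phi[disc.nbr])
    np.maximum.at(phimax, disc.nbr, phi[disc.own])
    np.minimum.at(phimin, disc.own, phi[disc.nbr])
    np.minimum.at(phimin, disc.nbr, phi[disc.own])
    psi = np.ones(n)
    for cells, dz, dr in (
        (disc.own, disc.fcz - disc.cell_z[disc.own], disc.fcr - disc.cell_r[disc.own]),
        (disc.nbr, disc.fcz - disc.cell_z[disc.nbr], disc.fcr - disc.cell_r[disc.nbr]),
    ):
        dphi = gz[cells] * dz + gr[cells] * dr
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(
                dphi > 0,
                (phimax[cells] - phi[cells]) / np.where(dphi == 0, 1.0, dphi),
                np.where(
                    dphi < 0,
                    (phimin[cells] - phi[cells]) / np.where(dphi == 0, 1.0, dphi),
                    1.0,
                ),
            )
        np.minimum.at(psi, cells, np.clip(ratio, 0.0, 1.0))
    return psi


def discretize_transport(
    disc: Discretization,
    *,
    phi: np.ndarray,
    Gamma_f: np.ndarray | float,
    flux: FaceFlux | None,
    rho_transient: np.ndarray | float | None = None,
    phi_old: np.ndarray | None = None,
    dt: float | None = None,
    S_P: np.ndarray | float = 0.0,
    S_c: np.ndarray | float = 0.0,
    scheme: str = "upwind",
    grad_phi: tuple[np.ndarray, np.ndarray] | None = None,
) -> LinearSystem:
    """Assemble one implicit convection-diffusion system.

    ``phi`` is the current iterate (used for deferred corrections and the
    limiter); ``Gamma_f`` the diffusivity at internal faces (scalar or
    per-face); ``flux`` the mass fluxes (None for pure diffusion);
    ``S_P <= 0`` enters the diagonal as -S_P dV keeping the matrix an
    M-matrix, ``S_c`` the explicit source density.  Transient term is
    backward Euler when ``dt`` is given.  Boundary conditions are applied
    separately via :func:`apply_boundary_conditions`.
    """
    Gamma_f = np.broadcast_to(np.asarray(Gamma_f, dtype=float), (disc.nf,))
    if np.any(Gamma_f < 0):
        raise ValueError("negative diffusivity")
    sysm = LinearSystem(disc)

    # transient (backward Euler)
    if dt is not None:
        if phi_old is None or rho_transient is None:
            raise ValueError("transient term needs phi_old and rho_transient")
        M = np.broadcast_to(np.asarray(rho_transient, dtype=float), (disc.n,)) * disc.vol / dt
        sysm.diag += M
        sysm.b += M * phi_old

    # diffusion: implicit orthogonal part, explicit non-orthogonal remainder
    D = Gamma_f * disc.Ef
    sysm.diag += np.bincount(disc.own, D, minlength=disc.n)
    sysm.diag += np.bincount(disc.nbr, D, minlength=disc.n)
    sysm.off_own[:] -= D
    sysm.off_nbr[:] -= D
    if grad_phi is not None:
        gz, gr = grad_phi
        gzf = disc.face_interp(gz)
        grf = disc.face_interp(gr)
        corr = Gamma_f * (gzf * disc.Tfz + grf * disc.Tfr)
        np.add.at(sysm.b, disc.own, corr)
        np.add.at(sysm.b, disc.nbr, -corr)

    # convection: implicit upwind (+ optional limited deferred correction)
    if flux is not None:
        m = flux.internal
        mp = np.maximum(m, 0.0)
        mm = np.minimum(m, 0.0)
        sysm.diag += np.bincount(disc.own, mp, minlength=disc.n)
        sysm.diag += np.bincount(disc.nbr, -mm, minlength=disc.n)
        sysm.off_own[:] += mm
        sysm.off_nbr[:] -= mp
        if scheme == "linear-upwind":
            if grad_phi is None:
                raise ValueError("linear-upwind scheme needs cell gradients")
            gz, gr = grad_phi
            psi = _bj_limiter(disc, phi, gz, gr)
            up = np.where(m >= 0.0, disc.own, disc.nbr)
            dphi = gz[up] * (disc.fcz - disc.cell_z[up]) + gr[up] * (
                disc.fcr - disc.cell_r[up]
            )
            corr = m * psi[up] * dphi
            np.add.at(sysm.b, disc.own, -corr)
            np.add.at(sysm.b, disc.nbr, corr)

    # linearized source
    S_P = np.broadcast_to(np.asarray(S_P, dtype=float), (disc.n,))
    S_c = np.broadcast_to(np.asarray(S_c, dtype=float), (disc.n,))
    sysm.diag -= S_P * disc.vol
    sysm.b += S_c * disc.vol
    return sysm


def apply_boundary_conditions(
    sysm: LinearSystem,
    *,
    bcs: dict[str, BoundaryCondition],
    flux: FaceFlux | None = None,
    Gamma_b: dict[str, np.ndarray | float] | None = None,
    grad_phi: tuple[np.ndarray, np.ndarray] | None = None,
    conv_factor: float = 1.0,
) -> LinearSystem:
    """Fold boundary faces into an assembled transport system.

    Dirichlet faces contribute an implicit one-sided diffusion flux
    ``Gamma Eb (phi_b - phi_P)`` and carry the boundary value into inflow
    convection.  Zero-gradient faces contribute no diffusion and advect the
    cell value (implicitly) through outflow and inflow alike.
    ``conv_factor`` scales convective fluxes (cp for the energy equation).
    Missing boundary groups in ``bcs`` raise ``KeyError``.
    """
    disc = sysm.disc
    for name, b in disc.boundaries.items():
        if name not in bcs:
            raise KeyError(f"missing boundary condition for '{name}'")
        bc = bcs[name]
        cells = b["cells"]
        nb = cells.size
        mask = bc.dirichlet_mask(nb)
        vals = bc.values(nb)

        if Gamma_b is not None and name in Gamma_b and np.any(mask):
            G = np.broadcast_to(np.asarray(Gamma_b[name], dtype=float), (nb,))
            Db = np.where(mask, G * b["Eb"], 0.0)
            np.add.at(sysm.diag, cells, Db)
            np.add.at(sysm.b, cells, Db * vals)
            if grad_phi is not None:
                gz, gr = grad_phi
                corr = np.where(mask, G * (gz[cells] * b["Tbz"] + gr[cells] * b["Tbr"]), 0.0)
                np.add.at(sysm.b, cells, corr)

        if flux is not None:
            mb = conv_factor * flux.boundary[name]
            # outflow always advects the cell value; inflow brings phi_b on
            # Dirichlet faces and the cell value on zero-gradient faces.
            out_part = np.maximum(mb, 0.0)
            in_part = np.minimum(mb, 0.0)
            np.add.at(sysm.diag, cells, out_part)
            np.add.at(sysm.b, cells, -in_part * np.where(mask, vals, 0.0))
            np.add.at(sysm.diag, cells, np.where(mask, 0.0, in_part))
    return sysm
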