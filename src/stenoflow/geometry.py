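"""Stenosed-vessel geometry and the axisymmetric finite-volume mesh.

The lumen wall is described by a piecewise radius profile r(z): a linear
converging ramp over the proximal half of the stenosis, a cosine diverging
ramp over the distal half, and the unobstructed radius R0 elsewhere.  A
symmetric double-cosine variant is available for sensitivity studies.

The mesh is a structured, body-fitted quadrilateral grid in (z, eta) with
eta = r / r_wall(z) in [0, 1].  All areas and volumes are per unit radian of
azimuth (the 2*pi factor cancels in every balance).  Face-area vectors are
exact polygon integrals of r along each straight edge, so the discrete
metric identity  sum_faces A + A_hoop * e_r = 0  holds to round-off for
every cell, where A_hoop is the planar cell area acting on the azimuthal
"hoop" closure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StenosisGeometry",
    "AxiMesh",
    "stenosis_radius",
    "build_mesh",
    "refine_mesh",
]


@dataclass(frozen=True)
class StenosisGeometry:
    """Parametric description of an axisymmetric stenosed vessel.

    Parameters
    ----------
    R0 : float
        Unobstructed vessel radius, m.
    L_vessel : float
        Vessel length, m.
    d : float
        Axial position where the stenosis begins, m.
    L0 : float
        Stenosis length, m (the throat sits at ``d + L0/2``).
    delta : float
        Stenosis height, m.  The blockage fraction is ``delta / R0``.
    symmetric : bool
        If True use a symmetric double-cosine bump instead of the default
        linear-converging / cosine-diverging profile.
    """

    R0: float
    L_vessel: float
    d: float
    L0: float
    delta: float
    symmetric: bool = False

    def __post_init__(self) -> None:
        if not (self.R0 > 0 and self.L_vessel > 0 and self.L0 > 0):
            raise ValueError("R0, L_vessel and L0 must be positive")
        if not (0.0 <= self.delta < self.R0):
            raise ValueError(
                f"stenosis height delta={self.delta} must satisfy 0 <= delta < R0={self.R0}"
            )
        if self.d < 0 or self.d + self.L0 > self.L_vessel + 1e-12 * self.L_vessel:
            raise ValueError("stenosis [d, d+L0] must lie inside [0, L_vessel]")

    @property
    def blockage_fraction(self) -> float:
        return self.delta / self.R0

    @property
    def throat_z(self) -> float:
        return self.d + 0.5 * self.L0

    def radius(self, z):
        return stenosis_radius(z, self)


def stenosis_radius(z, geom: StenosisGeometry):
    """Lumen radius r(z) of the stenosed vessel, m.

    Piecewise profile: linear taper on (d, d + L0/2], cosine recovery on
    (d + L0/2, d + L0], and R0 otherwise.  Continuous at the joints; the
    minimum radius R0 - delta occurs at the throat z = d + L0/2.

    Accepts scalars or arrays; raises ``ValueError`` for z outside
    [0, L_vessel].
    """
    z = np.asarray(z, dtype=float)
    scalar = z.ndim == 0
    z = np.atleast_1d(z)
    tol = 1e-12 * geom.L_vessel
    if np.any(z < -tol) or np.any(z > geom.L_vessel + tol):
        raise ValueError("axial position outside [0, L_vessel]")

    R0, d, L0, delta = geom.R0, geom.d, geom.L0, geom.delta
    r = np.full_like(z, R0)
    if geom.symmetric:
        in_sten = (z > d) & (z <= d + L0)
        zs = z[in_sten]
        r[in_sten] = R0 - 0.5 * delta * (1.0 - np.cos(2.0 * np.pi * (zs - d) / L0))
    else:
        conv = (z > d) & (z <= d + 0.5 * L0)
        div = (z > d + 0.5 * L0) & (z <= d + L0)
        # linear converging ramp: r/R0 = 1 - (2 delta / (R0 L0)) (z - d)
        r[conv] = R0 * (1.0 - 2.0 * delta / (R0 * L0) * (z[conv] - d))
        # cosine diverging ramp: r/R0 = 1 - (delta / 2R0)(1 + cos(2 pi/L0 (z - d - L0/2)))
        r[div] = R0 * (
            1.0
            - delta
            / (2.0 * R0)
            * (1.0 + np.cos(2.0 * np.pi / L0 * (z[div] - d - 0.5 * L0)))
        )
    return float(r[0]) if scalar else r


@dataclass
class AxiMesh:
    """Structured body-fitted axisymmetric finite-volume grid.

    Cells are indexed ``(i, j)`` with ``i`` axial (0-based from the inlet)
    and ``j`` radial (0-based from the axis), flattened as ``k = i*nr + j``.
    Vertices live at ``z = i * L/nz`` and ``r = (j/nr) * r_wall(z)``.

    Face bookkeeping (all areas per unit radian):

    * z-faces — constant-z quadrilateral faces between axially adjacent
      cells, area vector ``(A_z, 0)`` with ``A_z = (r_top^2 - r_bot^2)/2``.
    * r-faces — generally sloped faces between radially adjacent cells,
      area vector ``(-dr*(r1+r2)/2, dz*(r1+r2)/2)`` pointing outward from
      the lower-j cell.  Faces on the axis have exactly zero area.
    * the hoop closure — each cell's planar area ``Ap`` acts as an implicit
      azimuth-facing face with area vector ``(0, -Ap)``; including it the
      outward face-area vectors of every cell sum to the zero vector.
    """

    geom: StenosisGeometry
    nz: int
    nr: int
    # vertices
    zv: np.ndarray = field(repr=False)  # (nz+1,)
    rv: np.ndarray = field(repr=False)  # (nz+1, nr+1)
    # cell metrics
    zc: np.ndarray = field(repr=False)  # (nz, nr) centroid z
    rc: np.ndarray = field(repr=False)  # (nz, nr) centroid r
    vol: np.ndarray = field(repr=False)  # (nz, nr) per-radian volume
    area_planar: np.ndarray = field(repr=False)  # (nz, nr) planar area
    # z-face metrics, shape (nz+1, nr): plane i between cells i-1 and i
    zf_Az: np.ndarray = field(repr=False)
    zf_cz: np.ndarray = field(repr=False)
    zf_cr: np.ndarray = field(repr=False)
    # r-face metrics, shape (nz, nr+1): level j between cells j-1 and j
    rf_Az: np.ndarray = field(repr=False)
    rf_Ar: np.ndarray = field(repr=False)
    rf_cz: np.ndarray = field(repr=False)
    rf_cr: np.ndarray = field(repr=False)

    @property
    def n_cells(self) -> int:
        return self.nz * self.nr

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nz, self.nr)

    def cell_index(self, i, j):
        return i * self.nr + j

    def wall_radius_faces(self) -> np.ndarray:
        """Mid-edge radius of each wall face (j = nr), shape (nz,)."""
        return 0.5 * (self.rv[:-1, -1] + self.rv[1:, -1])

    def closed_cell_area_sums(self) -> np.ndarray:
        """Residual of the metric identity per cell, shape (nz, nr, 2).

        Sums outward face-area vectors (z- and r-faces plus the hoop
        closure ``(0, -Ap)``).  Zero to round-off on a valid mesh.
        """
        sz = self.zf_Az[1:, :] - self.zf_Az[:-1, :]
        sz = sz + (self.rf_Az[:, 1:] - self.rf_Az[:, :-1])
        sr = self.rf_Ar[:, 1:] - self.rf_Ar[:, :-1] - self.area_planar
        return np.stack([sz, sr], axis=-1)


def _segment_metrics(z1, r1, z2, r2):
    """Per-radian area vector and area centroid of a straight wall segment.

    The outward normal is taken on the (+r-ish) side obtained by rotating
    the tangent (dz, dr) by -90 degrees: n ~ (-dr, dz).
    """
    dz = z2 - z1
    dr = r2 - r1
    rbar = 0.5 * (r1 + r2)
    Az = -dr * rbar  # equals -(r2^2 - r1^2)/2 exactly
    Ar = dz * rbar
    cz = 0.5 * (z1 + z2)
    cr = rbar
    return Az, Ar, cz, cr


def _polygon_cell_metrics(zq, rq):
    """Planar area, per-radian volume and centroid of quadrilateral cells.

    ``zq, rq``: arrays (..., 4) of vertex coordinates in counter-clockwise
    order.  Uses exact polygon integrals: Ap = -oint r dz,
    V = -oint r^2/2 dz (per unit radian).
    """
    z2 = np.roll(zq, -1, axis=-1)
    r2 = np.roll(rq, -1, axis=-1)
    dz = z2 - zq
    Ap = -np.sum(dz * 0.5 * (rq + r2), axis=-1)
    vol = -np.sum(dz * (rq * rq + rq * r2 + r2 * r2) / 6.0, axis=-1)
    # planar centroid via shoelace moments (orientation-safe through /Ap)
    cross = zq * r2 - z2 * rq
    A_sl = 0.5 * np.sum(cross, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cz = np.sum((zq + z2) * cross, axis=-1) / (6.0 * A_sl)
        cr = np.sum((rq + r2) * cross, axis=-1) / (6.0 * A_sl)
    return Ap, vol, cz, cr


def _mesh_from_vertices(geom: StenosisGeometry, zv: np.ndarray, rv: np.ndarray) -> AxiMesh:
    nz = zv.size - 1
    nr = rv.shape[1] - 1

    # cell vertex loops, CCW: (i,j) -> (i+1,j) -> (i+1,j+1) -> (i,j+1)
    zq = np.stack(
        [
            np.broadcast_to(zv[:-1, None], (nz, nr)),
            np.broadcast_to(zv[1:, None], (nz, nr)),
            np.broadcast_to(zv[1:, None], (nz, nr)),
            np.broadcast_to(zv[:-1, None], (nz, nr)),
        ],
        axis=-1,
    )
    rq = np.stack([rv[:-1, :-1], rv[1:, :-1], rv[1:, 1:], rv[:-1, 1:]], axis=-1)
    Ap, vol, cz, cr = _polygon_cell_metrics(zq, rq)
    if np.any(vol <= 0):
        raise ValueError("mesh has non-positive cell volumes (degenerate geometry?)")

    # z-faces: at plane i, radial strip [rv[i,j], rv[i,j+1]]
    r_lo = rv[:, :-1]
    r_hi = rv[:, 1:]
    zf_Az = 0.5 * (r_hi**2 - r_lo**2)  # (nz+1, nr), normal +z
    zf_cz = np.broadcast_to(zv[:, None], zf_Az.shape).copy()
    zf_cr = 0.5 * (r_lo + r_hi)

    # r-faces: at level j, segment (zv[i], rv[i,j]) -> (zv[i+1], rv[i+1,j])
    z1 = np.broadcast_to(zv[:-1, None], (nz, nr + 1))
    z2 = np.broadcast_to(zv[1:, None], (nz, nr + 1))
    r1 = rv[:-1, :]
    r2 = rv[1:, :]
    rf_Az, rf_Ar, rf_cz, rf_cr = _segment_metrics(z1, r1, z2, r2)

    return AxiMesh(
        geom=geom,
        nz=nz,
        nr=nr,
        zv=zv,
        rv=rv,
        zc=cz,
        rc=cr,
        vol=vol,
        area_planar=Ap,
        zf_Az=zf_Az,
        zf_cz=zf_cz,
        zf_cr=zf_cr,
        rf_Az=rf_Az,
        rf_Ar=rf_Ar,
        rf_cz=rf_cz,
        rf_cr=rf_cr,
    )


def build_mesh(geom: StenosisGeometry, nz: int, nr: int) -> AxiMesh:
    """Build the body-fitted structured grid for a stenosed vessel.

    Vertex radii follow ``r = eta * r_wall(z)`` with uniform eta and z
    spacing, so the wall row of vertices lies exactly on the stenosis
    profile and every column carries ``nr`` cells across the local lumen.
    """
    if nz < 4 or nr < 4:
        raise ValueError("need nz >= 4 and nr >= 4")
    if geom.delta >= geom.R0:
        raise ValueError("degenerate geometry: delta >= R0 closes the lumen")
    zv = np.linspace(0.0, geom.L_vessel, nz + 1)
    eta = np.linspace(0.0, 1.0, nr + 1)
    rwall = stenosis_radius(zv, geom)
    rv = rwall[:, None] * eta[None, :]
    return _mesh_from_vertices(geom, zv, rv)


def refine_mesh(mesh: AxiMesh, factor: int = 2, resample_wall: bool = True) -> AxiMesh:
    """Nested refinement multiplying cell counts by ``factor`` per direction.

    With ``resample_wall=True`` (default) new wall vertices are placed on
    the exact stenosis profile, which is what a grid-convergence sequence
    needs.  With ``resample_wall=False`` new vertices are linear blends of
    the parent's, so child volumes sum to the parent volume to round-off.
    """
    if factor < 2:
        raise ValueError("refinement factor must be >= 2")
    if resample_wall:
        return build_mesh(mesh.geom, mesh.nz * factor, mesh.nr * factor)
    nz2 = mesh.nz * factor
    nr2 = mesh.nr * factor
    zv2 = np.linspace(mesh.zv[0], mesh.zv[-1], nz2 + 1)
    # bilinear interpolation of the vertex radii in (i, j) index space
    ii = np.linspace(0.0, mesh.nz, nz2 + 1)
    jj = np.linspace(0.0, mesh.nr, nr2 + 1)
    i0 = np.clip(np.floor(ii).astype(int), 0, mesh.nz - 1)
    j0 = np.clip(np.floor(jj).astype(int), 0, mesh.nr - 1)
    fi = (ii - i0)[:, None]
    fj = (jj - j0)[None, :]
    rv = mesh.rv
    rv2 = (
        rv[np.ix_(i0, j0)] * (1 - fi) * (1 - fj)
        + rv[np.ix_(i0 + 1, j0)] * fi * (1 - fj)
        + rv[np.ix_(i0, j0 + 1)] * (1 - fi) * fj
        + rv[np.ix_(i0 + 1, j0 + 1)] * fi * fj
    )
    return _mesh_from_vertices(mesh.geom, zv2, rv2)
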