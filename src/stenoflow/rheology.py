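"""Carreau shear-thinning rheology for blood.

Whole blood thins with shear: viscosity falls from a zero-shear plateau
``mu1`` to a high-shear plateau ``mu_inf`` as the shear rate grows past
``1/lam``.  The Carreau law

    mu(gamma_dot) = mu_inf + (mu1 - mu_inf) * (1 + (lam*gamma_dot)^2)^((n-1)/2)

with 0 < n < 1 interpolates smoothly between the plateaus.  Default
constants are the standard literature fit for blood: mu1 = 0.056 Pa.s,
mu_inf = 0.036 Pa.s, lam = 3.313 s, n = 0.3568.

The scalar shear rate fed to the law is the second invariant of the
rate-of-strain tensor, gamma_dot = sqrt(2 D:D), evaluated in axisymmetric
cylindrical coordinates (including the hoop term u_r/r).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CarreauParams", "BLOOD_CARREAU", "carreau_viscosity", "shear_rate_invariant"]


@dataclass(frozen=True)
class CarreauParams:
    """Four-parameter Carreau viscosity law.

    mu1 : zero-shear viscosity, Pa.s
    mu_inf : infinite-shear viscosity, Pa.s
    lam : relaxation time, s
    n : power index (dimensionless); n = 1 is Newtonian with mu = mu1
    """

    mu1: float = 0.056
    mu_inf: float = 0.036
    lam: float = 3.313
    n: float = 0.3568

    def __post_init__(self) -> None:
        if self.mu1 <= 0 or self.mu_inf <= 0:
            raise ValueError("viscosity plateaus must be positive")
        if self.mu_inf > self.mu1:
            raise ValueError("require mu_inf <= mu1 (shear-thinning or Newtonian)")
        if self.lam <= 0:
            raise ValueError("relaxation time lam must be positive")
        if not (0.0 < self.n <= 1.0):
            raise ValueError("power index n must lie in (0, 1]")

    @classmethod
    def newtonian(cls, mu: float) -> "CarreauParams":
        """Constant-viscosity degenerate case (mu1 = mu_inf = mu)."""
        return cls(mu1=mu, mu_inf=mu, lam=1.0, n=1.0)

    @property
    def is_newtonian(self) -> bool:
        return self.mu1 == self.mu_inf or self.n == 1.0


BLOOD_CARREAU = CarreauParams()


def carreau_viscosity(gamma_dot, p: CarreauParams = BLOOD_CARREAU):
    """Dynamic viscosity (Pa.s) at shear rate ``gamma_dot`` (1/s).

    Monotone non-increasing in gamma_dot, bounded in [mu_inf, mu1].
    Negative shear rates raise ``ValueError`` (the invariant is >= 0 by
    construction).
    """
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    mu = p.mu_inf + (p.mu1 - p.mu_inf) * (1.0 + (p.lam * g) ** 2) ** (0.5 * (p.n - 1.0))
    return float(mu) if np.isscalar(gamma_dot) or np.ndim(gamma_dot) == 0 else mu


def shear_rate_invariant(dudz_z, dudr_z, dudz_r, dudr_r, u_r, r):
    """Scalar shear rate sqrt(2 D:D) in axisymmetric cylindrical coordinates.

    Parameters are the four in-plane velocity-gradient components
    (``dudz_z`` = d(u_z)/dz, ``dudr_z`` = d(u_z)/dr, ``dudz_r`` = d(u_r)/dz,
    ``dudr_r`` = d(u_r)/dr), the radial velocity and the radius (for the
    hoop strain u_r/r; r = 0 entries use the symmetry limit u_r/r -> du_r/dr).

    2 D:D = 2[(du_r/dr)^2 + (u_r/r)^2 + (du_z/dz)^2] + (du_r/dz + du_z/dr)^2
    """
    dudz_z = np.asarray(dudz_z, dtype=float)
    hoop = np.where(
        np.asarray(r) > 0.0,
        np.divide(u_r, r, out=np.zeros_like(dudz_z), where=np.asarray(r) > 0),
        dudr_r,
    )
    dd2 = 2.0 * (np.asarray(dudr_r) ** 2 + hoop**2 + dudz_z**2) + (
        np.asarray(dudz_r) + np.asarray(dudr_z)
    ) ** 2
    out = np.sqrt(dd2)
    return float(out) if out.ndim == 0 else out
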