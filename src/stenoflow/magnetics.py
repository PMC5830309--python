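"""Applied magnetic field, Lorentz damping, Joule heating and magnetization force.

The vessel sits in a transverse static field applied over an axial window
(typically the distal portion of the vessel).  Under the low-magnetic-
Reynolds-number approximation the induced field is neglected and the current
density follows Ohm's law for a moving conductor, J = sigma (V x B).

A uniform transverse field is not exactly axisymmetric, so the model uses
the standard biofluid-dynamics reduction: the azimuthally averaged Lorentz
force is a pure damping -sigma B^2 u_z on the axial velocity, and the Joule
source is sigma B^2 u_z^2 >= 0.  This is exactly the momentum equation whose
straight-tube steady solution is the modified-Bessel Hartmann profile used
for validation.

Magnetization is linear and temperature-independent, M = chi * H, which
makes the magnetocaloric term mu0 T (dM/dT) DH/Dt identically zero; the
term is kept as an explicit hook returning zero so a temperature-dependent
law can be plugged in later.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

MU0_MAG = 4.0e-7 * np.pi  # vacuum permeability, T*m/A

__all__ = [
    "MagneticConfig",
    "field_envelope",
    "field_envelope_gradient",
    "lorentz_force_axial",
    "joule_heating",
    "magnetization_force",
    "magnetocaloric_term",
    "hartmann_number",
    "b0_for_hartmann",
]


@dataclass(frozen=True)
class MagneticConfig:
    """Applied-field description and electrical properties.

    B0 : applied transverse induction magnitude, T
    z_on, z_off : axial extent of the magnetized window, m
    ramp_len : half-width of the C1 cosine ramps smoothing the window edges, m
    chi : magnetic susceptibility (default 0: blood's volume
        susceptibility is ~1e-6, making the Kelvin force negligible next
        to the Lorentz damping at the field strengths studied; set it
        explicitly to activate the magnetization body force)
    sigma : electrical conductivity, S/m (blood: 0.8)
    mu0_mag : vacuum permeability, T*m/A
    """

    B0: float = 0.0
    z_on: float = 0.0
    z_off: float = 0.0
    ramp_len: float = 0.0
    chi: float = 0.0
    sigma: float = 0.8
    mu0_mag: float = MU0_MAG

    def __post_init__(self) -> None:
        if self.B0 < 0:
            raise ValueError("B0 must be >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.B0 > 0 and not (self.z_on < self.z_off):
            raise ValueError("magnetized window requires z_on < z_off")
        if self.ramp_len < 0:
            raise ValueError("ramp_len must be >= 0")

    def hartmann(self, R0: float, mu_ref: float) -> float:
        return hartmann_number(self.B0, R0, self.sigma, mu_ref)

    def with_hartmann(self, Ha: float, R0: float, mu_ref: float) -> "MagneticConfig":
        """Return a copy whose B0 realizes the requested Hartmann number."""
        return replace(self, B0=b0_for_hartmann(Ha, R0, self.sigma, mu_ref))


def field_envelope(z, cfg: MagneticConfig):
    """Local induction magnitude B(z), T.

    Plateau B0 on [z_on, z_off], zero outside [z_on - ramp_len,
    z_off + ramp_len], C1-smooth half-cosine ramps in between (value B0/2 at
    the ramp midpoints).  ``ramp_len = 0`` gives a sharp window.
    """
    z = np.asarray(z, dtype=float)
    if cfg.B0 == 0.0:
        out = np.zeros_like(z)
        return float(out) if out.ndim == 0 else out
    env = np.ones_like(z)
    if cfg.ramp_len > 0:
        up = (z > cfg.z_on - cfg.ramp_len) & (z < cfg.z_on)
        dn = (z > cfg.z_off) & (z < cfg.z_off + cfg.ramp_len)
        env[up] = 0.5 * (1.0 + np.cos(np.pi * (cfg.z_on - z[up]) / cfg.ramp_len))
        env[dn] = 0.5 * (1.0 + np.cos(np.pi * (z[dn] - cfg.z_off) / cfg.ramp_len))
        env[(z <= cfg.z_on - cfg.ramp_len) | (z >= cfg.z_off + cfg.ramp_len)] = 0.0
    else:
        env[(z < cfg.z_on) | (z > cfg.z_off)] = 0.0
    out = cfg.B0 * env
    return float(out) if out.ndim == 0 else out


def field_envelope_gradient(z, cfg: MagneticConfig):
    """Analytic dB/dz of the envelope, T/m (nonzero only on the ramps)."""
    z = np.asarray(z, dtype=float)
    g = np.zeros_like(z)
    if cfg.B0 == 0.0 or cfg.ramp_len == 0.0:
        return float(g) if g.ndim == 0 else g
    up = (z > cfg.z_on - cfg.ramp_len) & (z < cfg.z_on)
    dn = (z > cfg.z_off) & (z < cfg.z_off + cfg.ramp_len)
    a = np.pi / cfg.ramp_len
    g[up] = 0.5 * cfg.B0 * a * np.sin(a * (cfg.z_on - z[up]))
    g[dn] = -0.5 * cfg.B0 * a * np.sin(a * (z[dn] - cfg.z_off))
    return float(g) if g.ndim == 0 else g


def lorentz_force_axial(u_z, B_local, sigma):
    """Azimuthally averaged Lorentz body force on u_z, N/m^3.

    For V perpendicular to a transverse B, sigma (V x B) x B reduces to the
    damping -sigma B^2 u_z: always opposing the motion.
    """
    return -np.asarray(sigma) * np.asarray(B_local) ** 2 * np.asarray(u_z)


def joule_heating(u_z, B_local, sigma):
    """Volumetric Joule source J.J/sigma = sigma B^2 u_z^2 >= 0, W/m^3."""
    return np.asarray(sigma) * np.asarray(B_local) ** 2 * np.asarray(u_z) ** 2


def magnetization_force(H_local, grad_H, cfg: MagneticConfig):
    """Kelvin body force mu0 M grad(H) with the linear law M = chi H, N/m^3.

    Zero wherever the field is uniform (grad H = 0) and for chi = 0.
    """
    return cfg.mu0_mag * cfg.chi * np.asarray(H_local) * np.asarray(grad_H)


def magnetocaloric_term(T, H_local, dH_dt, cfg: MagneticConfig):
    """Magnetocaloric source mu0 T (dM/dT) DH/Dt, W/m^3.

    With the temperature-independent law M = chi H this is identically
    zero; kept as an explicit hook for temperature-dependent magnetization.
    """
    return np.zeros_like(np.asarray(T, dtype=float))


def hartmann_number(B0: float, R0: float, sigma: float, mu_ref: float) -> float:
    """Ha = B0 R0 sqrt(sigma / mu_ref).

    The reference viscosity is the high-shear plateau mu_inf, which governs
    the thin near-wall (Hartmann-type) layers.
    """
    if mu_ref <= 0:
        raise ValueError("reference viscosity must be positive")
    if R0 <= 0 or sigma < 0 or B0 < 0:
        raise ValueError("require R0 > 0, sigma >= 0, B0 >= 0")
    return B0 * R0 * np.sqrt(sigma / mu_ref)


def b0_for_hartmann(Ha: float, R0: float, sigma: float, mu_ref: float) -> float:
    """Invert the Hartmann-number definition for the induction magnitude."""
    if Ha < 0:
        raise ValueError("Ha must be >= 0")
    if sigma == 0:
        if Ha > 0:
            raise ValueError("cannot realize Ha > 0 with sigma = 0")
        return 0.0
    return Ha / (R0 * np.sqrt(sigma / mu_ref))
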