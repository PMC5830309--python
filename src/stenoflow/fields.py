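"""Field containers and scalar laws used by the finite-volume solver."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .rheology import BLOOD_CARREAU, CarreauParams

__all__ = ["FluidProps", "PulsatilePressure", "SolverConfig", "SimState", "inlet_pressure"]


@dataclass(frozen=True)
class FluidProps:
    """Bulk thermophysical properties of blood (SI units).

    rho : density, kg/m^3 (blood: 1050)
    cp : specific heat, J/(kg K) (blood: 3490)
    k : thermal conductivity, W/(m K) (blood: ~0.52)
    sigma : electrical conductivity, S/m (blood: 0.8)
    carreau : shear-thinning viscosity law
    """

    rho: float = 1050.0
    cp: float = 3490.0
    k: float = 0.52
    sigma: float = 0.8
    carreau: CarreauParams = field(default_factory=lambda: BLOOD_CARREAU)

    def __post_init__(self) -> None:
        if min(self.rho, self.cp, self.k) <= 0 or self.sigma < 0:
            raise ValueError("fluid properties must be positive (sigma >= 0)")


@dataclass(frozen=True)
class PulsatilePressure:
    """Sinusoidal driving pressure P(t) = Pm (1 + eps sin(omega0 t)).

    Pm : mean inlet gauge pressure, Pa
    eps : amplitude ratio Ps/Pm in [0, 1) so the pressure never reverses
    omega0 : angular frequency, rad/s (2*pi for a 1 Hz heartbeat)
    """

    Pm: float
    eps: float = 0.2
    omega0: float = 2.0 * np.pi

    def __post_init__(self) -> None:
        if not (0.0 <= self.eps < 1.0):
            raise ValueError("amplitude ratio eps must lie in [0, 1)")
        if self.omega0 <= 0:
            raise ValueError("omega0 must be positive")

    def __call__(self, t: float) -> float:
        return inlet_pressure(t, self)

    @property
    def period(self) -> float:
        return 2.0 * np.pi / self.omega0


def inlet_pressure(t, pp: PulsatilePressure):
    """Instantaneous inlet gauge pressure, Pa."""
    t = np.asarray(t, dtype=float)
    out = pp.Pm * (1.0 + pp.eps * np.sin(pp.omega0 * t))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SolverConfig:
    """Numerical controls for the SIMPLE time-marching solver.

    All tolerances are relative.  ``outer_tol`` bounds the normalized mass
    residual; ``mom_tol`` the normalized momentum residual at which the
    outer loop may stop.  ``steady=True`` drops the transient term and
    iterates straight to the steady state.
    """

    dt: float = 0.01
    t_end: float = 1.0
    outer_tol: float = 1.0e-6
    mom_tol: float = 1.0e-5
    max_outer: int = 2000
    relax_u: float = 0.9
    relax_p: float = 0.95
    relax_T: float = 1.0
    linear_tol: float = 1.0e-10
    steady: bool = False
    coupling: str = "simplec"  # "simplec" | "simple"
    convection: str = "upwind"  # "upwind" | "linear-upwind"
    full_stress: bool = True  # False: literal constant-viscosity Laplacian form
    T_inlet: float = 310.0
    cooled_wall: bool = False
    T_cool: float | None = None  # defaults to T_inlet
    divergence_patience: int = 50
    divergence_factor: float = 1.0e4

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_end < 0:
            raise ValueError("dt must be positive and t_end >= 0")
        for a in (self.relax_u, self.relax_p, self.relax_T):
            if not (0.0 < a <= 1.0):
                raise ValueError("under-relaxation factors must lie in (0, 1]")
        if min(self.outer_tol, self.mom_tol, self.linear_tol) <= 0:
            raise ValueError("tolerances must be positive")
        if self.convection not in ("upwind", "linear-upwind"):
            raise ValueError("convection must be 'upwind' or 'linear-upwind'")


@dataclass
class SimState:
    """Collocated cell-centred fields at one time level (flattened, k = i*nr + j)."""

    u_z: np.ndarray
    u_r: np.ndarray
    p: np.ndarray
    T: np.ndarray
    mu: np.ndarray
    t: float = 0.0

    @classmethod
    def zeros(cls, n_cells: int, mu0: float, T0: float = 310.0) -> "SimState":
        return cls(
            u_z=np.zeros(n_cells),
            u_r=np.zeros(n_cells),
            p=np.zeros(n_cells),
            T=np.full(n_cells, float(T0)),
            mu=np.full(n_cells, float(mu0)),
            t=0.0,
        )

    def copy(self) -> "SimState":
        return SimState(
            u_z=self.u_z.copy(),
            u_r=self.u_r.copy(),
            p=self.p.copy(),
            T=self.T.copy(),
            mu=self.mu.copy(),
            t=self.t,
        )
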