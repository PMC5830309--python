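"""Scenario configuration: schema, validation, units, presets and round-trip.

A scenario is one YAML document with blocks ``geometry``, ``rheology``,
``fluid``, ``magnetics``, ``pressure``, ``solver`` and ``output``.  All
internal quantities are strict SI; config values may carry explicit unit
suffixes for the units the vascular literature mixes freely::

    geometry:
      R0: "1 cm"
      L_vessel: "7 cm"
      stenosis_length: "2.824 cm"
      blockage_fraction: 0.5
    pressure:
      Pm: "0.26 mmHg"

Unknown keys are hard errors (no silent typos), and all validation
failures in a file are reported together with their key paths.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .fields import FluidProps, PulsatilePressure, SolverConfig
from .geometry import StenosisGeometry
from .magnetics import MU0_MAG, MagneticConfig, b0_for_hartmann
from .rheology import CarreauParams

__all__ = ["Scenario", "OutputConfig", "ScenarioError", "load_scenario", "save_scenario", "preset", "PRESET_NAMES"]

# Mean driving pressure of the base case, Pa: gives a straight-tube
# Newtonian (mu = mu_inf) mean-flow Reynolds number of about 100.
PM_BASE = 34.6
_LOW_DP_FRACTION = 0.75  # "low driving pressure" cases relative to the base

_LENGTH_UNITS = {"m": 1.0, "cm": 1e-2, "mm": 1e-3}
_PRESSURE_UNITS = {"pa": 1.0, "kpa": 1e3, "mmhg": 133.322387415}
_QTY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([a-zA-Z]+)\s*$")


class ScenarioError(ValueError):
    """Aggregated configuration errors, each tagged with its key path."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid scenario:\n  - " + "\n  - ".join(self.errors))


def _parse_quantity(value, units: dict[str, float], path: str, errors: list[str]) -> float:
    if isinstance(value, (int, float)):
        return float(value)
    m = _QTY_RE.match(str(value))
    if not m:
        errors.append(f"{path}: cannot parse quantity {value!r}")
        return np.nan
    num, unit = float(m.group(1)), m.group(2).lower()
    if unit not in units:
        errors.append(f"{path}: unknown unit {m.group(2)!r} (allowed: {sorted(units)})")
        return np.nan
    return num * units[unit]


@dataclass(frozen=True)
class OutputConfig:
    snapshot_times: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    probe_stations: tuple[float, ...] = (0.002, 0.02, 0.04)
    outdir: str | None = None


@dataclass(frozen=True)
class Scenario:
    """Fully resolved, validated simulation case."""

    name: str
    geometry: StenosisGeometry
    fluid: FluidProps
    magnetics: MagneticConfig
    pressure: PulsatilePressure
    solver: SolverConfig
    outputs: OutputConfig = field(default_factory=OutputConfig)
    mesh_nz: int = 96
    mesh_nr: int = 32

    def config_hash(self) -> str:
        """Stable hash of the resolved configuration (reproducibility log)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_dict(self) -> dict:
        def py(x):
            return float(x) if isinstance(x, (np.floating, np.integer)) else x

        g, f, m, pp, s, o = (
            self.geometry,
            self.fluid,
            self.magnetics,
            self.pressure,
            self.solver,
            self.outputs,
        )
        c = f.carreau
        return {
            "name": self.name,
            "geometry": {
                "R0": g.R0,
                "L_vessel": g.L_vessel,
                "stenosis_onset": g.d,
                "stenosis_length": g.L0,
                "blockage_fraction": g.delta / g.R0,
                "symmetric": g.symmetric,
            },
            "rheology": {
                "model": "newtonian" if c.is_newtonian else "carreau",
                "mu1": c.mu1,
                "mu_inf": c.mu_inf,
                "lam": c.lam,
                "n": c.n,
            },
            "fluid": {"rho": f.rho, "cp": f.cp, "k": f.k, "sigma": f.sigma},
            "magnetics": {
                "B0": py(m.B0),
                "z_on": py(m.z_on),
                "z_off": py(m.z_off),
                "ramp_len": py(m.ramp_len),
                "chi": py(m.chi),
            },
            "pressure": {"Pm": pp.Pm, "eps": pp.eps, "omega0": pp.omega0},
            "solver": {
                "dt": s.dt,
                "t_end": s.t_end,
                "outer_tol": s.outer_tol,
                "mom_tol": s.mom_tol,
                "max_outer": s.max_outer,
                "relax_u": s.relax_u,
                "relax_p": s.relax_p,
                "relax_T": s.relax_T,
                "steady": s.steady,
                "coupling": s.coupling,
                "convection": s.convection,
                "full_stress": s.full_stress,
                "T_inlet": s.T_inlet,
                "cooled_wall": s.cooled_wall,
                "T_cool": s.T_cool,
            },
            "mesh": {"nz": self.mesh_nz, "nr": self.mesh_nr},
            "output": {
                "snapshot_times": list(o.snapshot_times),
                "probe_stations": list(o.probe_stations),
                "outdir": o.outdir,
            },
        }


_SCHEMA = {
    "name": None,
    "geometry": {
        "R0",
        "L_vessel",
        "stenosis_onset",
        "stenosis_length",
        "blockage_fraction",
        "delta",
        "throat_z",
        "symmetric",
    },
    "rheology": {"model", "mu1", "mu_inf", "lam", "n", "mu"},
    "fluid": {"rho", "cp", "k", "sigma"},
    "magnetics": {"B0", "Ha", "z_on", "z_off", "ramp_len", "chi"},
    "pressure": {"Pm", "eps", "omega0"},
    "solver": {
        "dt",
        "t_end",
        "outer_tol",
        "mom_tol",
        "max_outer",
        "relax_u",
        "relax_p",
        "relax_T",
        "steady",
        "coupling",
        "convection",
        "full_stress",
        "T_inlet",
        "cooled_wall",
        "T_cool",
    },
    "mesh": {"nz", "nr"},
    "output": {"snapshot_times", "probe_stations", "outdir"},
}


def _check_unknown(doc: dict, errors: list[str]) -> None:
    for block, keys in doc.items():
        if block not in _SCHEMA:
            errors.append(f"{block}: unknown block (allowed: {sorted(_SCHEMA)})")
            continue
        if _SCHEMA[block] is None or not isinstance(keys, dict):
            continue
        for k in keys:
            if k not in _SCHEMA[block]:
                errors.append(f"{block}.{k}: unknown key (allowed: {sorted(_SCHEMA[block])})")


def _build(doc: dict, errors: list[str]) -> Scenario | None:
    base = preset("paper_case_50pct")
    name = doc.get("name", base.name)

    g = doc.get("geometry", {}) or {}
    R0 = _parse_quantity(g.get("R0", base.geometry.R0), _LENGTH_UNITS, "geometry.R0", errors)
    L = _parse_quantity(
        g.get("L_vessel", base.geometry.L_vessel), _LENGTH_UNITS, "geometry.L_vessel", errors
    )
    L0 = _parse_quantity(
        g.get("stenosis_length", base.geometry.L0), _LENGTH_UNITS, "geometry.stenosis_length", errors
    )
    if "delta" in g and "blockage_fraction" in g:
        errors.append("geometry: give either delta or blockage_fraction, not both")
    if "delta" in g:
        delta = _parse_quantity(g["delta"], _LENGTH_UNITS, "geometry.delta", errors)
    else:
        bf = g.get("blockage_fraction", base.geometry.delta / base.geometry.R0)
        if not isinstance(bf, (int, float)) or not (0.0 <= float(bf) < 1.0):
            errors.append(f"geometry.blockage_fraction: must be a number in [0, 1), got {bf!r}")
            bf = 0.5
        delta = float(bf) * R0
    if "stenosis_onset" in g and "throat_z" in g:
        errors.append("geometry: give either stenosis_onset or throat_z, not both")
    if "throat_z" in g:
        d_on = _parse_quantity(g["throat_z"], _LENGTH_UNITS, "geometry.throat_z", errors) - 0.5 * L0
    elif "stenosis_onset" in g:
        d_on = _parse_quantity(g["stenosis_onset"], _LENGTH_UNITS, "geometry.stenosis_onset", errors)
    else:
        d_on = base.geometry.d
    symmetric = bool(g.get("symmetric", False))

    r = doc.get("rheology", {}) or {}
    model = r.get("model", "carreau")
    if model == "newtonian":
        mu = float(r.get("mu", r.get("mu_inf", 0.036)))
        carreau = CarreauParams.newtonian(mu)
    elif model == "carreau":
        carreau = CarreauParams(
            mu1=float(r.get("mu1", 0.056)),
            mu_inf=float(r.get("mu_inf", 0.036)),
            lam=float(r.get("lam", 3.313)),
            n=float(r.get("n", 0.3568)),
        )
    else:
        errors.append(f"rheology.model: must be 'carreau' or 'newtonian', got {model!r}")
        carreau = CarreauParams()

    fl = doc.get("fluid", {}) or {}
    fluid = None
    try:
        fluid = FluidProps(
            rho=float(fl.get("rho", 1050.0)),
            cp=float(fl.get("cp", 3490.0)),
            k=float(fl.get("k", 0.52)),
            sigma=float(fl.get("sigma", 0.8)),
            carreau=carreau,
        )
    except ValueError as e:
        errors.append(f"fluid: {e}")

    mg = doc.get("magnetics", {}) or {}
    if "B0" in mg and "Ha" in mg:
        errors.append("magnetics: give exactly one of B0 or Ha, not both")
    throat = d_on + 0.5 * L0
    z_on = _parse_quantity(mg.get("z_on", throat), _LENGTH_UNITS, "magnetics.z_on", errors)
    z_off = _parse_quantity(mg.get("z_off", L), _LENGTH_UNITS, "magnetics.z_off", errors)
    ramp = _parse_quantity(mg.get("ramp_len", 0.1 * L0), _LENGTH_UNITS, "magnetics.ramp_len", errors)
    sigma = fluid.sigma if fluid else 0.8
    if "Ha" in mg:
        try:
            B0 = b0_for_hartmann(float(mg["Ha"]), R0, sigma, carreau.mu_inf)
        except ValueError as e:
            errors.append(f"magnetics.Ha: {e}")
            B0 = 0.0
    else:
        B0 = float(mg.get("B0", 0.0))
    magnetics = None
    try:
        magnetics = MagneticConfig(
            B0=B0,
            z_on=z_on,
            z_off=z_off,
            ramp_len=ramp,
            chi=float(mg.get("chi", 0.0)),
            sigma=sigma,
            mu0_mag=MU0_MAG,
        )
    except ValueError as e:
        errors.append(f"magnetics: {e}")

    pr = doc.get("pressure", {}) or {}
    pressure = None
    try:
        pressure = PulsatilePressure(
            Pm=_parse_quantity(pr.get("Pm", PM_BASE), _PRESSURE_UNITS, "pressure.Pm", errors),
            eps=float(pr.get("eps", 0.2)),
            omega0=float(pr.get("omega0", 2.0 * np.pi)),
        )
    except ValueError as e:
        errors.append(f"pressure: {e}")

    sv = doc.get("solver", {}) or {}
    solver = None
    try:
        solver = SolverConfig(**{k: v for k, v in sv.items()})
    except (TypeError, ValueError) as e:
        errors.append(f"solver: {e}")

    me = doc.get("mesh", {}) or {}
    nz = int(me.get("nz", 96))
    nr = int(me.get("nr", 32))
    if nz < 4 or nr < 4:
        errors.append(f"mesh: nz={nz}, nr={nr} must both be >= 4")

    ou = doc.get("output", {}) or {}
    outputs = OutputConfig(
        snapshot_times=tuple(float(x) for x in ou.get("snapshot_times", (0.0, 0.25, 0.5, 0.75, 1.0))),
        probe_stations=tuple(float(x) for x in ou.get("probe_stations", (0.002, 0.02, 0.04))),
        outdir=ou.get("outdir"),
    )

    geometry = None
    try:
        geometry = StenosisGeometry(
            R0=R0, L_vessel=L, d=d_on, L0=L0, delta=delta, symmetric=symmetric
        )
    except ValueError as e:
        errors.append(f"geometry: {e}")

    # cross-field consistency
    if solver is not None:
        for ts in outputs.snapshot_times:
            if not (0.0 <= ts <= solver.t_end + 1e-12):
                errors.append(f"output.snapshot_times: {ts} outside [0, t_end={solver.t_end}]")
    for zs in outputs.probe_stations:
        if not (0.0 <= zs <= L):
            errors.append(f"output.probe_stations: {zs} outside [0, L_vessel={L}]")

    if errors:
        return None
    return Scenario(
        name=name,
        geometry=geometry,
        fluid=fluid,
        magnetics=magnetics,
        pressure=pressure,
        solver=solver,
        outputs=outputs,
        mesh_nz=nz,
        mesh_nr=nr,
    )


def load_scenario(path_or_dict) -> Scenario:
    """Load and validate a scenario; an empty file yields the base case.

    Raises :class:`ScenarioError` listing every schema and physics
    violation with its key path.
    """
    if isinstance(path_or_dict, dict):
        doc = path_or_dict
    else:
        with open(path_or_dict) as fh:
            doc = yaml.safe_load(fh)
    if doc is None:
        return preset("paper_case_50pct")
    if not isinstance(doc, dict):
        raise ScenarioError(["top level must be a mapping of config blocks"])
    errors: list[str] = []
    _check_unknown(doc, errors)
    sc = _build(doc, errors)
    if errors or sc is None:
        raise ScenarioError(errors or ["unknown configuration failure"])
    return sc


def save_scenario(sc: Scenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(sc.to_dict(), fh, sort_keys=False)


# ------------------------------------------------------------------ presets
PRESET_NAMES = ("paper_case_50pct", "joule_60pct_lowdp", "ha_sweep", "blockage_sweep")

_BASE_GEOM = dict(R0=0.01, L0=0.02824, delta=0.005)


def _base_scenario(name: str, **over) -> Scenario:
    geom = StenosisGeometry(
        R0=0.01,
        L_vessel=over.pop("L_vessel", 0.07),
        d=0.02 - 0.5 * 0.02824,  # throat at z = 2 cm
        L0=0.02824,
        delta=over.pop("delta", 0.005),
    )
    fluid = FluidProps()
    Ha = over.pop("Ha", 0.0)
    B0 = b0_for_hartmann(Ha, geom.R0, fluid.sigma, fluid.carreau.mu_inf)
    magnetics = MagneticConfig(
        B0=B0,
        z_on=geom.throat_z,
        z_off=geom.L_vessel,
        ramp_len=0.1 * geom.L0,
        sigma=fluid.sigma,
    )
    pressure = PulsatilePressure(Pm=over.pop("Pm", PM_BASE), eps=over.pop("eps", 0.2))
    solver = SolverConfig(cooled_wall=over.pop("cooled_wall", False))
    nz = over.pop("nz", 96)
    nr = over.pop("nr", 32)
    if over:
        raise TypeError(f"unknown overrides: {sorted(over)}")
    return Scenario(
        name=name,
        geometry=geom,
        fluid=fluid,
        magnetics=magnetics,
        pressure=pressure,
        solver=solver,
        mesh_nz=nz,
        mesh_nr=nr,
    )


def preset(name: str):
    """Named scenarios mirroring the study's cases.

    * ``paper_case_50pct`` — 50 % blockage, 7 cm vessel, no applied field.
    * ``joule_60pct_lowdp`` — 60 % blockage, 6 cm vessel, Ha = 1, cooled
      distal stenosis wall, low driving pressure (post-throat recirculation
      regime).
    * ``ha_sweep`` — list of three base cases at Ha = 0, 0.1, 1.
    * ``blockage_sweep`` — list over blockages 20..85 %, 6 cm vessel.
    """
    if name == "paper_case_50pct":
        return _base_scenario(name)
    if name == "joule_60pct_lowdp":
        return _base_scenario(
            name,
            L_vessel=0.06,
            delta=0.006,
            Ha=1.0,
            Pm=PM_BASE * _LOW_DP_FRACTION,
            cooled_wall=True,
        )
    if name == "ha_sweep":
        return [
            replace(_base_scenario(f"ha_sweep_{ha:g}", Ha=ha))
            for ha in (0.0, 0.1, 1.0)
        ]
    if name == "blockage_sweep":
        return [
            _base_scenario(
                f"blockage_{int(100 * bf):d}pct", L_vessel=0.06, delta=bf * 0.01
            )
            for bf in (0.2, 0.4, 0.5, 0.6, 0.7, 0.8, 0.85)
        ]
    raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")
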