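"""Presets and run configuration.

All physical defaults live here, not in the library modules:

* Benchmark-nozzle geometry: a 12 mm diameter pipe converging through a
  20-degree (included angle) conical collector to a 4 mm diameter, 40 mm long
  throat that ends in a sudden expansion back to 12 mm.  z = 0 is the sudden
  expansion plane.  Inlet/outlet pipe lengths are configurable because only
  the collector/throat/expansion core is geometry-critical.
* Blood: rho = 1056 kg/m^3; Newtonian viscosity 3.5 mPa s (the CY
  infinite-shear value, i.e. the Newtonian approximation uses mu_inf).
* Carreau-Yasuda (Abraham et al. calibration) and Casson (Perktold-type)
  parameter sets; the Casson law is clamped below 0.1 1/s where it would
  diverge.
* Giersiepen-family hemolysis coefficients with standard blood composition.

The throat Reynolds number Re = rho * v_mean * D_throat / mu fixes the flow
rate: Re = 500 gives Q = 5.206e-6 m^3/s (a laminar regime).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .eos import EOSParams
from .geometry import NozzleGeometry, Segment
from .grid import AxiGrid
from .hemolysis import HemolysisCoefficients
from .rheology import RheologyParams
from .solver import InflowSpec, Solver, SolverConfig

__all__ = [
    "RHO_BLOOD", "MU_BLOOD", "THROAT_RADIUS", "INLET_RADIUS",
    "fda_nozzle", "rheology_preset", "flow_rate_for_throat_reynolds",
    "RunConfig", "load_config",
]

RHO_BLOOD = 1056.0        # kg/m^3
MU_BLOOD = 0.0035         # Pa s
INLET_RADIUS = 0.006      # m
THROAT_RADIUS = 0.002     # m
THROAT_LENGTH = 0.04      # m
CONE_HALF_ANGLE_DEG = 10.0
CONE_LENGTH = (INLET_RADIUS - THROAT_RADIUS) / np.tan(np.deg2rad(CONE_HALF_ANGLE_DEG))


def fda_nozzle(inlet_length: float = 0.04, outlet_length: float = 0.06) -> NozzleGeometry:
    """Benchmark nozzle in the sudden-expansion orientation (z=0 there)."""
    z_cone0 = -(CONE_LENGTH + THROAT_LENGTH)
    z_in0 = z_cone0 - inlet_length
    return NozzleGeometry([
        Segment(z_in0, z_cone0, "constant", INLET_RADIUS, INLET_RADIUS),
        Segment(z_cone0, -THROAT_LENGTH, "linear-cone", INLET_RADIUS, THROAT_RADIUS),
        Segment(-THROAT_LENGTH, 0.0, "constant", THROAT_RADIUS, THROAT_RADIUS),
        Segment(0.0, outlet_length, "constant", INLET_RADIUS, INLET_RADIUS),
    ])


def fda_nozzle_snapped(dz: float, inlet_length: float = 0.04,
                       outlet_length: float = 0.06) -> NozzleGeometry:
    """Benchmark nozzle with pipe lengths snapped to the grid spacing.

    The cone length is irrational in grid units, so the inlet pipe is
    stretched (never shrunk) until the total axial extent is an exact
    multiple of dz and the sudden-expansion plane z = 0 falls on a cell face.
    """
    zc = CONE_LENGTH + THROAT_LENGTH
    m = int(np.ceil((zc + inlet_length) / dz - 1e-9))
    n_out = max(int(round(outlet_length / dz)), 1)
    return fda_nozzle(inlet_length=m * dz - zc, outlet_length=n_out * dz)


_RHEOLOGY_PRESETS = {
    "newtonian": dict(model="newtonian", mu=MU_BLOOD),
    "carreau_yasuda_abraham": dict(model="carreau_yasuda", mu0=0.16,
                                   mu_inf=0.0035, lam=8.2, a_cy=0.64,
                                   n_cy=0.2128),
    "casson_perktold": dict(model="casson", k_tau=0.0105, k_mu=0.0035,
                            gamma_cutoff=0.1),
}


def rheology_preset(name: str) -> RheologyParams:
    if name not in _RHEOLOGY_PRESETS:
        raise KeyError(f"unknown rheology preset {name!r}; "
                       f"available: {sorted(_RHEOLOGY_PRESETS)}")
    return RheologyParams(**_RHEOLOGY_PRESETS[name])


def flow_rate_for_throat_reynolds(Re: float, R_throat: float = THROAT_RADIUS,
                                  mu: float = MU_BLOOD, rho: float = RHO_BLOOD) -> float:
    """Q such that Re = rho v_mean (2R) / mu at the throat."""
    return Re * np.pi * R_throat * mu / (2.0 * rho)


GEOMETRY_PRESETS = {"fda_nozzle": fda_nozzle, "fda_nozzle_snapped": fda_nozzle_snapped}


@dataclass
class RunConfig:
    """Assembled configuration for one simulation run."""

    geometry: NozzleGeometry
    grid: AxiGrid
    rheology: RheologyParams
    eos: EOSParams
    inflow: InflowSpec
    solver: SolverConfig = field(default_factory=SolverConfig)
    hemolysis: HemolysisCoefficients = field(default_factory=HemolysisCoefficients)
    initial: str = "poiseuille"
    transit_factor: float = 6.0   # damage-transport pseudo-time horizon
    output_dir: Optional[str] = None

    def build_solver(self) -> Solver:
        return Solver(self.geometry, self.grid, self.rheology, self.eos,
                      self.inflow, self.solver, self.hemolysis)


def _build_geometry(block: dict) -> NozzleGeometry:
    if "preset" in block:
        kwargs = {k: v for k, v in block.items() if k != "preset"}
        return GEOMETRY_PRESETS[block["preset"]](**kwargs)
    return NozzleGeometry([Segment(*s) for s in block["segments"]])


def load_config(path) -> RunConfig:
    """Read a YAML run configuration into a :class:`RunConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    geom = _build_geometry(raw["geometry"])
    gb = raw["grid"]
    grid = AxiGrid.for_geometry(geom, dr=float(gb["dr"]), dz=float(gb["dz"]))
    rb = raw.get("rheology", {"preset": "newtonian"})
    if "preset" in rb:
        rheo = rheology_preset(rb["preset"])
    else:
        rheo = RheologyParams(**rb)
    eos = EOSParams(**{k: float(v) for k, v in raw.get("eos", {}).items()})
    ib = raw["inflow"]
    if "throat_reynolds" in ib:
        Q = flow_rate_for_throat_reynolds(float(ib["throat_reynolds"]))
    else:
        Q = float(ib["Q"])
    sb = dict(raw.get("solver", {}))
    if "body_force" in sb:
        sb["body_force"] = tuple(float(x) for x in sb["body_force"])
    solver = SolverConfig(**sb)
    hb = raw.get("hemolysis", {})
    hemo = HemolysisCoefficients(**{k: float(v) for k, v in hb.items()}) if hb \
        else HemolysisCoefficients()
    return RunConfig(geometry=geom, grid=grid, rheology=rheo, eos=eos,
                     inflow=InflowSpec(Q=Q), solver=solver, hemolysis=hemo,
                     initial=raw.get("initial", "poiseuille"),
                     transit_factor=float(raw.get("transit_factor", 6.0)),
                     output_dir=raw.get("outputs", {}).get("dir"))
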