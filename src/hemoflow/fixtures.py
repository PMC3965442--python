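"""Synthetic analytic flow fields on toy geometries.

These fixtures make every downstream module testable without running the
solver: a Poiseuille field carries its own analytic shear stress, wall shear
stress, transit times and linear-damage distribution, so indicator and
hemolysis routines can be checked against closed forms.  The generator
deliberately emulates only smooth laminar fields - no turbulence and no
measurement-noise models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import NozzleGeometry, Segment, build_mask, geometry_integral
from .grid import AxiGrid
from .hemolysis import HemolysisCoefficients
from .state import FlowState

__all__ = [
    "FixtureSpec",
    "straight_tube",
    "stepped_tube",
    "cone_tube",
    "make_poiseuille_field",
    "make_plug_flow_field",
    "make_perturbed_field",
]


# -- toy geometries ---------------------------------------------------------

def straight_tube(R: float = 0.002, L: float = 0.03, z_min: float = 0.0) -> NozzleGeometry:
    return NozzleGeometry([Segment(z_min, z_min + L, "constant", R, R)])


def stepped_tube(R1: float = 0.003, R2: float = 0.0015, L1: float = 0.015,
                 L2: float = 0.015, z_min: float = 0.0) -> NozzleGeometry:
    """Two constant radii joined by a sudden (zero-length) radius jump."""
    return NozzleGeometry([
        Segment(z_min, z_min + L1, "constant", R1, R1),
        Segment(z_min + L1, z_min + L1 + L2, "constant", R2, R2),
    ])


def cone_tube(R1: float = 0.003, R2: float = 0.0015, L: float = 0.03,
              z_min: float = 0.0) -> NozzleGeometry:
    return NozzleGeometry([Segment(z_min, z_min + L, "linear-cone", R1, R2)])


@dataclass(frozen=True)
class FixtureSpec:
    kind: str = "poiseuille_tube"   # poiseuille_tube | plug_flow | stepped_tube | cone_tube
    geometry: Optional[NozzleGeometry] = None
    Q: float = 1.0e-6               # m^3/s
    mu: float = 0.0035              # Pa s (Newtonian, for analytic tau/damage)
    rho0: float = 1056.0            # kg/m^3
    dr: float = 1.25e-4
    dz: float = 2.5e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Q < 0 or self.mu <= 0 or self.rho0 <= 0:
            raise ValueError("need Q >= 0, mu > 0, rho0 > 0")

    def resolved_geometry(self) -> NozzleGeometry:
        if self.geometry is not None:
            return self.geometry
        if self.kind == "stepped_tube":
            return stepped_tube()
        if self.kind == "cone_tube":
            return cone_tube()
        return straight_tube()


@dataclass
class PoiseuilleMetadata:
    """Analytic companions to a generated Poiseuille field."""

    tau: np.ndarray          # shear-stress magnitude on the grid, Pa
    dl: np.ndarray           # linear damage accumulated from the inlet
    wss: np.ndarray          # wall shear stress 4 mu Q / (pi R(z)^3) vs z, Pa
    v_max: np.ndarray        # centerline velocity 2 Q / (pi R(z)^2) vs z, m/s
    Q: float
    mu: float

    def transit_time(self, s: float, geom: NozzleGeometry) -> float:
        """Inlet-to-outlet transit on the streamline of relative radius s."""
        I2 = geometry_integral(geom, 2.0)
        return np.pi * I2 / (2.0 * self.Q * (1.0 - s**2))


def _cumulative_radius_integral(geom: NozzleGeometry, q: float, z: np.ndarray) -> np.ndarray:
    """int_{z_min}^{z_k} R(z')^q dz' at each requested z, closed form per segment."""
    out = np.zeros_like(z)
    for k, zk in enumerate(z):
        total = 0.0
        for seg in geom.segments:
            if zk <= seg.z_start:
                break
            ze = min(zk, seg.z_end)
            if seg.R_start == seg.R_end:
                total += (ze - seg.z_start) * seg.R_start**q
            else:
                Re = seg.radius(ze)
                total += (Re ** (q + 1.0) - seg.R_start ** (q + 1.0)) / (seg.slope * (q + 1.0))
        out[k] = total
    return out


def make_poiseuille_field(spec: FixtureSpec,
                          coeff: Optional[HemolysisCoefficients] = None,
                          grid: Optional[AxiGrid] = None) -> tuple[FlowState, PoiseuilleMetadata]:
    """Poiseuille profile at every axial station with constant flow rate.

    v_z = 2Q/(pi R(z)^2) (1 - (r/R)^2), v_r = 0, rho = rho0.  The metadata
    carries the analytic shear stress tau = 4 mu Q r / (pi R^4), the wall
    value, and the analytic linear-damage field obtained by integrating the
    damage rate along the fixed-relative-radius streamlines from the inlet -
    exactly the construction behind the analytic hemolysis bound, so fixture
    and bound are mutually consistent oracles.
    """
    geom = spec.resolved_geometry()
    if grid is None:
        grid = AxiGrid.for_geometry(geom, spec.dr, spec.dz)
    mask = build_mask(geom, grid)
    st = FlowState.rest(grid, mask, spec.rho0)
    if coeff is None:
        coeff = HemolysisCoefficients()

    R = geom.radius_at(grid.z)[None, :]
    r = grid.r[:, None]
    s = np.clip(r / R, 0.0, 1.0)
    v_z = np.where(mask, 2.0 * spec.Q / (np.pi * R**2) * (1.0 - s**2), 0.0)
    st.m_z = spec.rho0 * v_z
    tau = np.where(mask, 4.0 * spec.mu * spec.Q * r / (np.pi * R**4), 0.0)

    q = coeff.bound_radius_exponent
    if spec.Q > 0.0:
        Icum = _cumulative_radius_integral(geom, q, grid.z)[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            dl = (coeff.rate_coefficient
                  * (4.0 * spec.mu * spec.Q / np.pi) ** (coeff.b_h / coeff.a_h)
                  * (np.pi / (2.0 * spec.Q)) * s ** (coeff.b_h / coeff.a_h)
                  / (1.0 - s**2) * Icum)
        dl = np.where(mask & (s < 1.0), dl, 0.0)
    else:
        dl = np.zeros_like(s)
    st.rho_dl = spec.rho0 * dl

    meta = PoiseuilleMetadata(
        tau=tau, dl=dl,
        wss=4.0 * spec.mu * spec.Q / (np.pi * geom.radius_at(grid.z) ** 3),
        v_max=2.0 * spec.Q / (np.pi * geom.radius_at(grid.z) ** 2),
        Q=spec.Q, mu=spec.mu)
    return st, meta


def make_plug_flow_field(spec: FixtureSpec, grid: Optional[AxiGrid] = None) -> FlowState:
    """Uniform axial velocity (zero interior shear); damage field zero."""
    geom = spec.resolved_geometry()
    if grid is None:
        grid = AxiGrid.for_geometry(geom, spec.dr, spec.dz)
    mask = build_mask(geom, grid)
    st = FlowState.rest(grid, mask, spec.rho0)
    R = geom.radius_at(grid.z)[None, :]
    st.m_z = np.where(mask, spec.rho0 * spec.Q / (np.pi * R**2), 0.0)
    return st


def make_perturbed_field(spec: FixtureSpec, amplitude: float, seed: Optional[int] = None,
                         coeff: Optional[HemolysisCoefficients] = None):
    """Poiseuille field plus a smooth divergence-free perturbation.

    The perturbation derives from a Stokes streamfunction
    psi = A r^2 (1 - (r/R)^2)^2 sin(2 pi k z / L + phase) with (k, phase)
    drawn from the seeded RNG, so v = ((-1/r) dpsi/dz, (1/r) dpsi/dr) is
    analytically divergence-free, vanishes at wall and axis, and carries zero
    net flux through every cross-section.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    st, meta = make_poiseuille_field(spec, coeff=coeff)
    if amplitude == 0.0:
        return st, meta
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    kmode = rng.integers(1, 4)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    g = st.grid
    geom = spec.resolved_geometry()
    R = geom.radius_at(g.z)[None, :]
    r = g.r[:, None]
    L = g.z_max - g.z_min
    kz = 2.0 * np.pi * kmode / L
    arg = kz * (g.z[None, :] - g.z_min) + phase
    shape = (1.0 - (r / R) ** 2) ** 2
    dshape_dr = -4.0 * (r / R**2) * (1.0 - (r / R) ** 2)
    # psi = A r^2 shape sin(arg)
    v_r = -amplitude * r * shape * kz * np.cos(arg)
    v_z = amplitude * (2.0 * shape + r * dshape_dr) * np.sin(arg)
    st.m_r = st.m_r + np.where(st.mask, spec.rho0 * v_r, 0.0)
    st.m_z = st.m_z + np.where(st.mask, spec.rho0 * v_z, 0.0)
    return st, meta
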