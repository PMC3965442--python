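"""Blood-damage (hemolysis) computations.

The underlying empirical law is the Giersiepen-family power law for the
damaged-hemoglobin fraction of blood held at constant shear stress tau for a
time t:

    D = C * tau^b * t^a,        0 < a < 1,  b > 0.

Because a < 1 the damage growth is sublinear in time, which makes the raw law
awkward to integrate along trajectories with varying stress.  The standard
change of variables introduces the *linear damage*

    D_l = D^(1/a),   with   dD_l/dt = C^(1/a) * tau^(b/a),

whose growth rate depends only on the instantaneous stress; for constant tau,
integrating the rate and un-linearizing (D = D_l^a) reproduces the power law
exactly.  D_l is a mathematical auxiliary: averages must always be taken over
the physical damage D = D_l^a, never over D_l (averaging the linear variable
overestimates damage whenever the exposure is heterogeneous - Jensen's
inequality for the concave map x -> x^a).

Four routes to a domain-averaged normalized index of hemolysis (NIH) are
implemented:

1. Lagrangian: integrate dD_l/dt along pathlines of a steady velocity field,
   un-linearize each pathline's damage, then flow-weight average.
2. Eulerian: evolve the conservative field rho*D_l inside the flow solver and
   flow-weight average D = D_l^a over radial cuts (see hemoflow.solver).
3. Analytic lower bound for Newtonian axisymmetric conduits, assuming a
   Poiseuille profile at every axial station; reduces to a single power-law
   geometry integral and a Beta function.
4. The time-explicit variant dD/dt = C a t^(a-1) tau^b, whose result depends
   on the chosen time origin.

The NIH in g/100 L follows from the averaged damage fraction via
NIH = 100 * (1 - Hct) * Hb * D with Hb the hemoglobin content in g/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import RegularGridInterpolator
from scipy.special import beta as beta_fn

from .geometry import NozzleGeometry, geometry_integral
from .profiles import ProfileSeries
from .rheology import RheologyParams, effective_shear_rate, shear_rate_tensor, viscosity
from .state import FlowState

__all__ = [
    "HemolysisCoefficients",
    "Pathline",
    "DamageResult",
    "damage_constant_exposure",
    "linear_damage_rate",
    "nih_from_damage",
    "trace_pathlines",
    "average_nih_pathlines",
    "eulerian_nih_profile",
    "analytic_lower_bound",
    "arora_nih",
    "linear_averaging_overestimate",
]


@dataclass(frozen=True)
class HemolysisCoefficients:
    """Power-law constants plus blood composition.

    Defaults are the Giersiepen et al. coefficients with D expressed as a
    fraction (not percent), and standard physiological blood composition.
    """

    C: float = 3.62e-7    # dimensionless scale (fractional damage)
    a_h: float = 0.785    # time exponent, sublinear
    b_h: float = 2.416    # stress exponent (tau in Pa)
    Hct: float = 0.45     # hematocrit volume fraction
    Hb: float = 150.0     # hemoglobin content, g/L

    def __post_init__(self) -> None:
        if self.C <= 0 or self.b_h <= 0:
            raise ValueError("C and b must be positive")
        if not 0.0 < self.a_h < 1.0:
            raise ValueError("time exponent a must lie in (0, 1)")
        if not 0.0 < self.Hct < 1.0:
            raise ValueError("hematocrit must lie in (0, 1)")
        if self.Hb <= 0:
            raise ValueError("hemoglobin content must be positive")

    @property
    def rate_coefficient(self) -> float:
        """C^(1/a), the prefactor of the linear-damage rate."""
        return self.C ** (1.0 / self.a_h)

    @property
    def bound_radius_exponent(self) -> float:
        """Radius exponent 2 - 3 b/a of the analytic-bound geometry integral."""
        return 2.0 - 3.0 * self.b_h / self.a_h


@dataclass
class Pathline:
    """A traced trajectory with sampled shear stress and linear damage."""

    seed_r: float
    seed_z: float
    t: np.ndarray
    r: np.ndarray
    z: np.ndarray
    tau: np.ndarray
    dl: np.ndarray            # accumulated linear damage along the path
    flow_weight: float        # m^3/s carried by this seed
    completed: bool = True    # False if the trajectory stalled (recirculation)

    @property
    def transit_time(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class DamageResult:
    dl: float
    D: float
    nih: float  # g / 100 L


def damage_constant_exposure(tau, t, coeff: HemolysisCoefficients):
    """Damage fraction D = C tau^b t^a for constant shear stress."""
    tau = np.asarray(tau, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(tau < 0) or np.any(t < 0):
        raise ValueError("shear stress and exposure time must be non-negative")
    out = coeff.C * tau**coeff.b_h * t**coeff.a_h
    return float(out) if out.ndim == 0 else out


def linear_damage_rate(tau, coeff: HemolysisCoefficients):
    """dD_l/dt = C^(1/a) tau^(b/a); integrating then un-linearizing recovers
    the constant-exposure power law exactly."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("shear stress must be non-negative")
    out = coeff.rate_coefficient * tau ** (coeff.b_h / coeff.a_h)
    return float(out) if out.ndim == 0 else out


def nih_from_damage(D, coeff: HemolysisCoefficients):
    """NIH (g/100 L) = 100 (1 - Hct) Hb D, with Hb in g/L."""
    return 100.0 * (1.0 - coeff.Hct) * coeff.Hb * np.asarray(D, dtype=float)


# ---------------------------------------------------------------------------
# Lagrangian route: pathline tracing and averaging
# ---------------------------------------------------------------------------

def shear_stress_magnitude(state: FlowState, rheology: RheologyParams) -> np.ndarray:
    """tau = mu(gamma_eff) * gamma_eff on the grid (zero on solid cells)."""
    shear = shear_rate_tensor(state.v_r, state.v_z, state.grid.dr, state.grid.dz,
                              mask=state.mask)
    g = effective_shear_rate(shear)
    return viscosity(rheology, g) * g


def _interpolators(state: FlowState, tau: np.ndarray):
    g = state.grid
    vr = np.where(state.mask, state.v_r, 0.0)
    vz = np.where(state.mask, state.v_z, 0.0)
    pts = (g.r, g.z)
    kw = dict(bounds_error=False, fill_value=None)  # linear extrapolation at edges
    return (RegularGridInterpolator(pts, vr, **kw),
            RegularGridInterpolator(pts, vz, **kw),
            RegularGridInterpolator(pts, tau, **kw))


def equal_flow_seed_radii(state: FlowState, n_seeds: int, j: int = 0) -> np.ndarray:
    """Seed radii on the inlet column splitting the flow into equal increments.

    Each seed then carries the same flow weight Q/n, which is the natural
    quadrature for flow-weighted averages.
    """
    g = state.grid
    vz = state.v_z[:, j]
    w = vz * g.r * g.dr                     # flux per cell / (2 pi rho-ish const)
    cum = np.concatenate([[0.0], np.cumsum(w)])
    cum /= cum[-1]
    r_edges = np.concatenate([[0.0], g.r + 0.5 * g.dr])
    targets = (np.arange(n_seeds) + 0.5) / n_seeds
    return np.interp(targets, cum, r_edges)


def trace_pathlines(state: FlowState, rheology: RheologyParams,
                    n_seeds: int = 64, z_start: Optional[float] = None,
                    z_end: Optional[float] = None,
                    max_transit_factor: float = 50.0,
                    coeff: Optional[HemolysisCoefficients] = None,
                    rtol: float = 1e-7, atol: float = 1e-10) -> list[Pathline]:
    """Integrate pathlines of a steady field from inlet to outlet.

    dx/dt = v(x) is solved with an adaptive Runge-Kutta method; velocity and
    shear stress are bilinearly interpolated.  The accumulated linear damage
    rides along as an extra ODE component, so its accuracy is controlled by
    the same adaptive tolerance.  Seeds sit at equal-flow-increment radii on
    the inlet section, each carrying flow weight Q/n.  Trajectories that do
    not reach the outlet within ``max_transit_factor`` times the mean transit
    time (fluid volume / flow rate) are flagged ``completed=False`` and are
    excluded from averages.
    """
    g = state.grid
    if z_start is None:
        z_start = g.z[0]
    if z_end is None:
        z_end = g.z[-1]
    tau_field = shear_stress_magnitude(state, rheology)
    f_vr, f_vz, f_tau = _interpolators(state, tau_field)

    j0 = int(np.argmin(np.abs(g.z - z_start)))
    radii = equal_flow_seed_radii(state, n_seeds, j=j0)
    vol = float(np.sum(state.mask * g.cell_volume()))
    Q = float(np.sum(2.0 * np.pi * g.r[:, None] * g.dr * state.v_z[:, [j0]] * state.mask[:, [j0]]))
    if Q <= 0:
        raise ValueError("no through-flow at the seeding station")
    t_max = max_transit_factor * vol / Q

    if coeff is None:
        coeff = HemolysisCoefficients()

    def rhs(t, y):
        r = abs(y[0])
        pt = np.array([[r, y[1]]])
        return [f_vr(pt)[0], f_vz(pt)[0],
                linear_damage_rate(max(f_tau(pt)[0], 0.0), coeff)]

    def reach_outlet(t, y):
        return y[1] - z_end
    reach_outlet.terminal = True
    reach_outlet.direction = 1

    paths: list[Pathline] = []
    for r0 in radii:
        sol = solve_ivp(rhs, (0.0, t_max), [r0, z_start, 0.0], method="RK45",
                        events=reach_outlet, rtol=rtol, atol=atol, max_step=t_max / 50.0)
        rr = np.abs(sol.y[0])
        zz = sol.y[1]
        tau_s = np.maximum(f_tau(np.column_stack([rr, zz])), 0.0)
        completed = len(sol.t_events[0]) > 0
        paths.append(Pathline(seed_r=float(r0), seed_z=float(z_start), t=sol.t,
                              r=rr, z=zz, tau=np.asarray(tau_s, dtype=float),
                              dl=sol.y[2], flow_weight=Q / n_seeds,
                              completed=completed))
    return paths


def integrate_pathline_damage(path: Pathline, coeff: HemolysisCoefficients) -> DamageResult:
    """Re-integrate dD_l/dt over a sampled stress history (trapezoid rule)."""
    rate = linear_damage_rate(path.tau, coeff)
    dl = float(np.trapezoid(rate, path.t))
    D = dl ** coeff.a_h if dl > 0 else 0.0
    return DamageResult(dl=dl, D=D, nih=float(nih_from_damage(D, coeff)))


def average_nih_pathlines(pathlines: Sequence[Pathline], coeff: HemolysisCoefficients,
                          use_stored_dl: bool = False) -> DamageResult:
    """Flow-weighted average damage over pathlines, un-linearized *before*
    averaging (the order of operations is essential; see module docstring)."""
    included = [p for p in pathlines if p.completed]
    if not included:
        raise ValueError("no completed pathlines to average")
    ws, Ds, dls = [], [], []
    for p in included:
        if use_stored_dl:
            dl = float(p.dl[-1])
        else:
            dl = integrate_pathline_damage(p, coeff).dl
        dls.append(dl)
        Ds.append(dl ** coeff.a_h if dl > 0 else 0.0)
        ws.append(p.flow_weight)
    w = np.asarray(ws) / np.sum(ws)
    D_avg = float(np.sum(w * np.asarray(Ds)))
    dl_avg = float(np.sum(w * np.asarray(dls)))
    return DamageResult(dl=dl_avg, D=D_avg, nih=float(nih_from_damage(D_avg, coeff)))


# ---------------------------------------------------------------------------
# Eulerian route
# ---------------------------------------------------------------------------

def eulerian_nih_profile(state: FlowState, coeff: HemolysisCoefficients) -> ProfileSeries:
    """NIH(z) from the evolved conservative linear-damage field.

    At each axial station the pointwise damage D = D_l^a is averaged with the
    (signed) axial mass-flux weight rho v_z r, i.e. the average transported
    downstream through the cut; the result is converted to NIH.
    """
    g = state.grid
    dl = state.dl
    D = np.where(dl > 0, dl, 0.0) ** coeff.a_h
    w = state.rho * state.v_z * g.r[:, None] * state.mask
    num = np.sum(w * D, axis=0)
    den = np.sum(w, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Dbar = np.where(np.abs(den) > 0, num / den, 0.0)
    return ProfileSeries(coordinate=g.z, values=nih_from_damage(Dbar, coeff),
                         quantity="NIH", units="g/100L",
                         metadata={"route": "eulerian"})


# ---------------------------------------------------------------------------
# Analytic axisymmetric lower bound
# ---------------------------------------------------------------------------

def analytic_lower_bound(geom: NozzleGeometry, mu: float, Q: float,
                         coeff: HemolysisCoefficients) -> DamageResult:
    """Closed-form averaged damage for a Newtonian Poiseuille-at-every-z flow.

    On the streamline of fixed relative radius s = r/R(z) the stress is
    tau = 4 mu Q s / (pi R^3) and dt = dz/v_z with v_z = 2Q(1-s^2)/(pi R^2).
    Integrating the linear-damage rate, un-linearizing, and flow-averaging in
    s (weight dF = 4 s (1-s^2) ds) gives

        <D> = 2 C (4 mu Q / pi)^b (pi I / (2 Q))^a B(b/2 + 1, 2 - a),

    with I = int R(z)^(2 - 3b/a) dz the geometry integral and B the Beta
    function.  Because the true velocity profile is not everywhere Poiseuille
    (entrance effects, jets, recirculation all raise the exposure), this is a
    lower bound on the CFD-computed damage.
    """
    if mu <= 0 or Q < 0:
        raise ValueError("need mu > 0 and Q >= 0")
    if Q == 0.0:
        return DamageResult(dl=0.0, D=0.0, nih=0.0)
    a, b, C = coeff.a_h, coeff.b_h, coeff.C
    I = geometry_integral(geom, coeff.bound_radius_exponent, unit_convention="m")
    D_avg = (2.0 * C * (4.0 * mu * Q / np.pi) ** b
             * (np.pi * I / (2.0 * Q)) ** a * beta_fn(b / 2.0 + 1.0, 2.0 - a))
    dl_equiv = D_avg ** (1.0 / a)
    return DamageResult(dl=dl_equiv, D=float(D_avg), nih=float(nih_from_damage(D_avg, coeff)))


# ---------------------------------------------------------------------------
# Time-explicit (Arora-type) variant
# ---------------------------------------------------------------------------

def arora_nih(pathlines: Sequence[Pathline], coeff: HemolysisCoefficients,
              time_origin_offset: float = 0.0) -> DamageResult:
    """Integrate the time-explicit rate dD/dt = C a t^(a-1) tau^b along
    pathlines.

    ``time_origin_offset`` >= 0 shifts the exposure clock: t = (path time) +
    offset.  For constant stress and zero offset the constant-exposure power
    law is recovered exactly.  Because t^(a-1) decreases (a < 1), placing the
    origin earlier (larger offset) strictly decreases the result - the route
    is origin-dependent, which is its documented weakness.
    """
    if time_origin_offset < 0:
        raise ValueError("time origin offset must be non-negative")
    included = [p for p in pathlines if p.completed]
    if not included:
        raise ValueError("no completed pathlines")
    a, b, C = coeff.a_h, coeff.b_h, coeff.C
    ws, Ds = [], []
    for p in included:
        t = p.t - p.t[0] + time_origin_offset
        with np.errstate(divide="ignore"):
            integrand = C * a * t ** (a - 1.0) * p.tau**b
        # t^(a-1) is integrable at t=0; drop the singular first node if offset=0
        if time_origin_offset == 0.0 and t[0] == 0.0:
            # exact treatment of the first interval assuming tau constant there
            D0 = C * p.tau[0] ** b * t[1] ** a if len(t) > 1 else 0.0
            D = D0 + float(np.trapezoid(integrand[1:], t[1:]))
        else:
            D = float(np.trapezoid(integrand, t))
        Ds.append(D)
        ws.append(p.flow_weight)
    w = np.asarray(ws) / np.sum(ws)
    D_avg = float(np.sum(w * np.asarray(Ds)))
    return DamageResult(dl=D_avg ** (1.0 / a) if D_avg > 0 else 0.0, D=D_avg,
                        nih=float(nih_from_damage(D_avg, coeff)))


# ---------------------------------------------------------------------------
# Linear-averaging overestimation analysis
# ---------------------------------------------------------------------------

def linear_averaging_overestimate(dl_values, weights, coeff: HemolysisCoefficients) -> float:
    """Ratio [mean(D_l)]^a / mean(D_l^a) quantifying the error of averaging
    the linear variable before un-linearizing.

    By Jensen's inequality (x^a concave for a < 1) the ratio is >= 1, with
    equality only for homogeneous damage.
    """
    dl = np.asarray(dl_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if dl.size == 0:
        raise ValueError("need at least one damage value")
    w = w / np.sum(w)
    a = coeff.a_h
    wrong = float(np.sum(w * dl)) ** a
    right = float(np.sum(w * dl**a))
    return wrong / right if right > 0 else 1.0
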