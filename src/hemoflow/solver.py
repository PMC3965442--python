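"""Explicit weakly-compressible axisymmetric Navier-Stokes solver.

The conservative fields (rho, m_r, m_z, and optionally the linear-damage
density rho*D_l) are advanced with SSP Runge-Kutta time stepping and
conservative finite-difference fluxes on a regular staggered-free
cell-centered (r, z) grid (see :mod:`hemoflow._kernels` for the scheme).
Boundaries:

* axis: reflection ghosts (v_r odd, everything else even);
* walls: staircase mask, no-slip enforced by mirrored face values;
* inflow: Poiseuille mass-flux profile imposed (ramped from rest), density
  free via the outgoing characteristic;
* outflow: characteristic (LODI) closure with the incoming wave relaxing
  pressure to the reference value - non-reflecting for outgoing acoustics.

The run is marched to steady state, detected by the windowed relative change
of the momentum fields.  The steady linear-damage field may either be
co-evolved with the flow or (default workflow, much cheaper) solved on the
frozen steady velocity by a pseudo-time transport march: the steady transport
equation is identical in both cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels as K
from .eos import EOSParams
from .geometry import NozzleGeometry, build_mask
from .grid import AxiGrid
from .hemolysis import HemolysisCoefficients
from .rheology import RheologyParams
from .state import FlowState

__all__ = ["SolverConfig", "InflowSpec", "ConvergenceReport", "Solver"]

_MODEL_IDS = {"newtonian": 0, "carreau_yasuda": 1, "casson": 2}


@dataclass(frozen=True)
class SolverConfig:
    cfl: float = 0.4
    interior_order: int = 6        # face-reconstruction order away from walls
    time_order: int = 3            # SSP-RK order (2 or 3)
    eps4: float = 0.02             # fourth-difference dissipation coefficient
    steady_tol: float = 1e-8       # windowed max-norm momentum change
    steady_window: int = 100       # steps per residual window
    max_steps: int = 2_000_000
    t_end: Optional[float] = None  # optional physical-time cap
    ramp_time: float = 0.02        # s, inflow spin-up
    body_force: tuple[float, float] = (0.0, 0.0)  # N/m^3, (f_r, f_z)
    outflow_sigma: float = 0.25    # LODI pressure-relaxation strength
    seed: int = 0                  # reserved; the scheme is deterministic
    check_interval: int = 20       # steps between dt refresh / NaN checks

    def __post_init__(self) -> None:
        if not 0.0 < self.cfl <= 1.0:
            raise ValueError("require 0 < cfl <= 1")
        if self.interior_order not in (2, 4, 6):
            raise ValueError("interior_order must be 2, 4 or 6")
        if self.time_order not in (2, 3):
            raise ValueError("time_order must be 2 or 3")
        if self.steady_tol <= 0 or self.steady_window < 1:
            raise ValueError("invalid steady-state criterion")


@dataclass(frozen=True)
class InflowSpec:
    """Volumetric inflow with a Poiseuille radial profile."""

    Q: float                      # m^3/s
    def v_max(self, R_inlet: float) -> float:
        # integrating the parabolic profile over the section gives Q = pi R^2 v_max / 2
        return 2.0 * self.Q / (np.pi * R_inlet**2)


@dataclass
class ConvergenceReport:
    steps: int = 0
    t: float = 0.0
    residual: float = np.inf
    residual_history: list = field(default_factory=list)
    converged: bool = False
    reason: str = "init"   # steady | t_end | max_steps | diverged


class Solver:
    """Binds geometry, grid, physics and scheme; advances flow states."""

    def __init__(self, geom: NozzleGeometry, grid: AxiGrid,
                 rheology: RheologyParams, eos: EOSParams,
                 inflow: InflowSpec, config: SolverConfig = SolverConfig(),
                 hemolysis: HemolysisCoefficients = HemolysisCoefficients(),
                 periodic_z: bool = False) -> None:
        self.geom = geom
        self.grid = grid
        self.rheology = rheology
        self.eos = eos
        self.inflow = inflow
        self.config = config
        self.hemolysis = hemolysis
        self.periodic_z = periodic_z

        self.mask = build_mask(geom, grid)
        ng, nr, nz = grid.ng, grid.nr, grid.nz
        self.NR, self.NZ = nr + 2 * ng, nz + 2 * ng
        self.r_full = (np.arange(self.NR) - ng + 0.5) * grid.dr

        self.fluid = np.zeros((self.NR, self.NZ), dtype=np.uint8)
        self.fluid[ng:ng + nr, ng:ng + nz] = self.mask
        for k in range(ng):  # axis ghosts mirror the first interior rows
            self.fluid[ng - 1 - k, ng:ng + nz] = self.mask[k]
        if periodic_z:
            self.fluid[:, :ng] = self.fluid[:, nz:nz + ng]
            self.fluid[:, ng + nz:] = self.fluid[:, ng:ng + ng]
        else:
            for k in range(ng):
                self.fluid[:, k] = self.fluid[:, ng]
                self.fluid[:, ng + nz + k] = self.fluid[:, ng + nz - 1]

        self.ord_r, self.ord_z = self._face_orders()
        self.bc_col = np.zeros(self.NZ, dtype=np.int8)
        if periodic_z:
            self.bc_col[:] = 3
        else:
            self.bc_col[ng] = 1
            self.bc_col[ng + nz - 1] = 2

        R_in = geom.inlet_radius()
        vmax = inflow.v_max(R_in)
        self.vz_targ = np.zeros(self.NR)
        rr = self.r_full
        prof = vmax * (1.0 - (rr / R_in) ** 2)
        self.vz_targ[:] = np.where((rr >= 0) & (rr <= R_in), np.maximum(prof, 0.0), 0.0)

        Lz = grid.nz * grid.dz
        self.k_relax = config.outflow_sigma * eos.c0 / Lz

        mid = _MODEL_IDS[rheology.model]
        self._coeff_args = (
            mid, rheology.mu, rheology.mu0, rheology.mu_inf, rheology.lam,
            rheology.a_cy, rheology.n_cy, rheology.k_tau, rheology.k_mu,
            rheology.gamma_cutoff, hemolysis.rate_coefficient,
            hemolysis.b_h / hemolysis.a_h)

    # ------------------------------------------------------------------
    def _face_orders(self) -> tuple[np.ndarray, np.ndarray]:
        g = self.grid
        ng, nr, nz = g.ng, g.nr, g.nz
        f = self.fluid.astype(bool)
        omax = self.config.interior_order
        ord_r = np.full((self.NR, self.NZ), K.NOFLUX, dtype=np.int8)
        ord_z = np.full((self.NR, self.NZ), K.NOFLUX, dtype=np.int8)
        for j in range(ng, ng + nz):
            for i in range(ng - 1, ng + nr):
                a, b = f[i, j], f[i + 1, j]
                if not a and not b:
                    continue
                if a != b:
                    ord_r[i, j] = K.WALL
                    continue
                o = 2
                if omax >= 4 and f[i - 1, j] and f[i + 2, j]:
                    o = 4
                    if omax >= 6 and i - 2 >= 0 and i + 3 < self.NR and \
                            f[i - 2, j] and f[i + 3, j]:
                        o = 6
                ord_r[i, j] = o
        jfaces = range(ng - 1, ng + nz) if self.periodic_z else range(ng, ng + nz - 1)
        interior_ok = (lambda j: True) if self.periodic_z else \
            (lambda j: ng <= j < ng + nz)
        for i in range(ng, ng + nr):
            for j in jfaces:
                a, b = f[i, j], f[i, j + 1]
                if not a and not b:
                    continue
                if a != b:
                    ord_z[i, j] = K.WALL
                    continue
                o = 2
                if omax >= 4 and f[i, j - 1] and f[i, j + 2] and \
                        interior_ok(j - 1) and interior_ok(j + 2):
                    o = 4
                    if omax >= 6 and f[i, j - 2] and f[i, j + 3] and \
                            interior_ok(j - 2) and interior_ok(j + 3):
                        o = 6
                ord_z[i, j] = o
        return ord_r, ord_z

    # ------------------------------------------------------------------
    def initial_state(self, kind: str = "rest") -> FlowState:
        st = FlowState.rest(self.grid, self.mask, self.eos.rho0)
        if kind == "rest":
            return st
        if kind == "poiseuille":
            # local Poiseuille guess at every z: good initial condition that
            # shortens the transient (exact in straight segments)
            R = self.geom.radius_at(self.grid.z)[None, :]
            r = self.grid.r[:, None]
            v = 2.0 * self.inflow.Q / (np.pi * R**2) * (1.0 - np.clip(r / R, 0, 1) ** 2)
            st.m_z = np.where(self.mask, self.eos.rho0 * v, 0.0)
            return st
        raise ValueError(f"unknown initial-state kind {kind!r}")

    def _full(self, interior: np.ndarray, fill: float = 0.0) -> np.ndarray:
        g = self.grid
        out = np.full((self.NR, self.NZ), fill)
        out[g.ng:g.ng + g.nr, g.ng:g.ng + g.nz] = interior
        return out

    def _interior(self, full: np.ndarray) -> np.ndarray:
        g = self.grid
        return full[g.ng:g.ng + g.nr, g.ng:g.ng + g.nz].copy()

    def _dt(self, rho, mr, mz) -> float:
        g, cfg = self.grid, self.config
        h = min(g.dr, g.dz)
        vmax = K.max_speed(rho, mr, mz, self.fluid, g.ng, g.nr, g.nz)
        cmax = self.eos.c0 * (np.max(rho[self.fluid == 1]) / self.eos.rho0) ** (
            (self.eos.gamma_ad - 1.0) / 2.0)
        dt_adv = cfg.cfl * h / (vmax + cmax)
        dt_visc = 0.2 * self.eos.rho0 * h**2 / self.rheology.mu_max
        return min(dt_adv, dt_visc)

    def _ramp(self, t: float) -> float:
        tr = self.config.ramp_time
        if tr <= 0 or t >= tr:
            return 1.0
        return float(np.sin(0.5 * np.pi * t / tr) ** 2)

    # ------------------------------------------------------------------
    def evaluate_rhs(self, state: FlowState, evolve_damage: bool = True):
        """Semi-discrete time derivatives of all conservative fields.

        Returns interior-shaped arrays (drho, dm_r, dm_z, drho_dl); mainly a
        verification hook (equilibrium and analytic-balance checks).
        """
        g, cfg, eos = self.grid, self.config, self.eos
        ng, nr, nz = g.ng, g.nr, g.nz
        state.validate()
        rho = self._full(state.rho, fill=eos.rho0)
        mr = self._full(state.m_r)
        mz = self._full(state.m_z)
        rdl = self._full(state.rho_dl)
        mu = np.zeros_like(rho)
        rate = np.zeros_like(rho)
        tau = np.zeros_like(rho)
        outs = [np.zeros_like(rho) for _ in range(4)]
        K.fill_ghosts(rho, mr, mz, rdl, ng, nr, nz, self.periodic_z, eos.rho0)
        K.compute_coeffs(rho, mr, mz, self.fluid, ng, nr, nz, g.dr, g.dz,
                         self.r_full, *self._coeff_args, mu, rate, tau)
        K.compute_rhs(rho, mr, mz, rdl, mu, rate, self.fluid, self.ord_r,
                      self.ord_z, self.bc_col, ng, nr, nz, g.dr, g.dz,
                      self.r_full, eos.p0, eos.rho0, eos.c0, eos.gamma_ad,
                      cfg.eps4, 1 if evolve_damage else 0, eos.p0,
                      self.k_relax, *cfg.body_force, *outs)
        return tuple(self._interior(o) for o in outs)

    # ------------------------------------------------------------------
    def advance_to_steady(self, state: FlowState,
                          evolve_damage: bool = False,
                          t_end: Optional[float] = None,
                          max_steps: Optional[int] = None,
                          steady_tol: Optional[float] = None) -> tuple[FlowState, ConvergenceReport]:
        """March the flow until steady, a time cap, or a step cap.

        Returns the final state and a convergence report; raises
        FloatingPointError on NaN/Inf with a cell diagnostic, and flags
        divergence if the windowed residual grows persistently.
        """
        g, cfg, eos = self.grid, self.config, self.eos
        ng, nr, nz = g.ng, g.nr, g.nz
        t_end = cfg.t_end if t_end is None else t_end
        max_steps = cfg.max_steps if max_steps is None else max_steps
        steady_tol = cfg.steady_tol if steady_tol is None else steady_tol
        ed = 1 if evolve_damage else 0

        rho = self._full(state.rho, fill=eos.rho0)
        mr = self._full(state.m_r)
        mz = self._full(state.m_z)
        rdl = self._full(state.rho_dl)
        mu = np.zeros_like(rho)
        rate = np.zeros_like(rho)
        tau = np.zeros_like(rho)
        drho = np.zeros_like(rho)
        dmr = np.zeros_like(rho)
        dmz = np.zeros_like(rho)
        drdl = np.zeros_like(rho)

        report = ConvergenceReport()
        t = state.t
        dt = self._dt(rho, mr, mz)
        mr_ref = mr.copy()
        mz_ref = mz.copy()
        mscale = max(float(np.max(np.abs(self.vz_targ))) * eos.rho0, 1e-30)
        grow = 0

        has_inflow = 0 if self.periodic_z else 1
        fz_r, fz_z = cfg.body_force

        if cfg.time_order == 3:
            stages = ((1.0, 0.0), (0.75, 0.25), (1.0 / 3.0, 2.0 / 3.0))
        else:
            stages = ((1.0, 0.0), (0.5, 0.5))

        step = 0
        while step < max_steps:
            if t_end is not None and t >= t_end:
                report.reason = "t_end"
                break
            if step % cfg.check_interval == 0:
                dt = self._dt(rho, mr, mz)
            if t_end is not None and t + dt > t_end:
                dt = t_end - t + 1e-30
            rho0s, mr0s, mz0s, rdl0s = rho.copy(), mr.copy(), mz.copy(), rdl.copy()
            for si, (a0, a1) in enumerate(stages):
                K.fill_ghosts(rho, mr, mz, rdl, ng, nr, nz, self.periodic_z, eos.rho0)
                if si == 0:
                    K.compute_coeffs(rho, mr, mz, self.fluid, ng, nr, nz,
                                     g.dr, g.dz, self.r_full,
                                     *self._coeff_args, mu, rate, tau)
                K.compute_rhs(rho, mr, mz, rdl, mu, rate, self.fluid,
                              self.ord_r, self.ord_z, self.bc_col,
                              ng, nr, nz, g.dr, g.dz, self.r_full,
                              eos.p0, eos.rho0, eos.c0, eos.gamma_ad,
                              cfg.eps4, ed, eos.p0, self.k_relax, fz_r, fz_z,
                              drho, dmr, dmz, drdl)
                K.euler_update(rho, drho, dt, ng, nr, nz)
                K.euler_update(mr, dmr, dt, ng, nr, nz)
                K.euler_update(mz, dmz, dt, ng, nr, nz)
                if ed:
                    K.euler_update(rdl, drdl, dt, ng, nr, nz)
                if si > 0:
                    K.rk_combine(rho0s, rho, a0, a1)
                    K.rk_combine(mr0s, mr, a0, a1)
                    K.rk_combine(mz0s, mz, a0, a1)
                    if ed:
                        K.rk_combine(rdl0s, rdl, a0, a1)
                K.enforce_bc_state(rho, mr, mz, rdl, self.fluid, self.vz_targ,
                                   self._ramp(t + dt), ng, nr, nz, eos.rho0,
                                   has_inflow)
            t += dt
            step += 1
            if step % cfg.steady_window == 0:
                diff = max(float(np.max(np.abs(mz - mz_ref))),
                           float(np.max(np.abs(mr - mr_ref))))
                res = diff / mscale
                report.residual_history.append((t, res))
                mr_ref[:] = mr
                mz_ref[:] = mz
                if not np.isfinite(res):
                    self._diagnose(rho, mr, mz, rdl)
                if len(report.residual_history) > 3 and t > cfg.ramp_time:
                    prev = report.residual_history[-2][1]
                    grow = grow + 1 if res > prev else 0
                    if grow > 50 and res > 1e3:
                        report.reason = "diverged"
                        break
                if res < steady_tol and t > cfg.ramp_time:
                    report.converged = True
                    report.reason = "steady"
                    report.residual = res
                    break
                report.residual = res
        else:
            report.reason = "max_steps"

        out = FlowState(grid=g, mask=self.mask.copy(), rho=self._interior(rho),
                        m_r=self._interior(mr), m_z=self._interior(mz),
                        rho_dl=self._interior(rdl), t=t)
        out.validate()
        report.steps = step
        report.t = t
        return out, report

    def _diagnose(self, rho, mr, mz, rdl) -> None:
        g = self.grid
        for name, f in (("rho", rho), ("m_r", mr), ("m_z", mz), ("rho_dl", rdl)):
            bad = ~np.isfinite(f[g.ng:g.ng + g.nr, g.ng:g.ng + g.nz]) & self.mask
            if np.any(bad):
                ij = np.argwhere(bad)[0]
                raise FloatingPointError(
                    f"non-finite {name} at (i={ij[0]}, j={ij[1]}), "
                    f"r={g.r[ij[0]]:.4g} m, z={g.z[ij[1]]:.4g} m")
        raise FloatingPointError("residual became non-finite")

    # ------------------------------------------------------------------
    def transport_damage(self, state: FlowState, transit_factor: float = 6.0,
                         cfl: float = 0.4, reset: bool = True) -> FlowState:
        """Solve the steady linear-damage transport on the frozen velocity.

        Marches d(rho Dl)/dt + div(rho Dl v) = rho*rate in pseudo-time on the
        given (steady) flow for ``transit_factor`` mean transit times
        (fluid volume / flow rate).  The steady fixed point is the same field
        the fully coupled evolution would reach, at a fraction of the cost
        because the march is limited by the advective, not acoustic, CFL.
        """
        g, eos = self.grid, self.eos
        ng, nr, nz = g.ng, g.nr, g.nz
        rho = self._full(state.rho, fill=eos.rho0)
        mr = self._full(state.m_r)
        mz = self._full(state.m_z)
        rdl = self._full(np.zeros_like(state.rho_dl) if reset else state.rho_dl)
        K.fill_ghosts(rho, mr, mz, rdl, ng, nr, nz, self.periodic_z, eos.rho0)
        mu = np.zeros_like(rho)
        rate = np.zeros_like(rho)
        tau = np.zeros_like(rho)
        K.compute_coeffs(rho, mr, mz, self.fluid, ng, nr, nz, g.dr, g.dz,
                         self.r_full, *self._coeff_args, mu, rate, tau)
        vr = np.where(self.fluid == 1, mr / rho, 0.0)
        vz = np.where(self.fluid == 1, mz / rho, 0.0)

        vol = float(np.sum(self.mask * g.cell_volume()))
        Q = max(self.inflow.Q, 1e-30)
        t_fill = transit_factor * vol / Q
        vrm = float(np.max(np.abs(vr))) + 1e-30
        vzm = float(np.max(np.abs(vz))) + 1e-30
        dt = cfl * min(g.dr / vrm, g.dz / vzm)
        nsteps = int(np.ceil(t_fill / dt))
        drdl = np.zeros_like(rdl)
        q0 = np.zeros_like(rdl)
        for _ in range(nsteps):
            q0[:] = rdl
            for si, (a0, a1) in enumerate(((1.0, 0.0), (0.5, 0.5))):
                K.fill_ghosts(rho, mr, mz, rdl, ng, nr, nz, self.periodic_z, eos.rho0)
                K.transport_rhs(rdl, vr, vz, rho, rate, self.fluid,
                                self.ord_r, self.ord_z, self.bc_col,
                                ng, nr, nz, g.dr, g.dz, self.r_full, drdl)
                K.euler_update(rdl, drdl, dt, ng, nr, nz)
                if si > 0:
                    K.rk_combine(q0, rdl, a0, a1)
        out = state.copy()
        out.rho_dl = self._interior(rdl)
        out.rho_dl[~self.mask] = 0.0
        return out
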