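"""Equation of state and solver building blocks (cheap checks).

The heavier steady-flow verification lives in test_acceptance.py, sharing
session-scoped runs.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hemoflow as hf
from hemoflow import config as cfg
from hemoflow.eos import eos_density, eos_pressure, sound_speed
from hemoflow.fixtures import straight_tube


class TestEOS:
    def test_reference_state(self):
        eos = hf.EOSParams(p0=1.0e4)
        assert eos_pressure(eos.rho0, eos) == pytest.approx(1.0e4)

    def test_sound_speed_is_dp_drho(self):
        eos = hf.EOSParams()
        h = 1e-6 * eos.rho0
        num = (eos_pressure(eos.rho0 + h, eos) - eos_pressure(eos.rho0 - h, eos)) / (2 * h)
        assert num == pytest.approx(eos.c0**2, rel=1e-7)
        assert sound_speed(eos.rho0, eos) == pytest.approx(eos.c0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(0.99, 1.01))
    def test_round_trip_identity(self, frac):
        eos = hf.EOSParams()
        rho = frac * eos.rho0
        back = eos_density(eos_pressure(rho, eos), eos)
        assert back == pytest.approx(rho, rel=1e-12)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            eos_pressure(-1.0, hf.EOSParams())


def _tube_solver(Q=0.0, periodic=False, nr=8, nz=50, L=0.02, R=0.002, **cfg_kw):
    geom = straight_tube(R, L)
    grid = hf.AxiGrid.for_geometry(geom, dr=R / nr, dz=L / nz)
    return hf.Solver(geom, grid, cfg.rheology_preset("newtonian"),
                     hf.EOSParams(), hf.InflowSpec(Q=Q),
                     hf.SolverConfig(**cfg_kw), periodic_z=periodic)


class TestRHSBasics:
    def test_rest_state_rhs_exactly_zero(self):
        sol = _tube_solver()
        st = sol.initial_state("rest")
        for d in sol.evaluate_rhs(st):
            assert np.max(np.abs(d)) == 0.0

    def test_rest_state_stays_at_rest(self):
        sol = _tube_solver(ramp_time=0.0)
        st = sol.initial_state("rest")
        out, rep = sol.advance_to_steady(st, max_steps=30)
        assert np.max(np.abs(out.m_z)) == 0.0
        assert np.max(np.abs(out.rho - 1056.0)) == 0.0

    def test_poiseuille_balance_residual(self):
        """With the analytic parabola and the matching axial driving force
        8 mu Q / (pi R^4): away from the wall the momentum RHS vanishes to
        rounding (centered viscous differences are exact on a parabola).
        The single wall-adjacent row carries the mirror-closure truncation,
        analytically G/8 * (r_face/r_center) -> a bounded local defect whose
        effect on the steady solution is confined to O(dr) near the wall
        (the steady-solve recovery test bounds the solution error)."""
        R, Q, mu = 0.002, 2.0e-6, 0.0035
        force = 8.0 * mu * Q / (np.pi * R**4)
        for nr in (8, 16):
            sol = _tube_solver(Q=Q, periodic=True, nr=nr, nz=16,
                               body_force=(0.0, force), eps4=0.0)
            st = sol.initial_state("rest")
            vz = 2 * Q / (np.pi * R**2) * (1 - (st.grid.r / R) ** 2)
            st.m_z = 1056.0 * np.tile(vz[:, None], (1, st.grid.nz))
            _, _, dmz, _ = sol.evaluate_rhs(st)
            assert np.max(np.abs(dmz[: nr - 1, :])) / force < 1e-12
            wall = np.max(np.abs(dmz[nr - 1, :])) / force
            assert wall == pytest.approx(0.125 * nr / (nr - 0.5), rel=0.05)

    def test_nan_input_diagnosed(self):
        sol = _tube_solver()
        st = sol.initial_state("rest")
        st.rho[3, 7] = np.nan
        with pytest.raises(FloatingPointError, match="rho"):
            sol.evaluate_rhs(st)


class TestConservation:
    def test_closed_periodic_box_conserves_mass(self):
        sol = _tube_solver(periodic=True, nr=8, nz=40, cfl=0.4)
        st = sol.initial_state("rest")
        z = st.grid.z
        L = st.grid.z_max
        pert = 1.0 + 1e-3 * np.sin(2 * np.pi * z / L)
        st.rho = st.rho * pert[None, :]
        st.m_z = 0.3 * st.rho * np.cos(2 * np.pi * z / L)[None, :] * st.mask
        w = st.grid.cell_volume()
        m0 = float(np.sum(st.rho * w))
        out, rep = sol.advance_to_steady(st, max_steps=200)
        m1 = float(np.sum(out.rho * w))
        assert abs(m1 - m0) / m0 < 1e-12  # conservative fluxes telescope

    def test_steady_mass_flux_constant_along_tube(self, tube_steady):
        from hemoflow.indicators import mass_flow_profile
        state, report = tube_steady
        prof = mass_flow_profile(state)
        assert np.max(np.abs(prof.values)) < 2e-3


class TestOutflowReflection:
    def test_acoustic_pulse_leaves_quietly(self):
        """A right-going acoustic pulse must exit through the characteristic
        outflow with a small reflected remnant (hard-wall reflection would
        return the full amplitude)."""
        R, L = 0.002, 0.04
        sol = _tube_solver(Q=0.0, R=R, L=L, nr=8, nz=100, ramp_time=0.0)
        st = sol.initial_state("rest")
        eos = hf.EOSParams()
        z = st.grid.z
        A = 5.0  # Pa
        bump = A * np.exp(-((z - 0.012) / 0.004) ** 2)
        drho = bump / eos.c0**2
        st.rho = st.rho + drho[None, :]
        # linear right-moving wave: dv = dp / (rho0 c0)
        st.m_z = st.m_z + (bump / eos.c0)[None, :]
        incident = np.max(np.abs(eos_pressure(st.rho, eos) - eos.p0))
        out, _ = sol.advance_to_steady(st, t_end=1.8 * L / eos.c0)
        residual = np.max(np.abs(eos_pressure(out.rho, eos) - eos.p0))
        assert residual < 0.05 * incident


class TestSteadyRobustness:
    def test_steady_solution_independent_of_cfl(self):
        outs = []
        for cfl in (0.4, 0.2):
            sol = _tube_solver(Q=1.5e-6, nr=8, nz=25, ramp_time=0.005, cfl=cfl)
            st = sol.initial_state("poiseuille")
            out, _ = sol.advance_to_steady(st, t_end=0.25)
            outs.append(out.v_z)
        diff = np.linalg.norm(outs[0] - outs[1]) / np.linalg.norm(outs[0])
        assert diff < 1e-3

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            hf.SolverConfig(cfl=1.5)
        with pytest.raises(ValueError):
            hf.SolverConfig(interior_order=5)
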