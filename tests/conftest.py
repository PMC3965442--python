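"""Shared fixtures.

Heavy solver runs are session-scoped so that the steady states feed both the
per-module tests and the acceptance suite without re-running the solver.
Problem sizes are deliberately scaled down from production resolutions; the
same physics is exercised.
"""

from __future__ import annotations

import numpy as np
import pytest

import hemoflow as hf
from hemoflow import config as cfg
from hemoflow.fixtures import FixtureSpec, make_poiseuille_field, straight_tube

TUBE_R = 0.002
TUBE_L = 0.03
TUBE_RE = 120.0


def tube_flow_rate(Re: float = TUBE_RE, R: float = TUBE_R) -> float:
    return cfg.flow_rate_for_throat_reynolds(Re, R_throat=R)


@pytest.fixture(scope="session")
def coeff() -> hf.HemolysisCoefficients:
    return hf.HemolysisCoefficients()


@pytest.fixture(scope="session")
def poiseuille_fixture():
    spec = FixtureSpec(kind="poiseuille_tube", geometry=straight_tube(TUBE_R, TUBE_L),
                       Q=tube_flow_rate(), dr=TUBE_R / 16, dz=TUBE_L / 120)
    state, meta = make_poiseuille_field(spec)
    return spec, state, meta


@pytest.fixture(scope="session")
def tube_solver():
    """Solver for the straight-tube verification case."""
    geom = straight_tube(TUBE_R, TUBE_L)
    grid = hf.AxiGrid.for_geometry(geom, dr=TUBE_R / 12, dz=TUBE_L / 60)
    return hf.Solver(geom, grid, cfg.rheology_preset("newtonian"), hf.EOSParams(),
                     hf.InflowSpec(Q=tube_flow_rate()),
                     hf.SolverConfig(ramp_time=0.01, interior_order=4))


@pytest.fixture(scope="session")
def tube_steady(tube_solver):
    """Straight-tube run from rest to (near) steady Poiseuille flow.

    1.2 s of physical time is about one radial viscous time R^2 rho / mu,
    enough for the profile to settle to discretization accuracy.
    """
    state = tube_solver.initial_state("rest")
    state, report = tube_solver.advance_to_steady(state, t_end=1.2,
                                                  steady_tol=2e-6)
    state = tube_solver.transport_damage(state, transit_factor=8.0)
    return state, report


@pytest.fixture(scope="session")
def nozzle_setup():
    Q = cfg.flow_rate_for_throat_reynolds(500.0)
    dz = 7.5e-4
    geom = cfg.fda_nozzle_snapped(dz=dz, inlet_length=0.012, outlet_length=0.032)
    grid = hf.AxiGrid.for_geometry(geom, dr=2.5e-4, dz=dz)
    return geom, grid, Q


def _nozzle_run(nozzle_setup, preset: str):
    geom, grid, Q = nozzle_setup
    solver = hf.Solver(geom, grid, cfg.rheology_preset(preset), hf.EOSParams(),
                       hf.InflowSpec(Q=Q),
                       hf.SolverConfig(ramp_time=0.01, interior_order=4))
    state = solver.initial_state("poiseuille")
    state, report = solver.advance_to_steady(state, t_end=0.9, steady_tol=1e-6)
    return solver, state, report


@pytest.fixture(scope="session")
def nozzle_newtonian(nozzle_setup):
    return _nozzle_run(nozzle_setup, "newtonian")


@pytest.fixture(scope="session")
def nozzle_cy(nozzle_setup):
    return _nozzle_run(nozzle_setup, "carreau_yasuda_abraham")


@pytest.fixture(scope="session")
def nozzle_fine():
    """Finer Newtonian nozzle run (dr = 0.125 mm, shortened pipes) used for
    the mass-conservation bound and the WSS-peak location, both of which are
    resolution-sensitive."""
    Q = cfg.flow_rate_for_throat_reynolds(500.0)
    dz = 3.75e-4
    geom = cfg.fda_nozzle_snapped(dz=dz, inlet_length=0.005, outlet_length=0.012)
    grid = hf.AxiGrid.for_geometry(geom, dr=1.25e-4, dz=dz)
    solver = hf.Solver(geom, grid, cfg.rheology_preset("newtonian"),
                       hf.EOSParams(), hf.InflowSpec(Q=Q),
                       hf.SolverConfig(ramp_time=0.01, interior_order=4))
    state = solver.initial_state("poiseuille")
    # the mass-flow and WSS metrics are unchanged between t = 0.5 and 0.9 s
    # (transients have left the cone/throat); 0.6 s is the documented horizon
    state, report = solver.advance_to_steady(state, t_end=0.6, steady_tol=1e-6)
    return solver, state, report


@pytest.fixture(scope="session")
def convergence_study(coeff):
    """Half-scale collector+throat geometry at resolution ratios 1:2:4.

    Returns per-resolution mass-flow error, WSS maximum and outlet NIH.
    """
    from hemoflow.geometry import NozzleGeometry, Segment
    from hemoflow.hemolysis import eulerian_nih_profile
    from hemoflow.indicators import mass_flow_rate, wss_profile

    R1, R2 = 0.003, 0.0015
    throat, inlet = 0.006, 0.003
    cone = (R1 - R2) / np.tan(np.deg2rad(10.0))
    Q = cfg.flow_rate_for_throat_reynolds(200.0, R_throat=R2)
    runs = []
    for dr in (3.75e-4, 1.875e-4, 9.375e-5):
        dz = 2.0 * dr
        zc = cone + throat
        m = int(np.ceil((zc + inlet) / dz - 1e-9))
        geom = NozzleGeometry([
            Segment(-m * dz, -zc, "constant", R1, R1),
            Segment(-zc, -throat, "linear-cone", R1, R2),
            Segment(-throat, 0.0, "constant", R2, R2),
        ])
        grid = hf.AxiGrid.for_geometry(geom, dr=dr, dz=dz)
        solver = hf.Solver(geom, grid, cfg.rheology_preset("newtonian"),
                           hf.EOSParams(), hf.InflowSpec(Q=Q),
                           hf.SolverConfig(ramp_time=0.01, interior_order=4))
        st = solver.initial_state("poiseuille")
        st, rep = solver.advance_to_steady(st, t_end=0.45, steady_tol=1e-7)
        st = solver.transport_damage(st, transit_factor=6.0)
        runs.append({
            "dr": dr,
            "mass_err": float(np.max(np.abs(
                mass_flow_rate(st) / (1056.0 * Q) - 1.0))),
            "wss_max": float(np.nanmax(wss_profile(st, solver.rheology).values)),
            "nih": float(eulerian_nih_profile(st, coeff).values[-2]),
            "residual": rep.residual,
        })
    return runs
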