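"""Blood-damage laws, pathline and Eulerian routes, analytic bound."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hemoflow as hf
from hemoflow import config as cfg
from hemoflow.fixtures import (FixtureSpec, cone_tube, make_plug_flow_field,
                               make_poiseuille_field, stepped_tube,
                               straight_tube)
from hemoflow.hemolysis import integrate_pathline_damage

from oracles import damage_piecewise_constant, lagrangian_poiseuille_damage

# 40-digit evaluation of C tau^b t^a at tau=100 Pa, t=1 s (Giersiepen values)
D_100PA_1S = 0.024587171500742080450


class TestDamageLaws:
    def test_zero_stress_zero_damage(self, coeff):
        assert hf.damage_constant_exposure(0.0, 5.0, coeff) == 0.0
        assert hf.linear_damage_rate(0.0, coeff) == 0.0

    def test_sublinear_time_growth(self, coeff):
        d1 = hf.damage_constant_exposure(50.0, 1.0, coeff)
        d2 = hf.damage_constant_exposure(50.0, 2.0, coeff)
        assert d2 == pytest.approx(2.0**coeff.a_h * d1, rel=1e-12)
        assert d2 < 2.0 * d1

    def test_against_high_precision_value(self, coeff):
        assert hf.damage_constant_exposure(100.0, 1.0, coeff) == \
            pytest.approx(D_100PA_1S, rel=1e-12)

    def test_negative_inputs_rejected(self, coeff):
        with pytest.raises(ValueError):
            hf.damage_constant_exposure(-1.0, 1.0, coeff)
        with pytest.raises(ValueError):
            hf.linear_damage_rate(-1.0, coeff)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(0.01, 300.0), st.floats(1e-3, 10.0))
    def test_linearization_identity(self, tau, t):
        # (rate * t)^a must equal the constant-exposure law exactly
        coeff = hf.HemolysisCoefficients()
        lhs = (hf.linear_damage_rate(tau, coeff) * t) ** coeff.a_h
        rhs = hf.damage_constant_exposure(tau, t, coeff)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_piecewise_history_matches_fine_step_integration(self, coeff):
        taus = [10.0, 80.0, 35.0]
        durs = [0.05, 0.12, 0.4]
        dl = sum(hf.linear_damage_rate(tau, coeff) * dt
                 for tau, dt in zip(taus, durs))
        D = dl ** coeff.a_h
        assert D == pytest.approx(
            damage_piecewise_constant(taus, durs, coeff), rel=1e-10)

    def test_nih_scales_with_blood_composition(self, coeff):
        base = hf.nih_from_damage(1e-6, coeff)
        double_hb = hf.HemolysisCoefficients(Hb=2 * coeff.Hb)
        assert hf.nih_from_damage(1e-6, double_hb) == pytest.approx(2 * base)
        h = hf.HemolysisCoefficients(Hct=0.9)
        assert hf.nih_from_damage(1e-6, h) == pytest.approx(
            base * (1 - 0.9) / (1 - coeff.Hct))


class TestAnalyticLowerBound:
    @pytest.mark.parametrize("geom", [
        straight_tube(0.002, 0.03),
        stepped_tube(0.003, 0.0015, 0.015, 0.015),
        cone_tube(0.003, 0.0015, 0.03),
        cfg.fda_nozzle(),
    ], ids=["straight", "stepped", "cone", "nozzle"])
    def test_matches_lagrangian_poiseuille_oracle(self, geom, coeff):
        mu, Q = 0.0035, 3.0e-6
        closed = hf.analytic_lower_bound(geom, mu, Q, coeff)
        brute = lagrangian_poiseuille_damage(geom, mu, Q, coeff)
        assert closed.D == pytest.approx(brute, rel=1e-6)

    def test_vanishes_with_flow(self, coeff):
        res = hf.analytic_lower_bound(straight_tube(), 0.0035, 0.0, coeff)
        assert res.D == 0.0 and res.nih == 0.0


class TestPathlines:
    def test_uniform_flow_transit_time(self, coeff):
        spec = FixtureSpec(kind="plug_flow", geometry=straight_tube(0.002, 0.03),
                           Q=2.0e-6, dr=1.25e-4, dz=5e-4)
        state = make_plug_flow_field(spec)
        paths = hf.trace_pathlines(state, cfg.rheology_preset("newtonian"),
                                   n_seeds=8, coeff=coeff)
        v = spec.Q / (np.pi * 0.002**2)
        L = state.grid.z[-1] - state.grid.z[0]
        for p in paths:
            assert p.completed
            assert p.transit_time == pytest.approx(L / v, rel=1e-3)

    def test_poiseuille_transit_and_stress(self, poiseuille_fixture, coeff):
        spec, state, meta = poiseuille_fixture
        paths = hf.trace_pathlines(state, cfg.rheology_preset("newtonian"),
                                   n_seeds=12, coeff=coeff)
        R, L = 0.002, state.grid.z[-1] - state.grid.z[0]
        vmax = 2.0 * spec.Q / (np.pi * R**2)
        for p in paths[:-2]:  # skip outermost seeds (slowest, larger interp error)
            v0 = vmax * (1 - (p.seed_r / R) ** 2)
            assert p.completed
            assert p.transit_time == pytest.approx(L / v0, rel=2e-2)
            tau_exact = 4 * spec.mu * spec.Q * p.seed_r / (np.pi * R**4)
            assert np.median(p.tau) == pytest.approx(tau_exact, rel=2e-2)

    def test_axis_seed_stays_on_axis(self, poiseuille_fixture, coeff):
        _, state, _ = poiseuille_fixture
        paths = hf.trace_pathlines(state, cfg.rheology_preset("newtonian"),
                                   n_seeds=3, coeff=coeff)
        p = min(paths, key=lambda p: p.seed_r)
        assert np.max(np.abs(p.r - p.seed_r)) < state.grid.dr


class TestAveraging:
    def test_identical_pathlines_average_to_single_value(self, poiseuille_fixture, coeff):
        _, state, _ = poiseuille_fixture
        paths = hf.trace_pathlines(state, cfg.rheology_preset("newtonian"),
                                   n_seeds=6, coeff=coeff)
        one = integrate_pathline_damage(paths[2], coeff)
        res = hf.average_nih_pathlines([paths[2]] * 4, coeff)
        assert res.nih == pytest.approx(one.nih, rel=1e-12)

    def test_two_pathline_weighted_mean(self, poiseuille_fixture, coeff):
        _, state, _ = poiseuille_fixture
        paths = hf.trace_pathlines(state, cfg.rheology_preset("newtonian"),
                                   n_seeds=8, coeff=coeff)
        a, b = paths[1], paths[5]
        a.flow_weight, b.flow_weight = 0.3, 0.7
        Da = integrate_pathline_damage(a, coeff).D
        Db = integrate_pathline_damage(b, coeff).D
        res = hf.average_nih_pathlines([a, b], coeff)
        assert res.nih == pytest.approx(
            float(hf.nih_from_damage(0.3 * Da + 0.7 * Db, coeff)), rel=1e-12)

    def test_poiseuille_pathline_average_near_analytic_bound(self, poiseuille_fixture, coeff):
        spec, state, _ = poiseuille_fixture
        geom = straight_tube(0.002, 0.03)
        paths = hf.trace_pathlines(state, cfg.rheology_preset("newtonian"),
                                   n_seeds=64, coeff=coeff)
        res = hf.average_nih_pathlines(paths, coeff, use_stored_dl=True)
        exact = hf.analytic_lower_bound(geom, spec.mu, spec.Q, coeff)
        assert res.nih == pytest.approx(exact.nih, rel=0.04)

    def test_empty_set_rejected(self, coeff):
        with pytest.raises(ValueError):
            hf.average_nih_pathlines([], coeff)


class TestEulerianRoute:
    def test_plug_flow_zero_nih(self, coeff):
        spec = FixtureSpec(kind="plug_flow", geometry=straight_tube(0.002, 0.03),
                           Q=2.0e-6, dr=1.25e-4, dz=5e-4)
        state = make_plug_flow_field(spec)
        prof = hf.eulerian_nih_profile(state, coeff)
        assert np.allclose(prof.values, 0.0)

    def test_inlet_station_near_zero(self, poiseuille_fixture, coeff):
        _, state, _ = poiseuille_fixture
        prof = hf.eulerian_nih_profile(state, coeff)
        assert prof.values[0] < 0.02 * prof.values[-1]

    def test_monotone_growth_along_tube(self, poiseuille_fixture, coeff):
        _, state, _ = poiseuille_fixture
        prof = hf.eulerian_nih_profile(state, coeff)
        assert np.all(np.diff(prof.values) >= 0)

    def test_matches_pathline_route_on_fixture(self, poiseuille_fixture, coeff):
        _, state, _ = poiseuille_fixture
        prof = hf.eulerian_nih_profile(state, coeff)
        paths = hf.trace_pathlines(state, cfg.rheology_preset("newtonian"),
                                   n_seeds=64, coeff=coeff)
        res = hf.average_nih_pathlines(paths, coeff, use_stored_dl=True)
        assert prof.values[-1] == pytest.approx(res.nih, rel=0.05)


class TestAroraRoute:
    def test_constant_stress_from_origin_matches_power_law(self, coeff):
        # synthetic pathline with constant stress
        t = np.linspace(0.0, 0.8, 4001)
        p = hf.Pathline(seed_r=0.0, seed_z=0.0, t=t, r=np.zeros_like(t),
                        z=t, tau=np.full_like(t, 60.0), dl=np.zeros_like(t),
                        flow_weight=1.0)
        res = hf.arora_nih([p], coeff)
        assert res.D == pytest.approx(
            hf.damage_constant_exposure(60.0, 0.8, coeff), rel=1e-4)

    def test_earlier_origin_strictly_smaller(self, poiseuille_fixture, coeff):
        _, state, _ = poiseuille_fixture
        paths = hf.trace_pathlines(state, cfg.rheology_preset("newtonian"),
                                   n_seeds=16, coeff=coeff)
        base = hf.arora_nih(paths, coeff, time_origin_offset=0.0)
        shifted = hf.arora_nih(paths, coeff, time_origin_offset=0.5)
        more = hf.arora_nih(paths, coeff, time_origin_offset=2.0)
        assert more.nih < shifted.nih < base.nih

    def test_negative_offset_rejected(self, poiseuille_fixture, coeff):
        with pytest.raises(ValueError):
            hf.arora_nih([], coeff, time_origin_offset=-1.0)


class TestLinearAveragingOverestimate:
    def test_homogeneous_ratio_is_one(self, coeff):
        r = hf.linear_averaging_overestimate([1e-5] * 6, np.ones(6), coeff)
        assert r == pytest.approx(1.0, rel=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_heterogeneous_ratio_exceeds_one(self, seed):
        coeff = hf.HemolysisCoefficients()
        rng = np.random.default_rng(seed)
        dl = rng.lognormal(-12.0, 1.5, size=12)
        w = rng.uniform(0.1, 1.0, size=12)
        assert hf.linear_averaging_overestimate(dl, w, coeff) > 1.0

    def test_poiseuille_distribution_matches_quadrature(self, coeff):
        """The overestimation factor of the analytic straight-tube Dl(s)
        distribution must approach the adaptive-quadrature value."""
        from scipy.integrate import quad
        a, b = coeff.a_h, coeff.b_h
        dl_shape = lambda s: s ** (b / a) / (1.0 - s * s)
        n = 20000
        s = (np.arange(n) + 0.5) / n
        w = 4.0 * s * (1.0 - s * s)          # flow weight density in s
        ratio = hf.linear_averaging_overestimate(dl_shape(s), w, coeff)
        num, _ = quad(lambda s: dl_shape(s) * 4 * s * (1 - s * s), 0, 1)
        den, _ = quad(lambda s: dl_shape(s) ** a * 4 * s * (1 - s * s), 0, 1)
        assert ratio == pytest.approx(num**a / den, rel=5e-3)
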