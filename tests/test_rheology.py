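"""Rheology: strain-rate invariant and the three viscosity laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hemoflow as hf
from hemoflow import config as cfg
from hemoflow.rheology import ShearField

CY = cfg.rheology_preset("carreau_yasuda_abraham")
CASSON = cfg.rheology_preset("casson_perktold")
NEWT = cfg.rheology_preset("newtonian")

# 40-digit evaluation of the CY law at gamma = 100 1/s (Abraham parameters)
CY_AT_100 = 0.0042825595004164327262


class TestShearRateTensor:
    def test_uniform_velocity_is_shear_free(self):
        v = np.full((8, 10), 0.3)
        sh = hf.shear_rate_tensor(np.zeros_like(v), v, 1e-4, 1e-4)
        g = hf.effective_shear_rate(sh)
        assert np.allclose(g[:, 1:-1], 0.0, atol=1e-12)

    def test_linear_profile_gives_constant_rate(self):
        nr, nz, dr = 12, 8, 1e-4
        r = (np.arange(nr) + 0.5) * dr
        k = 250.0
        vz = np.tile((k * r)[:, None], (1, nz))
        sh = hf.shear_rate_tensor(np.zeros_like(vz), vz, dr, 1e-4)
        g = hf.effective_shear_rate(sh)
        # interior rows: |dvz/dr| = k exactly for a linear profile
        assert np.allclose(g[1:-1, 1:-1], k, rtol=1e-12)

    def test_poiseuille_matches_analytic_derivative(self, poiseuille_fixture):
        spec, state, meta = poiseuille_fixture
        sh = hf.shear_rate_tensor(state.v_r, state.v_z, state.grid.dr,
                                  state.grid.dz, mask=state.mask)
        g = hf.effective_shear_rate(sh)
        R = 0.002
        exact = 4.0 * spec.Q * state.grid.r / (np.pi * R**4)
        # interior rows (centered differences are exact on a parabola)
        rows = slice(1, state.grid.nr - 1)
        assert np.allclose(g[rows, 5], exact[rows], rtol=1e-10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_equals_componentwise_sum(self, seed):
        rng = np.random.default_rng(seed)
        comps = rng.normal(size=(4, 3, 3))
        sh = ShearField(s_rr=comps[0], s_rz=comps[1], s_zz=comps[2], s_tt=comps[3])
        g = hf.effective_shear_rate(sh)
        brute = np.sqrt(2.0 * (comps[0]**2 + comps[2]**2 + comps[3]**2
                               + 2.0 * comps[1]**2))
        assert np.allclose(g, brute, rtol=1e-14)


class TestViscosity:
    def test_cy_zero_shear_limit(self):
        assert hf.viscosity(CY, 0.0) == pytest.approx(CY.mu0, rel=1e-14)

    def test_cy_infinite_shear_asymptote(self):
        assert hf.viscosity(CY, 1e7) == pytest.approx(CY.mu_inf, rel=1e-2)

    def test_cy_against_high_precision_value(self):
        assert hf.viscosity(CY, 100.0) == pytest.approx(CY_AT_100, rel=1e-12)

    def test_casson_zero_yield_is_newtonian(self):
        p = hf.RheologyParams(model="casson", k_tau=0.0, k_mu=0.004,
                              gamma_cutoff=0.1)
        g = np.array([0.5, 5.0, 500.0])
        assert np.allclose(hf.viscosity(p, g), 0.004, rtol=1e-14)

    def test_casson_cutoff_clamp(self):
        lo = hf.viscosity(CASSON, CASSON.gamma_cutoff / 10.0)
        at = hf.viscosity(CASSON, CASSON.gamma_cutoff)
        assert lo == pytest.approx(at, rel=1e-14)

    def test_negative_shear_rejected(self):
        with pytest.raises(ValueError):
            hf.viscosity(CY, -1.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(1e-4, 1e5), st.floats(1.01, 100.0))
    def test_cy_strictly_decreasing_and_bounded(self, g, fac):
        lo, hi = hf.viscosity(CY, g), hf.viscosity(CY, g * fac)
        assert CY.mu_inf <= hi < lo <= CY.mu0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(1e-4, 1e5), st.floats(1.01, 100.0))
    def test_casson_nonincreasing_finite_above_kmu(self, g, fac):
        lo, hi = hf.viscosity(CASSON, g), hf.viscosity(CASSON, g * fac)
        assert np.isfinite(lo) and hi <= lo and hi >= CASSON.k_mu

    def test_low_shear_model_ordering(self):
        g = CASSON.gamma_cutoff
        assert hf.viscosity(CASSON, g) >= hf.viscosity(CY, g) >= NEWT.mu


class TestViscosityField:
    def test_newtonian_constant_field(self, poiseuille_fixture):
        _, state, _ = poiseuille_fixture
        sh = hf.shear_rate_tensor(state.v_r, state.v_z, state.grid.dr,
                                  state.grid.dz, mask=state.mask)
        f = hf.viscosity_field(NEWT, sh)
        assert np.allclose(f, NEWT.mu)

    def test_cy_decreases_from_axis_to_wall(self, poiseuille_fixture):
        _, state, _ = poiseuille_fixture
        sh = hf.shear_rate_tensor(state.v_r, state.v_z, state.grid.dr,
                                  state.grid.dz, mask=state.mask)
        f = hf.viscosity_field(CY, sh)
        col = f[:, 5]
        assert np.all(np.diff(col) < 0)

    def test_field_equals_elementwise_scalar(self):
        sh = ShearField(s_rr=np.zeros((3, 3)), s_rz=np.full((3, 3), 50.0),
                        s_zz=np.zeros((3, 3)), s_tt=np.zeros((3, 3)))
        f = hf.viscosity_field(CY, sh)
        assert np.allclose(f, hf.viscosity(CY, 100.0), rtol=1e-14)
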