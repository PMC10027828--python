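"""Casson rheology: correlation values, limits, shear-thinning properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aneuflow.rheology import (CassonParams, apparent_viscosity,
                               newtonian_params, params_from_hematocrit,
                               shear_rate)


class TestHematocritCorrelation:
    def test_coefficients_increase_with_hematocrit(self):
        lo, mid, hi = (params_from_hematocrit(h) for h in (0.35, 0.40, 0.45))
        assert lo.tau_y < mid.tau_y < hi.tau_y
        assert lo.mu_inf < mid.mu_inf < hi.mu_inf

    @pytest.mark.parametrize("H", [0.35, 0.40, 0.45])
    def test_correlation_formula_values(self, H):
        # oracle: direct evaluation of the adopted Merrill/Einstein forms
        p = params_from_hematocrit(H)
        assert p.tau_y == pytest.approx(0.1 * (0.625 * H) ** 3, rel=1e-12)
        assert p.mu_inf == pytest.approx(0.00145 * (1 - H) ** -2.5, rel=1e-12)

    def test_normal_hematocrit_default(self):
        p = params_from_hematocrit(0.40)
        assert p.hematocrit == 0.40
        assert 0.004 < p.mu_inf < 0.007  # physiological whole-blood range

    @pytest.mark.parametrize("H", [0.0, 1.0, -0.1, 1.5])
    def test_out_of_range_rejected(self, H):
        with pytest.raises(ValueError):
            params_from_hematocrit(H)


class TestApparentViscosity:
    def test_zero_yield_is_exactly_newtonian(self):
        p = newtonian_params(0.0035)
        g = np.array([0.0, 1e-3, 1.0, 1e6])
        out = apparent_viscosity(g, p)
        np.testing.assert_array_equal(out, np.full(4, 0.0035))

    def test_high_shear_asymptote(self):
        p = CassonParams(tau_y=0.01, mu_inf=0.0035)
        assert apparent_viscosity(1e6, p) == pytest.approx(0.0035, rel=0.01)

    def test_closed_form_example(self):
        p = CassonParams(tau_y=0.01, mu_inf=0.0035)
        expect = (np.sqrt(0.01) + np.sqrt(0.0035)) ** 2
        assert apparent_viscosity(1.0, p) == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(0.0253322, abs=5e-7)

    def test_finite_at_zero_shear_via_floor(self):
        p = CassonParams(tau_y=0.01, mu_inf=0.0035, gamma_dot_min=1e-3)
        v0 = apparent_viscosity(0.0, p)
        assert np.isfinite(v0)
        assert v0 == apparent_viscosity(1e-3, p)

    @given(st.floats(1e-3, 1e6), st.floats(1e-3, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_shear_thinning_and_lower_bound(self, g1, g2):
        p = CassonParams(tau_y=0.005, mu_inf=0.004)
        v1, v2 = apparent_viscosity(g1, p), apparent_viscosity(g2, p)
        assert v1 >= p.mu_inf and v2 >= p.mu_inf
        if g1 < g2:
            assert v1 >= v2
        elif g2 < g1:
            assert v2 >= v1


class TestShearRate:
    def test_zero_tensor(self):
        assert shear_rate(np.zeros((2, 2))) == 0.0

    def test_pure_shear_closed_form(self):
        s = 3.7
        grad = np.array([[0.0, s], [0.0, 0.0]])
        assert shear_rate(grad) == pytest.approx(abs(s), rel=1e-12)

    def test_random_tensor_matches_elementwise_oracle(self):
        rng = np.random.default_rng(42)
        g = rng.normal(size=(100, 2, 2))
        d = 0.5 * (g + np.swapaxes(g, -1, -2))
        oracle = np.sqrt(2.0 * np.einsum("nij,nij->n", d, d))
        np.testing.assert_allclose(shear_rate(g), oracle, rtol=1e-12)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        CassonParams(tau_y=-1.0, mu_inf=0.003)
    with pytest.raises(ValueError):
        CassonParams(tau_y=0.0, mu_inf=0.0)
    with pytest.raises(ValueError):
        CassonParams(tau_y=0.0, mu_inf=0.003, gamma_dot_min=0.0)
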