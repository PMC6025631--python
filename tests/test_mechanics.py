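"""Ramberg-Osgood mechanics layer and Kelvin-Voigt viscoelastic element."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from ossein import (
    KelvinVoigtParams,
    RambergOsgoodParams,
    closed_form_toughness,
    creep_response,
    energy_decomposition,
    kelvin_voigt_stress,
    material_properties,
    ro_strain,
    ro_stress,
    stress_strain_curve,
)
from ossein.io_cli import REFERENCE_STATES
from ossein.mechanics import ValidityWarning

# (t, F, M) maturation states spanning the simulated window
STATES = REFERENCE_STATES


class TestMaterialMaps:
    def test_immature_state_is_out_of_validity(self):
        with pytest.warns(ValidityWarning):
            props = material_properties(0.0, 1.0)
        assert props.n == pytest.approx(-0.1)
        assert props.beta == pytest.approx(0.85)
        assert props.E == pytest.approx(10.0)

    def test_polynomial_maps_at_reference_state(self):
        _, F, M = STATES[0]
        props = material_properties(F, M)
        assert props.n == pytest.approx(30 * F**10 - 0.1 * M, rel=1e-12)
        assert props.beta == pytest.approx(-0.5 * F**5 + 0.85 * M, rel=1e-12)
        assert props.E == pytest.approx(-5 * F**2 + 10 * M, rel=1e-12)

    def test_hardening_exponent_rises_with_maturity(self):
        n_vals = [material_properties(F, M).n for _, F, M in STATES]
        assert np.all(np.diff(n_vals) > 0)

    def test_strain_decreases_with_maturity_in_elastic_regime(self):
        # below the modulus stress (sigma/E < 1) a more mature matrix is
        # stiffer: smaller plastic term via larger n and smaller beta
        sigma = 5.0
        strains = []
        for _, F, M in STATES:
            props = material_properties(F, M)
            strains.append(ro_strain(sigma, RambergOsgoodParams(10.0, props.beta, props.n)))
        assert np.all(np.diff(strains) < 0)


class TestRambergOsgood:
    def test_strain_examples(self):
        p = RambergOsgoodParams(E=10.0, beta=1.0, n=2.0)
        assert ro_strain(0.0, p) == 0.0
        assert ro_strain(10.0, p) == pytest.approx(2.0)
        lin = RambergOsgoodParams(E=10.0, beta=0.0, n=2.0)
        assert ro_strain(7.0, lin) == pytest.approx(0.7)

    @given(
        E=st.floats(min_value=1.0, max_value=100.0),
        beta=st.floats(min_value=0.0, max_value=5.0),
        n=st.floats(min_value=1.1, max_value=8.0),
        r=st.floats(min_value=1e-3, max_value=3.0),
    )
    @settings(max_examples=80, deadline=None)
    def test_inversion_round_trip(self, E, beta, n, r):
        p = RambergOsgoodParams(E=E, beta=beta, n=n)
        sigma = r * E
        eps = ro_strain(sigma, p)
        assert ro_stress(eps, p) == pytest.approx(sigma, rel=1e-10, abs=1e-10)


class TestCurvesAndEnergy:
    def test_linear_curve_and_energy(self):
        p = RambergOsgoodParams(E=10.0, beta=0.0, n=2.0)
        assert closed_form_toughness(p, 10.0) == pytest.approx(10.0**2 / (2 * 10.0))

    def test_worked_case(self):
        p = RambergOsgoodParams(E=10.0, beta=1.0, n=2.0)
        assert ro_strain(10.0, p) == pytest.approx(2.0)
        assert closed_form_toughness(p, 10.0) == pytest.approx(35.0 / 3.0, rel=1e-12)

    @given(
        E=st.floats(min_value=2.0, max_value=50.0),
        beta=st.floats(min_value=0.0, max_value=2.0),
        n=st.floats(min_value=1.2, max_value=6.0),
        r=st.floats(min_value=0.1, max_value=2.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_toughness_quadrature_matches_closed_form(self, E, beta, n, r):
        sigma_max = r * E
        p = RambergOsgoodParams(E=E, beta=beta, n=n)
        stresses = np.linspace(0, sigma_max, 2000)
        strains = ro_strain(stresses, p)
        quad = np.trapezoid(stresses, strains)
        assert quad == pytest.approx(closed_form_toughness(p, sigma_max), rel=1e-3)

    def test_state_fan_is_distinct_and_monotone(self):
        curves = [
            stress_strain_curve(F, M, sigma_max=120.0, E_fixed=10.0) for _, F, M in STATES
        ]
        ult = [c.strains[-1] for c in curves]
        assert len(set(np.round(ult, 6))) == len(STATES)
        for c in curves:
            assert np.all(np.diff(c.strains) > 0)

    def test_energy_decomposition_sums(self):
        curve = stress_strain_curve(0.7960, 0.5598, sigma_max=120.0, n_points=4000)
        split = energy_decomposition(curve)
        assert split.toughness == pytest.approx(split.we + split.wp_mech)
        assert split.we > 0 and split.wp_mech > 0
        assert curve.toughness == split.toughness

    def test_yield_none_assigns_plastic_remainder(self):
        curve = stress_strain_curve(0.7960, 0.5598, sigma_max=1.0, n_points=2000)
        split = energy_decomposition(curve, yield_method="none")
        # elastic share at sigma_max; remainder is the plastic work
        # beta*E*r^(n+1)*n/(n+1) from the closed-form antiderivative
        E, beta, n = curve.params.E, curve.params.beta, curve.params.n
        r = 1.0 / E
        assert split.we == pytest.approx(1.0 / (2 * E), rel=1e-9)
        assert split.wp_mech == pytest.approx(
            beta * E * r ** (n + 1) * n / (n + 1), rel=1e-2
        )

    def test_non_monotone_curve_rejected(self):
        from ossein.mechanics import StressStrainCurve

        bad = StressStrainCurve(
            stresses=np.array([0.0, 1.0, 2.0]),
            strains=np.array([0.0, 0.2, 0.1]),
            params=RambergOsgoodParams(E=10.0, beta=1.0, n=2.0),
        )
        with pytest.raises(ValueError, match="monotone"):
            energy_decomposition(bad)


class TestKelvinVoigt:
    def test_pure_spring(self):
        p = KelvinVoigtParams(E_spring=2.0, eta_visc=1.0)
        assert kelvin_voigt_stress(0.3, 0.0, p) == pytest.approx(0.6)

    def test_creep_worked_case_and_asymptote(self):
        p = KelvinVoigtParams(E_spring=2.0, eta_visc=1.0)
        assert creep_response(4.0, 0.5, p) == pytest.approx(2 * (1 - np.exp(-1.0)), rel=1e-12)
        assert creep_response(4.0, 1e6, p) == pytest.approx(2.0, rel=1e-9)

    def test_creep_matches_numerical_integration(self):
        p = KelvinVoigtParams(E_spring=2.0, eta_visc=1.0)
        sigma0 = 4.0
        sol = solve_ivp(
            lambda t, e: [(sigma0 - p.E_spring * e[0]) / p.eta_visc],
            (0, 3), [0.0], t_eval=np.linspace(0, 3, 31), rtol=1e-11, atol=1e-13,
        )
        np.testing.assert_allclose(
            sol.y[0], creep_response(sigma0, sol.t, p), atol=1e-8
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            KelvinVoigtParams(E_spring=0.0, eta_visc=1.0)
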