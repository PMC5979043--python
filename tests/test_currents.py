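"""Membrane and process current laws: frozen reference values, sign
conventions, stoichiometry and the rest calibration.

Expected numbers were computed independently with 30-digit arithmetic
from the tabulated parameters.
"""

import dataclasses
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pscsim.currents import (CompartmentState, background_current,
                             calibrate_rest, compute_currents, eaat_currents,
                             eaat_reversal, ecs_leak_current, kir_current,
                             nernst_potential, nka_currents,
                             poole_frenkel_current)
from pscsim.parameters import astro_params

concentrations = st.floats(min_value=1e-6, max_value=0.5,
                           allow_nan=False, allow_infinity=False)
voltages = st.floats(min_value=-0.15, max_value=0.05,
                     allow_nan=False, allow_infinity=False)


@st.composite
def states(draw):
    return CompartmentState(
        V_A=draw(voltages), K_PsC=draw(concentrations),
        Na_PsC=draw(concentrations), K_PsECS=draw(concentrations),
        Glu_PsECS=draw(st.floats(min_value=1e-7, max_value=1e-2)))


class TestNernst:
    @pytest.mark.parametrize("c_out, c_in, z, expected", [
        (0.003, 0.1, 1, -0.0936233),    # K+ across the cradle membrane
        (0.145, 0.015, 1, 0.0605727),   # Na+ across the cradle membrane
        (0.05, 0.05, 1, 0.0),           # equal concentrations
        (0.1, 0.003, -1, -0.0936233),   # valence enters the denominator
    ])
    def test_reference_values(self, c_out, c_in, z, expected, constants):
        assert nernst_potential(c_out, c_in, z, constants) == pytest.approx(
            expected, abs=1e-6)

    def test_nonpositive_concentration_rejected(self, constants):
        with pytest.raises(ValueError):
            nernst_potential(0.0, 0.1, 1, constants)
        with pytest.raises(ValueError):
            nernst_potential(0.003, -0.1, 1, constants)


class TestKir:
    def test_baseline_value_per_reversal_mode(self, baseline, morph, constants):
        """Frozen baseline currents for each Kir reversal convention."""
        cases = {"fixed": -7.02334e-15, "nernst_offset": -1.30553e-15,
                 "nernst": 2.21284e-16}
        for mode, expected in cases.items():
            p = astro_params(kir_reversal_mode=mode)
            assert kir_current(baseline, p, morph, constants) == pytest.approx(
                expected, rel=1e-4)

    def test_zero_at_reversal(self, morph, constants):
        p = astro_params(kir_reversal_mode="fixed")
        s = CompartmentState(V_A=0.025)
        assert kir_current(s, p, morph, constants) == 0.0

    def test_linear_in_extracellular_potassium_fixed_mode(self, morph, constants):
        p = astro_params(kir_reversal_mode="fixed")
        s1 = CompartmentState(K_PsECS=0.003)
        s2 = CompartmentState(K_PsECS=0.006)
        assert kir_current(s2, p, morph, constants) == pytest.approx(
            2 * kir_current(s1, p, morph, constants), rel=1e-12)


class TestBackground:
    def test_baseline_potassium_with_printed_conductance(self, baseline, morph,
                                                         constants):
        p = astro_params()
        assert background_current("K", baseline, p, morph, constants) == \
            pytest.approx(8.66342e-15, rel=1e-4)

    def test_zero_at_reversal(self, morph, constants):
        p = astro_params()
        e_k = nernst_potential(0.003, 0.1, 1, constants)
        s = CompartmentState(V_A=e_k)
        assert background_current("K", s, p, morph, constants) == pytest.approx(
            0.0, abs=1e-25)

    def test_linear_in_conductance(self, baseline, morph, constants):
        p1 = astro_params()
        p2 = astro_params(g_Na=2 * p1.g_Na)
        assert background_current("Na", baseline, p2, morph, constants) == \
            pytest.approx(2 * background_current("Na", baseline, p1, morph,
                                                 constants), rel=1e-12)

    def test_unknown_ion_rejected(self, baseline, morph, constants):
        with pytest.raises(ValueError, match="ion"):
            background_current("Ca", baseline, astro_params(), morph, constants)


class TestNKA:
    def test_baseline_magnitude(self, baseline, morph, constants):
        i_k, i_na = nka_currents(baseline, astro_params(), morph, constants)
        assert abs(i_k) == pytest.approx(6.10252e-15, rel=1e-4)
        assert i_k < 0  # K+ enters the PsC
        assert i_na > 0  # Na+ leaves

    def test_vanishes_without_cytosolic_sodium(self, morph, constants):
        s = CompartmentState(Na_PsC=1e-6)
        i_k, i_na = nka_currents(s, astro_params(), morph, constants)
        # Hill factor ~ (1e-6/1.5e-3)^1.5 ~ 2e-5 throttles the pump
        assert abs(i_k) < 5e-19
        assert abs(i_na) < 8e-19

    @given(s=states())
    @settings(max_examples=100, deadline=None)
    def test_three_to_two_stoichiometry_exact(self, s, morph, constants):
        i_k, i_na = nka_currents(s, astro_params(), morph, constants)
        assert i_na == pytest.approx(-1.5 * i_k, rel=1e-14)


class TestEAAT:
    def test_reversal_baseline(self, baseline, constants):
        assert eaat_reversal(baseline, astro_params(), constants) == \
            pytest.approx(0.0346282, abs=1e-6)

    def test_reversal_log_additivity_in_glutamate(self, baseline, constants):
        p = astro_params()
        s2 = dataclasses.replace(baseline, Glu_PsECS=baseline.Glu_PsECS * 1000)
        shift = eaat_reversal(s2, p, constants) - eaat_reversal(baseline, p, constants)
        assert shift == pytest.approx(constants.thermal_voltage / 2 * math.log(1000),
                                      rel=1e-9)

    def test_currents_vanish_at_uptake_threshold(self, morph, constants):
        p = astro_params()
        s = CompartmentState(Glu_PsECS=p.s_g)
        assert eaat_currents(s, p, morph, constants) == (0.0, 0.0, 0.0)

    def test_as_printed_profile_is_vanishingly_small(self, baseline, morph,
                                                     constants):
        """With the tabulated constants the transporter current is < 1e-20 A
        at baseline (the unit anomaly of the printed fitting parameters)."""
        i_k, i_na, i_glu = eaat_currents(baseline, astro_params(), morph, constants)
        assert abs(i_k) < 1e-20
        assert abs(i_na) < 1e-20

    @given(s=states())
    @settings(max_examples=100, deadline=None)
    def test_three_one_one_stoichiometry_exact(self, s, morph, constants):
        p = astro_params("rescaled")
        i_k, i_na, i_glu = eaat_currents(s, p, morph, constants)
        assert i_na == pytest.approx(-3.0 * i_k, rel=1e-14)
        assert i_glu == i_k


class TestPooleFrenkel:
    def test_zero_at_zero_driving_potential(self, baseline, morph, constants):
        # V_A = V_m and K_PsC = K_AS, so both voltage and Nernst terms vanish
        assert poole_frenkel_current("K", baseline, astro_params(), morph,
                                     constants) == 0.0

    def test_reference_value_at_10mV(self, morph, constants):
        """+10 mV driving potential with the tabulated well depth."""
        s = CompartmentState(V_A=-0.08)  # K_PsC = K_AS so V_r = 0
        i = poole_frenkel_current("K", s, astro_params(), morph, constants)
        assert i == pytest.approx(2.73449e-18, rel=1e-4)

    def test_sign_follows_driving_potential(self, morph, constants):
        p = astro_params()
        up = poole_frenkel_current("K", CompartmentState(V_A=-0.08), p, morph,
                                   constants)
        down = poole_frenkel_current("K", CompartmentState(V_A=-0.10), p, morph,
                                     constants)
        assert up > 0 > down
        assert up == pytest.approx(-down, rel=1e-12)

    def test_strictly_decreasing_in_well_depth(self, morph, constants):
        """Magnitude falls monotonically as phi_w grows from 4 to 15 k_B T."""
        s = CompartmentState(V_A=-0.08)
        kt = constants.kT_eV
        values = [abs(poole_frenkel_current(
            "K", s, astro_params(phi_w=m * kt), morph, constants))
            for m in range(4, 16)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_log_linear_in_sqrt_driving_potential(self, morph, constants):
        """At fixed T the barrier lowering makes ln|I| - ln|dV| linear in
        sqrt(dV) (the field-dependent activation-energy lowering)."""
        import numpy as np

        p = astro_params()
        dvs = np.array([0.005, 0.01, 0.02, 0.04, 0.08])
        logs = []
        for dv in dvs:
            i = poole_frenkel_current("K", CompartmentState(V_A=-0.09 + dv), p,
                                      morph, constants)
            logs.append(math.log(i / dv))
        x = np.sqrt(dvs)
        slope, intercept = np.polyfit(x, logs, 1)
        resid = np.array(logs) - (slope * x + intercept)
        assert np.abs(resid).max() < 1e-9
        # and the slope matches sqrt(Q/(l pi eps)) / kT
        eps = constants.eps0 * constants.eps_r
        expected = math.sqrt(constants.Q / (p.l_P * math.pi * eps)) / constants.kT_eV
        assert slope == pytest.approx(expected, rel=1e-9)

    def test_arrhenius_in_temperature(self, morph):
        """ln|I| is linear in 1/T with slope set by the well depth."""
        import numpy as np

        from pscsim.constants import Constants

        p = astro_params()
        s = CompartmentState(V_A=-0.08)
        temps = np.array([290.0, 300.0, 310.0, 320.0])
        logs = [math.log(abs(poole_frenkel_current(
            "K", s, p, morph, Constants(T=t)))) for t in temps]
        slope = np.polyfit(1.0 / temps, logs, 1)[0]
        # slope ~ -(Q phi_w - lowering)/k_B; dominated by the well term
        expected = -(p.phi_w * 1.6022e-19) / 1.38e-23
        assert slope == pytest.approx(expected, rel=0.02)


class TestEcsLeak:
    def test_zero_when_balanced(self, baseline, morph, constants):
        assert ecs_leak_current(baseline, astro_params(), morph, constants) == 0.0

    def test_reference_value_at_doubled_potassium(self, morph, constants):
        s = CompartmentState(K_PsECS=0.006)
        assert ecs_leak_current(s, astro_params(), morph, constants) == \
            pytest.approx(9.59747e-16, rel=1e-4)

    def test_linear_in_conductance(self, morph, constants):
        s = CompartmentState(K_PsECS=0.006)
        p1, p2 = astro_params(), astro_params(g_ECS=6.6)
        assert ecs_leak_current(s, p2, morph, constants) == pytest.approx(
            2 * ecs_leak_current(s, p1, morph, constants), rel=1e-12)


class TestCalibrateRest:
    def test_budgets_vanish_after_calibration(self, astro, baseline, morph,
                                              constants):
        cal = calibrate_rest(astro, baseline, morph, constants)
        assert abs(cal.residual_K) < 1e-22
        assert abs(cal.residual_Na) < 1e-22

    def test_printed_conductances_leave_recorded_residuals(self, astro, baseline,
                                                           morph, constants):
        """The tabulated g_K does not balance the K+ budget; the calibration
        records the residual instead of hiding it."""
        cal = calibrate_rest(astro, baseline, morph, constants)
        assert cal.residual_K_printed != 0.0
        assert abs(cal.residual_K_printed) > 1e-16
        # the printed g_Na is nearly self-consistent (the same construction
        # the source evidently used)
        assert abs(cal.residual_Na_printed) < 1e-16
        assert cal.g_Na == pytest.approx(astro.g_Na, rel=2e-3)

    def test_only_background_conductances_change(self, astro, baseline, morph,
                                                 constants):
        cal = calibrate_rest(astro, baseline, morph, constants)
        for f in dataclasses.fields(astro):
            if f.name in ("g_K", "g_Na"):
                continue
            assert getattr(cal.params, f.name) == getattr(astro, f.name)


@given(s=states())
@settings(max_examples=50, deadline=None)
def test_all_currents_finite_over_state_space(s, morph, constants):
    """Every channel law returns a finite current on physiological states."""
    cs = compute_currents(s, astro_params("rescaled"), morph, constants)
    for name, value in cs.to_dict().items():
        assert math.isfinite(value), name
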