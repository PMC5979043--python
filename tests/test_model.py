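"""Coupled-system assembly: derivative bookkeeping, the Euler stepper,
the compiled loop, determinism and convergence."""

import dataclasses
import math

import numpy as np
import pytest

from pscsim import _kernel as K
from pscsim.currents import CompartmentState, background_current
from pscsim.model import (SystemState, euler_step, pack_params, pack_protocol,
                          prepare_setup, run_simulation, system_derivatives)
from pscsim.neuron import NeuronState
from pscsim.parameters import astro_params, neuron_params
from pscsim.protocols import (ClampSpec, ProtocolSpec, build_k_driven,
                              build_unstimulated)


@pytest.fixture(scope="module")
def rest_system(setup_default):
    return SystemState(astro=setup_default.initial,
                       neuron=setup_default.neuron_rest, t=0.0)


class TestDerivatives:
    def test_calibrated_rest_is_a_fixed_point(self, setup_default, rest_system):
        d = system_derivatives(rest_system, setup_default.astro,
                               setup_default.neuron, setup_default.morph,
                               setup_default.constants)
        for name in ("V_A", "K_PsC", "Na_PsC", "K_PsECS", "Glu_PsECS"):
            assert abs(d[name]) < 1e-12, name
        assert abs(d["V_Neu"]) < 1e-5

    def test_current_to_concentration_conversion(self, setup_default,
                                                 rest_system):
        """With only the background K+ channel open, the PsC K+ derivative
        is exactly -I/(F Vol): the unit-conversion path z F Vol."""
        su = setup_default
        p = astro_params(g_Kir=0.0, g_Na=0.0, P_nka_max=0.0, K_K=0.0, K_Na=0.0,
                         g_ECS=0.0, alpha_EAAT=0.0, g_K=su.astro.g_K)
        neu = dataclasses.replace(su.neuron, g_KNeu=0.0, P_nka_max_neu=0.0)
        s = SystemState(astro=CompartmentState(V_A=-0.08),
                        neuron=su.neuron_rest, t=0.0)
        d = system_derivatives(s, p, neu, su.morph, su.constants)
        i_kb = background_current("K", s.astro, p, su.morph, su.constants)
        expected = -i_kb / (su.constants.F * su.morph.Vol_PS)
        assert d["K_PsC"] == pytest.approx(expected, rel=1e-12)

    def test_membrane_transfer_conserves_moles(self, setup_default, rest_system):
        """K+ leaving the PsECS through the astrocyte membrane appears in the
        PsC mole-for-mole when the leak, process and neurone routes are off."""
        su = setup_default
        p = astro_params(g_ECS=0.0, K_K=0.0, K_Na=0.0, g_K=su.astro.g_K,
                         g_Na=su.astro.g_Na)
        neu = dataclasses.replace(su.neuron, g_KNeu=0.0, P_nka_max_neu=0.0)
        s = SystemState(astro=CompartmentState(V_A=-0.07, K_PsECS=0.006),
                        neuron=su.neuron_rest, t=0.0)
        d = system_derivatives(s, p, neu, su.morph, su.constants)
        gain_psc = d["K_PsC"] * su.morph.Vol_PS
        loss_psecs = -d["K_PsECS"] * su.morph.Vol_PsECS
        assert gain_psc == pytest.approx(loss_psecs, rel=1e-12)

    def test_clamped_variables_have_zero_derivative(self, setup_default,
                                                    rest_system):
        su = setup_default
        s = SystemState(astro=CompartmentState(V_A=-0.07, K_PsECS=0.006,
                                               Glu_PsECS=1e-4),
                        neuron=su.neuron_rest, t=0.0)
        d = system_derivatives(s, su.astro, su.neuron, su.morph, su.constants,
                               clamps=ClampSpec(hold_K_PsECS=True, hold_Glu=True))
        assert d["K_PsECS"] == 0.0
        assert d["Glu_PsECS"] == 0.0


class TestEulerStep:
    def test_zero_derivatives_leave_state_unchanged(self, rest_system):
        zeros = {k: 0.0 for k in ("V_A", "K_PsC", "Na_PsC", "K_PsECS",
                                  "Glu_PsECS", "V_Neu", "n", "m", "h")}
        out = euler_step(rest_system, zeros, 1e-5)
        assert out.astro == rest_system.astro
        assert out.neuron == rest_system.neuron
        assert out.t == pytest.approx(1e-5)

    def test_glutamate_floor_enforced(self, rest_system):
        derivs = {k: 0.0 for k in ("V_A", "K_PsC", "Na_PsC", "K_PsECS",
                                   "V_Neu", "n", "m", "h")}
        derivs["Glu_PsECS"] = -1.0  # forced negative increment
        out = euler_step(rest_system, derivs, 1e-3,
                         clamps=ClampSpec(glu_floor=1e-6))
        assert out.astro.Glu_PsECS == 1e-6

    def test_nonpositive_concentration_raises_with_advice(self, rest_system):
        derivs = {k: 0.0 for k in ("V_A", "Na_PsC", "K_PsECS", "Glu_PsECS",
                                   "V_Neu", "n", "m", "h")}
        derivs["K_PsC"] = -1e6
        with pytest.raises(ValueError, match="smaller dt"):
            euler_step(rest_system, derivs, 1e-3)


class TestKernelAgreement:
    def test_one_step_matches_reference_implementation(self, setup_default):
        """The compiled loop and the pure-Python reference produce the same
        Euler update from a perturbed state."""
        su = setup_default
        astro0 = CompartmentState(V_A=-0.085, K_PsC=0.102, Na_PsC=0.014,
                                  K_PsECS=0.004, Glu_PsECS=2e-6)
        neuron0 = NeuronState(V_Neu=-0.06, n=0.4, m=0.2, h=0.5)
        s = SystemState(astro=astro0, neuron=neuron0, t=0.0)
        dt = 1e-5
        d = system_derivatives(s, su.astro, su.neuron, su.morph, su.constants)
        expected = euler_step(s, d, dt)

        proto = ProtocolSpec(kind="unstimulated", drive_kind="none",
                             stim_start=0.0, stim_end=dt, duration=dt, dt=dt,
                             record_dt=dt)
        P = pack_params(su.astro, su.neuron, su.morph, su.constants)
        R = pack_protocol(proto)
        y0 = np.array([astro0.V_A, astro0.K_PsC, astro0.Na_PsC, astro0.K_PsECS,
                       astro0.Glu_PsECS, neuron0.V_Neu, neuron0.n, neuron0.m,
                       neuron0.h])
        Y, stats = K.integrate(y0, P, R, 1, 1)
        got = Y[-1]
        ref = [expected.astro.V_A, expected.astro.K_PsC, expected.astro.Na_PsC,
               expected.astro.K_PsECS, expected.astro.Glu_PsECS,
               expected.neuron.V_Neu, expected.neuron.n, expected.neuron.m,
               expected.neuron.h]
        assert got == pytest.approx(ref, rel=1e-12)

    def test_total_potassium_conserved_without_sinks(self, setup_default):
        """With the leak, process and neurone routes disabled, total K+
        moles in PsC + PsECS are conserved along a trajectory."""
        su = setup_default
        p = astro_params(g_ECS=0.0, K_K=0.0, K_Na=0.0, g_K=su.astro.g_K,
                         g_Na=su.astro.g_Na)
        neu = dataclasses.replace(su.neuron, g_KNeu=0.0, P_nka_max_neu=0.0)
        setup = dataclasses.replace(
            su, astro=p, neuron=neu,
            initial=CompartmentState(V_A=-0.07, K_PsECS=0.006))
        proto = ProtocolSpec(kind="unstimulated", drive_kind="none",
                             stim_start=0.0, stim_end=1e-9, duration=2.0,
                             dt=1e-5)
        res = run_simulation(proto, setup=setup)
        moles = (res.states["K_PsC"] * su.morph.Vol_PS
                 + res.states["K_PsECS"] * su.morph.Vol_PsECS)
        assert moles.max() - moles.min() <= 1e-9 * moles.iloc[0]


class TestRunSimulation:
    def test_identical_protocols_are_bit_identical(self, setup_default):
        proto = build_k_driven(40, duration=8.0, stim_start=1.0, stim_end=7.0)
        a = run_simulation(proto, setup=setup_default)
        b = run_simulation(proto, setup=setup_default)
        assert np.array_equal(a.states.to_numpy(), b.states.to_numpy())

    def test_metadata_records_profile_and_calibration(self, unstimulated_run):
        meta = unstimulated_run.metadata
        assert meta["eaat_profile"] == "as_printed"
        assert "g_K" in meta["calibration"]
        assert "deterministic" in meta["determinism"]

    def test_uniform_sampling(self, unstimulated_run):
        dts = np.diff(unstimulated_run.times)
        assert np.allclose(dts, dts[0])

    def test_blowup_reports_time_and_variable(self, setup_default):
        """An unstable step size fails with an informative error rather
        than returning garbage."""
        su = setup_default
        bad = dataclasses.replace(su, astro=astro_params(
            g_K=su.astro.g_K, g_Na=su.astro.g_Na, P_nka_max=1e-2))
        proto = build_unstimulated(duration=1.0)
        with pytest.raises(RuntimeError, match="t ="):
            run_simulation(proto, setup=bad)

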