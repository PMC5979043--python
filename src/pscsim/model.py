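"""Assembly of the coupled astrocyte/neurone system and its integration.

The five astrocyte state variables (membrane voltage, PsC K+ and Na+,
PsECS K+ and glutamate) and the four neuronal variables (voltage and the
HH gating triplet) are advanced synchronously by fixed-step forward
Euler.  Concentration derivatives are current sums divided by ``z F Vol``
of the receiving compartment; the astrocyte membrane voltage integrates
the total membrane current (the process hopping current runs to the soma
and does not cross the perisynaptic membrane, so it enters the
concentration budgets but not the voltage equation).

Two implementations exist: a readable pure-Python reference
(:func:`system_derivatives` / :func:`euler_step`) used by the tests, and
the compiled loop in :mod:`pscsim._kernel` used by
:func:`run_simulation`; a unit test holds them to agreement.

Positivity of concentrations is enforced by error rather than silent
clipping; the only sanctioned clip is the glutamate floor, which stands
in for the unmodelled glutamate resupply pathways.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernel as K
from .constants import Constants, DEFAULT_CONSTANTS
from .currents import (CompartmentState, CurrentSet, RestCalibration,
                       calibrate_rest, compute_currents)
from .geometry import DerivedMorphology, MorphologySpec, derive_morphology
from .neuron import (NeuronState, calibrate_neuron_nka,
                     calibrate_release_fraction, hh_derivatives,
                     hh_rest_state, neuron_k_release_current,
                     neuron_nka_current)
from .parameters import AstroParams, NeuronParams, astro_params, neuron_params
from .protocols import ClampSpec, ProtocolSpec

logger = logging.getLogger(__name__)

STATE_COLUMNS = ("V_A", "K_PsC", "Na_PsC", "K_PsECS", "Glu_PsECS",
                 "V_Neu", "n", "m", "h")


@dataclass(frozen=True)
class SystemState:
    """Astrocyte + neurone state at one instant of the simulation clock."""

    astro: CompartmentState
    neuron: NeuronState
    t: float = 0.0


@dataclass(frozen=True)
class SimSetup:
    """Calibrated parameter bundle shared by one or more runs."""

    astro: AstroParams                # after rest calibration
    astro_uncalibrated: AstroParams   # before rest calibration (sweep base)
    neuron: NeuronParams              # release fraction + pump calibrated
    morph: DerivedMorphology
    constants: Constants
    rest_calibration: RestCalibration
    neuron_rest: NeuronState
    initial: CompartmentState


def prepare_setup(astro: AstroParams | None = None,
                  neuron: NeuronParams | None = None,
                  morph: MorphologySpec | None = None,
                  constants: Constants | None = None,
                  initial: CompartmentState | None = None,
                  morph_derived: DerivedMorphology | None = None,
                  neuron_calibrated: NeuronParams | None = None,
                  eaat_profile: str = "as_printed") -> SimSetup:
    """Derive morphology and run the full calibration chain.

    Order: (1) the neuronal coupling fraction is fixed by the
    high-frequency release/clearance balance, (2) the neuronal pump is
    set to cancel resting K+ leak, (3) the astrocyte background
    conductances are solved so the tabulated initial state is a fixed
    point.  Pass ``neuron_calibrated`` to reuse a previous neuronal
    calibration (parameter sweeps hold it fixed at the reference).
    """
    constants = constants or DEFAULT_CONSTANTS
    m = morph_derived if morph_derived is not None else derive_morphology(morph or MorphologySpec())
    astro = astro if astro is not None else astro_params(eaat_profile)
    initial = initial or CompartmentState()
    if neuron_calibrated is not None:
        neu = neuron_calibrated
    else:
        neu = neuron or neuron_params()
        neu = calibrate_release_fraction(neu, astro, m, constants)
        neu = calibrate_neuron_nka(neu, m, K_PsECS=initial.K_PsECS, constants=constants)
    cal = calibrate_rest(astro, initial, m, constants)
    return SimSetup(astro=cal.params, astro_uncalibrated=astro, neuron=neu,
                    morph=m, constants=constants, rest_calibration=cal,
                    neuron_rest=hh_rest_state(neu), initial=initial)


# ---------------------------------------------------------------------------
# Pure-Python reference derivative / step (tests, small explorations)
# ---------------------------------------------------------------------------


def system_derivatives(s: SystemState, astro: AstroParams, neuron: NeuronParams,
                       m: DerivedMorphology,
                       constants: Constants = DEFAULT_CONSTANTS,
                       clamps: ClampSpec | None = None,
                       I_app: float = 0.0) -> dict:
    """Time derivatives of every state variable (SI units per second).

    Clamped variables return a zero derivative; soma and global-ECS
    concentrations are parameters and never change.
    """
    clamps = clamps or ClampSpec()
    cs = compute_currents(s.astro, astro, m, constants)
    for name, v in cs.to_dict().items():
        if not math.isfinite(v):
            raise ArithmeticError(f"non-finite current {name} at t={s.t}")
    i_kneu = neuron_k_release_current(s.neuron, neuron, m)
    i_knka_neu = neuron_nka_current(s.astro.K_PsECS, neuron, m, constants)

    f = constants.F
    d_k_psc = -(cs.I_K_membrane + cs.I_KPF) / (f * m.Vol_PS)
    d_na_psc = -(cs.I_Na_membrane + cs.I_NaPF) / (f * m.Vol_PS)
    d_k_psecs = (cs.I_K_membrane - cs.I_KECSL + i_kneu - i_knka_neu) / (f * m.Vol_PsECS)
    d_glu = -cs.I_GluEAAT / (f * m.Vol_PsECS)
    d_v_a = -(cs.I_K_membrane + cs.I_Na_membrane) / (constants.C_m * m.SA_PS)
    if clamps.hold_K_PsECS:
        d_k_psecs = 0.0
    if clamps.hold_Glu:
        d_glu = 0.0
    dv_n, dn, dm, dh = hh_derivatives(s.neuron, neuron, I_app=I_app)
    return {"V_A": d_v_a, "K_PsC": d_k_psc, "Na_PsC": d_na_psc,
            "K_PsECS": d_k_psecs, "Glu_PsECS": d_glu,
            "V_Neu": dv_n, "n": dn, "m": dm, "h": dh,
            "currents": cs, "I_KNeu": i_kneu, "I_KNKANeu": i_knka_neu}


def euler_step(s: SystemState, derivs: dict, dt: float,
               clamps: ClampSpec | None = None) -> SystemState:
    """One forward-Euler update ``s + dt * derivs`` with the glutamate
    floor applied afterwards."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    clamps = clamps or ClampSpec()
    a = s.astro
    glu = a.Glu_PsECS + dt * derivs["Glu_PsECS"]
    glu = max(glu, clamps.glu_floor)
    new = {
        "V_A": a.V_A + dt * derivs["V_A"],
        "K_PsC": a.K_PsC + dt * derivs["K_PsC"],
        "Na_PsC": a.Na_PsC + dt * derivs["Na_PsC"],
        "K_PsECS": a.K_PsECS + dt * derivs["K_PsECS"],
        "Glu_PsECS": glu,
    }
    for name in ("K_PsC", "Na_PsC", "K_PsECS"):
        if new[name] <= 0:
            raise ValueError(
                f"Euler step drove {name} non-positive ({new[name]:.3e} M); "
                f"use a smaller dt")
    astro = CompartmentState(**new)
    neuron = NeuronState(
        V_Neu=s.neuron.V_Neu + dt * derivs["V_Neu"],
        n=min(1.0, max(0.0, s.neuron.n + dt * derivs["n"])),
        m=min(1.0, max(0.0, s.neuron.m + dt * derivs["m"])),
        h=min(1.0, max(0.0, s.neuron.h + dt * derivs["h"])),
    )
    return SystemState(astro=astro, neuron=neuron, t=s.t + dt)


# ---------------------------------------------------------------------------
# Packing for the compiled loop
# ---------------------------------------------------------------------------

_KIR_MODE_CODE = {"nernst": 0.0, "nernst_offset": 1.0, "fixed": 2.0}


def pack_params(astro: AstroParams, neuron: NeuronParams, m: DerivedMorphology,
                constants: Constants) -> np.ndarray:
    P = np.zeros(K.N_PARAMS)
    P[K.P_VM] = astro.V_m
    P[K.P_PHI_W] = astro.phi_w
    P[K.P_G_KIR] = astro.g_Kir
    P[K.P_G_K] = astro.g_K
    P[K.P_G_NA] = astro.g_Na
    P[K.P_K_K] = astro.K_K
    P[K.P_K_NA] = astro.K_Na
    P[K.P_PNKA] = astro.P_nka_max
    P[K.P_K_NAI] = astro.K_Nai
    P[K.P_K_KE] = astro.K_KE
    P[K.P_E_KIR_FIXED] = astro.e_kir_fixed
    P[K.P_KIR_OFFSET] = astro.kir_offset
    P[K.P_G_ECS] = astro.g_ECS
    P[K.P_ALPHA] = astro.alpha_EAAT
    P[K.P_BETA] = astro.beta_EAAT
    P[K.P_R_G] = astro.r_g
    P[K.P_S_G] = astro.s_g
    P[K.P_PREF] = astro.eaat_prefactor
    P[K.P_GLU_PSC] = astro.Glu_PsC
    P[K.P_H_PSC] = astro.H_PsC
    P[K.P_K_AS] = astro.K_AS
    P[K.P_NA_AS] = astro.Na_AS
    P[K.P_H_PSECS] = astro.H_PsECS
    P[K.P_NA_PSECS] = astro.Na_PsECS
    P[K.P_K_GECS] = astro.K_GECS
    P[K.P_NA_GECS] = astro.Na_GECS
    P[K.P_L_P] = astro.l_P
    P[K.P_KIR_MODE] = _KIR_MODE_CODE[astro.kir_reversal_mode]
    P[K.P_SA_PS] = m.SA_PS
    P[K.P_CSA_P] = m.CSA_P
    P[K.P_SA_ECSL] = m.SA_PsECS_GECS
    P[K.P_SA_SYN] = m.SA_Syn
    P[K.P_VOL_PSC] = m.Vol_PS
    P[K.P_VOL_PSECS] = m.Vol_PsECS
    P[K.P_RT_F] = constants.thermal_voltage
    P[K.P_F] = constants.F
    P[K.P_Q] = constants.Q
    P[K.P_KT_EV] = constants.kT_eV
    P[K.P_EPS] = constants.eps0 * constants.eps_r
    P[K.P_C_M] = constants.C_m
    P[K.P_G_NA_HH] = neuron.g_Na_hh
    P[K.P_G_K_HH] = neuron.g_K_hh
    P[K.P_G_L_HH] = neuron.g_L_hh
    P[K.P_E_NA_N] = neuron.E_Na
    P[K.P_E_K_N] = neuron.E_K
    P[K.P_E_L_N] = neuron.E_L
    P[K.P_C_M_NEU] = neuron.C_m_neu
    P[K.P_SHIFT] = neuron.voltage_shift
    P[K.P_G_KNEU] = neuron.g_KNeu
    P[K.P_E_KNEU] = neuron.E_KNeu
    P[K.P_PNKA_NEU] = abs(neuron.P_nka_max_neu)
    P[K.P_K_NAI_NEU] = neuron.K_NaiNeu
    P[K.P_K_KE_NEU] = neuron.K_KENeu
    P[K.P_NA_SYN] = neuron.Na_Syn
    P[K.P_F_REL] = neuron.release_fraction
    return P


_DRIVE_CODE = {"none": 0.0, "constant": 1.0, "pulse": 2.0}


def pack_protocol(proto: ProtocolSpec) -> np.ndarray:
    R = np.zeros(K.N_PROTO)
    R[K.R_DT] = proto.dt
    R[K.R_STIM_START] = proto.stim_start
    R[K.R_STIM_END] = proto.stim_end
    R[K.R_DRIVE_KIND] = _DRIVE_CODE[proto.drive_kind]
    R[K.R_AMP] = proto.drive_amplitude
    R[K.R_RATE] = proto.firing_rate
    R[K.R_PULSE_W] = proto.pulse_width
    if proto.clamps.hold_Glu:
        R[K.R_GLU_MODE] = 0.0
        R[K.R_GLU_CLAMP] = proto.clamps.Glu_value
    elif proto.glu_puff_peak > 0.0:
        R[K.R_GLU_MODE] = 2.0
        R[K.R_GLU_PEAK] = proto.glu_puff_peak
        R[K.R_GLU_T0] = proto.glu_puff_centre
        R[K.R_GLU_SIGMA] = proto.glu_puff_sigma
        R[K.R_GLU_BASE] = proto.clamps.glu_floor
    else:
        R[K.R_GLU_MODE] = 1.0
    R[K.R_GLU_FLOOR] = proto.clamps.glu_floor
    R[K.R_K_CLAMP] = 1.0 if proto.clamps.hold_K_PsECS else 0.0
    R[K.R_K_CLAMP_VAL] = proto.clamps.K_PsECS_value
    R[K.R_SPIKE_PUFF] = proto.glu_puff_per_spike
    R[K.R_SPIKE_THR] = proto.spike_threshold
    R[K.R_REFRACTORY] = proto.refractory
    return R


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Uniformly sampled trajectory of states and currents plus metadata.

    ``states``/``currents`` are DataFrames indexed by row with a ``t``
    column in seconds; ``stats`` holds full-resolution extrema gathered
    inside the stimulation window during integration.
    """

    times: np.ndarray
    states: pd.DataFrame
    currents: pd.DataFrame
    stats: dict
    metadata: dict

    def series(self, column: str) -> tuple[np.ndarray, np.ndarray]:
        frame = self.states if column in self.states else self.currents
        return self.times, frame[column].to_numpy()


def _currents_frame(Y: np.ndarray, astro: AstroParams, neuron: NeuronParams,
                    m: DerivedMorphology, constants: Constants) -> pd.DataFrame:
    """Vectorised re-evaluation of every current along a trajectory."""
    v_a, k_psc, na_psc, k_psecs, glu = (Y[:, i] for i in range(5))
    v_n, gn = Y[:, 5], Y[:, 6]
    rt_f = constants.thermal_voltage
    sa = m.SA_PS

    e_n = rt_f * np.log(k_psecs / k_psc)
    if astro.kir_reversal_mode == "fixed":
        e_kir = np.full_like(e_n, astro.e_kir_fixed)
    elif astro.kir_reversal_mode == "nernst_offset":
        e_kir = e_n + astro.kir_offset
    else:
        e_kir = e_n
    i_kir = astro.g_Kir * k_psecs * (v_a - e_kir) * sa
    i_kb = astro.g_K * (v_a - e_n) * sa
    e_na = rt_f * np.log(astro.Na_PsECS / na_psc)
    i_nab = astro.g_Na * (v_a - e_na) * sa

    na15 = na_psc ** 1.5
    hill = na15 / (na15 + astro.K_Nai ** 1.5)
    mm = k_psecs / (k_psecs + astro.K_KE)
    base = constants.F * astro.P_nka_max * hill * mm * sa
    i_knka = -2.0 * base
    i_nanka = 3.0 * base

    ratio = ((astro.Na_PsECS / na_psc) ** 3 * (k_psc / k_psecs)
             * (astro.H_PsECS / astro.H_PsC) * (glu / astro.Glu_PsC))
    v_rev = 0.5 * rt_f * np.log(ratio)
    i_mg = astro.eaat_prefactor * (-astro.alpha_EAAT
                                   * (np.exp(-astro.beta_EAAT * (v_a - v_rev)) - 1.0))
    sat = 1.0 - np.exp(astro.r_g * (astro.s_g - glu))
    j = -i_mg * sat * sa

    eps = constants.eps0 * constants.eps_r
    def pf(k_const, c_soma, c_in):
        dv = v_a - astro.V_m - rt_f * np.log(c_soma / c_in)
        dphi = np.sqrt(constants.Q * np.abs(dv) / (astro.l_P * np.pi * eps))
        return (k_const * (dv / astro.l_P)
                * np.exp(-(astro.phi_w - dphi) / constants.kT_eV) * m.CSA_P)

    i_kpf = pf(astro.K_K, astro.K_AS, k_psc)
    i_napf = pf(astro.K_Na, astro.Na_AS, na_psc)
    i_kecsl = astro.g_ECS * rt_f * np.log(k_psecs / astro.K_GECS) * m.SA_PsECS_GECS

    i_kneu = (neuron.release_fraction * neuron.g_KNeu * gn**4
              * (v_n - neuron.E_KNeu) * m.SA_Syn)
    na15_syn = neuron.Na_Syn ** 1.5
    hill_neu = na15_syn / (na15_syn + neuron.K_NaiNeu ** 1.5)
    mm_neu = k_psecs / (k_psecs + neuron.K_KENeu)
    i_knka_neu = (2.0 * constants.F * abs(neuron.P_nka_max_neu) * hill_neu
                  * mm_neu * neuron.release_fraction * m.SA_Syn)

    return pd.DataFrame({
        "I_Kir": i_kir, "I_KB": i_kb, "I_KNKA": i_knka, "I_KEAAT": j,
        "I_KPF": i_kpf, "I_KECSL": i_kecsl, "I_NaB": i_nab,
        "I_NaNKA": i_nanka, "I_NaEAAT": -3.0 * j, "I_NaPF": i_napf,
        "I_GluEAAT": j, "I_K_membrane": i_kir + i_kb + i_knka + j,
        "I_Na_membrane": i_nab + i_nanka - 3.0 * j,
        "I_KNeu": i_kneu, "I_KNKANeu": i_knka_neu,
    })


def run_simulation(protocol: ProtocolSpec,
                   astro: AstroParams | None = None,
                   neuron: NeuronParams | None = None,
                   morph: MorphologySpec | None = None,
                   constants: Constants | None = None,
                   setup: SimSetup | None = None) -> SimulationResult:
    """Integrate one protocol and return the sampled trajectory.

    Parameters are calibrated (release fraction, neuronal pump, resting
    background conductances) before integration unless a prepared
    ``setup`` is supplied.  The run is fully deterministic: no source of
    randomness exists anywhere in the model.
    """
    if setup is None:
        setup = prepare_setup(astro=astro, neuron=neuron, morph=morph,
                              constants=constants,
                              eaat_profile=protocol.eaat_profile)
    elif setup.astro.eaat_profile != protocol.eaat_profile:
        logger.warning("setup EAAT profile %r differs from protocol profile %r; "
                       "using the setup's parameters",
                       setup.astro.eaat_profile, protocol.eaat_profile)

    P = pack_params(setup.astro, setup.neuron, setup.morph, setup.constants)
    R = pack_protocol(protocol)
    n_steps = int(round(protocol.duration / protocol.dt))
    record_every = max(1, int(round(protocol.record_dt / protocol.dt)))

    y0 = np.array([setup.initial.V_A, setup.initial.K_PsC,
                   setup.initial.Na_PsC, setup.initial.K_PsECS,
                   setup.initial.Glu_PsECS,
                   setup.neuron_rest.V_Neu, setup.neuron_rest.n,
                   setup.neuron_rest.m, setup.neuron_rest.h])

    Y, raw_stats = K.integrate(y0, P, R, n_steps, record_every)
    if raw_stats[K.S_STATUS] != 0.0:
        var = K.FAIL_NAMES.get(raw_stats[K.S_FAIL_VAR], "state")
        raise RuntimeError(
            f"simulation failed at t = {raw_stats[K.S_T_FAIL]:.6f} s: "
            f"{var} became invalid (try a smaller dt)")

    times = np.arange(Y.shape[0]) * protocol.record_dt
    states = pd.DataFrame(Y, columns=STATE_COLUMNS)
    states.insert(0, "t", times)
    currents = _currents_frame(Y, setup.astro, setup.neuron, setup.morph,
                               setup.constants)
    currents.insert(0, "t", times)
    stats = {
        "max_abs_IK_membrane": float(raw_stats[K.S_MAX_IK_MEM]),
        "max_IK_influx": float(raw_stats[K.S_MAX_IK_IN]),
        "max_INa_influx": float(raw_stats[K.S_MAX_INA_IN]),
        "max_abs_IKPF": float(raw_stats[K.S_MAX_IKPF]),
        "max_abs_INa_membrane": float(raw_stats[K.S_MAX_INA_MEM]),
        "max_abs_INaPF": float(raw_stats[K.S_MAX_INAPF]),
        "kir_sign_changes": int(raw_stats[K.S_KIR_SIGN_CHANGES]),
        "spike_count": int(raw_stats[K.S_SPIKES]),
    }
    metadata = {
        "protocol": protocol.to_dict(),
        "dt": protocol.dt,
        "record_dt": protocol.record_dt,
        "n_steps": n_steps,
        "eaat_profile": setup.astro.eaat_profile,
        "kir_reversal_mode": setup.astro.kir_reversal_mode,
        "determinism": "deterministic: the model contains no random number source",
        "calibration": {
            "g_K": setup.rest_calibration.g_K,
            "g_Na": setup.rest_calibration.g_Na,
            "residual_K_printed": setup.rest_calibration.residual_K_printed,
            "residual_Na_printed": setup.rest_calibration.residual_Na_printed,
            "P_nka_max_neu": setup.neuron.P_nka_max_neu,
            "release_fraction": setup.neuron.release_fraction,
            "V_Neu_rest": setup.neuron_rest.V_Neu,
        },
    }
    return SimulationResult(times=times, states=states, currents=currents,
                            stats=stats, metadata=metadata)
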