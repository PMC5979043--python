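"""Astrocyte membrane and process current laws.

Every operation is a pure function of a compartment state and the
parameter set, returning a current in amperes under a single sign
convention:

    **positive current = the ion leaves the named compartment**

i.e. efflux from the PsC for the membrane and process currents, and
efflux from the PsECS toward the global ECS for the leak current.  Each
channel's sign is assigned from its physiology: the NKA imports K+ and
exports Na+, the glutamate transporter (EAAT1/2) exports one K+ while
importing three Na+ and one glutamate, the background channels and Kir
follow their electrochemical driving force, and the process hopping
current carries the sign of its driving potential difference.

The process current follows Poole-Frenkel emission: cations trapped in
potential wells (depth ``phi_w``) formed by fixed negative membrane
charge escape thermally, with the well barrier lowered by the electric
field along the process by ``sqrt(Q |dV| / (l pi eps))``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

from .constants import Constants, DEFAULT_CONSTANTS
from .geometry import DerivedMorphology
from .parameters import AstroParams

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompartmentState:
    """Dynamic astrocyte state: membrane voltage plus the four free
    concentrations (M)."""

    V_A: float = -0.09
    K_PsC: float = 0.1
    Na_PsC: float = 0.015
    K_PsECS: float = 0.003
    Glu_PsECS: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("K_PsC", "Na_PsC", "K_PsECS", "Glu_PsECS"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"concentration {name!r} must be positive, got {v!r}")
        if not math.isfinite(self.V_A):
            raise ValueError(f"V_A must be finite, got {self.V_A!r}")


@dataclass(frozen=True)
class CurrentSet:
    """All per-channel currents (A) at one instant.

    Signs: positive = efflux from the PsC (membrane/process channels) or
    from the PsECS toward the GECS (``I_KECSL``).
    """

    I_Kir: float
    I_KB: float
    I_KNKA: float
    I_KEAAT: float
    I_KPF: float
    I_KECSL: float
    I_NaB: float
    I_NaNKA: float
    I_NaEAAT: float
    I_NaPF: float
    I_GluEAAT: float

    @property
    def I_K_membrane(self) -> float:
        """Total K+ current across the perisynaptic membrane (excludes the
        process current, which runs to the soma)."""
        return self.I_Kir + self.I_KB + self.I_KNKA + self.I_KEAAT

    @property
    def I_Na_membrane(self) -> float:
        return self.I_NaB + self.I_NaNKA + self.I_NaEAAT

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["I_K_membrane"] = self.I_K_membrane
        d["I_Na_membrane"] = self.I_Na_membrane
        return d


def nernst_potential(c_out: float, c_in: float, valence: int,
                     constants: Constants = DEFAULT_CONSTANTS) -> float:
    """Nernst potential (RT/zF) ln(c_out/c_in) in volts."""
    if c_out <= 0 or c_in <= 0:
        raise ValueError(
            f"Nernst potential requires positive concentrations, got c_out={c_out!r}, c_in={c_in!r}")
    if valence == 0:
        raise ValueError("valence must be nonzero")
    return constants.thermal_voltage / valence * math.log(c_out / c_in)


def kir_reversal(state: CompartmentState, p: AstroParams,
                 constants: Constants = DEFAULT_CONSTANTS) -> float:
    """Reversal potential of the Kir channel under the configured mode."""
    if p.kir_reversal_mode == "fixed":
        return p.e_kir_fixed
    e_n = nernst_potential(state.K_PsECS, state.K_PsC, 1, constants)
    if p.kir_reversal_mode == "nernst_offset":
        return e_n + p.kir_offset
    return e_n


def kir_current(state: CompartmentState, p: AstroParams, m: DerivedMorphology,
                constants: Constants = DEFAULT_CONSTANTS) -> float:
    """Inward-rectifying K+ channel current.

    ``g_Kir * [K+]_PsECS * (V_A - E_Kir) * SA_PsC``; the conductance scales
    with the extracellular K+ concentration.  Negative (influx into the
    PsC) whenever ``V_A`` is below the channel reversal.
    """
    e_kir = kir_reversal(state, p, constants)
    return p.g_Kir * state.K_PsECS * (state.V_A - e_kir) * m.SA_PS


def background_current(ion: str, state: CompartmentState, p: AstroParams,
                       m: DerivedMorphology,
                       constants: Constants = DEFAULT_CONSTANTS) -> float:
    """Passive electrochemical background channel ``g_i (V_A - E_i) SA_PsC``.

    ``E_i`` is the ion's Nernst potential between PsECS and PsC.
    """
    if ion == "K":
        g, c_out, c_in = p.g_K, state.K_PsECS, state.K_PsC
    elif ion == "Na":
        g, c_out, c_in = p.g_Na, p.Na_PsECS, state.Na_PsC
    else:
        raise ValueError(f"ion must be 'K' or 'Na', got {ion!r}")
    e_i = nernst_potential(c_out, c_in, 1, constants)
    return g * (state.V_A - e_i) * m.SA_PS


def nka_pump_factor(state: CompartmentState, p: AstroParams) -> float:
    """Dimensionless NKA activation: Hill(1.5) in cytosolic Na+ times
    Michaelis-Menten in extracellular K+."""
    na15 = state.Na_PsC ** 1.5
    hill = na15 / (na15 + p.K_Nai ** 1.5)
    mm = state.K_PsECS / (state.K_PsECS + p.K_KE)
    return hill * mm


def nka_currents(state: CompartmentState, p: AstroParams, m: DerivedMorphology,
                 constants: Constants = DEFAULT_CONSTANTS) -> tuple[float, float]:
    """Na+/K+-ATPase currents ``(I_KNKA, I_NaNKA)``.

    3:2 stoichiometry per cycle: K+ enters the PsC (negative) at magnitude
    ``2 F P_max * activation * SA_PsC`` and Na+ leaves (positive) at 3/2
    that magnitude.
    """
    base = constants.F * p.P_nka_max * nka_pump_factor(state, p) * m.SA_PS
    return -2.0 * base, 3.0 * base


def eaat_reversal(state: CompartmentState, p: AstroParams,
                  constants: Constants = DEFAULT_CONSTANTS) -> float:
    """EAAT1/2 reversal potential from the eight coupled concentrations.

    ``(RT/2F) ln( (Na_o/Na_i)^3 (K_i/K_o) (H_o/H_i) (Glu_o/Glu_i) )`` --
    the two elementary charges moved per cycle give the 2F denominator.
    """
    for name, v in (("Na_PsECS", p.Na_PsECS), ("Na_PsC", state.Na_PsC),
                    ("K_PsC", state.K_PsC), ("K_PsECS", state.K_PsECS),
                    ("H_PsECS", p.H_PsECS), ("H_PsC", p.H_PsC),
                    ("Glu_PsECS", state.Glu_PsECS), ("Glu_PsC", p.Glu_PsC)):
        if v <= 0:
            raise ValueError(f"EAAT reversal requires positive {name}, got {v!r}")
    ratio = ((p.Na_PsECS / state.Na_PsC) ** 3
             * (state.K_PsC / state.K_PsECS)
             * (p.H_PsECS / p.H_PsC)
             * (state.Glu_PsECS / p.Glu_PsC))
    return constants.thermal_voltage / 2.0 * math.log(ratio)


def eaat_currents(state: CompartmentState, p: AstroParams, m: DerivedMorphology,
                  constants: Constants = DEFAULT_CONSTANTS) -> tuple[float, float, float]:
    """Glutamate transporter currents ``(I_KEAAT, I_NaEAAT, I_GluEAAT)``.

    One forward cycle exports 1 K+ from the PsC while importing 3 Na+ and
    1 glutamate: ``I_KEAAT`` is the signed transport rate J (positive =
    forward), ``I_NaEAAT = -3 J`` and ``I_GluEAAT = +J`` with the
    convention that positive ``I_GluEAAT`` removes glutamate from the
    PsECS.  J combines a voltage-dependent maximum uptake rate (driven by
    ``V_A - V_rev``) with a saturating dependence on extracellular
    glutamate above the uptake threshold ``s_g``.
    """
    v_rev = eaat_reversal(state, p, constants)
    i_mg = p.eaat_prefactor * (-p.alpha_EAAT
                               * (math.exp(-p.beta_EAAT * (state.V_A - v_rev)) - 1.0))
    saturation = 1.0 - math.exp(p.r_g * (p.s_g - state.Glu_PsECS))
    j = -i_mg * saturation * m.SA_PS
    return j, -3.0 * j, j


def poole_frenkel_current(ion: str, state: CompartmentState, p: AstroParams,
                          m: DerivedMorphology,
                          constants: Constants = DEFAULT_CONSTANTS) -> float:
    """Field-assisted hopping current of a cation along the thin process.

    ``K_i (dV/l) exp(-(phi_w - dphi)/(k_B T / Q)) CSA_P`` where
    ``dV = V_A - V_m - V_r`` (``V_r`` the soma/PsC Nernst potential) and
    ``dphi = sqrt(Q |dV| / (l pi eps))`` is the Poole-Frenkel barrier
    lowering.  The magnitude of the field enters the barrier term and the
    current carries the sign of ``dV``, so reverse driving is symmetric.
    """
    if ion == "K":
        k_const, c_soma, c_psc = p.K_K, p.K_AS, state.K_PsC
    elif ion == "Na":
        k_const, c_soma, c_psc = p.K_Na, p.Na_AS, state.Na_PsC
    else:
        raise ValueError(f"ion must be 'K' or 'Na', got {ion!r}")
    v_r = nernst_potential(c_soma, c_psc, 1, constants)
    dv = state.V_A - p.V_m - v_r
    if dv == 0.0:
        return 0.0
    eps = constants.eps0 * constants.eps_r
    dphi = math.sqrt(constants.Q * abs(dv) / (p.l_P * math.pi * eps))
    exponent = -(p.phi_w - dphi) / constants.kT_eV
    return k_const * (dv / p.l_P) * math.exp(exponent) * m.CSA_P


def ecs_leak_current(state: CompartmentState, p: AstroParams,
                     m: DerivedMorphology,
                     constants: Constants = DEFAULT_CONSTANTS) -> float:
    """K+ leak from the PsECS to the global ECS:
    ``g_ECS * E_ECS * SA_PsECS-GECS`` with
    ``E_ECS = (RT/F) ln([K]_PsECS/[K]_GECS)``.  Positive when K+ leaves
    the PsECS."""
    e_ecs = nernst_potential(state.K_PsECS, p.K_GECS, 1, constants)
    return p.g_ECS * e_ecs * m.SA_PsECS_GECS


def compute_currents(state: CompartmentState, p: AstroParams,
                     m: DerivedMorphology,
                     constants: Constants = DEFAULT_CONSTANTS) -> CurrentSet:
    """Evaluate every astrocyte channel at one state."""
    i_knka, i_nanka = nka_currents(state, p, m, constants)
    i_keaat, i_naeaat, i_glueaat = eaat_currents(state, p, m, constants)
    return CurrentSet(
        I_Kir=kir_current(state, p, m, constants),
        I_KB=background_current("K", state, p, m, constants),
        I_KNKA=i_knka,
        I_KEAAT=i_keaat,
        I_KPF=poole_frenkel_current("K", state, p, m, constants),
        I_KECSL=ecs_leak_current(state, p, m, constants),
        I_NaB=background_current("Na", state, p, m, constants),
        I_NaNKA=i_nanka,
        I_NaEAAT=i_naeaat,
        I_NaPF=poole_frenkel_current("Na", state, p, m, constants),
        I_GluEAAT=i_glueaat,
    )


@dataclass(frozen=True)
class RestCalibration:
    """Outcome of the background-conductance calibration."""

    params: AstroParams
    g_K: float
    g_Na: float
    residual_K_printed: float   # net K+ current (A) left by the tabulated g_K
    residual_Na_printed: float  # net Na+ current (A) left by the tabulated g_Na
    residual_K: float           # net K+ current (A) after calibration
    residual_Na: float


def calibrate_rest(p: AstroParams, state0: CompartmentState,
                   m: DerivedMorphology,
                   constants: Constants = DEFAULT_CONSTANTS,
                   tol: float = 1e-22) -> RestCalibration:
    """Choose ``g_K`` and ``g_Na`` so the resting state is a fixed point.

    The background conductances are solved so that the total K+ and Na+
    currents (membrane plus process) each vanish at ``state0``; all other
    parameters are untouched.  The residual currents obtained with the
    tabulated conductances are reported and logged.
    """
    from dataclasses import replace

    cs0 = compute_currents(state0, p, m, constants)
    res_k_printed = cs0.I_K_membrane + cs0.I_KPF
    res_na_printed = cs0.I_Na_membrane + cs0.I_NaPF

    e_k = nernst_potential(state0.K_PsECS, state0.K_PsC, 1, constants)
    e_na = nernst_potential(p.Na_PsECS, state0.Na_PsC, 1, constants)
    drive_k = (state0.V_A - e_k) * m.SA_PS
    drive_na = (state0.V_A - e_na) * m.SA_PS

    fixed_k = cs0.I_Kir + cs0.I_KNKA + cs0.I_KEAAT + cs0.I_KPF
    fixed_na = cs0.I_NaNKA + cs0.I_NaEAAT + cs0.I_NaPF

    budget = {"K": (fixed_k, drive_k), "Na": (fixed_na, drive_na)}
    g_new = {}
    for ion, (fixed, drive) in budget.items():
        if drive == 0.0:
            raise ValueError(
                f"calibration infeasible for {ion}: zero electrochemical driving force "
                f"at rest cannot balance a fixed current of {fixed:.3e} A")
        g = -fixed / drive
        if g < 0:
            raise ValueError(
                f"calibration infeasible for {ion}: balancing the fixed current budget "
                f"({fixed:.3e} A against driving term {drive:.3e} V m^2) "
                f"would require negative conductance {g:.4g} S/m^2")
        g_new[ion] = g

    p_cal = replace(p, g_K=g_new["K"], g_Na=g_new["Na"])
    cs1 = compute_currents(state0, p_cal, m, constants)
    res_k = cs1.I_K_membrane + cs1.I_KPF
    res_na = cs1.I_Na_membrane + cs1.I_NaPF
    if abs(res_k) > tol or abs(res_na) > tol:
        logger.warning("rest calibration residuals above tolerance: K %.3e A, Na %.3e A",
                       res_k, res_na)
    logger.info(
        "rest calibration: g_K %.4f -> %.4f S/m^2 (printed residual %.3e A), "
        "g_Na %.4f -> %.4f S/m^2 (printed residual %.3e A)",
        p.g_K, g_new["K"], res_k_printed, p.g_Na, g_new["Na"], res_na_printed)
    return RestCalibration(params=p_cal, g_K=g_new["K"], g_Na=g_new["Na"],
                           residual_K_printed=res_k_printed,
                           residual_Na_printed=res_na_printed,
                           residual_K=res_k, residual_Na=res_na)
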