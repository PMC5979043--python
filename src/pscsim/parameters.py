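"""Parameter sets for the astrocyte and the presynaptic neurone.

Two EAAT parameter profiles are provided:

``as_printed``
    The glutamate-transporter fitting constants exactly as tabulated
    (``beta_EAAT`` in V^-1, ``r_g`` in M^-1).  With these values
    ``r_g * [Glu]`` is ~1e-12 and ``beta_EAAT * dV`` is ~1e-3, so EAAT
    currents are vanishingly small (< 1e-20 A) at every physiological
    state.

``rescaled``
    A unit-audit profile that reads the same printed numbers on shifted
    scales -- ``beta_EAAT`` as mV^-1 (0.0288 mV^-1 = 28.8 V^-1) and
    ``r_g`` as uM^-1 (5e-7 uM^-1 = 0.5 M^-1) -- which yields small but
    non-negligible glutamate-transport currents and hence a measurable
    Na+ microdomain under glutamate stimulation.

Every simulation records which profile was active.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace

from .constants import Constants, DEFAULT_CONSTANTS

logger = logging.getLogger(__name__)

EAAT_PROFILES = ("as_printed", "rescaled")
KIR_REVERSAL_MODES = ("nernst", "nernst_offset", "fixed")


def _check_positive(obj, names) -> None:
    for name in names:
        v = getattr(obj, name)
        if not (math.isfinite(v) and v > 0):
            raise ValueError(f"parameter {name!r} must be positive and finite, got {v!r}")


def _check_nonnegative(obj, names) -> None:
    for name in names:
        v = getattr(obj, name)
        if not (math.isfinite(v) and v >= 0):
            raise ValueError(f"parameter {name!r} must be non-negative and finite, got {v!r}")


@dataclass(frozen=True)
class AstroParams:
    """Astrocyte membrane/process parameters (SI units, concentrations in M).

    ``P_nka_max`` is a pump turnover rate in mol m^-2 s^-1 (an ampere
    result requires a rate even though the source table prints mol m^-2).
    ``phi_w`` is the process potential-well depth in eV; 0.267 eV is
    10 k_B T at 310 K.

    ``kir_reversal_mode`` selects how the Kir reversal potential is formed:

    * ``"nernst_offset"`` (default): the instantaneous K+ Nernst
      potential between PsECS and PsC plus ``kir_offset`` (+25 mV).  The
      reversal then tracks the K+ microdomain (the channel's uptake
      diminishes as PsC K+ accumulates) while the +25 mV offset keeps the
      channel inward at rest, the physiology ascribed to it.
    * ``"nernst"``: the bare Nernst potential.
    * ``"fixed"``: constant ``e_kir_fixed`` volts (+25 mV absolute).
    """

    V_m: float = -0.09               # resting membrane potential, V
    phi_w: float = 0.267             # process well activation energy, eV
    g_Kir: float = 144.0             # Kir conductance, S m^-2 (per M of [K+]_PsECS)
    g_K: float = 16.9131             # background K+ conductance, S m^-2
    g_Na: float = 0.4293             # background Na+ conductance, S m^-2
    K_K: float = 0.018               # K+ process hopping constant, S m^-1
    K_Na: float = 0.018              # Na+ process hopping constant, S m^-1
    P_nka_max: float = 1.0e-6        # NKA max pump rate, mol m^-2 s^-1
    K_Nai: float = 1.5e-3            # NKA Na+ half-activation, M
    K_KE: float = 10e-3              # NKA K+ half-activation, M
    z_K: int = 1
    z_Na: int = 1
    z_Glu: int = -1
    e_kir_fixed: float = 0.025       # Kir reversal when mode == "fixed", V
    kir_offset: float = 0.025        # offset when mode == "nernst_offset", V
    kir_reversal_mode: str = "nernst_offset"
    g_ECS: float = 3.3               # PsECS -> GECS leak conductance, S m^-2
    alpha_EAAT: float = 0.0032       # EAAT fitting parameter, A m^-2
    beta_EAAT: float = 0.0288        # EAAT fitting parameter, V^-1
    r_g: float = 5e-7                # glutamate uptake slope, M^-1
    s_g: float = 9e-6                # glutamate uptake threshold, M
    eaat_prefactor: float = 1.0 / 6.0
    Glu_PsC: float = 1.5e-3          # fixed PsC glutamate, M
    H_PsC: float = 60e-9             # fixed PsC H+, M
    K_AS: float = 0.1                # fixed soma K+, M
    Na_AS: float = 0.015             # fixed soma Na+, M
    H_PsECS: float = 40e-9           # fixed PsECS H+, M
    Na_PsECS: float = 0.145          # fixed PsECS Na+, M
    K_GECS: float = 3e-3             # fixed global-ECS K+, M
    Na_GECS: float = 0.145           # fixed global-ECS Na+, M
    l_P: float = 25e-6               # process length, m
    eaat_profile: str = "as_printed"

    def __post_init__(self) -> None:
        _check_positive(self, ["phi_w", "K_Nai", "K_KE", "s_g", "Glu_PsC", "H_PsC",
                               "K_AS", "Na_AS", "H_PsECS", "Na_PsECS", "K_GECS",
                               "Na_GECS", "l_P"])
        _check_nonnegative(self, ["g_Kir", "g_K", "g_Na", "K_K", "K_Na",
                                  "P_nka_max", "g_ECS", "alpha_EAAT",
                                  "beta_EAAT", "r_g"])
        if self.eaat_profile not in EAAT_PROFILES:
            raise ValueError(f"eaat_profile must be one of {EAAT_PROFILES}, got {self.eaat_profile!r}")
        if self.kir_reversal_mode not in KIR_REVERSAL_MODES:
            raise ValueError(
                f"kir_reversal_mode must be one of {KIR_REVERSAL_MODES}, got {self.kir_reversal_mode!r}")

    def phi_w_in_kBT(self, constants: Constants = DEFAULT_CONSTANTS) -> float:
        """Well depth expressed as a multiple of k_B*T."""
        return self.phi_w / constants.kT_eV

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def astro_params(profile: str = "as_printed", **overrides) -> AstroParams:
    """Construct an :class:`AstroParams` under a named EAAT profile."""
    p = AstroParams(eaat_profile=profile)
    if profile == "rescaled":
        p = replace(p, beta_EAAT=28.8, r_g=0.5)
        logger.info("EAAT 'rescaled' profile active: beta_EAAT read as mV^-1 "
                    "(28.8 V^-1), r_g read as uM^-1 (0.5 M^-1)")
    if overrides:
        p = replace(p, **overrides)
    return p


@dataclass(frozen=True)
class NeuronParams:
    """Hodgkin-Huxley presynaptic neurone plus its NKA coupling to the PsECS.

    The classic squid-axon parameter set is used, translated by
    ``voltage_shift`` so the resting potential sits near -70 mV.  The K+
    release channel of the coupling (n^4 kinetics) reuses the HH potassium
    conductance and reversal.

    ``release_fraction`` is the fraction of the synaptic terminal surface
    whose K+ flux exchanges with the tiny perisynaptic extracellular shell
    (the rest faces bulk ECS); it multiplies both the spike K+ release and
    the neuronal NKA reuptake.  The default is fixed by requiring that the
    80 Hz spike-driven K+ release rate match the astrocytic NKA clearance
    capacity, the balance that defines the high-frequency steady state
    (see :func:`pscsim.neuron.calibrate_release_fraction`).

    ``P_nka_max_neu`` carries the tabulated magnitude; its printed negative
    sign is absorbed into the sign convention (the pump always removes K+
    from the PsECS).  Calibration replaces it so the neuronal K+ budget is
    zero at rest.
    """

    g_Na_hh: float = 1200.0          # S m^-2
    g_K_hh: float = 360.0            # S m^-2
    g_L_hh: float = 3.0              # S m^-2
    E_Na_hh: float = 0.050           # V, classic frame (pre-shift)
    E_K_hh: float = -0.077           # V
    E_L_hh: float = -0.054387       # V
    C_m_neu: float = 0.01            # F m^-2
    voltage_shift: float = -0.005    # V, translates the classic frame
    g_KNeu: float = 360.0            # S m^-2, release channel (= g_K_hh)
    P_nka_max_neu: float = 6.8017e-9  # mol m^-2 s^-1, magnitude as tabulated
    K_NaiNeu: float = 1.5e-3         # M
    K_KENeu: float = 10e-3           # M
    Na_Syn: float = 0.015            # M, held constant
    release_fraction: float = 0.125
    I_app: float = 0.0               # A m^-2, applied drive

    def __post_init__(self) -> None:
        _check_positive(self, ["g_Na_hh", "g_K_hh", "g_L_hh", "C_m_neu",
                               "K_NaiNeu", "K_KENeu"])
        _check_nonnegative(self, ["g_KNeu", "Na_Syn"])
        if not (0.0 < self.release_fraction <= 1.0):
            raise ValueError(
                f"parameter 'release_fraction' must lie in (0, 1], got {self.release_fraction!r}")

    @property
    def E_Na(self) -> float:
        return self.E_Na_hh + self.voltage_shift

    @property
    def E_K(self) -> float:
        return self.E_K_hh + self.voltage_shift

    @property
    def E_L(self) -> float:
        return self.E_L_hh + self.voltage_shift

    @property
    def E_KNeu(self) -> float:
        """Reversal of the K+ release channel (equals the HH K+ reversal)."""
        return self.E_K

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def neuron_params(**overrides) -> NeuronParams:
    return NeuronParams(**overrides)
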