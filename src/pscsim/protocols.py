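"""Declarative stimulation protocols and parameter sweeps.

Three experiment families are provided:

* ``k_driven`` -- the presynaptic neurone fires at a fixed rate and
  releases K+ into the perisynaptic ECS while extracellular glutamate is
  clamped at its background level.
* ``glu_puff`` -- no neuronal firing; extracellular glutamate follows a
  prescribed Gaussian pulse while extracellular K+ is clamped, probing
  the EAAT-driven Na+ microdomain.
* ``combined`` -- the neurone fires and each spike additionally releases
  a glutamate puff into the PsECS; glutamate evolves freely with EAAT
  uptake and a floor at its background level as the only removal routes.

Protocols default to the standard timing: a 0.1 min unstimulated
equilibration, stimulation from 0.1 min to 1 min, and a 0.2 min
post-stimulus observation window.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

GLU_BASELINE = 1e-6  # M, background PsECS glutamate
K_PSECS_BASELINE = 3e-3  # M

PROTOCOL_KINDS = ("k_driven", "glu_puff", "combined", "unstimulated")
SWEEP_PARAMETERS = ("SA_scale", "Pmax_scale", "phi_w")


@dataclass(frozen=True)
class ClampSpec:
    """Clamping rules applied during integration.

    ``glu_floor`` is always enforced when glutamate evolves freely (EAAT
    uptake would otherwise drain the PsECS completely).  ``hold_*`` pin a
    variable to a constant value for the whole run.
    """

    glu_floor: float = GLU_BASELINE
    hold_K_PsECS: bool = False
    K_PsECS_value: float = K_PSECS_BASELINE
    hold_Glu: bool = False
    Glu_value: float = GLU_BASELINE

    def __post_init__(self) -> None:
        for name in ("glu_floor", "K_PsECS_value", "Glu_value"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"clamp value {name!r} must be positive, got {v!r}")


@dataclass(frozen=True)
class ProtocolSpec:
    """Complete description of one simulation experiment.

    Times in seconds, concentrations in M.  ``glu_puff_peak > 0`` selects
    the prescribed Gaussian glutamate trajectory (centre at the stimulus
    midpoint, ``sigma = width / 6`` so ~99.7% of the pulse falls inside
    the stated width); ``glu_puff_per_spike > 0`` adds an instantaneous
    concentration increment at every detected spike.
    """

    kind: str = "unstimulated"
    firing_rate: float = 0.0
    stim_start: float = 6.0
    stim_end: float = 60.0
    duration: float = 72.0
    dt: float = 1e-5
    record_dt: float = 1e-3
    drive_kind: str = "pulse"       # 'none' | 'constant' | 'pulse'
    drive_amplitude: float = 30.0   # A m^-2
    pulse_width: float = 1e-3       # s
    glu_puff_peak: float = 0.0      # M; 0 disables the Gaussian
    glu_puff_width: float = 10.0    # s
    glu_puff_per_spike: float = 0.0  # M per spike
    clamps: ClampSpec = field(default_factory=ClampSpec)
    eaat_profile: str = "as_printed"
    spike_threshold: float = 0.0    # V
    refractory: float = 2e-3        # s

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ValueError(f"protocol kind must be one of {PROTOCOL_KINDS}, got {self.kind!r}")
        if not (self.stim_start < self.stim_end <= self.duration):
            raise ValueError(
                f"require stim_start < stim_end <= duration, got "
                f"{self.stim_start}, {self.stim_end}, {self.duration}")
        if self.dt <= 0 or self.record_dt < self.dt:
            raise ValueError("require dt > 0 and record_dt >= dt")
        if self.drive_kind not in ("none", "constant", "pulse"):
            raise ValueError(f"unknown drive_kind {self.drive_kind!r}")
        if self.firing_rate < 0 or self.glu_puff_peak < 0 or self.glu_puff_per_spike < 0:
            raise ValueError("rates and puff amplitudes must be non-negative")

    @property
    def glu_puff_centre(self) -> float:
        return 0.5 * (self.stim_start + self.stim_end)

    @property
    def glu_puff_sigma(self) -> float:
        return self.glu_puff_width / 6.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["clamps"] = asdict(self.clamps)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        d = dict(d)
        clamps = d.pop("clamps", None)
        if clamps is not None:
            clamps = ClampSpec(**clamps)
            return cls(clamps=clamps, **d)
        return cls(**d)


def build_unstimulated(duration: float = 6.0, dt: float = 1e-5) -> ProtocolSpec:
    """Control run: no neuronal drive, glutamate clamped at background."""
    return ProtocolSpec(
        kind="unstimulated", firing_rate=0.0, drive_kind="none",
        stim_start=0.0 if duration > 0 else 0.0,
        # a degenerate stimulation window keeps validation happy while the
        # 'none' drive guarantees no stimulus is delivered
        stim_end=min(1e-9, duration), duration=duration, dt=dt,
        clamps=ClampSpec(hold_Glu=True),
    )


def build_k_driven(rate: float, duration: float = 72.0, stim_start: float = 6.0,
                   stim_end: float = 60.0, dt: float = 1e-5) -> ProtocolSpec:
    """Neuronal K+ release at ``rate`` Hz with glutamate clamped at baseline.

    ``rate = 0`` degenerates to the unstimulated control over the same
    window.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rate == 0:
        return replace(build_unstimulated(duration=duration, dt=dt), kind="k_driven")
    return ProtocolSpec(
        kind="k_driven", firing_rate=rate, drive_kind="pulse",
        stim_start=stim_start, stim_end=stim_end, duration=duration, dt=dt,
        clamps=ClampSpec(hold_Glu=True),
    )


def build_glu_puff(peak: float = 1e-3, width: float = 10.0,
                   duration: float | None = None, stim_start: float = 6.0,
                   dt: float = 1e-4, eaat_profile: str = "rescaled") -> ProtocolSpec:
    """Gaussian glutamate pulse with extracellular K+ clamped at 3 mM.

    The prescribed pulse peaks at ``peak`` and lasts ~``width`` seconds;
    the run continues well past the pulse (>= 120 s) to capture the slow
    Na+ decay tail.  No neuronal drive, so the default time step is the
    100 us no-spiking fast mode.
    """
    if peak <= 0:
        raise ValueError("peak must be positive")
    stim_end = stim_start + width
    if duration is None:
        duration = stim_end + 130.0
    return ProtocolSpec(
        kind="glu_puff", firing_rate=0.0, drive_kind="none",
        stim_start=stim_start, stim_end=stim_end, duration=duration, dt=dt,
        glu_puff_peak=peak, glu_puff_width=width,
        clamps=ClampSpec(hold_K_PsECS=True),
        eaat_profile=eaat_profile,
    )


def build_combined(rate: float, puff: float = 1e-4, duration: float = 72.0,
                   stim_start: float = 6.0, stim_end: float = 60.0,
                   dt: float = 1e-5, eaat_profile: str = "rescaled") -> ProtocolSpec:
    """Neuronal K+ release plus a glutamate puff at every spike.

    ``puff = 0`` degenerates to :func:`build_k_driven` except that
    glutamate evolves freely above its floor instead of being clamped.
    """
    if rate <= 0 or puff < 0:
        raise ValueError("rate must be positive and puff non-negative")
    return ProtocolSpec(
        kind="combined", firing_rate=rate, drive_kind="pulse",
        stim_start=stim_start, stim_end=stim_end, duration=duration, dt=dt,
        glu_puff_per_spike=puff,
        clamps=ClampSpec(),
        eaat_profile=eaat_profile,
    )


@dataclass(frozen=True)
class SweepSpec:
    """One-dimensional parameter sweep around a base protocol.

    ``parameter`` is one of ``SA_scale`` (multiplies the PsC membrane
    area), ``Pmax_scale`` (multiplies the astrocytic NKA maximum pump
    rate) or ``phi_w`` (well depth, values in multiples of k_B T).
    """

    parameter: str
    values: tuple
    base: ProtocolSpec

    def __post_init__(self) -> None:
        if self.parameter not in SWEEP_PARAMETERS:
            raise ValueError(f"sweep parameter must be one of {SWEEP_PARAMETERS}, got {self.parameter!r}")
        if len(self.values) == 0:
            raise ValueError("sweep values must be nonempty")
        if any(v <= 0 for v in self.values):
            raise ValueError("sweep values must all be positive")

    def to_dict(self) -> dict:
        return {"parameter": self.parameter, "values": list(self.values),
                "base": self.base.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "SweepSpec":
        return cls(parameter=d["parameter"], values=tuple(d["values"]),
                   base=ProtocolSpec.from_dict(d["base"]))


def run_sweep(sweep: SweepSpec, astro=None, neuron=None, morph=None,
              constants=None):
    """Run one simulation per sweep value and summarise each.

    The system is calibrated once at the reference parameters and the
    scaling is then applied to the calibrated system, so a scaled pump
    rate deliberately unbalances the resting budgets -- the drift that
    results (e.g. net PsC K+ loss when the pump is weak) is the
    sensitivity phenomenon under study, not an artefact to remove.
    Individual run failures are recorded in the ``error`` column and the
    sweep continues.

    Returns a :class:`pandas.DataFrame` with one row per value: peak
    PsC K+, trough PsC Na+, and peak process K+ current magnitude.
    """
    import pandas as pd
    from dataclasses import replace as _replace

    from .constants import DEFAULT_CONSTANTS
    from .model import prepare_setup, run_simulation

    constants = constants or DEFAULT_CONSTANTS
    base_setup = prepare_setup(astro=astro, neuron=neuron, morph=morph,
                               constants=constants,
                               eaat_profile=sweep.base.eaat_profile)
    rows = []
    for value in sweep.values:
        row = {"value": value, "error": None}
        try:
            setup = base_setup
            if sweep.parameter == "SA_scale":
                m_v = _replace(setup.morph, SA_PS=setup.morph.SA_PS * value)
                setup = _replace(setup, morph=m_v)
            elif sweep.parameter == "Pmax_scale":
                astro_v = _replace(setup.astro, P_nka_max=setup.astro.P_nka_max * value)
                setup = _replace(setup, astro=astro_v)
            elif sweep.parameter == "phi_w":
                astro_v = _replace(setup.astro, phi_w=value * constants.kT_eV)
                setup = _replace(setup, astro=astro_v)
            res = run_simulation(sweep.base, setup=setup)
            row.update(
                peak_K_PsC=float(res.states["K_PsC"].max()),
                trough_K_PsC=float(res.states["K_PsC"].min()),
                trough_Na_PsC=float(res.states["Na_PsC"].min()),
                peak_Na_PsC=float(res.states["Na_PsC"].max()),
                peak_abs_IKPF=res.stats["max_abs_IKPF"],
                peak_K_PsECS=float(res.states["K_PsECS"].max()),
            )
        except Exception as exc:  # noqa: BLE001 - sweep robustness is the contract
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
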