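"""Reading and writing simulation artefacts and configuration files.

A simulation is stored as a CSV of the sampled trajectory (one row per
sample, states then currents, with a unit-annotation comment line) plus
a JSON metadata sidecar carrying the protocol, calibration record,
parameter profile and integration stats.  Configurations round-trip
through YAML with every parameter explicit.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import Constants
from .geometry import MorphologySpec
from .model import SimulationResult
from .parameters import AstroParams, NeuronParams
from .protocols import ProtocolSpec

logger = logging.getLogger(__name__)

#: units for the column annotation line and config error messages
UNITS = {
    "t": "s", "V_A": "V", "K_PsC": "M", "Na_PsC": "M", "K_PsECS": "M",
    "Glu_PsECS": "M", "V_Neu": "V", "n": "1", "m": "1", "h": "1",
    "g_Kir": "S/m^2", "g_K": "S/m^2", "g_Na": "S/m^2", "g_ECS": "S/m^2",
    "P_nka_max": "mol/m^2/s", "phi_w": "eV", "K_K": "S/m", "K_Na": "S/m",
    "alpha_EAAT": "A/m^2", "beta_EAAT": "1/V", "r_g": "1/M", "s_g": "M",
}
for _c in ("I_Kir", "I_KB", "I_KNKA", "I_KEAAT", "I_KPF", "I_KECSL",
           "I_NaB", "I_NaNKA", "I_NaEAAT", "I_NaPF", "I_GluEAAT",
           "I_K_membrane", "I_Na_membrane", "I_KNeu", "I_KNKANeu"):
    UNITS[_c] = "A"


def write_result(result: SimulationResult, csv_path, meta_path=None) -> None:
    """Write the sampled trajectory as CSV plus a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    if meta_path is None:
        meta_path = csv_path.with_suffix(".meta.json")
    frame = pd.concat([result.states,
                       result.currents.drop(columns=["t"])], axis=1)
    units_line = "# units: " + ",".join(UNITS.get(c, "?") for c in frame.columns)
    with open(csv_path, "w") as fh:
        fh.write(units_line + "\n")
        frame.to_csv(fh, index=False, float_format="%.12g")
    meta = dict(result.metadata)
    meta["stats"] = result.stats
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1)
    logger.info("wrote %s (%d samples) and %s", csv_path, len(frame), meta_path)


def read_result(csv_path, meta_path=None) -> SimulationResult:
    """Load a trajectory written by :func:`write_result`."""
    csv_path = Path(csv_path)
    if meta_path is None:
        meta_path = csv_path.with_suffix(".meta.json")
    frame = pd.read_csv(csv_path, comment="#")
    with open(meta_path) as fh:
        meta = json.load(fh)
    stats = meta.pop("stats", {})
    state_cols = ["t", "V_A", "K_PsC", "Na_PsC", "K_PsECS", "Glu_PsECS",
                  "V_Neu", "n", "m", "h"]
    current_cols = ["t"] + [c for c in frame.columns if c.startswith("I_")]
    states = frame[state_cols].copy()
    currents = frame[current_cols].copy()
    return SimulationResult(times=frame["t"].to_numpy(), states=states,
                            currents=currents, stats=stats, metadata=meta)


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

_SECTIONS = {
    "constants": Constants,
    "morphology": MorphologySpec,
    "astrocyte": AstroParams,
    "neuron": NeuronParams,
    "protocol": ProtocolSpec,
}


def save_config(path, *, constants: Constants | None = None,
                morphology: MorphologySpec | None = None,
                astrocyte: AstroParams | None = None,
                neuron: NeuronParams | None = None,
                protocol: ProtocolSpec | None = None) -> None:
    """Write the given sections to a YAML config file."""
    from dataclasses import asdict

    doc = {}
    for name, obj in (("constants", constants), ("morphology", morphology),
                      ("astrocyte", astrocyte), ("neuron", neuron)):
        if obj is not None:
            doc[name] = asdict(obj)
    if protocol is not None:
        doc["protocol"] = protocol.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> dict:
    """Load a YAML config, validating each section's keys.

    Returns a dict mapping section name to the constructed object.  A
    missing or unknown key raises ``ValueError`` naming the key (with
    its expected unit where known).
    """
    from dataclasses import fields as dc_fields

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    out = {}
    for section, payload in doc.items():
        if section not in _SECTIONS:
            raise ValueError(f"unknown config section {section!r}; expected one of "
                             f"{sorted(_SECTIONS)}")
        cls = _SECTIONS[section]
        expected = {f.name for f in dc_fields(cls)}
        got = set(payload)
        missing = expected - got
        unknown = got - expected
        if missing:
            key = sorted(missing)[0]
            unit = UNITS.get(key)
            hint = f" (expected units: {unit})" if unit else ""
            raise ValueError(f"config section {section!r} is missing key {key!r}{hint}")
        if unknown:
            raise ValueError(f"config section {section!r} has unknown key "
                             f"{sorted(unknown)[0]!r}")
        if cls is ProtocolSpec:
            out[section] = ProtocolSpec.from_dict(payload)
        else:
            out[section] = cls(**payload)
    return out


def write_spike_times(path, spike_times) -> None:
    """Plain-text event file: one spike time (s) per line."""
    with open(path, "w") as fh:
        for t in np.asarray(spike_times, dtype=float):
            fh.write(f"{t:.6f}\n")


def read_spike_times(path) -> np.ndarray:
    return np.loadtxt(path, ndmin=1)
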