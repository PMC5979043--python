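"""Physical constants shared by every current law in the model.

``eps_r = 0.82`` is kept exactly as tabulated for the cytoplasm of thin
glial processes even though it is below the vacuum value and therefore
physically unusual; a warning is emitted once at import of the default
set so the choice is visible in logs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

logger = logging.getLogger(__name__)

_EPS_R_WARNED = False


@dataclass(frozen=True)
class Constants:
    """Physical constants (SI units).

    Attributes
    ----------
    R : gas constant, J mol^-1 K^-1
    T : absolute temperature, K
    F : Faraday constant, C mol^-1
    Q : elementary charge, C
    k_B : Boltzmann constant, J K^-1
    eps0 : vacuum permittivity, F m^-1
    eps_r : relative permittivity of the process cytoplasm (dimensionless,
        tabulated value used verbatim)
    C_m : specific membrane capacitance, F m^-2
    """

    R: float = 8.31
    T: float = 310.0
    F: float = 96485.0
    Q: float = 1.6022e-19
    k_B: float = 1.38e-23
    eps0: float = 8.85e-12
    eps_r: float = 0.82
    C_m: float = 0.01

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"T must be positive, got {self.T}")
        global _EPS_R_WARNED
        if self.eps_r < 1.0 and not _EPS_R_WARNED:
            logger.warning(
                "eps_r = %.3g < 1 is physically unusual; using the tabulated "
                "value verbatim.",
                self.eps_r,
            )
            _EPS_R_WARNED = True

    @property
    def thermal_voltage(self) -> float:
        """RT/F in volts (~26.7 mV at 310 K)."""
        return self.R * self.T / self.F

    @property
    def kT_eV(self) -> float:
        """k_B*T expressed in electron-volts (~26.7 meV at 310 K)."""
        return self.k_B * self.T / self.Q

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


DEFAULT_CONSTANTS = Constants()
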