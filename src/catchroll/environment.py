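"""Thermodynamic environment: temperature, solvent viscosity, kBT."""

from __future__ import annotations

from dataclasses import dataclass, field

#: Boltzmann constant in pN nm / K (1.380649e-23 J/K expressed in pN nm).
BOLTZMANN_PN_NM = 1.380649e-2


@dataclass(frozen=True)
class Environment:
    """Solvent conditions shared by all kinetic and hydrodynamic models.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin. Default 293.15 K (20 degC, the
        temperature at which the rolling-adhesion experiments are run).
    viscosity : float
        Dynamic viscosity of the medium in Pa s. Default is water at 20 degC.

    Attributes
    ----------
    thermal_energy : float
        kB * T in pN nm; the energy scale dividing every Bell exponent.
    """

    temperature: float = 293.15
    viscosity: float = 1.002e-3
    thermal_energy: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if not self.viscosity > 0:
            raise ValueError(f"viscosity must be positive, got {self.viscosity}")
        object.__setattr__(
            self, "thermal_energy", BOLTZMANN_PN_NM * self.temperature
        )
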