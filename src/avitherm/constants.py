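"""Physical constants and moist-air property functions.

Air transport properties are linear fits to standard engineering tables
over the 0-45 degC range relevant to metabolic-chamber work; saturation
vapor pressure uses a Magnus-type closed form (Alduchov & Eskridge
coefficients).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError

KELVIN = 273.15


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed physical constants of the heat-balance model.

    ``fractional_lw_depth`` places the effective longwave-radiating
    surface at that fraction of the feather-coat depth (0.9: radiation is
    exchanged just below the coat's outer boundary). ``oxyjoule_J_per_ml_o2``
    converts oxygen consumption to heat production.
    """

    stefan_boltzmann: float = 5.670e-8      # W m-2 K-4
    emissivity_lw: float = 0.95             # longwave emissivity of plumage
    oxyjoule_J_per_ml_o2: float = 20.1      # J per ml O2
    fractional_lw_depth: float = 0.9        # dimensionless
    o2_fraction_air: float = 0.2094         # mole fraction O2 in dry air
    prandtl: float = 0.71                   # Pr of air, ~constant 0-45 degC
    lewis: float = 0.87                     # Le for water vapor in air
    air_pressure_pa: float = 101325.0
    cp_air: float = 1006.0                  # J kg-1 K-1
    r_water_vapor: float = 461.5            # J kg-1 K-1

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not value > 0:
                raise InvalidParameterError(f"{name} must be positive, got {value}")


DEFAULT_CONSTANTS = PhysicalConstants()


def air_conductivity(temp_C: float) -> float:
    """Thermal conductivity of air (W m-1 K-1)."""
    return 0.02436 + 7.5e-5 * temp_C


def kinematic_viscosity(temp_C: float) -> float:
    """Kinematic viscosity of air (m2 s-1)."""
    return 1.338e-5 + 9.0e-8 * temp_C


def air_density(temp_C: float, constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Dry-air density (kg m-3) from the ideal gas law."""
    return constants.air_pressure_pa / (287.05 * (temp_C + KELVIN))


def latent_heat_vaporization(temp_C: float) -> float:
    """Latent heat of vaporization of water (J kg-1)."""
    return 2.501e6 - 2369.0 * temp_C


def saturation_vapor_pressure(temp_C: float) -> float:
    """Saturation vapor pressure over water (Pa), Magnus form."""
    return 610.94 * math.exp(17.625 * temp_C / (temp_C + 243.04))


def vapor_density(temp_C: float, rel_humidity_pct: float,
                  constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Ambient water-vapor density (kg m-3) at the given RH (%)."""
    if not 0.0 <= rel_humidity_pct <= 100.0:
        raise InvalidParameterError(
            f"relative humidity must be in [0, 100], got {rel_humidity_pct}")
    e = saturation_vapor_pressure(temp_C) * rel_humidity_pct / 100.0
    return e / (constants.r_water_vapor * (temp_C + KELVIN))
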