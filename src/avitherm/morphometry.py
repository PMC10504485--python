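"""Body geometry and feather-coat transforms.

The bird's trunk is modelled as a prolate spheroid whose volume follows
from body mass and density; the feather coat is described per dorsal and
ventral half by its depth (the insulating layer actually trapped against
the skin) and the length of the feathers, which caps how far ptiloerection
can deepen the layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import InvalidParameterError


@dataclass(frozen=True)
class BirdMorphology:
    """Morphological traits entering the heat balance.

    Feather-coat descriptors are held separately for the dorsal and
    ventral body halves; ``single_coat`` collapses them to their means for
    analyses that vary one coat (e.g. the sensitivity design).
    """

    mass_g: float
    feather_depth_dorsal_mm: float
    feather_depth_ventral_mm: float
    feather_length_dorsal_mm: float
    feather_length_ventral_mm: float
    body_density: float = 875.0          # kg m-3
    shape_ratio_max: float = 3.0         # max long/short axis ratio
    fat_fraction: float = 0.04           # carried, unused in the balance
    fiber_diameter_mm: float = 0.03
    fiber_density_per_mm2: float = 50.0
    fiber_conductivity: float = 0.209    # W m-1 K-1 (keratin feather)

    def __post_init__(self) -> None:
        positive = ("mass_g", "feather_depth_dorsal_mm", "feather_depth_ventral_mm",
                    "feather_length_dorsal_mm", "feather_length_ventral_mm",
                    "body_density", "shape_ratio_max", "fiber_diameter_mm",
                    "fiber_density_per_mm2", "fiber_conductivity")
        for name in positive:
            if not getattr(self, name) > 0:
                raise InvalidParameterError(
                    f"{name} must be strictly positive, got {getattr(self, name)}")
        if self.shape_ratio_max < 1:
            raise InvalidParameterError("shape_ratio_max must be >= 1")
        if not 0 <= self.fat_fraction < 1:
            raise InvalidParameterError("fat_fraction must be in [0, 1)")
        if self.feather_depth_dorsal_mm > self.feather_length_dorsal_mm:
            raise InvalidParameterError("dorsal feather depth exceeds feather length")
        if self.feather_depth_ventral_mm > self.feather_length_ventral_mm:
            raise InvalidParameterError("ventral feather depth exceeds feather length")

    def single_coat(self) -> "BirdMorphology":
        """Replace the two coats by their arithmetic means (one-coat mode)."""
        depth = 0.5 * (self.feather_depth_dorsal_mm + self.feather_depth_ventral_mm)
        length = 0.5 * (self.feather_length_dorsal_mm + self.feather_length_ventral_mm)
        return replace(self, feather_depth_dorsal_mm=depth, feather_depth_ventral_mm=depth,
                       feather_length_dorsal_mm=length, feather_length_ventral_mm=length)


@dataclass(frozen=True)
class BodyGeometry:
    semi_major_m: float
    semi_minor_m: float
    volume_m3: float
    surface_area_m2: float
    characteristic_length_m: float


@dataclass(frozen=True)
class PtiloerectionScenario:
    """A named degree of feather erection.

    ``depth_multiplier`` scales the measured coat depth; ``None`` means the
    depth is set to the full feather length (fully erect feathers).
    """

    label: str
    depth_multiplier: float | None


SCENARIOS: dict[str, PtiloerectionScenario] = {
    "none": PtiloerectionScenario("none", 1.00),
    "p35": PtiloerectionScenario("p35", 1.35),
    "p75": PtiloerectionScenario("p75", 1.75),
    "p200": PtiloerectionScenario("p200", 3.00),
    "full": PtiloerectionScenario("full", None),
}

#: scenarios ordered by increasing effective depth
SCENARIO_ORDER = ("none", "p35", "p75", "p200", "full")


def ellipsoid_geometry(mass_g: float, body_density: float,
                       shape_ratio: float) -> BodyGeometry:
    """Prolate-spheroid trunk geometry for a given mass, density and shape.

    The semi-axes satisfy a = shape_ratio * b (b = c) with the volume fixed
    by mass/density. ``characteristic_length`` is the equal-volume-sphere
    diameter, used by the convection correlation.
    """
    if mass_g <= 0 or body_density <= 0:
        raise InvalidParameterError("mass and density must be positive")
    if shape_ratio < 1:
        raise InvalidParameterError("shape_ratio must be >= 1")
    volume = (mass_g / 1000.0) / body_density
    b = (3.0 * volume / (4.0 * math.pi * shape_ratio)) ** (1.0 / 3.0)
    a = shape_ratio * b
    if shape_ratio == 1.0:
        area = 4.0 * math.pi * b * b
    else:
        e = math.sqrt(1.0 - (b / a) ** 2)
        area = 2.0 * math.pi * b * b * (1.0 + (a / (b * e)) * math.asin(e))
    d_eq = (6.0 * volume / math.pi) ** (1.0 / 3.0)
    return BodyGeometry(semi_major_m=a, semi_minor_m=b, volume_m3=volume,
                        surface_area_m2=area, characteristic_length_m=d_eq)


def apply_ptiloerection(feather_depth_mm: float, feather_length_mm: float,
                        scenario: str | PtiloerectionScenario) -> float:
    """Effective coat depth (mm) under a ptiloerection scenario.

    Multiplicative scenarios are capped at the feather length; the feathers
    cannot stand deeper than they are long.
    """
    if isinstance(scenario, str):
        try:
            scenario = SCENARIOS[scenario]
        except KeyError:
            raise InvalidParameterError(
                f"unknown ptiloerection scenario {scenario!r}; "
                f"choose from {sorted(SCENARIOS)}") from None
    if not 0 < feather_depth_mm <= feather_length_mm:
        raise InvalidParameterError(
            f"need 0 < depth <= length, got depth={feather_depth_mm}, "
            f"length={feather_length_mm}")
    if scenario.depth_multiplier is None:
        return feather_length_mm
    return min(feather_depth_mm * scenario.depth_multiplier, feather_length_mm)
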