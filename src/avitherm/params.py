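"""Parameter-file loading and validation.

Flat key-value YAML (or JSON, a YAML subset) using the conventional
endotherm-model mnemonics; unknown keys are rejected by name, missing
mandatory keys are reported all at once, and every value is range-checked
in its stated units before the model objects are built.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import yaml

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .errors import InvalidParameterError
from .heatbalance import Physiology
from .morphometry import BirdMorphology

#: mnemonic -> (min, max) plausibility bounds in file units
_SCHEMA: dict[str, tuple[float, float]] = {
    "AMASS": (3.0, 50.0),
    "TC": (35.0, 43.0),
    "TC_DAY": (35.0, 45.0),
    "TC_MAX": (35.0, 47.0),
    "TB_INCREMENT": (0.01, 2.0),
    "SHAPE_B_MAX": (1.0, 10.0),
    "DHAIR": (0.005, 0.5),
    "LHAIR_DORSAL": (1.0, 60.0),
    "LHAIR_VENTRAL": (1.0, 60.0),
    "ZFUR_DORSAL": (0.1, 60.0),
    "ZFUR_VENTRAL": (0.1, 60.0),
    "RHO": (0.1, 5000.0),
    "QBASAL": (0.01, 5.0),
    "QRESTING": (0.01, 10.0),
    "BODY_DENSITY": (500.0, 1500.0),
    "FAT_FRACTION": (0.0, 0.6),
    "FIBER_CONDUCTIVITY": (0.01, 1.0),
    "O2_EXTRACTION": (0.05, 0.95),
    "BREATH_OFFSET": (0.0, 15.0),
    "WET_SKIN": (0.0, 1.0),
    "PANT_MAX": (1.0, 50.0),
    "PANT_MULTIPLIER": (1.0, 5.0),
    "DIGESTION_COEFFICIENT": (0.1, 1.0),
}


def default_parameter_path() -> Path:
    """Path of the packaged waxbill parameter file."""
    return Path(importlib.resources.files("avitherm.data") / "waxbill.yaml")


def load_parameters(path: str | Path | None = None,
                    ) -> tuple[BirdMorphology, Physiology, PhysicalConstants]:
    """Load and validate a parameter file into model objects.

    ``path=None`` loads the packaged waxbill defaults. The returned
    :class:`Physiology` carries both day and night core temperatures and
    floors; physical constants are the package defaults (a parameter file
    carries traits, not physics).
    """
    if path is None:
        path = default_parameter_path()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise InvalidParameterError(f"{path}: expected a flat key-value mapping")
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise InvalidParameterError(
            f"{path}: unknown parameter key(s): {', '.join(sorted(unknown))}")
    missing = set(_SCHEMA) - set(raw)
    if missing:
        raise InvalidParameterError(
            f"{path}: missing mandatory key(s): {', '.join(sorted(missing))}")
    values: dict[str, float] = {}
    for key, value in raw.items():
        lo, hi = _SCHEMA[key]
        try:
            value = float(value)
        except (TypeError, ValueError):
            raise InvalidParameterError(f"{path}: {key} is not numeric: {value!r}")
        if not lo <= value <= hi:
            raise InvalidParameterError(
                f"{path}: {key}={value} outside plausible range [{lo}, {hi}]")
        values[key] = value
    morph = BirdMorphology(
        mass_g=values["AMASS"], body_density=values["BODY_DENSITY"],
        shape_ratio_max=values["SHAPE_B_MAX"], fat_fraction=values["FAT_FRACTION"],
        feather_depth_dorsal_mm=values["ZFUR_DORSAL"],
        feather_depth_ventral_mm=values["ZFUR_VENTRAL"],
        feather_length_dorsal_mm=values["LHAIR_DORSAL"],
        feather_length_ventral_mm=values["LHAIR_VENTRAL"],
        fiber_diameter_mm=values["DHAIR"], fiber_density_per_mm2=values["RHO"],
        fiber_conductivity=values["FIBER_CONDUCTIVITY"])
    phys = Physiology(
        bmr_W=values["QBASAL"], rmr_W=values["QRESTING"], tb_core_C=values["TC"],
        tb_day_C=values["TC_DAY"], tb_max_C=values["TC_MAX"],
        tb_increment_C=values["TB_INCREMENT"], o2_extraction=values["O2_EXTRACTION"],
        breath_offset_C=values["BREATH_OFFSET"], wet_skin_fraction=values["WET_SKIN"],
        pant_max=values["PANT_MAX"], pant_bmr_multiplier=values["PANT_MULTIPLIER"],
        digestion_coefficient=values["DIGESTION_COEFFICIENT"])
    return morph, phys, DEFAULT_CONSTANTS


def dump_parameters(morph: BirdMorphology, phys: Physiology,
                    path: str | Path) -> None:
    """Write model objects back to a parameter file (round-trip inverse)."""
    values = {
        "AMASS": morph.mass_g, "TC": phys.tb_core_C, "TC_DAY": phys.tb_day_C,
        "TC_MAX": phys.tb_max_C, "TB_INCREMENT": phys.tb_increment_C,
        "SHAPE_B_MAX": morph.shape_ratio_max, "DHAIR": morph.fiber_diameter_mm,
        "LHAIR_DORSAL": morph.feather_length_dorsal_mm,
        "LHAIR_VENTRAL": morph.feather_length_ventral_mm,
        "ZFUR_DORSAL": morph.feather_depth_dorsal_mm,
        "ZFUR_VENTRAL": morph.feather_depth_ventral_mm,
        "RHO": morph.fiber_density_per_mm2, "QBASAL": phys.bmr_W,
        "QRESTING": phys.rmr_W, "BODY_DENSITY": morph.body_density,
        "FAT_FRACTION": morph.fat_fraction,
        "FIBER_CONDUCTIVITY": morph.fiber_conductivity,
        "O2_EXTRACTION": phys.o2_extraction, "BREATH_OFFSET": phys.breath_offset_C,
        "WET_SKIN": phys.wet_skin_fraction, "PANT_MAX": phys.pant_max,
        "PANT_MULTIPLIER": phys.pant_bmr_multiplier,
        "DIGESTION_COEFFICIENT": phys.digestion_coefficient,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(values, fh, sort_keys=True)
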