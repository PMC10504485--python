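"""Energy budgets: intake calorimetry, fat equivalents, time-energy
budgets, the hourly 73-h biophysical simulation, and model comparison.

Net energy intake (NEI) discounts metabolizable energy (gross food energy
minus excreta energy) by a digestion-cost coefficient; it equals energy
expenditure only at constant body mass, so mass changes are carried either
as a raw covariate or converted to fat-energy equivalents (39.5 kJ
mobilisable per g fat; storing costs 1.17 kJ per kJ stored).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InvalidParameterError
from .heatbalance import Physiology, thermoregulatory_cascade
from .morphometry import BirdMorphology
from .tnz import chamber_environment

FAT_ENERGY_KJ_PER_G = 39.5
FAT_STORAGE_COST_KJ_PER_KJ = 1.17
DIGESTION_COEFFICIENT = 0.83


@dataclass(frozen=True)
class FeedingTrial:
    """One individual's 73-h feeding-trial bookkeeping."""

    individual_id: str
    food_offered_g: float
    food_leftover_g: float
    excreta_g: float
    energy_food_consumed_kJ: float
    energy_excreta_kJ: float
    mass_pre_g: float
    mass_post_g: float
    duration_h: float = 73.0

    def __post_init__(self) -> None:
        if self.food_leftover_g > self.food_offered_g:
            raise InvalidParameterError("leftover food exceeds food offered")
        if self.energy_food_consumed_kJ < 0 or self.energy_excreta_kJ < 0:
            raise InvalidParameterError("energies must be >= 0")
        if self.duration_h <= 0:
            raise InvalidParameterError("duration must be positive")

    @property
    def mass_change_g(self) -> float:
        return self.mass_post_g - self.mass_pre_g


def net_energy_intake(trial: FeedingTrial,
                      digestion_coefficient: float = DIGESTION_COEFFICIENT) -> float:
    """NEI (kJ) = coefficient x (gross food energy - excreta energy)."""
    metabolizable = trial.energy_food_consumed_kJ - trial.energy_excreta_kJ
    if metabolizable < 0:
        warnings.warn(
            f"negative metabolizable energy for {trial.individual_id}: "
            f"{metabolizable:.2f} kJ", stacklevel=2)
    return digestion_coefficient * metabolizable


def fat_energy_equivalent(mass_change_g: float) -> tuple[float, str]:
    """Energy equivalent (kJ) of a body-mass change, with its direction.

    Mass loss: energy mobilised from fat. Mass gain: total energy diverted
    to storage, including the 17% conversion overhead.
    """
    if not np.isfinite(mass_change_g):
        raise InvalidParameterError("mass change must be finite")
    if mass_change_g == 0:
        return 0.0, "none"
    if mass_change_g < 0:
        return FAT_ENERGY_KJ_PER_G * abs(mass_change_g), "mobilized"
    stored = FAT_ENERGY_KJ_PER_G * mass_change_g
    return FAT_STORAGE_COST_KJ_PER_KJ * stored, "stored"


def fat_energy_covariate(mass_change_g: float) -> float:
    """Signed fat-energy term: positive when intake was diverted to
    storage, negative when reserves subsidised expenditure."""
    energy, direction = fat_energy_equivalent(mass_change_g)
    return energy if direction != "mobilized" else -energy


def time_energy_budget(bmr_W: float, daylight_h: float, night_h: float,
                       activity_multiplier: float = 2.0) -> float:
    """Classical time-energy-budget EE (kJ): active days, basal nights."""
    if daylight_h < 0 or night_h < 0:
        raise InvalidParameterError("hours must be >= 0")
    return bmr_W * (activity_multiplier * daylight_h + night_h) * 3600.0 / 1000.0


def default_day_night_mask(hours: int = 73) -> np.ndarray:
    """Boolean day mask for the 73-h trial: 40 daylight / 33 night hours.

    Three diel cycles (the first with a 14-h day, then two 13-h days)
    plus a final night hour, so the trial ends on a night hour.
    """
    blocks = [(5, False), (14, True), (5, False),
              (6, False), (13, True), (5, False),
              (6, False), (13, True), (5, False), (1, False)]
    mask = np.concatenate([np.full(n, flag) for n, flag in blocks])
    return mask[:hours]


def simulate_EE(hourly_temps_C: Sequence[float], morph: BirdMorphology,
                phys: Physiology, scenario_set: Sequence[str] = ("full",),
                day_night_mask: Sequence[bool] | None = None,
                day_scenario_set: Sequence[str] = ("none",),
                wind_m_s: float = 0.1, rel_humidity_pct: float = 5.0,
                ) -> tuple[np.ndarray, float]:
    """Hourly heat-balance simulation over a temperature trace.

    Daytime hours run with the daytime core temperature and the resting
    (RMR) floor on the unerected coat; night hours run with the night
    core temperature, the basal floor, and ``scenario_set`` ptiloerection.
    Returns the hourly metabolic rates (W) and their total (kJ).
    """
    temps = np.asarray(hourly_temps_C, dtype=float)
    if day_night_mask is None:
        day_night_mask = default_day_night_mask(temps.size)
    mask = np.asarray(day_night_mask, dtype=bool)
    if mask.size != temps.size:
        raise InvalidParameterError(
            f"mask length {mask.size} != temperature trace length {temps.size}")
    hourly = np.empty(temps.size)
    for i, (t, is_day) in enumerate(zip(temps, mask)):
        env = chamber_environment(float(t), wind_m_s, rel_humidity_pct)
        try:
            if is_day:
                sol = thermoregulatory_cascade(
                    morph, phys, env, day_scenario_set,
                    tb_C=phys.tb_day_C, floor_W=phys.rmr_W)
            else:
                sol = thermoregulatory_cascade(
                    morph, phys, env, scenario_set,
                    tb_C=phys.tb_core_C, floor_W=phys.bmr_W)
        except Exception as exc:
            raise type(exc)(f"{exc} (at hour {i}, Ta={t} degC)") from exc
        hourly[i] = sol.metabolic_rate_W
    total_kJ = float(hourly.sum() * 3600.0 / 1000.0)
    return hourly, total_kJ


_MODEL_SPECS = {
    "nm+fat_energy": ("ee_nm_kJ", "fat_energy_kJ"),
    "nm+mass_change": ("ee_nm_kJ", "mass_change_g"),
    "teb+fat_energy": ("ee_teb_kJ", "fat_energy_kJ"),
    "teb+mass_change": ("ee_teb_kJ", "mass_change_g"),
}


def fit_origin_forced(y: np.ndarray, X: np.ndarray) -> dict:
    """Least-squares fit with the intercept forced through zero.

    Returns slope vector statistics plus the Gaussian AIC with the
    constant term dropped, AIC = n ln(RSS/n) + 2k, k = regressors + 1.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InvalidParameterError("rank-deficient design matrix")
    fit = sm.OLS(y, X).fit()
    rss = float(np.sum(fit.resid ** 2))
    n = y.size
    k = X.shape[1] + 1
    rss_aic = max(rss, np.finfo(float).tiny)  # guard exact fits
    return {
        "params": np.asarray(fit.params), "bse": np.asarray(fit.bse),
        "tvalues": np.asarray(fit.tvalues), "r_squared": float(fit.rsquared),
        "rss": rss, "aic": float(n * np.log(rss_aic / n) + 2 * k), "n": n,
    }


def compare_models(table: pd.DataFrame, adjust_nei: bool = False) -> pd.DataFrame:
    """Fit the four origin-forced linear models of observed NEI and rank
    them by AIC.

    Each model regresses observed NEI on one EE prediction (biophysical or
    time-energy budget) plus one mass-accounting covariate (raw mass change
    or signed fat energy), intercept forced through zero. With
    ``adjust_nei=True`` the fat-energy models instead subtract the signed
    fat energy from NEI and fit the prediction alone. Absolute AICs carry
    an arbitrary additive constant; only differences are meaningful.
    """
    required = {"nei_kJ", "ee_nm_kJ", "ee_teb_kJ", "mass_change_g", "fat_energy_kJ"}
    missing = required - set(table.columns)
    if missing:
        raise InvalidParameterError(f"comparison table lacks columns {sorted(missing)}")
    if len(table) < 3:
        raise InvalidParameterError("need at least three individuals")
    y = table["nei_kJ"].to_numpy(dtype=float)
    rows = []
    for name, cols in _MODEL_SPECS.items():
        predictor, covariate = cols
        if adjust_nei and covariate == "fat_energy_kJ":
            y_fit = y - table["fat_energy_kJ"].to_numpy(dtype=float)
            X = table[[predictor]].to_numpy(dtype=float)
        else:
            y_fit = y
            X = table[list(cols)].to_numpy(dtype=float)
        try:
            fit = fit_origin_forced(y_fit, X)
        except InvalidParameterError:
            raise InvalidParameterError(
                f"rank-deficient design for model {name}: columns {cols}") from None
        rows.append({
            "model": name, "predictor": predictor, "covariate": covariate,
            "slope": float(fit["params"][0]), "slope_se": float(fit["bse"][0]),
            "slope_t": float(fit["tvalues"][0]),
            "covariate_coef": (float(fit["params"][1]) if fit["params"].size > 1
                               else 0.0),
            "r_squared": fit["r_squared"], "rss": fit["rss"], "aic": fit["aic"],
        })
    return (pd.DataFrame(rows)
            .sort_values("aic", kind="mergesort")
            .reset_index(drop=True))
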