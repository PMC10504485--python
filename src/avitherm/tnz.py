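"""Metabolic-chamber simulation and thermoneutral-zone detection.

A respirometry chamber is emulated by a temperature ramp at low wind and
humidity with no solar input; the lower critical temperature is read off
the simulated (or observed) metabolic-rate curve as the point of maximum
positive curvature bounding the basal plateau.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import InvalidParameterError, NoBreakpointError
from .heatbalance import (Environment, MetabolicSolution, Physiology,
                          thermoregulatory_cascade)
from .morphometry import BirdMorphology

#: plateau threshold as a fraction of the basal rate, per degC
PLATEAU_SLOPE_FRACTION = 0.005


def chamber_environment(air_temp_C: float, wind_m_s: float = 0.1,
                        rel_humidity_pct: float = 5.0) -> Environment:
    """Metabolic-chamber conditions: still air, dry, no solar load."""
    return Environment(air_temp_C=air_temp_C, wind_m_s=wind_m_s,
                       rel_humidity_pct=rel_humidity_pct, solar_W_m2=0.0)


@dataclass(frozen=True)
class MetabolicCurve:
    """Metabolic rate vs. air temperature, sorted ascending in temperature."""

    air_temp_C: np.ndarray
    metabolic_rate_W: np.ndarray
    solutions: tuple[MetabolicSolution, ...] | None = None

    def __post_init__(self) -> None:
        temps = np.asarray(self.air_temp_C, dtype=float)
        rates = np.asarray(self.metabolic_rate_W, dtype=float)
        object.__setattr__(self, "air_temp_C", temps)
        object.__setattr__(self, "metabolic_rate_W", rates)
        if temps.size < 4:
            raise InvalidParameterError("a metabolic curve needs >= 4 points")
        if temps.size != rates.size:
            raise InvalidParameterError("temperature/rate length mismatch")
        if not np.all(np.diff(temps) > 0):
            raise InvalidParameterError("temperatures must be strictly increasing")
        if not np.all(rates > 0):
            raise InvalidParameterError("metabolic rates must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"air_temp_C": self.air_temp_C,
                             "metabolic_rate_W": self.metabolic_rate_W})


@dataclass(frozen=True)
class TNZResult:
    lower_critical_temp_C: float
    curve: MetabolicCurve
    scenario_label: str


def simulate_chamber(morph: BirdMorphology, phys: Physiology,
                     scenario_set: Sequence[str] = ("p200",),
                     t_min: float = 10.0, t_max: float = 40.0, step: float = 1.0,
                     wind_m_s: float = 0.1, rel_humidity_pct: float = 5.0,
                     tb_C: float | None = None,
                     floor_W: float | None = None) -> MetabolicCurve:
    """Run the thermoregulatory cascade across a chamber temperature ramp.

    Night physiology (core temperature ``phys.tb_core_C``, basal floor) is
    the default, matching the respirometry protocol the curve is compared
    against.
    """
    if not t_min < t_max:
        raise InvalidParameterError("need t_min < t_max")
    temps = np.arange(t_min, t_max + 0.5 * step, step, dtype=float)
    solutions = []
    for t in temps:
        env = chamber_environment(float(t), wind_m_s, rel_humidity_pct)
        try:
            solutions.append(thermoregulatory_cascade(
                morph, phys, env, scenario_set, tb_C=tb_C, floor_W=floor_W))
        except Exception as exc:
            raise type(exc)(f"{exc} (at chamber temperature {t} degC)") from exc
    rates = np.array([s.metabolic_rate_W for s in solutions])
    return MetabolicCurve(temps, rates, tuple(solutions))


def lower_critical_temperature(curve: MetabolicCurve, bmr_W: float | None = None,
                               window: int = 3,
                               plateau_tol_W_per_C: float | None = None) -> float:
    """Lower bound of the thermoneutral zone from a metabolic-rate curve.

    Second derivative of the rate over temperature (Savitzky-Golay,
    quadratic; ``window=3`` reduces exactly to central second differences);
    the breakpoint is the temperature of maximum positive curvature, and
    the curve beyond it must be a plateau (mean slope within tolerance,
    default 0.5% of the basal rate per degC). Raises
    :class:`NoBreakpointError` for monotone or flat curves.
    """
    temps = curve.air_temp_C
    rates = curve.metabolic_rate_W
    steps = np.diff(temps)
    if not np.allclose(steps, steps[0]):
        raise InvalidParameterError("breakpoint detection needs a uniform ramp")
    step = float(steps[0])
    if window < 3 or window % 2 == 0:
        raise InvalidParameterError("window must be an odd integer >= 3")
    window = min(window, rates.size if rates.size % 2 else rates.size - 1)
    if bmr_W is None:
        bmr_W = float(rates.min())
    tol = (PLATEAU_SLOPE_FRACTION * bmr_W if plateau_tol_W_per_C is None
           else plateau_tol_W_per_C)

    d1 = np.gradient(rates, temps)
    if not np.any(d1 < -tol):
        raise NoBreakpointError("curve has no decreasing segment")
    d2 = savgol_filter(rates, window, polyorder=2, deriv=2, delta=step)

    # candidates must be followed by a plateau (mean tail slope ~ 0)
    candidates = []
    for i in range(1, temps.size - 1):
        tail_slope = (rates[-1] - rates[i]) / (temps[-1] - temps[i])
        if abs(tail_slope) <= tol:
            candidates.append(i)
    if not candidates:
        raise NoBreakpointError("curve never reaches a basal plateau")
    idx = max(candidates, key=lambda i: d2[i])
    if d2[idx] <= 0:
        raise NoBreakpointError("no positive curvature at the plateau onset")
    return float(temps[idx])


def rmse(predicted: MetabolicCurve, observed: pd.DataFrame | np.ndarray) -> float:
    """Root-mean-square error of a predicted curve against observed points.

    Predictions are linearly interpolated to the observed temperatures;
    observations outside the predicted ramp are rejected, not extrapolated.
    """
    obs = _as_points(observed)
    if obs.shape[0] == 0:
        raise InvalidParameterError("no observed points supplied")
    t_obs, m_obs = obs[:, 0], obs[:, 1]
    if t_obs.min() < predicted.air_temp_C[0] or t_obs.max() > predicted.air_temp_C[-1]:
        raise InvalidParameterError(
            "observed temperatures fall outside the predicted ramp")
    m_pred = np.interp(t_obs, predicted.air_temp_C, predicted.metabolic_rate_W)
    return float(np.sqrt(np.mean((m_pred - m_obs) ** 2)))


def rank_scenarios(morph: BirdMorphology, phys: Physiology,
                   observed: pd.DataFrame | np.ndarray,
                   scenario_list: Sequence[str] = ("p35", "p75", "p200", "full"),
                   **chamber_kwargs) -> pd.DataFrame:
    """Score fixed-ptiloerection chamber simulations against observations.

    Each scenario is forced (no cascade selection between scenarios) so
    that the ranking isolates the insulation hypothesis; rows are sorted
    ascending by RMSE.
    """
    if len(scenario_list) < 2:
        raise InvalidParameterError("need at least two scenarios to rank")
    rows = []
    for scenario in scenario_list:
        curve = simulate_chamber(morph, phys, scenario_set=(scenario,),
                                 **chamber_kwargs)
        rows.append({"scenario": scenario, "rmse_W": rmse(curve, observed)})
    return (pd.DataFrame(rows)
            .sort_values("rmse_W", kind="mergesort")
            .reset_index(drop=True))


def _as_points(observed: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(observed, pd.DataFrame):
        return observed[["air_temp_C", "metabolic_rate_W"]].to_numpy(dtype=float)
    arr = np.asarray(observed, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise InvalidParameterError("observed points must be (temp, rate) pairs")
    return arr[:, :2]
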