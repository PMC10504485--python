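"""Steady-state endotherm heat balance with a thermoregulatory cascade.

The solver returns the metabolic rate an endotherm must sustain to stay in
homeothermy under given environmental conditions. Dry heat loss runs
through a series resistance network — skin at core temperature, conduction
through the feather coat, then parallel convection and longwave radiation
at the coat surface. The coat on each body half (dorsal/ventral) is
treated as half of a concentric spherical shell whose inner sphere matches
the trunk's total surface area; this keeps the strong area expansion of a
deep coat on a small body, which a flat-slab resistance would miss.

Thermoregulation follows a cascade: in the cold, the bird erects its
feathers (the scenario with the lowest required rate is selected); in the
heat, once even the basal rate exceeds what the body can dissipate, core
temperature rises stepwise toward its maximum, then panting scales up
respiratory ventilation. Panting adds no metabolic heat when the
pant-cost multiplier is 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy.optimize import brentq

from . import constants as cst
from .constants import DEFAULT_CONSTANTS, KELVIN, PhysicalConstants
from .errors import InvalidParameterError, NumericalFailureError
from .morphometry import (BirdMorphology, BodyGeometry, apply_ptiloerection,
                          ellipsoid_geometry)

# residual tolerance on any regulated heat balance (W)
BALANCE_TOL = 1e-6


@dataclass(frozen=True)
class Physiology:
    """Physiological state and regulation limits.

    ``tb_core_C`` is the night-time (basal) core temperature and
    ``tb_day_C`` the daytime one; ``bmr_W``/``rmr_W`` are the matching
    resting floors. ``pant_max`` is the maximum ventilation multiplier
    reached at full panting, whose metabolic cost is scaled by
    ``pant_bmr_multiplier`` (1 = costless panting).
    """

    bmr_W: float
    rmr_W: float
    tb_core_C: float = 39.1
    tb_day_C: float = 41.6
    tb_max_C: float = 44.0
    tb_increment_C: float = 0.25
    o2_extraction: float = 0.25
    breath_offset_C: float = 5.0
    wet_skin_fraction: float = 0.01
    pant_max: float = 15.0
    pant_bmr_multiplier: float = 1.0
    digestion_coefficient: float = 0.83

    def __post_init__(self) -> None:
        if self.bmr_W <= 0:
            raise InvalidParameterError("bmr_W must be positive")
        if self.rmr_W < self.bmr_W:
            raise InvalidParameterError("rmr_W must be >= bmr_W")
        if self.tb_max_C < self.tb_core_C:
            raise InvalidParameterError("tb_max_C must be >= tb_core_C")
        if not 0 < self.o2_extraction < 1:
            raise InvalidParameterError("o2_extraction must be in (0, 1)")
        if not 0 <= self.wet_skin_fraction <= 1:
            raise InvalidParameterError("wet_skin_fraction must be in [0, 1]")
        if self.pant_max < 1:
            raise InvalidParameterError("pant_max must be >= 1")
        if self.tb_increment_C <= 0:
            raise InvalidParameterError("tb_increment_C must be positive")


@dataclass(frozen=True)
class Environment:
    """Ambient conditions for one time step."""

    air_temp_C: float
    wind_m_s: float = 0.1
    rel_humidity_pct: float = 5.0
    solar_W_m2: float = 0.0

    def __post_init__(self) -> None:
        if self.wind_m_s < 0:
            raise InvalidParameterError("wind speed must be >= 0")
        if not 0 <= self.rel_humidity_pct <= 100:
            raise InvalidParameterError("relative humidity must be in [0, 100]")
        if self.solar_W_m2 < 0:
            raise InvalidParameterError("solar radiation must be >= 0")


@dataclass(frozen=True)
class MetabolicSolution:
    """A solved heat balance and the cascade state that produced it."""

    metabolic_rate_W: float
    required_W: float            # unclamped homeothermy requirement
    q_conduction_W: float        # dry loss through the coat (= conv + rad)
    q_convection_W: float
    q_radiation_W: float
    q_resp_evap_W: float
    q_cut_evap_W: float
    tb_used_C: float
    scenario_used: str
    pant_level: float
    regulated_flag: str          # cold-stress | thermoneutral | heat-stress | hyperthermic
    residual_W: float
    coat_surface_temp_C: float = field(default=math.nan)

    @property
    def loss_total_W(self) -> float:
        return self.q_conduction_W + self.q_resp_evap_W + self.q_cut_evap_W


@dataclass(frozen=True)
class _ShellLoss:
    q_W: float
    q_convection_W: float
    q_radiation_W: float
    surface_temp_C: float


def effective_coat_conductivity(morph: BirdMorphology, effective_depth_mm: float,
                                mean_coat_temp_C: float, side: str = "dorsal") -> float:
    """Effective conductivity (W m-1 K-1) of the air-feather coat.

    A volume-fraction mixing rule between still air and feather keratin:
    the fiber volume fraction is the fiber volume rooted in 1 mm2 of skin
    divided by the coat depth, clipped to [0, 1]. Erecting the coat
    (larger depth at fixed fiber load) dilutes the fibers toward pure air.
    """
    if effective_depth_mm <= 0:
        raise InvalidParameterError("effective_depth_mm must be positive")
    if side not in ("dorsal", "ventral"):
        raise InvalidParameterError(f"side must be dorsal or ventral, got {side!r}")
    length = (morph.feather_length_dorsal_mm if side == "dorsal"
              else morph.feather_length_ventral_mm)
    fiber_area = math.pi * morph.fiber_diameter_mm ** 2 / 4.0
    f_v = morph.fiber_density_per_mm2 * fiber_area * length / effective_depth_mm
    f_v = min(max(f_v, 0.0), 1.0)
    k_air = cst.air_conductivity(mean_coat_temp_C)
    return k_air + (morph.fiber_conductivity - k_air) * f_v


def convection_coefficient(geometry: BodyGeometry, env: Environment,
                           constants: PhysicalConstants = DEFAULT_CONSTANTS,
                           characteristic_length_m: float | None = None) -> float:
    """Mixed convection coefficient h (W m-2 K-1), sphere correlation.

    Nu = 2 + 0.6 Re^1/2 Pr^1/3; the stagnant-air sphere limit Nu = 2 is
    the floor as wind -> 0. The length scale defaults to the body's
    equal-volume-sphere diameter; the dry-loss network overrides it with
    the coat's outer diameter, since the boundary layer forms on the coat
    surface, not on the skin.
    """
    length = (geometry.characteristic_length_m
              if characteristic_length_m is None else characteristic_length_m)
    k_air = cst.air_conductivity(env.air_temp_C)
    re = env.wind_m_s * length / cst.kinematic_viscosity(env.air_temp_C)
    nu = 2.0 + 0.6 * math.sqrt(re) * constants.prandtl ** (1.0 / 3.0)
    return nu * k_air / length


def _half_shell_loss(r_skin_m: float, depth_m: float, k_eff: float,
                     env: Environment, tb_C: float, h: float,
                     constants: PhysicalConstants) -> _ShellLoss:
    """Solve one coat sector (half shell) for its steady dry heat flow.

    Radiation is exchanged from an effective surface located at
    ``fractional_lw_depth`` of the coat, using both the (smaller) area and
    the (warmer) conduction-profile temperature at that depth; the radiant
    environment is the chamber wall at air temperature.
    """
    r_out = r_skin_m + depth_m
    r_rad = r_skin_m + constants.fractional_lw_depth * depth_m
    sector = 2.0 * math.pi  # half of a full 4*pi shell
    r_cond = (1.0 / r_skin_m - 1.0 / r_out) / (sector * k_eff)
    r_cond_rad = (1.0 / r_skin_m - 1.0 / r_rad) / (sector * k_eff)
    area_out = sector * r_out ** 2
    area_rad = sector * r_rad ** 2
    ta = env.air_temp_C
    sig = constants.stefan_boltzmann * constants.emissivity_lw
    ta_K4 = (ta + KELVIN) ** 4

    def parts(q: float) -> tuple[float, float, float]:
        t_s = tb_C - q * r_cond
        t_r = tb_C - q * r_cond_rad
        q_conv = h * area_out * (t_s - ta)
        q_rad = sig * area_rad * ((t_r + KELVIN) ** 4 - ta_K4)
        return q_conv, q_rad, t_s

    def balance(q: float) -> float:
        q_conv, q_rad, _ = parts(q)
        return q - q_conv - q_rad

    # bracket q via surface temperatures well beyond any physical solution
    q_lo = (tb_C - (ta + 150.0)) / r_cond
    q_hi = (tb_C - (ta - 150.0)) / r_cond
    try:
        q = brentq(balance, q_lo, q_hi, xtol=1e-12, rtol=8.9e-16)
    except ValueError as exc:  # pragma: no cover - defensive
        raise NumericalFailureError(
            f"coat-surface solve failed: tb={tb_C}, Ta={ta}, depth={depth_m} m, "
            f"k_eff={k_eff}") from exc
    q_conv, q_rad, t_s = parts(q)
    return _ShellLoss(q_W=q, q_convection_W=q_conv, q_radiation_W=q_rad,
                      surface_temp_C=t_s)


def dry_heat_loss(morph: BirdMorphology, geometry: BodyGeometry, env: Environment,
                  effective_depth_mm: float | Mapping[str, float], tb_C: float,
                  constants: PhysicalConstants = DEFAULT_CONSTANTS,
                  ) -> tuple[float, float, dict[str, _ShellLoss]]:
    """Total dry (sensible) heat loss through both coat halves.

    ``effective_depth_mm`` may be a scalar (uniform coat) or a mapping with
    ``dorsal``/``ventral`` entries. Returns the signed total loss (negative
    = heat gain), the area-weighted coat-surface temperature, and the
    per-half breakdown.
    """
    if isinstance(effective_depth_mm, Mapping):
        depths = dict(effective_depth_mm)
    else:
        depths = {"dorsal": float(effective_depth_mm),
                  "ventral": float(effective_depth_mm)}
    r_skin = math.sqrt(geometry.surface_area_m2 / (4.0 * math.pi))
    mean_coat_t = 0.5 * (tb_C + env.air_temp_C)
    halves: dict[str, _ShellLoss] = {}
    for side, depth_mm in depths.items():
        k_eff = effective_coat_conductivity(morph, depth_mm, mean_coat_t, side)
        # convection length scale: outer diameter of this half's coat
        h = convection_coefficient(geometry, env, constants,
                                   characteristic_length_m=2.0 * (r_skin + depth_mm / 1000.0))
        halves[side] = _half_shell_loss(r_skin, depth_mm / 1000.0, k_eff, env,
                                        tb_C, h, constants)
    q_total = sum(s.q_W for s in halves.values())
    t_surface = sum(s.surface_temp_C for s in halves.values()) / len(halves)
    return q_total, t_surface, halves


def respiratory_evaporation(metabolic_rate_W: float, env: Environment,
                            phys: Physiology, pant_level: float = 1.0,
                            tb_C: float | None = None,
                            constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Respiratory evaporative heat loss (W).

    Ventilation follows from oxygen demand at the given metabolic rate and
    extraction efficiency; expired air leaves saturated at the breath
    temperature (air temperature plus a fixed offset, never above core
    temperature). Panting multiplies ventilation by ``pant_level``.
    """
    if metabolic_rate_W < 0:
        raise InvalidParameterError("metabolic_rate_W must be >= 0")
    if not 1.0 <= pant_level <= phys.pant_max:
        raise InvalidParameterError(
            f"pant_level must be in [1, {phys.pant_max}], got {pant_level}")
    vo2_ml_s = metabolic_rate_W / constants.oxyjoule_J_per_ml_o2
    vent_m3_s = vo2_ml_s / (constants.o2_fraction_air * phys.o2_extraction) * 1e-6
    vent_m3_s *= pant_level
    t_exp = env.air_temp_C + phys.breath_offset_C
    if tb_C is not None:
        t_exp = min(t_exp, tb_C)
    rho_in = cst.vapor_density(env.air_temp_C, env.rel_humidity_pct, constants)
    rho_out = cst.vapor_density(t_exp, 100.0, constants)
    lam = cst.latent_heat_vaporization(0.5 * (env.air_temp_C + t_exp))
    return max(lam * vent_m3_s * (rho_out - rho_in), 0.0)


def cutaneous_evaporation(geometry: BodyGeometry, env: Environment,
                          coat_surface_temp_C: float,
                          wet_skin_fraction: float = 0.01,
                          constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Cutaneous evaporative heat loss (W) over the wet skin fraction.

    Mass-transfer analogy to convection, h_m = h / (rho cp) * Le^(-2/3),
    driven by the vapor-density gradient between saturation at the coat
    surface and the ambient air; zero when the gradient reverses.
    """
    if not 0 <= wet_skin_fraction <= 1:
        raise InvalidParameterError("wet_skin_fraction must be in [0, 1]")
    if wet_skin_fraction == 0:
        return 0.0
    h = convection_coefficient(geometry, env, constants)
    rho_cp = cst.air_density(env.air_temp_C, constants) * constants.cp_air
    h_m = h / rho_cp * constants.lewis ** (-2.0 / 3.0)
    rho_skin = cst.vapor_density(coat_surface_temp_C, 100.0, constants)
    rho_amb = cst.vapor_density(env.air_temp_C, env.rel_humidity_pct, constants)
    lam = cst.latent_heat_vaporization(coat_surface_temp_C)
    area = geometry.surface_area_m2 * wet_skin_fraction
    return max(h_m * area * (rho_skin - rho_amb) * lam, 0.0)


def _effective_depths(morph: BirdMorphology, scenario: str) -> dict[str, float]:
    return {
        "dorsal": apply_ptiloerection(morph.feather_depth_dorsal_mm,
                                      morph.feather_length_dorsal_mm, scenario),
        "ventral": apply_ptiloerection(morph.feather_depth_ventral_mm,
                                       morph.feather_length_ventral_mm, scenario),
    }


def solve_required_metabolic_rate(morph: BirdMorphology, phys: Physiology,
                                  env: Environment, scenario: str = "none",
                                  tb_C: float | None = None,
                                  floor_W: float | None = None,
                                  pant_level: float = 1.0,
                                  constants: PhysicalConstants = DEFAULT_CONSTANTS,
                                  ) -> MetabolicSolution:
    """Metabolic rate required for homeothermy under a fixed scenario.

    Finds MR such that MR = q_dry + q_resp(MR) + q_cut by a bracketed root
    find; the result is clamped below at ``floor_W`` (basal or resting
    rate). Solutions whose unclamped requirement falls below the floor are
    flagged ``thermoneutral`` — the cascade resolves how the surplus heat
    is dumped. Shortwave exchange is out of scope; solar input must be 0.
    """
    if env.solar_W_m2 != 0:
        raise NotImplementedError("shortwave/solar exchange is not modelled")
    tb = phys.tb_core_C if tb_C is None else tb_C
    floor = phys.bmr_W if floor_W is None else floor_W
    geometry = ellipsoid_geometry(morph.mass_g, morph.body_density,
                                  morph.shape_ratio_max)
    depths = _effective_depths(morph, scenario)
    q_dry, t_surf, halves = dry_heat_loss(morph, geometry, env, depths, tb, constants)
    q_cut = cutaneous_evaporation(geometry, env, t_surf, phys.wet_skin_fraction,
                                  constants)

    def imbalance(mr: float) -> float:
        # ventilation (hence q_resp) vanishes for non-positive trial rates
        q_resp = respiratory_evaporation(max(mr, 0.0), env, phys, pant_level,
                                         tb, constants)
        return mr - q_dry - q_resp - q_cut

    hi = max(100.0 * phys.bmr_W, q_dry + q_cut + 1.0)
    lo = min(0.0, q_dry + q_cut) - 1.0
    if imbalance(hi) < 0:
        raise NumericalFailureError(
            f"no metabolic-rate root below {hi:.2f} W at Ta={env.air_temp_C} degC")
    required = brentq(imbalance, lo, hi, xtol=1e-12, rtol=8.9e-16)
    mr = max(required, floor)
    q_resp = respiratory_evaporation(mr, env, phys, pant_level, tb, constants)
    flag = "cold-stress" if required > floor + BALANCE_TOL else "thermoneutral"
    return MetabolicSolution(
        metabolic_rate_W=mr, required_W=required, q_conduction_W=q_dry,
        q_convection_W=sum(s.q_convection_W for s in halves.values()),
        q_radiation_W=sum(s.q_radiation_W for s in halves.values()),
        q_resp_evap_W=q_resp, q_cut_evap_W=q_cut, tb_used_C=tb,
        scenario_used=scenario, pant_level=pant_level, regulated_flag=flag,
        residual_W=mr - q_dry - q_resp - q_cut, coat_surface_temp_C=t_surf)


def _loss_at(morph, phys, env, depths, tb, mr, pant, constants):
    """Total loss (W) with metabolic rate pinned at ``mr``."""
    geometry = ellipsoid_geometry(morph.mass_g, morph.body_density,
                                  morph.shape_ratio_max)
    q_dry, t_surf, halves = dry_heat_loss(morph, geometry, env, depths, tb, constants)
    q_cut = cutaneous_evaporation(geometry, env, t_surf, phys.wet_skin_fraction,
                                  constants)
    q_resp = respiratory_evaporation(mr, env, phys, pant, tb, constants)
    return q_dry + q_cut + q_resp, t_surf, halves, q_cut, q_resp


def _heat_side(morph: BirdMorphology, phys: Physiology, env: Environment,
               depths_lo: Mapping[str, float], depths_hi: Mapping[str, float],
               scenario_label: str, tb0: float, floor: float,
               constants: PhysicalConstants) -> MetabolicSolution:
    """Resolve a below-floor requirement: sleek the coat, raise tb, pant.

    First the effective coat depth relaxes continuously between the most
    and least erected levels available (birds modulate ptiloerection
    smoothly); if the least insulated coat still traps too much heat, core
    temperature climbs on the increment grid (refined continuously inside
    the bracketing step), then panting scales ventilation. A solution that
    maximal panting still cannot balance is flagged hyperthermic and
    carries the unresolved residual.
    """

    def depths_at(s: float) -> dict[str, float]:
        return {side: depths_lo[side] + s * (depths_hi[side] - depths_lo[side])
                for side in depths_lo}

    def deficit(depths, tb: float, pant: float = 1.0) -> float:
        loss, *_ = _loss_at(morph, phys, env, depths, tb, floor, pant, constants)
        return loss - floor

    def package(depths, tb: float, pant: float, flag: str) -> MetabolicSolution:
        loss, t_surf, halves, q_cut, q_resp = _loss_at(
            morph, phys, env, depths, tb, floor, pant, constants)
        q_dry = sum(s.q_W for s in halves.values())
        return MetabolicSolution(
            metabolic_rate_W=floor, required_W=loss,
            q_conduction_W=q_dry,
            q_convection_W=sum(s.q_convection_W for s in halves.values()),
            q_radiation_W=sum(s.q_radiation_W for s in halves.values()),
            q_resp_evap_W=q_resp, q_cut_evap_W=q_cut, tb_used_C=tb,
            scenario_used=scenario_label, pant_level=pant, regulated_flag=flag,
            residual_W=floor - loss, coat_surface_temp_C=t_surf)

    # relax ptiloerection first: deficit at s=1 is < 0 (that is why we are
    # here); if the sleeked coat dissipates enough, balance lies between
    if deficit(depths_at(0.0), tb0) >= 0:
        if deficit(depths_at(1.0), tb0) >= 0:  # degenerate: identical depths
            return package(depths_at(1.0), tb0, 1.0, "thermoneutral")
        s_star = brentq(lambda s: deficit(depths_at(s), tb0), 0.0, 1.0, xtol=1e-10)
        return package(depths_at(s_star), tb0, 1.0, "thermoneutral")
    depths = depths_at(0.0)
    # walk the tb increment grid until dissipation covers the floor
    n_steps = max(int(math.ceil((phys.tb_max_C - tb0) / phys.tb_increment_C)), 0)
    tb_prev = tb0
    for k in range(1, n_steps + 1):
        tb_k = min(tb0 + k * phys.tb_increment_C, phys.tb_max_C)
        if deficit(depths, tb_k) >= 0:
            tb_star = brentq(lambda tb: deficit(depths, tb), tb_prev, tb_k,
                             xtol=1e-9)
            return package(depths, tb_star, 1.0, "thermoneutral")
        tb_prev = tb_k
    tb_hot = phys.tb_max_C
    if deficit(depths, tb_hot, phys.pant_max) >= 0:
        pant_star = brentq(lambda p: deficit(depths, tb_hot, p), 1.0,
                           phys.pant_max, xtol=1e-9)
        return package(depths, tb_hot, pant_star, "heat-stress")
    return package(depths, tb_hot, phys.pant_max, "hyperthermic")


def thermoregulatory_cascade(morph: BirdMorphology, phys: Physiology,
                             env: Environment,
                             scenario_set: Sequence[str] = ("p35", "p75", "p200", "full"),
                             tb_C: float | None = None,
                             floor_W: float | None = None,
                             constants: PhysicalConstants = DEFAULT_CONSTANTS,
                             ) -> MetabolicSolution:
    """Full thermoregulatory response at one set of conditions.

    Cold side: every allowed ptiloerection level is evaluated and the
    minimum-rate solution returned. Heat side: with the least insulating
    level engaged, body temperature rises toward its maximum and panting
    follows until the floor heat production can be dissipated.
    """
    scenario_set = tuple(scenario_set)
    if not scenario_set:
        raise InvalidParameterError("scenario_set must be non-empty")
    tb = phys.tb_core_C if tb_C is None else tb_C
    floor = phys.bmr_W if floor_W is None else floor_W
    solutions = [solve_required_metabolic_rate(morph, phys, env, s, tb, floor,
                                               constants=constants)
                 for s in scenario_set]
    best = min(solutions, key=lambda s: s.required_W)
    if best.required_W >= floor:
        return best
    # heat side: dump the surplus, starting from the least insulation available
    min_insulation = min(
        scenario_set,
        key=lambda s: sum(_effective_depths(morph, s).values()))
    return _heat_side(morph, phys, env,
                      _effective_depths(morph, min_insulation),
                      _effective_depths(morph, best.scenario_used),
                      min_insulation, tb, floor, constants)
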