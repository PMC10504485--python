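"""Heat-balance components, the metabolic-rate solver and the cascade."""

import dataclasses
import math

import numpy as np
import pytest

from avitherm import (Environment, InvalidParameterError,
                      convection_coefficient, cutaneous_evaporation,
                      dry_heat_loss, effective_coat_conductivity,
                      ellipsoid_geometry, respiratory_evaporation,
                      solve_required_metabolic_rate, thermoregulatory_cascade)
from avitherm.constants import (air_conductivity, kinematic_viscosity,
                                latent_heat_vaporization, vapor_density)
from avitherm.heatbalance import BALANCE_TOL
from avitherm.tnz import chamber_environment


@pytest.fixture(scope="module")
def geometry(morph):
    return ellipsoid_geometry(morph.mass_g, morph.body_density, morph.shape_ratio_max)


class TestCoatConductivity:
    def test_pure_air_limit(self, morph):
        sparse = dataclasses.replace(morph, fiber_density_per_mm2=1e-9)
        k = effective_coat_conductivity(sparse, 6.0, 20.0)
        assert k == pytest.approx(air_conductivity(20.0), rel=1e-6)

    def test_solid_fiber_limit(self, morph):
        dense = dataclasses.replace(morph, fiber_density_per_mm2=1e6)
        assert effective_coat_conductivity(dense, 6.0, 20.0) == pytest.approx(0.209)

    def test_mixing_rule_value(self, morph):
        # independent arithmetic: f_v = 50 * pi*0.03^2/4 * 16.1 / 6.0
        f_v = 50.0 * math.pi * 0.03 ** 2 / 4.0 * 16.1 / 6.0
        k_air = air_conductivity(20.0)
        expected = k_air + (0.209 - k_air) * f_v
        assert effective_coat_conductivity(morph, 6.0, 20.0, "dorsal") == \
            pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.043, abs=2e-3)

    def test_erection_dilutes_fibers(self, morph):
        k_flat = effective_coat_conductivity(morph, 2.0, 20.0)
        k_erect = effective_coat_conductivity(morph, 6.0, 20.0)
        assert k_erect < k_flat

    def test_zero_depth_rejected(self, morph):
        with pytest.raises(InvalidParameterError):
            effective_coat_conductivity(morph, 0.0, 20.0)


class TestConvection:
    def test_stagnant_limit_is_conduction_shell(self, geometry):
        env = Environment(air_temp_C=20.0, wind_m_s=0.0)
        h = convection_coefficient(geometry, env)
        assert h == pytest.approx(
            2.0 * air_conductivity(20.0) / geometry.characteristic_length_m)

    def test_hand_evaluated_correlation(self, geometry):
        env = Environment(air_temp_C=20.0, wind_m_s=0.1)
        length = geometry.characteristic_length_m
        re = 0.1 * length / kinematic_viscosity(20.0)
        nu = 2.0 + 0.6 * math.sqrt(re) * 0.71 ** (1 / 3)
        assert convection_coefficient(geometry, env) == \
            pytest.approx(nu * air_conductivity(20.0) / length, rel=1e-12)

    def test_increasing_in_wind(self, geometry):
        hs = [convection_coefficient(geometry, Environment(20.0, w))
              for w in (0.0, 0.1, 0.5, 2.0)]
        assert hs == sorted(hs)
        assert hs[-1] > hs[0]


class TestDryHeatLoss:
    def test_zero_gradient(self, morph, geometry):
        env = chamber_environment(39.1)
        q, t_s, _ = dry_heat_loss(morph, geometry, env, 6.0, 39.1)
        assert abs(q) < 1e-9
        assert t_s == pytest.approx(39.1)

    def test_deeper_coat_reduces_loss(self, morph, geometry):
        env = chamber_environment(15.0)
        q_thin, _, _ = dry_heat_loss(morph, geometry, env, 2.0, 39.1)
        q_deep, _, _ = dry_heat_loss(morph, geometry, env, 6.0, 39.1)
        assert 0 < q_deep < q_thin

    def test_resistance_network_oracle(self, morph, geometry):
        """Each half closes term by term against independently summed
        resistances: conduction flux equals convection plus radiation."""
        env = chamber_environment(15.0)
        depths = {"dorsal": 6.0, "ventral": 7.5}
        tb = 39.1
        q_total, _, halves = dry_heat_loss(morph, geometry, env, depths, tb)
        r_skin = math.sqrt(geometry.surface_area_m2 / (4.0 * math.pi))
        for side, depth_mm in depths.items():
            part = halves[side]
            k_eff = effective_coat_conductivity(morph, depth_mm, 0.5 * (tb + 15.0), side)
            r_out = r_skin + depth_mm / 1000.0
            r_cond = (1 / r_skin - 1 / r_out) / (2.0 * math.pi * k_eff)
            # conduction through the coat carries exactly the half's flux
            q_cond = (tb - part.surface_temp_C) / r_cond
            assert q_cond == pytest.approx(part.q_W, rel=1e-9)
            assert part.q_convection_W + part.q_radiation_W == \
                pytest.approx(part.q_W, abs=1e-9)
            h = convection_coefficient(
                geometry, env, characteristic_length_m=2.0 * r_out)
            assert part.q_convection_W == pytest.approx(
                h * 2.0 * math.pi * r_out ** 2 * (part.surface_temp_C - 15.0), rel=1e-9)
        assert q_total == pytest.approx(sum(p.q_W for p in halves.values()))


class TestRespiratoryEvaporation:
    def test_no_gradient_no_loss(self, phys):
        # saturated ambient air and no breath warming: nothing to evaporate
        no_offset = dataclasses.replace(phys, breath_offset_C=0.0)
        env = Environment(air_temp_C=20.0, rel_humidity_pct=100.0)
        assert respiratory_evaporation(0.2, env, no_offset) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluation(self, phys):
        env = Environment(air_temp_C=20.0, rel_humidity_pct=5.0)
        vo2 = 0.2 / 20.1                       # ml O2 / s
        vent = vo2 / (0.2094 * 0.25) * 1e-6    # m3 / s
        drho = vapor_density(25.0, 100.0) - vapor_density(20.0, 5.0)
        expected = latent_heat_vaporization(22.5) * vent * drho
        assert respiratory_evaporation(0.2, env, phys) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.010, abs=2e-3)

    def test_panting_scales_ventilation(self, phys):
        env = Environment(air_temp_C=30.0, rel_humidity_pct=20.0)
        qs = [respiratory_evaporation(0.2, env, phys, pant_level=p)
              for p in (1.0, 5.0, 15.0)]
        assert qs == sorted(qs) and qs[0] < qs[-1]
        assert qs[1] == pytest.approx(5.0 * qs[0], rel=1e-9)

    def test_breath_capped_at_core_temperature(self, phys):
        env = Environment(air_temp_C=40.0, rel_humidity_pct=5.0)
        capped = respiratory_evaporation(0.2, env, phys, tb_C=41.6)
        uncapped = respiratory_evaporation(0.2, env, phys)
        assert capped < uncapped


class TestCutaneousEvaporation:
    def test_zero_wet_fraction(self, geometry):
        env = chamber_environment(20.0)
        assert cutaneous_evaporation(geometry, env, 30.0, wet_skin_fraction=0.0) == 0.0

    def test_saturated_air_at_skin_temperature(self, geometry):
        env = Environment(air_temp_C=30.0, rel_humidity_pct=100.0)
        assert cutaneous_evaporation(geometry, env, 30.0) == pytest.approx(0.0, abs=1e-12)

    def test_lewis_analogy_hand_value(self, geometry):
        env = Environment(air_temp_C=20.0, rel_humidity_pct=5.0)
        h = convection_coefficient(geometry, env)
        from avitherm.constants import air_density
        h_m = h / (air_density(20.0) * 1006.0) * 0.87 ** (-2 / 3)
        drho = vapor_density(25.0, 100.0) - vapor_density(20.0, 5.0)
        expected = h_m * geometry.surface_area_m2 * 0.01 * drho * \
            latent_heat_vaporization(25.0)
        assert cutaneous_evaporation(geometry, env, 25.0) == pytest.approx(expected, rel=1e-12)


class TestRequiredMetabolicRate:
    def test_residual_below_tolerance(self, morph, phys):
        sol = solve_required_metabolic_rate(morph, phys, chamber_environment(15.0), "p200")
        assert abs(sol.residual_W) < BALANCE_TOL
        assert sol.metabolic_rate_W >= phys.bmr_W

    def test_warm_saturated_chamber_clamps_to_basal(self, morph, phys):
        env = Environment(air_temp_C=39.1, rel_humidity_pct=99.0, wind_m_s=0.1)
        sol = solve_required_metabolic_rate(morph, phys, env, "none")
        assert sol.required_W <= 0.05
        assert sol.metabolic_rate_W == pytest.approx(phys.bmr_W)
        assert sol.regulated_flag == "thermoneutral"

    def test_plateau_at_32C(self, morph, summer_phys):
        sol = solve_required_metabolic_rate(morph, summer_phys,
                                            chamber_environment(32.0), "p200")
        assert sol.metabolic_rate_W == pytest.approx(summer_phys.bmr_W)

    def test_monotone_in_air_temperature(self, morph, phys):
        mr10 = solve_required_metabolic_rate(morph, phys, chamber_environment(10.0), "p200")
        mr20 = solve_required_metabolic_rate(morph, phys, chamber_environment(20.0), "p200")
        assert mr10.metabolic_rate_W > mr20.metabolic_rate_W

    def test_matches_grid_search_oracle(self, morph, phys):
        """Root-found rate agrees with a 1e-4 W grid search minimizing the
        balance residual, over 20 random parameter draws."""
        from avitherm.heatbalance import (cutaneous_evaporation, dry_heat_loss,
                                          respiratory_evaporation)
        from avitherm.morphometry import apply_ptiloerection
        rng = np.random.default_rng(42)
        scenarios = ("none", "p35", "p75", "p200", "full")
        for _ in range(20):
            m = dataclasses.replace(
                morph, mass_g=float(rng.uniform(6, 10)),
                feather_depth_dorsal_mm=float(rng.uniform(1.5, 6.0)),
                feather_depth_ventral_mm=float(rng.uniform(1.5, 6.0)),
                fiber_diameter_mm=float(rng.uniform(0.02, 0.06)))
            p = dataclasses.replace(phys, bmr_W=float(rng.uniform(0.15, 0.26)))
            env = chamber_environment(float(rng.uniform(5.0, 25.0)))
            scen = str(rng.choice(scenarios))
            sol = solve_required_metabolic_rate(m, p, env, scen)
            # independent oracle: exhaustive scan of the imbalance magnitude
            geo = ellipsoid_geometry(m.mass_g, m.body_density, m.shape_ratio_max)
            depths = {
                "dorsal": apply_ptiloerection(m.feather_depth_dorsal_mm,
                                              m.feather_length_dorsal_mm, scen),
                "ventral": apply_ptiloerection(m.feather_depth_ventral_mm,
                                               m.feather_length_ventral_mm, scen)}
            q_dry, t_s, _ = dry_heat_loss(m, geo, env, depths, p.tb_core_C)
            q_cut = cutaneous_evaporation(geo, env, t_s, p.wet_skin_fraction)
            grid = np.arange(0.0, 20.0 * p.bmr_W, 1e-4)
            resid = np.array([abs(mr - q_dry - q_cut -
                                  respiratory_evaporation(mr, env, p, tb_C=p.tb_core_C))
                              for mr in grid])
            oracle = grid[int(np.argmin(resid))]
            assert sol.required_W == pytest.approx(oracle, abs=1e-3)

    def test_solar_input_out_of_scope(self, morph, phys):
        env = Environment(air_temp_C=20.0, solar_W_m2=100.0)
        with pytest.raises(NotImplementedError):
            solve_required_metabolic_rate(morph, phys, env, "none")


class TestCascade:
    def test_cold_side_argmin(self, morph, phys):
        env = chamber_environment(15.0)
        scenarios = ("p35", "p75", "p200", "full")
        best = thermoregulatory_cascade(morph, phys, env, scenarios)
        singles = [solve_required_metabolic_rate(morph, phys, env, s)
                   for s in scenarios]
        assert best.metabolic_rate_W <= min(s.metabolic_rate_W for s in singles) + 1e-12
        assert best.scenario_used == "full"

    def test_prefers_deeper_erection_when_cold(self, morph, phys):
        env = chamber_environment(15.0)
        sol = thermoregulatory_cascade(morph, phys, env, ("p35", "p200"))
        assert sol.scenario_used == "p200"
        alt = solve_required_metabolic_rate(morph, phys, env, "p35")
        assert sol.metabolic_rate_W < alt.metabolic_rate_W

    def test_tb_elevation_engages_before_panting(self, morph, phys):
        env = chamber_environment(40.0)
        sol = thermoregulatory_cascade(morph, phys, env, ("none",))
        assert sol.tb_used_C > phys.tb_core_C
        assert sol.tb_used_C <= phys.tb_max_C
        assert sol.pant_level == pytest.approx(1.0)
        assert abs(sol.residual_W) < BALANCE_TOL

    def test_panting_engages_when_tb_max_insufficient(self, morph, phys):
        tight = dataclasses.replace(phys, tb_max_C=phys.tb_core_C + 0.5)
        env = Environment(air_temp_C=39.5, wind_m_s=0.1, rel_humidity_pct=5.0)
        sol = thermoregulatory_cascade(morph, tight, env, ("none",))
        assert sol.tb_used_C == pytest.approx(tight.tb_max_C)
        assert sol.pant_level > 1.0
        assert sol.regulated_flag in ("heat-stress", "hyperthermic")

    def test_every_regulated_solution_balances(self, morph, phys):
        for ta in (5.0, 15.0, 25.0, 32.0, 38.0):
            sol = thermoregulatory_cascade(morph, phys, chamber_environment(ta),
                                           ("p35", "p200", "full"))
            if sol.regulated_flag != "hyperthermic":
                assert abs(sol.residual_W) < BALANCE_TOL
            assert sol.metabolic_rate_W >= phys.bmr_W - 1e-12

    def test_empty_scenario_set_rejected(self, morph, phys):
        with pytest.raises(InvalidParameterError):
            thermoregulatory_cascade(morph, phys, chamber_environment(20.0), ())
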