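# avitherm

Biophysical thermal energetics of small passerine birds.

Small (sub)tropical passerines such as the common waxbill (*Estrilda
astrild*, 7–9 g) radiate heat fast relative to their mass, so whether an
introduced population can persist in a cooler climate is largely an
energy question. `avitherm` is a library for ecophysiologists who want to
answer it mechanistically: it solves a steady-state heat balance for the
metabolic rate `M` an endotherm must sustain to stay in homeothermy,

    M = Q_dry + Q_resp(M) + Q_cut,

with sensible loss `Q_dry` through a ptiloerectable feather coat (series
conduction into parallel convection + longwave radiation), respiratory
evaporation tied to ventilation, and cutaneous evaporation over a wet
skin fraction. A thermoregulatory cascade — feather erection in the cold;
coat sleeking, body-temperature elevation and panting in the heat —
selects the regulatory state at each ambient temperature.

On top of the solver the package provides:

- **TNZ prediction** (`avitherm.tnz`): metabolic-chamber ramps, detection
  of the lower critical temperature from the curve's second derivative,
  RMSE scoring and ptiloerection-scenario ranking against observed
  respirometry.
- **Energy budgets** (`avitherm.energetics`): net energy intake from
  feeding-trial calorimetry (`NEI = 0.83 (E_food − E_excreta)`),
  fat-energy equivalents of mass change, classical time-energy budgets,
  hourly 73-h energy-expenditure simulation, and origin-forced regression
  with AIC ranking of intake vs. prediction.
- **Sensitivity analysis** (`avitherm.sensitivity`): Latin-hypercube
  sampling over nine morphological/physiological parameters and
  boosted-regression-tree relative influence on the lower TNZ bound and
  the 73-h EE.
- **Synthetic data** (`avitherm.synthetic`): cohorts, respirometry
  curves, feeding trials and diel temperature logs with the statistical
  structure the analyses assume, so everything is testable offline.

The packaged default parameter file carries common-waxbill trait values
(mass 7.99 g, night/day core temperature 39.1/41.6 °C, BMR 0.17 W, RMR
0.37 W, dorsal/ventral coat depth 2.0/2.5 mm, feather length
16.1/14.1 mm, ...); `load_parameters()` accepts your own YAML with the
same mnemonics.

## Worked example

```python
import dataclasses
from avitherm import load_parameters, simulate_chamber, lower_critical_temperature

morph, phys, _ = load_parameters()
summer = dataclasses.replace(phys, bmr_W=0.20)   # chamber work used summer BMR
curve = simulate_chamber(morph, summer, scenario_set=("p200",))
print(lower_critical_temperature(curve, summer.bmr_W))
```

Running `python examples/tnz_curve.py` prints the ramp and the detected
bound:

```
air_temp_C  metabolic_rate_W
       10  0.514
       15  0.437
       20  0.358
       25  0.277
       30  0.200
       ...
lower critical temperature: 30.0 degC
```

The rate climbs from the 0.20 W basal plateau to ~0.51 W at 10 °C —
the thermoregulatory cost of a cold chamber — and the plateau onset
(lower bound of the thermoneutral zone) is detected at 30 °C under the
200% ptiloerection scenario. `python examples/energy_budget_73h.py`
compares the three 73-h energy numbers:

```
biophysical EE, 73 h:       122.38 kJ
time-energy budget, 73 h:    69.16 kJ
net energy intake (mean):   109.43 kJ
```

At ~21 °C (below the TNZ) the heat balance adds thermoregulatory cost the
2×BMR activity budget cannot represent, which is why the time-energy
budget falls far short of measured intake while the biophysical estimate
lands near it. The other examples cover the sensitivity ranking and the
synthetic-data round trips.

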