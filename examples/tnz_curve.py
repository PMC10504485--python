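"""Predict the metabolic-rate curve and the lower TNZ bound.

Simulates a metabolic chamber (10-40 degC, wind 0.1 m/s, RH 5%, no solar
load) for the packaged waxbill parameterization under the 200%
ptiloerection scenario, then detects where the curve stops falling and
plateaus at the basal rate: the lower critical temperature.
"""

import dataclasses

from avitherm import (load_parameters, lower_critical_temperature,
                      simulate_chamber)

morph, phys, _ = load_parameters()
# chamber respirometry was done in summer; use the summer basal rate
summer = dataclasses.replace(phys, bmr_W=0.20)

curve = simulate_chamber(morph, summer, scenario_set=("p200",))
print("air_temp_C  metabolic_rate_W")
for t, m in zip(curve.air_temp_C[::5], curve.metabolic_rate_W[::5]):
    print(f"{t:9.0f}  {m:.3f}")

lct = lower_critical_temperature(curve, summer.bmr_W)
print(f"\nlower critical temperature: {lct:.1f} degC")
print("Below this air temperature the bird must raise heat production above")
print("its basal rate to stay at core temperature; above it, the curve sits")
print(f"on the basal plateau ({summer.bmr_W:.2f} W).")
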