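"""Rank parameter influence on 73-h energy expenditure.

Draws a Latin-hypercube sample over the nine morphological and
physiological parameters, evaluates the hourly simulation per variant and
fits a boosted regression-tree ensemble whose normalized split-gain gives
each parameter's relative influence in percent. A modest sample is used
here so the example runs in seconds; n=1000 reproduces the study scale.
"""

from avitherm import load_parameters
from avitherm.sensitivity import (evaluate_variants, latin_hypercube,
                                  relative_influence)
from avitherm.synthetic import generate_temperature_log

morph, phys, _ = load_parameters()
samples = latin_hypercube(n=200, seed=0)
outputs = evaluate_variants(samples, morph, phys, outputs=("EE_73h_kJ",),
                            temperature_log=generate_temperature_log(seed=0))
influence = relative_influence(samples, outputs["EE_73h_kJ"], seed=0)

print("relative influence on 73-h EE (%):")
for name, pct in influence.sort_values(ascending=False).items():
    print(f"  {name:12s} {pct:5.1f}")
print()
print("Coat fiber traits dominate here because the mixing-rule conductivity")
print("sweeps from still air to solid keratin across the sampled ranges;")
print("see docs/methods.md for how this differs from fur-conduction models")
print("that saturate well below the solid-fiber limit.")
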