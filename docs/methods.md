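# Methods

`avitherm` models the thermal energetics of a small passerine — the
common waxbill (*Estrilda astrild*, ~8 g) is the packaged default — with
a steady-state heat balance: at each set of ambient conditions it solves
for the metabolic rate `M` that keeps the bird in homeothermy,

    M = Q_dry + Q_resp(M) + Q_cut,

where `Q_dry` is sensible loss through the feather coat, `Q_resp`
respiratory evaporative loss (itself proportional to `M` through
ventilation), and `Q_cut` cutaneous evaporative loss. Shortwave/solar
exchange is out of scope (all in-scope experiments run at zero solar
load), as is transient heat storage.

## Geometry

The trunk is a prolate spheroid with semi-axes `a = k·b` (`k` = maximum
length/width ratio, default 3) and volume fixed by mass over body density
(875 kg/m³). For conduction through the coat, the body is mapped to the
sphere with the *same surface area* (radius ~14.1 mm for the default
bird): this preserves the skin area that controls the thin-coat (slab)
limit. Dorsal and ventral coats are two parallel half-shells, each with
its own depth and feather length; `BirdMorphology.single_coat()` collapses
them to their means for the one-coat sensitivity design.

## Feather coat

Effective coat conductivity uses a volume-fraction mixing rule between
still air and feather keratin (0.209 W/mK):

    k_eff = k_air(T) + (k_fiber − k_air(T)) · f_v,
    f_v   = ρ_fiber · (π d²/4) · L / z,

with fiber density `ρ_fiber` (1/mm²), fiber diameter `d`, feather length
`L` and coat depth `z`, `f_v` clipped to [0, 1]. Erecting the coat
(ptiloerection) deepens `z` at fixed fiber load, diluting the fibers
toward still air — insulation improves both through added thickness and
reduced conductivity. Scenarios scale the measured depth by 1.35 / 1.75 /
3.00 ("35%", "75%", "200%") or set it to the feather length ("full"),
always capped at the feather length.

This mixing rule is the *parallel* (upper Wiener) bound on a two-phase
medium. Fur-conduction models that resolve fiber orientation saturate
well below the solid-fiber limit; with the rule used here, coat
conductivity responds strongly to fiber diameter and density wherever
`f_v` is large (thin, unerected coats). This matters for the sensitivity
rankings (see Limitations).

## Dry heat loss

Each coat half is a concentric spherical-shell sector: conduction
resistance `(1/r_skin − 1/r_out)/(2π k_eff)`, in series with parallel
convection and longwave radiation at the outer boundary. Longwave
exchange uses an effective radiating surface at 0.9 of the coat depth —
both its (smaller) area and its (warmer) conduction-profile temperature —
against a radiant environment at air temperature (chamber walls), with
emissivity 0.95. The scalar flux balance per half is solved by Brent's
method to 1e-12 W; the skin is held at core temperature (no flesh
resistance: in a 7–9 g bird with ~4% fat, peripheral temperature tracks
core closely).

Convection uses the sphere correlation `Nu = 2 + 0.6 Re^1/2 Pr^1/3`, with
the stagnant-air floor `Nu = 2`. The Reynolds length scale is the *coat's
outer diameter* for the dry-loss network: the boundary layer forms on the
coat surface, and under full ptiloerection the outer diameter is more
than twice the body's, which materially lowers `h`. (Called directly,
`convection_coefficient` defaults to the body's equal-volume-sphere
diameter.)

## Evaporation

Respiratory: ventilation follows from oxygen demand, `V̇ = (M / 20.1 J/ml)
/ (0.2094 · 0.25)`, with expired air saturated at air temperature + 5 °C
(never above core temperature); the loss is latent heat times the
vapor-density difference between expired and inspired air, and panting
multiplies ventilation by a pant level up to 15 (metabolic cost multiplier
1, i.e. costless panting, with the hook for a cost > 1). Cutaneous: Lewis
mass-transfer analogy `h_m = h/(ρ c_p) · Le^(−2/3)` over 1% wet skin at
the coat-surface temperature. Saturation vapor pressure is a Magnus form
(Alduchov–Eskridge coefficients); air properties are linear fits to
standard tables over 0–45 °C.

## Thermoregulatory cascade

Cold side: every allowed ptiloerection level is solved and the
minimum-rate solution returned (bracketed root-find on `M`, residual
< 1e-6 W, floored at the basal/resting rate). Heat side, when even the
floor rate exceeds what the body can dissipate: (1) effective coat depth
relaxes continuously between the most- and least-erected levels available
(birds modulate ptiloerection smoothly, so exact balance exists between
discrete scenarios); (2) core temperature rises on a 0.25 °C increment
grid toward its maximum, the balance point refined continuously inside
the bracketing increment; (3) panting scales ventilation up to the pant
maximum. If all three stages fail, the solution is flagged hyperthermic
and carries the unresolved residual — the only flag exempt from the
residual invariant.

## TNZ detection

The chamber ramp (default 10→40 °C, 1 °C steps, wind 0.1 m/s, RH 5%)
yields a Scholander-type curve: declining, then flat at the basal rate.
The lower critical temperature is the temperature of maximum positive
second derivative bounding the basal plateau. The second derivative is a
Savitzky–Golay quadratic filter whose default window of 3 reduces exactly
to central second differences (the model curves are noise-free); noisy
observed curves should use window 7, which keeps breakpoint recovery
within 1 °C at noise of 2% of BMR in the recovery tests. The plateau
criterion is a mean tail slope within 0.5% of BMR per °C (configurable;
noisy curves need a looser absolute tolerance, e.g. 0.005 W/°C).
Curves that never decline or never plateau raise `NoBreakpointError`.
Predictions are scored against observed points by RMSE after linear
interpolation; observations outside the ramp are rejected rather than
extrapolated.

## Energy budgets

Net energy intake: `NEI = 0.83 × (E_food − E_excreta)` (digestion-cost
coefficient 0.83). Mass changes over a trial are carried either raw or as
fat-energy equivalents: 39.5 kJ mobilisable per g lost; storage costs
1.17 kJ per kJ stored (so a gain of Δm diverts `1.17 · 39.5 · Δm` kJ of
intake). The 73-h simulation runs one cascade solve per hour: daylight
hours (40) use the daytime core temperature (41.6 °C) with the resting
rate (0.37 W) as floor on the *unerected* coat; night hours (33) use the
night core temperature (39.1 °C), the basal floor (0.17 W), and the night
ptiloerection scenario set (default full erection). Daytime ptiloerection
is deliberately off: the night-only wording of the study design is
followed, and a bird alert and active by day does not sit fully fluffed.
The time-energy budget comparator is `BMR · (2 · 40 h + 33 h)` converted
to kJ.

Model comparison fits four origin-forced linear models of observed NEI on
either EE prediction (biophysical or time-budget) plus either mass-change
covariate (raw grams or signed fat energy), ranked by Gaussian AIC with
the additive constant dropped (`n ln(RSS/n) + 2k`, `k` = regressors + 1);
only AIC differences are meaningful. An `adjust_nei` flag instead
subtracts the signed fat energy from NEI and fits the prediction alone.

## Sensitivity analysis

Nine parameters (core and maximum body temperature, shape ratio, fiber
diameter, feather length, coat depth, fiber density, BMR, mass) are
sampled by Latin hypercube (scipy's sampler: one sample per
equal-probability stratum, columns independently permuted by the seeded
generator). The feather-density bounds are read as [0.7, 140] /mm² — the
upper bound is editable, and the fixed trait value (50 /mm²) lies inside
the band. Per variant, a single-coat bird is built (sampled depth clamped
to the sampled feather length; daytime core temperature = sampled core
+ 2.5 °C, capped at the sampled maximum; RMR scaled from BMR by the
cohort ratio 0.37/0.17) and the model produces the lower TNZ bound
(chamber ramp, 200% scenario) and the 73-h EE (full-ptiloerection
nights). Failed breakpoint detections carry NaN and abort the run above a
20% failure fraction. Relative influence is the normalized split-gain
importance of a gradient-boosted tree ensemble (squared error, depth 3,
shrinkage 0.05, tree count by validation-set early stopping), with a
permutation-importance alternative for robustness checks. Default sample
size is 1000 variants; rank-stability tests use 500 per seed.

## Synthetic data

The generator emulates the study conditions so every stage is testable
offline: cohorts with mass ~ Normal(7.99, 0.93) g truncated above 4 g and
metabolic rates `a · mass^0.66 · e^ε` (conventional small-bird scaling
exponent; configurable), with the scale calibrated so realized cohort
means equal 0.17 W (BMR) and 0.37 W (RMR) exactly and RMR floored at BMR;
Scholander respirometry curves `BMR + slope · max(0, T_lc − T) + noise`;
feeding trials that invert the NEI bookkeeping around an assumed true
expenditure (excreta energy fraction 0.13 of food energy, millet at
15.66 kJ/g, 50 g offered); and 73-h diel temperature traces clipped to
the recorded indoor band 19.6–22.3 °C with a 40/33 day/night mask ending
on a night hour. What the generator does *not* emulate: individual
variation in insulation, behavioural microclimate selection, heterothermy
and measurement drift — so passing recovery tests demonstrate estimator
correctness under the assumed statistical structure, not robustness to
every feature of real respirometry or calorimetry data.

## Numerical choices

Root-finding is Brent's method throughout (flux solves to 1e-12,
metabolic-rate solves bracketed in [min(0, Q), max(100·BMR, Q+1)] W);
every regulated solution satisfies |gain − loss| < 1e-6 W. Coat air
conductivity is evaluated at the mean of core and air temperature. The
simulations behind the headline numbers use the study-scale problem
sizes — 31-point chamber ramps, 73-hour traces, 100-individual recovery
cohorts, 500–1000-variant hypercubes — chosen to match the design being
emulated.

## Limitations

- The original analysis ran a closed-source endotherm modelling framework
  whose internal heat-transfer formulations are not published alongside
  the study; this package re-derives them from first principles, so
  agreement with the study's printed outputs is approximate by
  construction. In practice the network here loses somewhat more heat
  through the thin unerected coat than the original: the predicted lower
  TNZ bound lands at 30 °C (reported ≈28 °C) and the 73-h EE near 122 kJ
  (reported 106.89 kJ), both within the tolerance the comparison was
  designed for but at its warm/high side.
- Under the mixing-rule conductivity, sweeping fiber diameter and density
  across their literature-wide ranges drives `f_v` over orders of
  magnitude, so those two traits dominate the boosted-tree influence
  rankings for both outputs; the study instead reported coat depth as the
  leading EE driver. This is a structural consequence of the conductivity
  model, not of the sampling or the ensemble — fur models that saturate
  below the solid-fiber limit would damp the fiber traits' leverage.
- No flesh resistance, no wind penetration of the coat, no solar load, no
  heterothermy; the upper critical temperature is not evaluated (the
  reference respirometry stops at 32 °C).
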