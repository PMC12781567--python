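# flapwave

Flap-rate analysis of soaring seabirds against wind and swell.

Albatrosses cover thousands of kilometres on foraging trips while
barely flapping, by dynamic soaring on the wind-shear gradient and
wave-slope soaring on the updrafts of traveling swells. Flapping is the
expensive part of their flight budget, so the hourly wingbeat count is
a field-standard proxy for flight cost. `flapwave` is a pipeline for
movement ecologists that turns raw biologging streams into
species-level models of that cost:

1. **Wingbeat detection** — 25 Hz heave-axis accelerometry is rotated
   into the animal frame, smoothed with LULU rank operators (`L_n` =
   running max of running min and its dual `U_n`, which strip impulses
   up to `n` samples wide), and wingbeats are picked as residual peaks
   above a threshold with a refractory gap, summed per UTC hour.
2. **Movement states** — GPS tracks interpolated to 10 min become step
   lengths and turn angles; a 3-state hidden Markov model (gamma steps,
   von Mises turns) separates resting on water, foraging, and
   commuting, and rest calls are validated against wet/dry immersion
   loggers.
3. **Track-environment syncing** — hourly 10-m wind and total-swell
   fields are sampled bilinearly at the bird's hourly position; the
   bird-wind and bird-swell angles (BWA, BSA) are folded to [0°, 180°]
   with 0° = traveling with the flow. Hours touching a rest interval
   are dropped so the table holds only continuous flight.
4. **Flap-rate models** — six candidate penalized additive count models
   (negative binomial, log link, per-bird random intercept): a null
   model, windspeed or swell height alone, tensor products of each
   magnitude with its relative angle, and the wind x swell tensor
   product (Model V). Candidates are compared by AICc and Akaike
   weights; surfaces are trimmed to the 99% kernel-density region of
   the observed covariate space, and the headline statistic is the
   percent reduction in predicted flap rate from the 95th to the 5th
   quantile of the masked surface: `100 * (max − min) / max`.
5. **Context** — 95% utilization kernels of foraging tracks on an
   equal-area projection, monthly wind/swell climatologies inside them,
   and tercile-based condition categories from species-balanced bird
   subsets.

A first-class synthetic-data generator (`flapwave.synth`) produces all
four input streams plus ground truth (true states, true wingbeat times,
true response coefficients), so every stage is testable at desk scale
without any field data.

## Worked example

Generate a synthetic hourly flight table whose counts truly depend on
both windspeed and swell height, fit all six candidates, and compute
the flap-rate reduction:

```python
from flapwave import SimConfig, gen_hourly_table
from flapwave.models import (
    fit_all_models, model_selection_table, predict_surface, flap_reduction,
)

table = gen_hourly_table(SimConfig(seed=0), seed=4, n_birds=24, hours_per_bird=60)
fits = fit_all_models(table)          # Models 0, I-V on identical rows
print(model_selection_table(fits))
r = flap_reduction(predict_surface(fits["V"]))
print(f"max {r.max_rate:.1f} flaps/h (95th), min {r.min_rate:.1f} (5th): "
      f"{r.reduction_pct:.2f}% reduction")
```

Output:

```text
model                   terms    AICc  dAICc   df  weight    R2    DE
    V Windspeed, Swell height 17064.1    0.0 33.2     1.0 0.991 0.988
    I               Windspeed 17244.5  180.4 27.4     0.0 0.893 0.904
  III          Windspeed, BWA 17261.9  197.8 36.1     0.0 0.894 0.904
   II            Swell height 18349.3 1285.2 27.4     0.0 0.443 0.419
   IV       Swell height, BSA 18354.6 1290.5 35.9     0.0 0.449 0.425
    0                    Null 18579.2 1515.1 23.9     0.0 0.338 0.315

max 841.1 flaps/h (95th), min 103.9 (5th): 87.64% reduction
```

The model carrying both covariates (V) wins decisively — it alone
carries all the Akaike weight — and the masked surface says a bird in
the windiest, highest-swell conditions it actually experiences flaps
~88% less per hour than in the calmest: soaring on wind and waves
nearly eliminates flapping. The wind-only models (I, III) beat the
swell-only models (II, IV) because this table was generated with the
stronger effect on windspeed.

The same analysis runs from the shell on files:

```bash
flapwave simulate --seed 1 --n-birds 6 --outdir data/   # synthetic cohort
flapwave flaps data/accel/bird000.csv --out counts.csv  # wingbeats per hour
flapwave states data/gps.csv --seed 1                   # HMM decode
flapwave model hourly.csv --out selection.csv           # Models 0, I-V
flapwave reduce hourly.csv                              # reduction statistic
flapwave run-all config.yaml                            # whole pipeline
```

`flapwave import-dryad` ingests an externally deposited hourly-summary
CSV (bird, hour, flaps, windspeed, swell height, angles) straight into
the modeling stage, for re-analyses of real deployments.

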