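# Methods

This note documents the models and procedures implemented in `flapwave`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic-data generator does and does
not emulate.

## Scientific setting

Albatrosses and other procellariiform seabirds travel at very low
energetic cost by soaring: dynamic soaring extracts energy from the
vertical wind-shear gradient above the sea surface, and wave-slope
soaring rides the updrafts on the windward faces of traveling swells.
When neither source suffices, the birds flap — the single most
expensive component of their flight budget. The package quantifies that
trade-off: it counts individual wingbeats from body-mounted
accelerometers, restricts analysis to hours of continuous flight using
a movement-state model on GPS tracks, attaches the wind and swell
conditions at the bird's hourly position, and models hourly flap rate
as a smooth function of windspeed, swell height, and the bird-relative
flow angles.

## Wingbeat detection (`flapwave.lulu`, `flapwave.accel`)

Wingbeats appear as impulsive spikes on the heave (dorsoventral, z)
axis. The detector has three stages.

**Animal-frame rotation.** Tag placement on feathers is never perfectly
aligned. The gravity direction is estimated from the quietest decile of
10-s windows (lowest summed triaxial variance) after a 0.5 Hz low-pass,
and a single rigid (Rodrigues) rotation maps it to +z. A trace without
enough windows falls back to the global low-pass mean with a warning.
The estimate needs at least 60 s of data.

**LULU smoothing.** `L_n` (running max of running min, window `n+1`)
removes upward impulses up to `n` samples wide; its dual `U_n` removes
downward ones. Sequences are extended constantly beyond their ends — the
infinite-extension definition — so every monotone sequence is a fixed
point of both operators; both compositions are idempotent. The detector
smooths the heave with `L` first, then `U` (config string `"LU"` means
application order). The order matters: applying `U` first bridges the
short gaps between the half-sine lobes of a wingbeat burst into a
plateau wider than `n`, which `L` then cannot remove, and the residual
carrying the spikes vanishes.

**Peak picking.** The residual `heave − LULU(heave)` is searched for
local maxima above a threshold, accepted greedily in descending height
with a refractory gap (default 0.12 s ≈ a third of a wingbeat period);
plateaus resolve to their first sample. Defaults: window `n = 5`
samples (0.2 s at 25 Hz, shorter than one ~3 Hz wingbeat), threshold
0.8 g. The threshold default is set above the noise ceiling of the
residual rather than midway between noise sd and spike amplitude: the
opening-type smoother rides the lower envelope of the noise, so the
flap-free residual is positively biased (mean ≈ 0.11 g, extremes
≈ 0.85 g at 0.15 g noise sd) and a 0.5 g threshold would admit
hundreds of false peaks per hour. All three knobs are per-deployment
configuration, to be re-tuned per tag type.

75 Hz tags are decimated 3:1 to the 25 Hz working rate after a 10 Hz
anti-alias low-pass. Hourly counts use UTC clock hours, half-open
`[h, h+1)`, matching the environment grid's time index.

## Movement states (`flapwave.hmm`)

Tracks interpolated to 10 minutes (linear in lat/lon; gaps > 60 min
left missing) are reduced to great-circle step lengths (haversine,
R = 6371 km) and turn angles (signed change of initial bearing,
wrapped to (−π, π]). A 3-state HMM — rest on water, forage, commute —
is fitted to these metrics pooled across birds, with birds as
independent sequences.

Emissions are gamma for step length (zero steps floored at 1 m) and
von Mises for turn angle, the standard movement-HMM pairing; both the
von Mises mean and concentration are estimated per state. The initial
distribution is the stationary distribution of the transition matrix.
Fitting maximises the forward log-likelihood directly (L-BFGS on
unconstrained transforms: row-softmax for the transition matrix, logs
for positive parameters) from 25 seeded random starts centred on step
quantiles; this keeps the maximised objective identical to the
exhaustive path-enumeration oracle used in the tests. After fitting,
states are relabeled so mean step length orders rest < forage <
commute; relabeling leaves the likelihood invariant. Decoding is
Viterbi with ties resolved toward the lower state index. The
recursions are jit-compiled with numba when available, with a pure
numpy fallback.

Rest calls are validated against leg-mounted immersion loggers: a
10-min interval is "on-water" if any wet record of ≥ 6 s (two 3-s
samples) overlaps it, and the reported statistic is the fraction of
HMM-rest intervals that are immersion-on-water.

## Track-environment syncing (`flapwave.trackenv`)

Hourly wind (10 m u/v, m/s) and total-swell (significant height, mean
direction) fields are interpolated bilinearly in space at the exact
hourly field; directions go through their unit-vector components to
avoid the 0/360 wrap. Windspeed is reported in km/h; `wind_from`
follows the meteorological origin convention,
`(270 − atan2(v, u)·180/π) mod 360`.

The bird-wind angle (BWA) and bird-swell angle (BSA) are folded to
[0°, 180°]: 0° is travel with the flow (direct tailwind), 180° directly
against it. Swell direction is treated in the same coming-from
convention as wind by default, with a grid-level flag (`toward`) for
products using the propagation convention.

The hourly modeling table keeps one row per bird-hour of continuous
flight: any hour containing a rest-labeled 10-min interval is dropped,
as are hours without full track coverage or with positions outside the
grid; every drop is logged with its reason. The hour's position is the
interpolated top-of-hour fix and its bearing the initial great-circle
bearing to the next hour's position — the hourly resolution at which
BWA/BSA enter the models. Incomplete trips stay in the modeling table
(flagged); only the conditions-experienced summaries exclude them.

## Flap-rate models (`flapwave.gam`, `flapwave.models`)

Six candidate structures for hourly flap counts, all with a log link
and a ridge-penalized per-bird random intercept:

| Model | Environmental term |
|-------|--------------------|
| 0     | none (null)        |
| I     | s(windspeed)       |
| II    | s(swell height)    |
| III   | te(windspeed, BWA) |
| IV    | te(swell height, BSA) |
| V     | te(windspeed, swell height) |

Smooths are penalized B-splines (P-splines: cubic basis of dimension 5,
second-order difference penalty, centred columns); tensor products are
row-wise Kronecker products of the marginal bases (5 × 5) with one
smoothing parameter per margin. The folded angles are plain bounded
covariates (no circular basis), consistent with their 0–180° definition.
A four-way wind×angle×swell×angle interaction is deliberately not
offered; it would be uninterpretable.

The count family is negative binomial (NB2) by default — flaps/hour are
overdispersed counts — with a single dispersion per species table
estimated by moments from a Poisson null fit and shared across all six
candidates, so AICc compares them on one likelihood; Poisson is
available by configuration. Fitting is penalized IRLS; smoothing
parameters minimise the model's own AICc (Nelder–Mead on
log-smoothing-parameters), with effective degrees of freedom taken as
the trace of the influence matrix, covering penalized and random-effect
terms alike. Selecting every candidate under the same criterion it is
compared by serves the same purpose as a common-likelihood (ML rather
than REML) convention in penalized-likelihood software.

`AICc = −2ℓ + 2·edf + 2·edf·(edf+1)/(n − edf − 1)`; Akaike weights are
`exp(−Δ/2)` normalized over the candidate set. R² is reported as the
squared correlation of fitted and observed counts; deviance explained
is relative to the intercept-only deviance of the same family.

**Prediction-space trimming.** Before interpretation, two-variable
surfaces are restricted to the densest region of the observed covariate
space holding ~99% of the observations: a Gaussian-product KDE with
normal-reference (Silverman) bandwidth, thresholded at the 1st
percentile of its own values at the observed points.

**Reduction statistic.** The headline number is the percent reduction
from the 95th to the 5th quantile of predictions over the masked grid
cells (equal cell weights, linear-interpolation quantiles):
`100·(max − min)/max`, reported to two decimals. It is invariant to
rescaling all predictions.

**Conditional profiles.** Model V is also summarised along one variable
with the other held at its mean observed value and the random effect at
the population level; 95% pointwise intervals come from the penalized
coefficient covariance on the linear-predictor scale.

**Down-sampling robustness.** To probe sensitivity to the smallest
species sample (18 birds), Model V is refitted on 100 draws of 12
brood-guard + 6 incubation birds (without replacement) and the per-cell
5–95% envelope of the resulting surfaces is compared with the full-data
surface.

## Environmental context (`flapwave.context`)

Foraging ranges are 95% utilization regions of a 2-D Gaussian KDE
(reference bandwidth) on fixes projected with a Lambert azimuthal
equal-area projection about the colony — equal-area so density mass is
not distorted at high latitude, and free of antimeridian issues. The
density threshold is chosen on a grid so the enclosed KDE mass is 95%
to grid precision (the accepted region always holds 94–96%). Monthly
climatologies average the fields over grid cells inside the region with
cos(latitude) area weights, excluding missing (sea-ice) cells, per
calendar month across years.

Experienced-condition categories use tercile thresholds (1/3 and 2/3
quantiles) of windspeed and swell height pooled over a species-balanced
subset of complete-trip birds (34 per ocean basin, equal per species),
so no species' sample size biases the breaks. Magnitude classes are
closed on the left (`med = [t1, t2)`). Relative-angle classes use equal
60° bins — tail/cross/head at 60° and 120° — a declared default, not an
estimate, exposed in configuration. Proportions are computed per bird
and then averaged across birds.

## Synthetic data (`flapwave.synth`)

The generator produces every input stream with the statistical
structure the analysis assumes, plus ground truth:

- **Tracks**: a 3-state Markov chain (default transition matrix with
  0.8–0.85 self-transition) with per-state gamma steps (means 0.1, 3,
  8 km per 10 min) and von Mises turns (κ = 0.3, 1, 15); trips start at
  the colony and the heading is steered home over the final 20% of
  intervals so trips complete.
- **Accelerometry**: 25 Hz; heave = 1 g + Gaussian noise (0.15 g) +
  a 0.1–0.3 Hz soaring undulation (0.1 g) in flight states; wingbeats
  are positive half-sine bursts at 3 Hz and 1.2 g placed in
  non-overlapping bout slots, with the per-interval bout count Poisson.
  True peak instants and hourly counts are recorded; rest intervals
  contain no flaps. Within-bout wingbeat-frequency variability is a
  parameter (default off) since no field estimate of it is assumed.
- **Environment**: smooth Gaussian random fields, hourly, 0.5°
  resolution, with spatial correlation scale 2° and temporal scale 3 h;
  the swell field is generated from noise independent of the wind
  components (swell is made by distant weather, not local wind) and is
  clamped non-negative. Constant-field mode supports exactness tests.
- **Linkage**: the expected hourly flap rate is
  `exp(b0 + b1·windspeed + b2·swell)` at the bird's position (defaults
  b0 = 7.5, b1 = −0.035 per km/h, b2 = −0.2 per m — chosen so a bird in
  typical conditions flaps a few hundred times per hour and the
  reduction across the experienced range is of order 90%), times a
  lognormal per-bird effect (sd 0.25).
- **Immersion**: wet during rest, dry in flight, at 3-s alignment, with
  an optional per-interval flip-error probability; flips act on whole
  10-min intervals, which is what makes the rest-vs-wet agreement equal
  one minus the flip rate in expectation.

A faster path (`gen_hourly_table`) samples the hourly modeling table
directly — windspeed gamma(mean 32 km/h, sd 12), swell gamma(mean
2.5 m, sd 0.8), angles uniform on [0°, 180°], Poisson counts — for
model-recovery experiments where the accelerometer and HMM stages are
not under test.

**What the generator does not emulate**: reanalysis wind/wave spectra,
tag firmware artifacts (clock drift, dropouts, saturation),
species-specific morphology or airspeed-dependent gait changes, wind
waves correlated with local wind, or behavioral feedback of conditions
on state switching. Tests passing on this generator demonstrate that
the estimators recover the structure they assume; they do not by
themselves validate the behavioral model on real birds.

## Numerical choices and degenerate inputs

- HMM likelihood uses log-space recursions; missing steps/turns
  contribute nothing; all-zero steps are floored at 1 m.
- IRLS clips the linear predictor at ±30 and adds a 1e-8 ridge before
  solving; rank problems surface as errors naming the model.
- Quantiles everywhere are linear-interpolation (numpy default).
- Degenerate inputs are rejected loudly: zero-variance KDE dimensions,
  all-equal tercile inputs (t1 = t2), non-stochastic transition
  matrices, unordered GPS timestamps, super-Nyquist wingbeat
  frequencies.
- An all-constant accelerometer trace yields zero flap events, and
  an all-equal prediction surface yields 0% reduction — neither is an
  error.

## Problem sizes used in the shipped checks

The test-suite and the reproduction script run at desk scale: 100
synthetic flight hours for detection recovery, 2000 intervals for HMM
recovery, 50 seeded cohorts of 8 birds × 60 hours for model selection,
1000 rest intervals for the immersion statistic, and 4000–5000 points
for the KDE contracts. These sizes are the package's own choice of a
scale at which the asymptotic claims (recovery tolerances, win rates)
are already stable.

## Known limitations

- The GAM engine offers exactly the structures the analysis needs
  (univariate smooths, 2-D tensors, random intercepts); it is not a
  general formula-driven GAM replacement.
- AICc-based smoothing selection can undersmooth slightly relative to
  marginal-likelihood criteria on very small tables.
- NB2 dispersion is fixed per table rather than profiled per model;
  with strong covariate effects the moment estimate from the null fit
  is conservative (it absorbs explainable variance into dispersion).
- The HMM assumes time-homogeneous transitions and no covariate effects
  on switching, by design.
- Bilinear extraction ignores sub-hour temporal variation of the
  fields, matching the hourly product resolution.
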