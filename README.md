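# woodfrog

Mechanistic simulation of wood frog (*Rana sylvatica*) post-hibernation
emergence phenology, for ecologists studying how exogenous drivers
(meteorology, geography) and endogenous traits (behavior, morphology,
physiology) shape the timing of spring activity in a freeze-tolerant,
pond-breeding amphibian.

Adult wood frogs overwinter a few centimeters below the soil surface and
emerge in early spring to breed in vernal ponds. The package couples a
simplified below-canopy microclimate model to a rule-based frog model
and asks which knobs actually move the emergence date.

## The model

**Microclimate.** Daily forcing (tmin, tmax, precipitation) is
transformed per pond into:

- hourly air temperature at frog height — a piecewise sinusoid between
  the daily extremes (minimum 05:00, maximum 15:00) whose departure from
  the daily mean is damped by canopy cover, `1 − d·C`;
- a daily snowpack — precipitation on days with mean temperature below
  0 °C falls as snow, is reduced by canopy interception `(1 − i·C)`, and
  melts at a degree-day rate `f·max(T̄, 0)·(1 − m·C)`, so shaded ponds
  receive less snow but keep it longer;
- an hourly soil-temperature profile — backward-Euler finite differences
  on ∂T/∂t = κ ∂²T/∂z², zero-flux bottom boundary, and a surface
  boundary `T₀ = w·T_air` with `w = exp(−h_snow/s)`: deep snow decouples
  the soil from the air and pins the interface toward 0 °C (the
  subnivium effect).

**Frog.** A dormant frog at fixed burrow depth (default 2.5 cm) tracks
the soil temperature at the nearest node. It may emerge at the first
hour when all of the following hold: the calendar is past DOY 65; daily
minimum body temperature exceeded −0.16 °C (the thaw-inflection
temperature) for 3 consecutive days; the microsite was snow-free for 5
consecutive days; and air temperature has been at or above the frog's
chosen emergence temperature for a required run of consecutive hours
without exceeding CT_max.

**Analysis machinery.** Climatological-normals null model (per-DOY
average forcing, snow physics recomputed); RMSE/MAE validation against
egg-mass-weighted survey dates; error GLM on min-max-scaled covariates
with percentile-bootstrap CIs; drought filtering on a user-supplied
PDSI; pooled decadal trend with pond fixed intercepts; one-at-a-time
sensitivity analysis with importance = range of the interannual-mean
emergence date over each parameter's {min, mean, max}, attributed to
exogenous/endogenous categories as shares of summed importance.

All of it runs on synthetic data: a seasonal-cycle + AR(1) weather
generator, a pond network spanning canopy cover 0–0.9 near 236 m ASL,
and surveys synthesized as emergence plus a stochastic oviposition lag.

## Worked example

```python
from woodfrog import (WeatherConfig, generate_daily_weather,
                      generate_pond_network, generate_observations,
                      RunConfig, run_simulation, simulate_null, validate)

weather = generate_daily_weather(WeatherConfig(seed=1), n_years=6, start_year=2000)
ponds = generate_pond_network(4, (0.0, 0.9), 236.0, seed=2)
cfg = RunConfig(2000, 2005, ponds)          # first year is burn-in

dynamic = run_simulation(cfg, weather)
obs = generate_observations(dynamic, lag_mean=5, lag_sd=0,
                            surveys_per_year=1, seed=3)
print(validate(dynamic, obs).mae)           # 5.0  (exact lag recovery)

null = simulate_null(cfg, weather)
print(validate(null, obs).rmse)             # 9.59 (vs 5.0 for the dynamic model)
```

The dynamic model recovers the 5-day oviposition lag exactly (MAE =
5.0 days), while the climatological-normals null — identical forcing
every year, hence zero interannual variation in its predictions — pays
for ignoring real weather with an RMSE of 9.59 days.

The full analysis lives in `analysis/01…05_*.py`, which generate a
26-year, 64-pond synthetic study system and write tidy tables under
`results/`. On the default configuration the sensitivity step prints

```
empirical trait ranges:
  meteorology   73.1% (62.6 d)
  geography     13.3% (11.4 d)
  behavior      12.7% (10.9 d)
  morphology     0.0% (0.0 d)
  physiology     0.9% (0.8 d)
```

i.e. exogenous drivers dominate the variation in emergence date,
behavior plays a moderate role, and morphology/physiology barely
register — even after trait-range inflation (widening the
consecutive-warm-hours requirement from 1–24 h to 1–96 h raises the
behavior share to 26.0%).

A thin CLI mirrors the library: `woodfrog synth|simulate|nullmodel|
validate|trend|sensitivity` (see `woodfrog --help`).

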