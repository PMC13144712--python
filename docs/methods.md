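# Methods

This note documents the models in `woodfrog`, the choices behind their
parameters, what the synthetic data do and do not emulate, and the
numerical decisions a maintainer would want to know about.

## Weather generator

Daily mean temperature is a sinusoid with period 365.25 d (annual mean
9 °C, amplitude 13 °C, minimum at DOY 15 — a southern New England
climate), plus a linear warming trend (default 0) and an AR(1) anomaly
process. `anomaly_sd` (default 3 °C) is the *marginal* SD of the
anomalies; the innovation SD is `anomaly_sd·√(1−φ²)` with φ = 0.7
(synoptic persistence of a few days). tmin/tmax sit symmetrically about
the daily mean. The diurnal range itself has a seasonal cycle (default
9 ± 3 °C, largest in summer), because clear warm-season days heat more
strongly than overcast winter days; this is also what makes below-canopy
temperature *maxima* more canopy-sensitive than minima (amplitude
damping is symmetric, so with a constant diurnal range the two
sensitivities would tie exactly). Setting `diurnal_range_seasonal = 0`
recovers a constant range.

Precipitation is Bernoulli(0.35) × Gamma(0.7, 12 mm), giving ≈ 1050
mm yr⁻¹ — totals in the range of the region the network emulates. Years
are exactly 365 days (leap days dropped): every phenology quantity is a
day-of-year, and a fixed-length year keeps hourly arrays rectangular.

One weather series is shared by the whole pond network, as for a single
~4-km meteorological grid cell; ponds differ only in canopy cover,
elevation, area and LAI. No spatial correlation structure, humidity,
wind or radiation is generated.

The synthetic observations are emergence dates plus
`max(0, round(N(lag_mean, lag_sd)))` days (defaults 7 ± 3 d), then
weekly follow-up surveys with declining new-egg-mass counts. The lag
distribution is a free setting, not an estimate — no published
distribution of the emergence→oviposition interval exists for this
system. Because predictions date *emergence* while surveys date
*oviposition*, validation against these observations carries the lag as
a systematic bias for every model compared (as it does with real survey
data); `analysis/03` therefore also reports bias-removed error SDs.

## Microclimate

- **Diurnal downscaling.** Piecewise sinusoid with minimum at 05:00 and
  maximum at 15:00 (a 10-h rising limb, 14-h falling limb). Canopy
  multiplies the departure from the daily mean by
  `1 − canopy_amplitude_damping·C` (default damping 0.5), so a 90%-shaded
  pond has 55% of the open-site diurnal range. Output is bounded by
  [tmin, tmax] by construction. Days are downscaled independently (no
  cross-midnight continuity constraint).
- **Rain/snow partition.** All-or-nothing at a daily-mean threshold of
  0 °C — the forcing is daily, so a within-day mixed-phase treatment
  would be false precision. `snowfall_multiplier` scales snowfall to
  represent microhabitat drifting (windthrown snow around rocks and
  woody debris); water is conserved exactly when it is 1.
- **Snowpack.** Degree-day melt (3 mm SWE °C⁻¹ d⁻¹) damped under canopy
  (factor `1 − 0.5·C`), interception `1 − 0.4·C`, bulk density
  250 kg m⁻³ for SWE→depth. Melt is capped at available SWE, so the mass
  balance `Σ effective snowfall − Σ melt = SWE` closes to float rounding
  on any forcing. These defaults were chosen once for qualitative
  realism: open ponds reach higher peak SWE, shaded ponds hold snow
  later — the canopy→snow-persistence→emergence-order pathway.
- **Soil.** 1-D conduction, κ = 5×10⁻⁷ m² s⁻¹ (moist loam), default
  nodes at 0, 2.5, 5, 10, 20, 50 cm so the 2–5 cm hibernaculum range is
  bracketed. Backward-Euler stepping (hourly in the pipeline) is
  unconditionally stable and satisfies the discrete maximum principle;
  the system matrix is factored once per run and the hot loop is
  numba-compiled. Against the analytic damped-sinusoid solution for a
  24-h surface wave (damping depth D = √(2κ/ω) ≈ 11.7 cm), a
  0.5-cm/300-s verification grid reproduces amplitudes within ~1% and
  phase lags within ~0.6% at 2.5–30 cm.
- **Snow insulation.** Instead of an explicit snow conduction layer, the
  surface boundary is `w·T_air + (1−w)·0 °C` with
  `w = exp(−h_snow / 7 cm)`: one parameter captures the subnivium —
  20 cm of snow leaves 6% coupling to air and pins the soil interface
  near 0 °C.
- **Elevation.** A fixed lapse rate of −6.5 °C km⁻¹ relative to a 236 m
  datum, applied to tmin/tmax before downscaling.
- `rain_absorption` is accepted and validated but currently inert: there
  is no soil-moisture budget for absorbed rain to act on, and hydric
  effects are out of scope. It is excluded from the default sensitivity
  table so a structurally-zero importance does not dilute the category
  shares.

## Frog model

Body temperature equals the soil temperature at the node nearest the
burrow depth (ties to the shallower node). A small buried ectotherm
equilibrates within minutes, so the default thermal time constant is 0;
setting it positive enables exact first-order relaxation with the
constant scaled by `(mass/11.6 g)^(1/3)`, which is the only pathway by
which mass enters the model.

Emergence gates (all defaults from field thresholds for this species):
calendar past DOY 65; daily *minimum* body temperature above −0.16 °C
for 3 consecutive days — the strictest reading, so a night that
refreezes the topsoil resets the window; snow depth exactly 0 for 5
consecutive days; and, hourly, a run of `favorable_consecutive_hours`
(default 1) at or above the chosen emergence air temperature (default
5 °C, boundary inclusive) with air ≤ CT_max (35 °C). Trailing windows
include the current day — the weakest sufficient reading of "for N
consecutive days", centralized in `_trailing_all` so the convention can
be changed in one place. Gates are evaluated daily, favorability hourly;
the emergence hour is the first favorable hour of the first day passing
all gates. The warm-hour counter starts fresh each simulated year.

The frog stays at its burrow depth until emergence: no within-winter
vertical movement, feeding, energetics, mortality or movement to ponds.

## Pipeline

- **Burn-in.** The first simulated year (default 1) equilibrates the
  soil profile and snowpack and is discarded from all records.
- **Null model.** The climatological-normals construction averages the
  daily *forcing* per DOY across years and replicates the normal year.
  Averaging daily tmin/tmax and then downscaling is algebraically
  identical to averaging hourly air temperature at fixed (DOY, hour),
  because the downscaling is linear in (tmin, tmax). Snow (and hence
  soil) state is *recomputed* on the averaged year rather than averaged
  directly — averaging snow depth across years can produce perpetual
  trace snow that never satisfies a snow-free window. This is the one
  place where the two constructions differ; where no snow is involved,
  the recomputed soil normal equals the average of the per-year soils
  exactly (the conduction chain is linear). Note that averaging
  intermittent precipitation smears it into small daily amounts, which
  tends to make the normal-year snowpack more persistent than a typical
  year's — a known artifact of any normals construction over
  intermittent forcing.
- **Validation.** Observed date per pond-year is the egg-mass-weighted
  mean survey DOY (all-zero counts fall back to the unweighted mean);
  the join with predictions is inner, with unmatched records counted and
  logged, never imputed. Error = predicted − observed.
- **Error regression.** OLS with intercept on min-max-scaled covariates;
  constant covariates are dropped with a warning. CIs are percentile
  bootstrap over case resampling (vectorized batched normal equations).
  Percentile bootstrap is asymptotic: at n ≈ 80 rows its empirical
  coverage is ~92%; the coverage checks use 250 rows, where it reaches
  ~94–95%.
- **Trend.** Slope of DOY on year with pond fixed intercepts, computed
  by within-pond demeaning, with a case bootstrap over pond-years. With
  no random slopes the fixed-intercept estimand coincides with the
  mixed-model mean slope, which avoids a mixed-effects dependency. The
  bootstrap treats pond-years as exchangeable and therefore understates
  uncertainty from year effects shared across ponds — adequate for the
  constructed-arithmetic checks it serves, conservative conclusions
  should not rest on its CI width for short spans.

## Sensitivity analysis

The OAT design shares a single all-means baseline, so P parameters need
2P + 1 runs; the baseline *is* each parameter's mean-value run.
Importance is `max − min` of the three interannual-mean emergence dates,
which captures non-monotone responses (a {100, 90, 100} response scores
10 d, where an endpoints-only rule would score 0). Pond-years without
emergence are excluded from interannual means and counted; a parameter
whose every run fails to emerge is flagged undefined, never silently 0.
Runs use a single reference pond (canopy 0.45, 236 m) with site
parameters governed by the table. Category shares are
`Σ importance in category / Σ importance × 100`.

The default table has 12 parameters. Ranges printed in the field
literature: mass 7.6–15.6 g, consecutive warm hours 1–24 (inflation
override 1–96 h), canopy cover 0–0.9, ambient offsets ±2 °C. The
remaining ranges (precipitation ×0.5–1.5, snowfall multiplier ×0.5–1.5,
elevation ±100 m, emergence temperature 2–8 °C, snow-free window 3–7 d,
burrow depth 2–5 cm, thaw threshold ±1 °C, thermal time constant 0–2 h)
were chosen once as field-plausible spans and not revisited. The thermal
time constant's mean is 1 h so that mass is exercisable at all; with the
default instantaneous equilibrium mass would be structurally inert.
Trait inflation widens min/max about an unchanged mean, clipped at each
parameter's physical bounds. A DEB on/off contrast is not implemented
(no energy-budget model here); the result schema leaves room for it.

Microclimate sensitivity applies the same machinery with responses =
interannual means of the annual min and max of hourly air and topsoil
(2.5 cm) temperature, restricted to exogenous parameters.

## Problem sizes and what passing tests show

The shipped analyses use a 64-pond network over 26 years (one burn-in),
OAT at one reference pond over 16 years in the acceptance script, 200
randomized pond-years for the rule-oracle comparison, 1000 forcing years
for mass balance, and 1000×1000 replicates×bootstraps for coverage —
sizes at which every property is sharp while the whole suite runs in
minutes on one CPU.

The synthetic system has no radiation, humidity, soil moisture, spatial
weather structure, or observation error beyond the oviposition lag, and
the frog model has no energetics or behavior beyond the gate rules.
Passing tests therefore demonstrate internal correctness (the code
implements the stated models exactly, and the pipeline's comparative
statements — null vs dynamic, exogenous vs endogenous, warming direction
— follow from those models), not that the models are calibrated to any
real pond network. Magnitudes (RMSE values, category percentages) are
properties of the synthetic configuration.

## Known limitations

- The warming-direction property (a uniform +2 °C never delays
  emergence) holds on the default synthetic conditions but is not a
  theorem of the model: losing snow insulation earlier can in principle
  expose the topsoil to refreezing nights and reset the thaw window.
- The null model's snow artifact under averaged intermittent
  precipitation (above) biases its predictions late; comparisons with
  the dynamic model should use the same observation set and, for
  tracking skill, the bias-removed error SD.
- Survey synthesis ties new-egg-mass counts to nothing biological; the
  egg-count covariate in the error regression is exercised, not
  interpreted.
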