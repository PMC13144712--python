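"""One-at-a-time (OAT) sensitivity analysis of emergence phenology.

Each parameter gets three values (min, mean, max); one simulation varies
that parameter while every other parameter is held at its mean, so a
P-parameter experiment needs 2P + 1 distinct runs (the all-means
baseline is shared).  A parameter's importance is the range (max − min)
of the three interannual-mean emergence dates, which captures
non-monotone responses.  Importances are attributed to five categories
— meteorology and geography (exogenous) versus behavior, morphology and
physiology (endogenous) — as percentage shares of the summed importance.

Trait ranges can be inflated about their means to probe whether wider
phenotypes would change the attribution, and the same OAT machinery can
be pointed at microclimate outputs (annual min/max of below-canopy air
and topsoil temperature) for the exogenous parameters only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, fields as dc_fields
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .frog_model import FrogTraits
from .microclimate import MicroParams, run_microclimate
from .pipeline import RunConfig, run_simulation

CATEGORIES = ("meteorology", "geography", "behavior", "morphology", "physiology")
EXOGENOUS = ("meteorology", "geography")
ENDOGENOUS = ("behavior", "morphology", "physiology")

PLAN_COLUMNS = ["run_id", "parameter", "level", "value"]


@dataclass(frozen=True)
class ParameterSpec:
    name: str
    category: str
    min: float
    mean: float
    max: float
    applies_to: str            # e.g. "traits.mass", "site.canopy_cover",
                               # "micro.snowfall_multiplier", "weather.temp_offset"
    inflatable: bool = False
    lower_bound: float = -math.inf   # physical clip for inflation
    upper_bound: float = math.inf

    def validate(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not (self.min <= self.mean <= self.max):
            raise ValueError(f"{self.name}: need min <= mean <= max")


@dataclass
class SensitivityResult:
    parameter: str
    category: str
    mean_at_min: float
    mean_at_mean: float
    mean_at_max: float
    importance: float          # days (or °C for microclimate responses)
    n_missing_years: int = 0
    undefined: bool = False    # no run of this parameter produced a response


def default_parameter_table() -> list[ParameterSpec]:
    """Default OAT table covering the drivers exercised by this model.

    Ranges printed in the field literature are used where available
    (mass 7.6–15.6 g; consecutive emergence hours 1–24; canopy cover
    0–0.9; ±2 °C ambient offsets); the rest span field-plausible values.
    """
    return [
        ParameterSpec("air_temp_offset", "meteorology", -2.0, 0.0, 2.0,
                      "weather.temp_offset"),
        ParameterSpec("precip_multiplier", "meteorology", 0.5, 1.0, 1.5,
                      "weather.precip_multiplier", lower_bound=0.0),
        ParameterSpec("snowfall_multiplier", "meteorology", 0.5, 1.0, 1.5,
                      "micro.snowfall_multiplier", lower_bound=0.0),
        ParameterSpec("canopy_cover", "geography", 0.0, 0.45, 0.9,
                      "site.canopy_cover", lower_bound=0.0, upper_bound=1.0),
        ParameterSpec("elevation", "geography", 136.0, 236.0, 336.0,
                      "site.elevation"),
        ParameterSpec("emergence_air_temp", "behavior", 2.0, 5.0, 8.0,
                      "traits.emergence_air_temp", inflatable=True),
        ParameterSpec("favorable_consecutive_hours", "behavior", 1, 12, 24,
                      "traits.favorable_consecutive_hours", inflatable=True,
                      lower_bound=1),
        ParameterSpec("snowfree_consecutive_days", "behavior", 3, 5, 7,
                      "traits.snowfree_consecutive_days", inflatable=True,
                      lower_bound=1),
        ParameterSpec("burrow_depth", "behavior", 2.0, 2.5, 5.0,
                      "traits.burrow_depth", inflatable=True, lower_bound=0.5),
        ParameterSpec("mass", "morphology", 7.6, 11.6, 15.6,
                      "traits.mass", inflatable=True, lower_bound=0.5),
        ParameterSpec("thaw_threshold_temp", "physiology", -1.16, -0.16, 0.84,
                      "traits.thaw_threshold_temp", inflatable=True),
        ParameterSpec("thermal_time_constant", "physiology", 0.0, 1.0, 2.0,
                      "traits.thermal_time_constant", inflatable=True,
                      lower_bound=0.0),
    ]


def write_parameter_table(params: Sequence[ParameterSpec], path) -> None:
    pd.DataFrame([{
        "name": p.name, "category": p.category, "min": p.min, "mean": p.mean,
        "max": p.max, "applies_to": p.applies_to, "inflatable": p.inflatable,
        "lower_bound": p.lower_bound, "upper_bound": p.upper_bound,
    } for p in params]).to_csv(path, index=False)


def read_parameter_table(path) -> list[ParameterSpec]:
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples(index=False):
        spec = ParameterSpec(r.name, r.category, float(r.min), float(r.mean),
                             float(r.max), r.applies_to, bool(r.inflatable),
                             float(getattr(r, "lower_bound", -math.inf)),
                             float(getattr(r, "upper_bound", math.inf)))
        spec.validate()
        out.append(spec)
    return out


# ---------------------------------------------------------------------------
# OAT design and execution


def oat_design(params: Sequence[ParameterSpec]) -> pd.DataFrame:
    """Serializable run plan: one shared baseline plus low/high per parameter.

    Parameters with zero span (min == mean == max) contribute no runs
    beyond the baseline.  2P + 1 rows for P non-degenerate parameters.
    """
    if len(params) == 0:
        raise ValueError("need at least one parameter")
    names = [p.name for p in params]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate parameter names: {dupes}")
    for p in params:
        p.validate()

    rows = [("baseline", "", "baseline", np.nan)]
    for p in params:
        if p.min == p.mean == p.max:
            continue
        rows.append((f"{p.name}__low", p.name, "low", p.min))
        rows.append((f"{p.name}__high", p.name, "high", p.max))
    return pd.DataFrame(rows, columns=PLAN_COLUMNS)


def write_plan(plan: pd.DataFrame, path) -> None:
    plan.to_csv(path, index=False)


def read_plan(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["parameter"] = df["parameter"].fillna("")
    return df[PLAN_COLUMNS]


def run_oat(plan: pd.DataFrame, simulator: Callable[[Mapping[str, float]], float],
            params: Sequence[ParameterSpec]) -> list[SensitivityResult]:
    """Execute an OAT plan against a response simulator.

    ``simulator(overrides)`` maps {parameter name: value} to the
    interannual-mean response (emergence DOY); it must be deterministic
    and may return NaN when no pond-year emerged.  The baseline (empty
    overrides) is executed exactly once and reused as every parameter's
    mean-value run.  Importance is the range of the three means, so
    non-monotone responses are captured.
    """
    by_name = {p.name: p for p in params}
    baseline_rows = plan[plan["level"] == "baseline"]
    if len(baseline_rows) != 1:
        raise ValueError("plan must contain exactly one baseline run")

    responses: dict[str, float] = {}
    responses["baseline"] = float(simulator({}))
    for row in plan.itertuples(index=False):
        if row.level == "baseline":
            continue
        responses[row.run_id] = float(simulator({row.parameter: row.value}))

    results = []
    for p in params:
        if p.min == p.mean == p.max:
            results.append(SensitivityResult(
                p.name, p.category, responses["baseline"], responses["baseline"],
                responses["baseline"], importance=0.0))
            continue
        lo = responses[f"{p.name}__low"]
        mid = responses["baseline"]
        hi = responses[f"{p.name}__high"]
        three = np.array([lo, mid, hi], dtype=float)
        finite = three[np.isfinite(three)]
        if finite.size == 0:
            results.append(SensitivityResult(p.name, p.category, lo, mid, hi,
                                             importance=np.nan, undefined=True))
            continue
        importance = float(finite.max() - finite.min())
        results.append(SensitivityResult(p.name, p.category, lo, mid, hi,
                                         importance=importance,
                                         undefined=bool(finite.size < three.size)))
    return results


def results_to_frame(results: Sequence[SensitivityResult]) -> pd.DataFrame:
    df = pd.DataFrame([{
        "parameter": r.parameter, "category": r.category,
        "mean_at_min": r.mean_at_min, "mean_at_mean": r.mean_at_mean,
        "mean_at_max": r.mean_at_max, "importance": r.importance,
        "undefined": r.undefined,
    } for r in results])
    total = df.loc[np.isfinite(df["importance"]), "importance"].sum()
    if total > 0:
        df["share_pct"] = np.where(np.isfinite(df["importance"]),
                                   100.0 * df["importance"] / total, np.nan)
    else:
        df["share_pct"] = np.nan
    return df


def category_attribution(results: Sequence[SensitivityResult]) -> pd.DataFrame:
    """Share of total importance per category (%); shares sum to 100."""
    finite = [r for r in results if np.isfinite(r.importance)]
    if not finite:
        raise ValueError("no finite importances to attribute")
    total = sum(r.importance for r in finite)
    if total == 0:
        raise ValueError("total importance is 0: attribution undefined")
    rows = []
    for cat in CATEGORIES:
        imp = sum(r.importance for r in finite if r.category == cat)
        rows.append((cat, imp, 100.0 * imp / total))
    return pd.DataFrame(rows, columns=["category", "importance_days", "share_pct"])


def inflate_trait_ranges(params: Sequence[ParameterSpec],
                         inflation: float | Mapping[str, object] = 2.0
                         ) -> list[ParameterSpec]:
    """Widen the (min, max) of inflatable parameters about their means.

    ``inflation`` is either a scalar factor (min/max move to
    mean ± factor × their current offsets, clipped at the parameter's
    physical bounds) or a mapping of parameter name to a factor or an
    explicit ``(min, max)`` override, e.g.
    ``{"favorable_consecutive_hours": (1, 96)}``.
    """
    out = []
    for p in params:
        if not p.inflatable:
            out.append(p)
            continue
        spec = inflation.get(p.name, None) if isinstance(inflation, Mapping) \
            else inflation
        if spec is None:
            out.append(p)
            continue
        if isinstance(spec, (tuple, list)):
            new_min, new_max = float(spec[0]), float(spec[1])
        else:
            f = float(spec)
            new_min = p.mean - f * (p.mean - p.min)
            new_max = p.mean + f * (p.max - p.mean)
        new_min = max(new_min, p.lower_bound)
        new_max = min(new_max, p.upper_bound)
        if new_min > new_max:
            raise ValueError(f"{p.name}: inflation produced min > max")
        out.append(replace(p, min=new_min, max=new_max))
    return out


# ---------------------------------------------------------------------------
# concrete simulators


_INT_TRAITS = {"thaw_consecutive_days", "snowfree_consecutive_days",
               "earliest_doy", "favorable_consecutive_hours"}


def _apply_overrides(overrides: Mapping[str, float],
                     params: Sequence[ParameterSpec],
                     weather: pd.DataFrame, pond, traits: FrogTraits,
                     micro: MicroParams):
    """Bind parameter values onto forcing, site, traits and micro params."""
    by_name = {p.name: p for p in params}
    weather = weather.copy()
    pond_fields = pond._asdict() if hasattr(pond, "_asdict") else dict(pond)
    traits_kw = {f.name: getattr(traits, f.name) for f in dc_fields(traits)}
    micro_kw = {f.name: getattr(micro, f.name) for f in dc_fields(micro)}

    for name, value in overrides.items():
        spec = by_name[name]
        target = spec.applies_to
        if target == "weather.temp_offset":
            weather["tmin"] = weather["tmin"] + value
            weather["tmax"] = weather["tmax"] + value
        elif target == "weather.precip_multiplier":
            weather["precip"] = weather["precip"] * value
        elif target.startswith("micro."):
            micro_kw[target.split(".", 1)[1]] = value
        elif target.startswith("site."):
            pond_fields[target.split(".", 1)[1]] = value
        elif target.startswith("traits."):
            fname = target.split(".", 1)[1]
            traits_kw[fname] = (int(round(value)) if fname in _INT_TRAITS
                                else value)
        else:
            raise ValueError(f"unknown binding {target!r} for parameter {name!r}")

    from collections import namedtuple
    Pond = namedtuple("Pond", list(pond_fields))
    return weather, Pond(**pond_fields), FrogTraits(**traits_kw), MicroParams(**micro_kw)


class EmergenceSimulator:
    """OAT response function: interannual mean emergence DOY at one
    reference pond, burn-in discarded, missing years excluded (their
    count is kept on ``last_n_missing``)."""

    def __init__(self, weather: pd.DataFrame, pond, params: Sequence[ParameterSpec],
                 traits: FrogTraits | None = None,
                 micro_params: MicroParams | None = None,
                 burn_in_years: int = 1):
        self.weather = weather
        self.pond = pond
        self.params = list(params)
        self.traits = traits or FrogTraits()
        self.micro_params = micro_params or MicroParams()
        self.burn_in_years = burn_in_years
        self.last_n_missing = 0
        self.n_calls = 0

    def __call__(self, overrides: Mapping[str, float]) -> float:
        self.n_calls += 1
        w, pond, traits, micro_params = _apply_overrides(
            overrides, self.params, self.weather, self.pond,
            self.traits, self.micro_params)
        years = np.sort(w["year"].unique())
        config = RunConfig(start_year=int(years[0]), end_year=int(years[-1]),
                           ponds=pd.DataFrame([pond._asdict()]),
                           traits=traits, micro_params=micro_params,
                           burn_in_years=self.burn_in_years)
        records = run_simulation(config, w)
        doys = records["emergence_doy"].to_numpy(float)
        self.last_n_missing = int(np.isnan(doys).sum())
        if np.all(np.isnan(doys)):
            return float("nan")
        return float(np.nanmean(doys))


class MicroclimateSensitivitySimulator:
    """OAT response for microclimate outputs: interannual means of the
    annual minimum and maximum of hourly below-canopy air temperature
    and topsoil (shallowest below-surface node) temperature."""

    RESPONSES = ("air_min", "air_max", "soil_min", "soil_max")

    def __init__(self, weather: pd.DataFrame, pond,
                 params: Sequence[ParameterSpec],
                 micro_params: MicroParams | None = None,
                 burn_in_years: int = 1):
        self.weather = weather
        self.pond = pond
        self.params = list(params)
        self.micro_params = micro_params or MicroParams()
        self.burn_in_years = burn_in_years

    def __call__(self, overrides: Mapping[str, float]) -> dict[str, float]:
        w, pond, _, micro_params = _apply_overrides(
            overrides, self.params, self.weather, self.pond,
            FrogTraits(), self.micro_params)
        series = run_microclimate(pond, w, micro_params)
        years = np.sort(np.unique(series.year))[self.burn_in_years:]
        mins_a, maxs_a, mins_s, maxs_s = [], [], [], []
        for y in years:
            m = series.year == y
            air = series.air_temp[m]
            soil = series.soil_temp[m, 1]  # shallowest below-surface node
            mins_a.append(air.min()); maxs_a.append(air.max())
            mins_s.append(soil.min()); maxs_s.append(soil.max())
        return {"air_min": float(np.mean(mins_a)),
                "air_max": float(np.mean(maxs_a)),
                "soil_min": float(np.mean(mins_s)),
                "soil_max": float(np.mean(maxs_s))}


def microclimate_sensitivity(params: Sequence[ParameterSpec],
                             simulator: Callable[[Mapping[str, float]], Mapping[str, float]]
                             ) -> pd.DataFrame:
    """OAT importances of below-canopy temperature extremes.

    Only exogenous (meteorology, geography) parameters are allowed; the
    frog plays no role in the microclimate.  Returns one row per
    parameter with four importances (°C): air_min, air_max, soil_min,
    soil_max.
    """
    bad = [p.name for p in params if p.category not in EXOGENOUS]
    if bad:
        raise ValueError(f"endogenous parameters not allowed here: {bad}")
    plan = oat_design(params)
    responses = {"baseline": simulator({})}
    for row in plan.itertuples(index=False):
        if row.level == "baseline":
            continue
        responses[row.run_id] = simulator({row.parameter: row.value})

    rows = []
    for p in params:
        rec = {"parameter": p.name, "category": p.category}
        for key in MicroclimateSensitivitySimulator.RESPONSES:
            if p.min == p.mean == p.max:
                rec[f"importance_{key}"] = 0.0
                continue
            vals = np.array([responses[f"{p.name}__low"][key],
                             responses["baseline"][key],
                             responses[f"{p.name}__high"][key]])
            rec[f"importance_{key}"] = float(vals.max() - vals.min())
        rows.append(rec)
    return pd.DataFrame(rows)
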