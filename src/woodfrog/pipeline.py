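"""Multi-pond, multi-year orchestration and validation statistics.

Couples the microclimate and frog models across a pond network and a
span of years, discards burn-in, and provides the statistics used to
evaluate predictions against oviposition surveys:

* a climatological-normals null model (per-DOY average forcing,
  replicated, with snow physics recomputed on the averaged year);
* weighted observed oviposition dates (surveys weighted by new egg-mass
  counts);
* RMSE/MAE validation with per-pond error tables and moving-window SDs;
* an error GLM (Gaussian OLS on min-max-scaled covariates) with
  percentile-bootstrap confidence intervals;
* a drought filter on a user-supplied per-year PDSI index;
* a pooled decadal phenology trend with pond fixed intercepts and a
  case bootstrap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .frog_model import FrogTraits, simulate_frog_year
from .microclimate import MicroclimateSeries, MicroParams, run_microclimate
from .synthetic_weather import DAYS_PER_YEAR

logger = logging.getLogger("woodfrog")

EMERGENCE_COLUMNS = ["pond_id", "year", "emergence_doy", "emergence_hour"]


@dataclass
class RunConfig:
    start_year: int
    end_year: int
    ponds: pd.DataFrame
    traits: FrogTraits = field(default_factory=FrogTraits)
    micro_params: MicroParams = field(default_factory=MicroParams)
    burn_in_years: int = 1
    elevation_override: float | None = None

    def validate(self) -> None:
        n_years = self.end_year - self.start_year + 1
        if n_years <= self.burn_in_years:
            raise ValueError("need at least one non-burn-in year")
        if self.burn_in_years < 0:
            raise ValueError("burn_in_years must be >= 0")


def run_simulation(config: RunConfig, weather: pd.DataFrame) -> pd.DataFrame:
    """Simulate emergence for every pond and non-burn-in year.

    Returns a tidy frame (pond_id, year, emergence_doy, emergence_hour);
    missing emergence is NaN.  When ``elevation_override`` is set every
    pond is simulated at that elevation (the validation configuration,
    which removes elevation-driven bias across a low-relief network).
    """
    config.validate()
    years = np.arange(config.start_year, config.end_year + 1)
    span = weather[(weather["year"] >= config.start_year)
                   & (weather["year"] <= config.end_year)]
    missing_years = set(years.tolist()) - set(span["year"].unique().tolist())
    if missing_years:
        raise ValueError(f"weather does not cover years {sorted(missing_years)}")

    rows = []
    for pond in config.ponds.itertuples(index=False):
        if config.elevation_override is not None:
            pond = pond._replace(elevation=config.elevation_override)
        micro = run_microclimate(pond, span, config.micro_params)
        for year in years[config.burn_in_years:]:
            rec = simulate_frog_year(micro.year_slice(int(year)), config.traits)
            rows.append((rec.pond_id, rec.year,
                         rec.emergence_doy if rec.emerged else np.nan,
                         rec.emergence_hour if rec.emerged else np.nan))
    return pd.DataFrame(rows, columns=EMERGENCE_COLUMNS)


def climatological_normals_weather(weather: pd.DataFrame,
                                   n_replicates: int,
                                   start_year: int | None = None) -> pd.DataFrame:
    """Average daily forcing across years at fixed DOY, then concatenate
    ``n_replicates`` identical copies of the normal year."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    lengths = weather.groupby("year")["doy"].count().unique()
    if len(lengths) != 1 or lengths[0] != DAYS_PER_YEAR:
        raise ValueError("all input years must be complete 365-day years")
    normals = (weather.groupby("doy")[["tmin", "tmax", "precip"]]
               .mean().reset_index())
    if start_year is None:
        start_year = int(weather["year"].min())
    site = weather["site_id"].iloc[0] if "site_id" in weather else "NORMALS"
    reps = []
    for r in range(n_replicates):
        block = normals.copy()
        block.insert(0, "site_id", site)
        block.insert(1, "year", start_year + r)
        reps.append(block)
    return pd.concat(reps, ignore_index=True)


def climatological_null(weather: pd.DataFrame, site, params: MicroParams,
                        n_replicates: int,
                        start_year: int | None = None) -> MicroclimateSeries:
    """Climatological-normals microclimate for one pond.

    Hourly air temperature equals the per-(DOY, hour) multi-year mean
    (the diurnal downscaling is linear in tmin/tmax, so averaging daily
    extremes first is exact); snowpack and soil state are *recomputed*
    on the averaged forcing rather than averaged directly, which keeps
    the snow physics self-consistent.  The result is ``n_replicates``
    identical concatenated years.
    """
    normals = climatological_normals_weather(weather, n_replicates, start_year)
    return run_microclimate(site, normals, params)


def simulate_null(config: RunConfig, weather: pd.DataFrame) -> pd.DataFrame:
    """Emergence predictions driven by climatological normals.

    The normal year is replicated across the run span; after burn-in the
    prediction is identical every year (zero interannual variance by
    construction)."""
    config.validate()
    years = np.arange(config.start_year, config.end_year + 1)
    rows = []
    for pond in config.ponds.itertuples(index=False):
        if config.elevation_override is not None:
            pond = pond._replace(elevation=config.elevation_override)
        micro = climatological_null(weather, pond, config.micro_params,
                                    n_replicates=len(years),
                                    start_year=config.start_year)
        for year in years[config.burn_in_years:]:
            rec = simulate_frog_year(micro.year_slice(int(year)), config.traits)
            rows.append((rec.pond_id, rec.year,
                         rec.emergence_doy if rec.emerged else np.nan,
                         rec.emergence_hour if rec.emerged else np.nan))
    return pd.DataFrame(rows, columns=EMERGENCE_COLUMNS)


# ---------------------------------------------------------------------------
# observation handling and validation


def weighted_observation_doy(surveys: pd.DataFrame) -> float:
    """Egg-mass-weighted mean survey DOY for one pond-year.

    Falls back to the unweighted mean of survey dates when every count
    is zero (a survey visit that found no new masses carries no weight).
    """
    if len(surveys) == 0:
        raise ValueError("need at least one survey")
    doy = surveys["survey_doy"].to_numpy(float)
    counts = surveys["new_egg_masses"].to_numpy(float)
    if np.any(counts < 0):
        raise ValueError("new_egg_masses must be nonnegative")
    total = counts.sum()
    if total == 0:
        return float(doy.mean())
    return float((doy * counts).sum() / total)


def observed_phenology(observations: pd.DataFrame) -> pd.DataFrame:
    """Collapse surveys to one weighted oviposition DOY per pond-year."""
    rows = [
        (pond, int(year), weighted_observation_doy(grp), grp["new_egg_masses"].sum())
        for (pond, year), grp in observations.groupby(["pond_id", "year"])
    ]
    return pd.DataFrame(rows, columns=["pond_id", "year", "observed_doy",
                                       "total_egg_masses"])


@dataclass
class ValidationReport:
    rmse: float
    mae: float
    n_pairs: int
    errors: pd.DataFrame          # pond_id, year, predicted, observed, error
    per_pond: pd.DataFrame        # pond_id, rmse, mae, n
    pred_moving_sd: pd.Series
    obs_moving_sd: pd.Series


def moving_window_sd(annual_series: pd.Series, window: int = 5) -> pd.Series:
    """Sample SD over trailing windows of consecutive years.

    ``annual_series`` is indexed by year (consecutive); incomplete
    windows are omitted, so a series shorter than the window yields an
    empty result.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    s = annual_series.sort_index()
    years = np.asarray(s.index, dtype=int)
    if len(years) > 1 and not np.all(np.diff(years) == 1):
        raise ValueError("annual series must be on consecutive years")
    if len(s) < window:
        return pd.Series(dtype=float)
    return s.rolling(window).std(ddof=1).dropna()


def validate(predictions: pd.DataFrame, observations: pd.DataFrame,
             window: int = 5) -> ValidationReport:
    """Compare predicted emergence with (weighted) observed oviposition.

    Inner join on (pond_id, year); unmatched records are dropped and
    counted in the log, never imputed.  Error is predicted − observed.
    """
    obs = (observations if "observed_doy" in observations.columns
           else observed_phenology(observations))
    pred = predictions.dropna(subset=["emergence_doy"])
    merged = pred.merge(obs, on=["pond_id", "year"], how="inner")
    n_dropped = (len(pred) - len(merged)) + (len(obs) - len(merged))
    if n_dropped:
        logger.info("validate: dropped %d unmatched pond-year records", n_dropped)
    if len(merged) == 0:
        raise ValueError("no matched prediction/observation pairs")

    err = merged["emergence_doy"].to_numpy(float) - merged["observed_doy"].to_numpy(float)
    merged = merged.assign(error=err)
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))

    per_pond = (merged.groupby("pond_id")["error"]
                .agg(rmse=lambda e: float(np.sqrt(np.mean(e ** 2))),
                     mae=lambda e: float(np.mean(np.abs(e))),
                     n="count")
                .reset_index())

    pred_annual = merged.groupby("year")["emergence_doy"].mean()
    obs_annual = merged.groupby("year")["observed_doy"].mean()

    def _sd(series):
        try:
            return moving_window_sd(series, window)
        except ValueError:
            return pd.Series(dtype=float)

    return ValidationReport(
        rmse=rmse, mae=mae, n_pairs=len(merged),
        errors=merged[["pond_id", "year", "emergence_doy", "observed_doy", "error"]],
        per_pond=per_pond,
        pred_moving_sd=_sd(pred_annual),
        obs_moving_sd=_sd(obs_annual),
    )


# ---------------------------------------------------------------------------
# error regression, drought filter, trend


def _minmax_scale(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    return (x - lo) / (hi - lo)


def error_regression(errors: np.ndarray, covariates: pd.DataFrame,
                     n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Gaussian OLS of prediction error on min-max-scaled covariates.

    Covariates are scaled to [0, 1] so coefficients are comparable;
    constant covariates are dropped with a warning (their scaling is
    undefined).  95% CIs are percentile bootstrap over case resampling.
    Returns a frame (term, estimate, ci_low, ci_high).
    """
    y = np.asarray(errors, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 rows for the error regression")
    if not np.all(np.isfinite(covariates.to_numpy(float))):
        raise ValueError("covariates must be finite")

    kept, cols = [], []
    for name in covariates.columns:
        x = covariates[name].to_numpy(float)
        if x.max() == x.min():
            warnings.warn(f"dropping constant covariate {name!r} "
                          "(min-max scaling undefined)", stacklevel=2)
            continue
        kept.append(_minmax_scale(x))
        cols.append(name)
    X = np.column_stack([np.ones(len(y))] + kept)
    terms = ["intercept"] + cols

    fit = sm.OLS(y, X).fit()
    est = fit.params

    rng = np.random.default_rng(seed)
    n, p = X.shape
    idx = rng.integers(0, n, size=(n_boot, n))
    Xb = X[idx]                                   # (B, n, p)
    yb = y[idx]                                   # (B, n)
    XtX = np.einsum("bij,bik->bjk", Xb, Xb)
    Xty = np.einsum("bij,bi->bj", Xb, yb)
    betas = np.linalg.solve(XtX, Xty[..., None])[..., 0]   # (B, p)
    lo, hi = np.percentile(betas, [2.5, 97.5], axis=0)

    return pd.DataFrame({"term": terms, "estimate": est,
                         "ci_low": lo, "ci_high": hi})


def drought_filter(records: pd.DataFrame, pdsi_by_year: dict,
                   threshold: float = -2.5) -> pd.DataFrame:
    """Drop records from severe-drought years (PDSI below the threshold).

    PDSI is supplied per year by the user (it is not computed here);
    every record year must be present in the mapping.
    """
    years = set(int(y) for y in records["year"].unique())
    missing = sorted(y for y in years if y not in pdsi_by_year)
    if missing:
        raise KeyError(f"PDSI missing for years {missing}")
    keep = records["year"].map(lambda y: pdsi_by_year[int(y)] >= threshold)
    return records[keep].reset_index(drop=True)


@dataclass
class TrendResult:
    slope_per_year: float
    slope_per_decade: float
    ci_low_per_decade: float
    ci_high_per_decade: float
    n_pond_years: int


def decadal_trend(observations: pd.DataFrame, n_boot: int = 1000,
                  seed: int = 0, doy_column: str = "observed_doy") -> TrendResult:
    """Pooled phenology trend with pond fixed intercepts.

    The slope of oviposition DOY on year, with a separate intercept per
    pond, is computed by within-pond demeaning (exactly the fixed-
    intercept OLS slope).  The 95% CI is a case bootstrap over
    pond-years.  Reported per year and per decade.
    """
    df = observations.dropna(subset=[doy_column])
    if df["year"].nunique() < 2:
        raise ValueError("need at least 2 distinct years for a trend")

    pond = df["pond_id"].to_numpy()
    year = df["year"].to_numpy(float)
    doy = df[doy_column].to_numpy(float)

    def _slope(pond, year, doy):
        d = pd.DataFrame({"pond": pond, "year": year, "doy": doy})
        g = d.groupby("pond")
        xt = d["year"] - g["year"].transform("mean")
        yt = d["doy"] - g["doy"].transform("mean")
        sxx = float((xt * xt).sum())
        if sxx == 0.0:
            return np.nan
        return float((xt * yt).sum() / sxx)

    slope = _slope(pond, year, doy)
    rng = np.random.default_rng(seed)
    n = len(doy)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        boots[b] = _slope(pond[idx], year[idx], doy[idx])
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])

    return TrendResult(slope_per_year=slope, slope_per_decade=10.0 * slope,
                       ci_low_per_decade=10.0 * lo, ci_high_per_decade=10.0 * hi,
                       n_pond_years=n)
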