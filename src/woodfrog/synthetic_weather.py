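"""Synthetic daily meteorology, pond networks, and oviposition surveys.

The generator emulates the statistical structure of daily gridded
meteorology over a southern New England forest: a sinusoidal seasonal
cycle in daily mean temperature, AR(1) synoptic anomalies, an optional
linear warming trend, and Bernoulli-gamma daily precipitation.  All
phenology downstream operates on a 365-day calendar (leap days are never
generated), because emergence dates are expressed as day-of-year.

A single weather series is shared by every pond in a network; ponds
differ only in their site descriptors (canopy cover, elevation, area).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365
TROPICAL_YEAR = 365.25  # period of the seasonal cycle

WEATHER_COLUMNS = ["site_id", "year", "doy", "tmin", "tmax", "precip"]
POND_COLUMNS = [
    "pond_id", "canopy_cover", "elevation", "latitude", "area", "leaf_area_index",
]
OBSERVATION_COLUMNS = ["pond_id", "year", "survey_doy", "new_egg_masses"]


@dataclass
class WeatherConfig:
    """Parameters of the daily weather generator.

    Defaults describe a northeastern-Connecticut-like climate: annual
    mean near 9 °C, winter minimum in mid-January, ~1000 mm yr⁻¹ of
    precipitation, and synoptic temperature anomalies with a few days of
    persistence.
    """

    mean_annual_temp: float = 9.0      # °C
    seasonal_amplitude: float = 13.0   # °C, half peak-to-trough
    coldest_doy: int = 15              # DOY of the seasonal minimum
    diurnal_range: float = 9.0         # °C, annual-mean tmax - tmin
    diurnal_range_seasonal: float = 3.0  # °C, seasonal cycle of the diurnal
                                         # range (largest in summer; 0 = constant)
    ar1_coeff: float = 0.7             # lag-1 autocorrelation of anomalies
    anomaly_sd: float = 3.0            # °C, marginal SD of daily anomalies
    warming_trend: float = 0.0         # °C per year
    precip_prob: float = 0.35          # wet-day probability
    precip_shape: float = 0.7          # gamma shape of wet-day totals
    precip_scale: float = 12.0         # gamma scale (mm)
    seed: int = 0

    def validate(self) -> None:
        numeric = {k: v for k, v in asdict(self).items()}
        for name, value in numeric.items():
            if not math.isfinite(float(value)):
                raise ValueError(f"WeatherConfig.{name} must be finite, got {value!r}")
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be >= 0")
        if not 0.0 <= self.precip_prob <= 1.0:
            raise ValueError("precip_prob must be in [0, 1]")
        if not 0.0 <= self.ar1_coeff < 1.0:
            raise ValueError("ar1_coeff must be in [0, 1)")
        if self.diurnal_range < 0:
            raise ValueError("diurnal_range must be >= 0")
        if self.diurnal_range_seasonal < 0:
            raise ValueError("diurnal_range_seasonal must be >= 0")
        if self.precip_shape <= 0 or self.precip_scale < 0:
            raise ValueError("precip gamma parameters must be positive")
        if self.anomaly_sd < 0:
            raise ValueError("anomaly_sd must be >= 0")


def seasonal_mean_temperature(config: WeatherConfig, year_index: np.ndarray,
                              doy: np.ndarray) -> np.ndarray:
    """Deterministic part of the daily mean temperature (no anomalies)."""
    phase = 2.0 * np.pi * (doy - config.coldest_doy) / TROPICAL_YEAR
    return (config.mean_annual_temp
            + config.warming_trend * year_index
            - config.seasonal_amplitude * np.cos(phase))


def generate_daily_weather(config: WeatherConfig, n_years: int,
                           start_year: int = 2000,
                           site_id: str = "YMF") -> pd.DataFrame:
    """Generate a tidy daily weather table for ``n_years`` 365-day years.

    The daily mean follows the seasonal sinusoid plus an AR(1) anomaly
    with marginal SD ``anomaly_sd``; tmin/tmax sit symmetrically below
    and above the mean, half the (seasonally modulated) diurnal range
    apart.  Precipitation is Bernoulli(precip_prob) × Gamma(shape,
    scale), in mm water equivalent.  Bit-reproducible for a given seed.
    """
    config.validate()
    if n_years < 2:
        raise ValueError("n_years must be >= 2 (one burn-in year plus analysis years)")

    rng = np.random.default_rng(config.seed)
    n_days = n_years * DAYS_PER_YEAR
    year_index = np.repeat(np.arange(n_years), DAYS_PER_YEAR)
    doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), n_years)

    mean = seasonal_mean_temperature(config, year_index, doy)

    # AR(1) anomalies with the configured *marginal* SD
    phi = config.ar1_coeff
    innov_sd = config.anomaly_sd * math.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, 1.0, n_days)
    anomalies = np.empty(n_days)
    prev = rng.normal(0.0, 1.0) * config.anomaly_sd
    for i in range(n_days):
        prev = phi * prev + innov_sd * eps[i]
        anomalies[i] = prev
    mean = mean + anomalies

    # diurnal range has its own seasonal cycle (clear warm-season days have
    # stronger daytime heating); clipped at 0 so tmax >= tmin always holds
    phase = 2.0 * np.pi * (doy - config.coldest_doy) / TROPICAL_YEAR
    daily_range = np.maximum(
        config.diurnal_range - config.diurnal_range_seasonal * np.cos(phase), 0.0)
    half = daily_range / 2.0
    tmin = mean - half
    tmax = mean + half

    wet = rng.random(n_days) < config.precip_prob
    totals = rng.gamma(config.precip_shape, config.precip_scale, n_days)
    precip = np.where(wet, totals, 0.0)

    return pd.DataFrame({
        "site_id": site_id,
        "year": start_year + year_index,
        "doy": doy,
        "tmin": tmin,
        "tmax": tmax,
        "precip": precip,
    })


def generate_pond_network(n_ponds: int,
                          canopy_range: tuple[float, float] = (0.0, 0.9),
                          elevation_mean: float = 236.0,
                          seed: int = 0) -> pd.DataFrame:
    """Generate a network of ponds spanning a canopy-cover gradient.

    Canopy covers are evenly spaced across ``canopy_range`` (endpoints
    included whenever ``n_ponds >= 2``); elevations are scattered around
    ``elevation_mean``; leaf area index scales with canopy cover.
    """
    if n_ponds < 1:
        raise ValueError("n_ponds must be >= 1")
    lo, hi = canopy_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("canopy_range must satisfy 0 <= lo <= hi <= 1")

    rng = np.random.default_rng(seed)
    if n_ponds == 1:
        canopy = np.array([(lo + hi) / 2.0])
    else:
        canopy = np.linspace(lo, hi, n_ponds)

    width = max(n_ponds - 1, 1)
    ndig = len(str(width + 1))
    pond_ids = [f"pond_{i + 1:0{max(ndig, 2)}d}" for i in range(n_ponds)]
    elevation = rng.normal(elevation_mean, 18.0, n_ponds)
    latitude = rng.normal(41.95, 0.02, n_ponds)
    area = np.exp(rng.normal(math.log(900.0), 0.6, n_ponds))  # m², lognormal
    lai = np.clip(5.5 * canopy + rng.normal(0.0, 0.15, n_ponds), 0.0, None)

    return pd.DataFrame({
        "pond_id": pond_ids,
        "canopy_cover": canopy,
        "elevation": elevation,
        "latitude": latitude,
        "area": area,
        "leaf_area_index": lai,
    })


def generate_observations(emergence: pd.DataFrame,
                          lag_mean: float = 7.0,
                          lag_sd: float = 3.0,
                          surveys_per_year: int = 3,
                          seed: int = 0,
                          survey_spacing_days: int = 7) -> pd.DataFrame:
    """Synthesize oviposition surveys from predicted emergence dates.

    Oviposition follows emergence by a stochastic lag: the first survey
    recording new egg masses falls at ``emergence_doy +
    max(0, round(N(lag_mean, lag_sd)))``.  Subsequent surveys follow on a
    weekly cadence (``survey_spacing_days``) with declining new-mass
    counts, mirroring field protocols of at-least-weekly pond searches.
    Pond-years with missing emergence produce no surveys.
    """
    if lag_mean < 0:
        raise ValueError("lag_mean must be >= 0")
    if lag_sd < 0:
        raise ValueError("lag_sd must be >= 0")
    if surveys_per_year < 1:
        raise ValueError("surveys_per_year must be >= 1")
    if survey_spacing_days < 1:
        raise ValueError("survey_spacing_days must be >= 1")

    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    for rec in emergence.itertuples(index=False):
        doy = getattr(rec, "emergence_doy")
        if doy is None or (isinstance(doy, float) and math.isnan(doy)):
            continue
        lag = max(0, int(round(rng.normal(lag_mean, lag_sd))))
        first = int(doy) + lag
        count = 1 + int(rng.poisson(25))
        for k in range(surveys_per_year):
            survey_doy = first + k * survey_spacing_days
            if survey_doy > 366:
                break
            rows.append((rec.pond_id, int(rec.year), survey_doy, count))
            count = int(math.floor(count * rng.uniform(0.2, 0.6)))
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


# ---------------------------------------------------------------------------
# tidy-CSV writers/readers (fixed column contracts)

def write_weather_csv(weather: pd.DataFrame, path) -> None:
    weather[WEATHER_COLUMNS].to_csv(path, index=False)


def read_weather_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(WEATHER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"weather CSV missing columns: {sorted(missing)}")
    return df[WEATHER_COLUMNS]


def write_ponds_csv(ponds: pd.DataFrame, path) -> None:
    ponds[POND_COLUMNS].to_csv(path, index=False)


def read_ponds_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(POND_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pond CSV missing columns: {sorted(missing)}")
    return df[POND_COLUMNS]


def write_observations_csv(obs: pd.DataFrame, path) -> None:
    obs[OBSERVATION_COLUMNS].to_csv(path, index=False)


def read_observations_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(OBSERVATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"observation CSV missing columns: {sorted(missing)}")
    return df[OBSERVATION_COLUMNS]
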