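import numpy as np
import pytest

from woodfrog.microclimate import MicroclimateSeries
from woodfrog.synthetic_weather import DAYS_PER_YEAR, WeatherConfig, \
    generate_daily_weather, generate_pond_network

H = DAYS_PER_YEAR * 24


def micro_from_arrays(air, soil_shallow, snow_depth_daily, year=2001,
                      pond_id="pond_test", snow_density=250.0):
    """Assemble a one-year MicroclimateSeries from raw hourly air/soil
    series and a daily snow-depth series (constant within each day)."""
    air = np.asarray(air, dtype=float)
    soil = np.asarray(soil_shallow, dtype=float)
    assert air.shape == (H,) and soil.shape == (H,)
    depth_h = np.repeat(np.asarray(snow_depth_daily, dtype=float), 24)
    assert depth_h.shape == (H,)
    soil_temp = np.column_stack([soil, soil])  # nodes at 0 and 2.5 cm
    return MicroclimateSeries(
        pond_id=pond_id,
        year=np.full(H, year, dtype=int),
        doy=np.repeat(np.arange(1, DAYS_PER_YEAR + 1), 24),
        hour=np.tile(np.arange(24), DAYS_PER_YEAR),
        air_temp=air,
        soil_temp=soil_temp,
        swe=depth_h * snow_density / 100.0,
        snow_depth=depth_h,
        depths_cm=(0.0, 2.5),
    )


def random_pond_year(rng, year=2001):
    """A randomized but seasonally-plausible synthetic pond-year."""
    doy = np.repeat(np.arange(1, DAYS_PER_YEAR + 1), 24)
    hour = np.tile(np.arange(24), DAYS_PER_YEAR)
    seasonal = 9.0 - 13.0 * np.cos(2 * np.pi * (doy - 15) / 365.25)
    diurnal = 4.5 * np.sin(2 * np.pi * (hour - 9) / 24.0)
    air = seasonal + diurnal + rng.normal(0, 3.0, H)
    soil = seasonal + 0.5 * diurnal + rng.normal(0, 1.0, H)
    # random snow spells ending somewhere in spring
    melt_doy = int(rng.integers(40, 130))
    depth_daily = np.where(np.arange(1, DAYS_PER_YEAR + 1) <= melt_doy,
                           rng.uniform(0, 30), 0.0)
    # sprinkle a few late flurries
    for _ in range(int(rng.integers(0, 4))):
        d = int(rng.integers(melt_doy, min(melt_doy + 40, 364)))
        depth_daily[d] = rng.uniform(0.5, 5.0)
    return micro_from_arrays(air, soil, depth_daily, year=year)


def oracle_emergence(micro, traits):
    """Literal hour-by-hour scan of the emergence rules.

    Independent of the vectorized implementation: trailing windows are
    checked with explicit loops, the warm-hour counter is maintained
    hour by hour, and the body temperature is the soil temperature at
    the nearest node to the burrow (equilibrium assumption).
    """
    depths = list(micro.depths_cm)
    node = min(range(len(depths)), key=lambda j: abs(depths[j] - traits.burrow_depth))
    body = micro.soil_temp[:, node]
    daily_min = [min(body[d * 24:(d + 1) * 24]) for d in range(DAYS_PER_YEAR)]
    daily_snowfree = [all(micro.snow_depth[d * 24 + h] == 0 for h in range(24))
                      for d in range(DAYS_PER_YEAR)]
    warm_count = 0
    for i in range(DAYS_PER_YEAR * 24):
        d = i // 24
        doy = d + 1
        if micro.air_temp[i] >= traits.emergence_air_temp:
            warm_count += 1
        else:
            warm_count = 0
        if doy <= traits.earliest_doy:
            continue
        k = traits.thaw_consecutive_days
        m = traits.snowfree_consecutive_days
        if d + 1 < k or d + 1 < m:
            continue
        if not all(daily_min[d - j] > traits.thaw_threshold_temp for j in range(k)):
            continue
        if not all(daily_snowfree[d - j] for j in range(m)):
            continue
        if warm_count >= traits.favorable_consecutive_hours \
                and micro.air_temp[i] <= traits.ct_max:
            return float(doy), float(i % 24)
    return None, None


@pytest.fixture(scope="session")
def small_weather():
    return generate_daily_weather(WeatherConfig(seed=7), n_years=4, start_year=2000)


@pytest.fixture(scope="session")
def small_ponds():
    return generate_pond_network(4, (0.0, 0.9), 236.0, seed=3)
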