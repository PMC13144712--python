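#!/usr/bin/env python
"""Couple microclimate and frog models over the synthetic pond network.

Reads results/synthetic/{weather,ponds}.csv, simulates hourly
microclimate and rule-based emergence for every pond-year (first year
discarded as burn-in), then synthesizes oviposition surveys from the
predicted emergence dates plus a stochastic lag.  Writes emergence.csv
and observations.csv.
"""

from pathlib import Path

import numpy as np

from woodfrog.pipeline import RunConfig, run_simulation
from woodfrog.synthetic_weather import (
    generate_observations, read_ponds_csv, read_weather_csv,
    write_observations_csv,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 20260926

if __name__ == "__main__":
    weather = read_weather_csv(OUT / "weather.csv")
    ponds = read_ponds_csv(OUT / "ponds.csv")
    years = np.sort(weather["year"].unique())
    cfg = RunConfig(int(years[0]), int(years[-1]), ponds,
                    elevation_override=236.0)
    emergence = run_simulation(cfg, weather)
    emergence.to_csv(OUT / "emergence.csv", index=False)

    doys = emergence["emergence_doy"].dropna()
    print(f"{len(emergence)} pond-years simulated; "
          f"{emergence['emergence_doy'].isna().sum()} without emergence")
    print(f"emergence DOY: median {doys.median():.0f}, "
          f"range {doys.min():.0f}-{doys.max():.0f}")

    obs = generate_observations(emergence, lag_mean=7.0, lag_sd=3.0,
                                surveys_per_year=3, seed=SEED + 2)
    write_observations_csv(obs, OUT / "observations.csv")
    print(f"wrote {len(obs)} surveys across "
          f"{obs.groupby(['pond_id', 'year']).ngroups} pond-years")
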