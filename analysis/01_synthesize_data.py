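#!/usr/bin/env python
"""Generate the synthetic study system: forcing, pond network, config.

Writes a 26-year daily weather series (one shared series for the whole
network, as for a single ~4-km meteorology grid cell; the first year is
burn-in, leaving a 25-year analysis record), a 64-pond network spanning
canopy cover 0-0.9 around 236 m ASL, and the configuration used by the
later steps, under results/synthetic/.
"""

from pathlib import Path

from woodfrog.config import save_config
from woodfrog.frog_model import FrogTraits
from woodfrog.microclimate import MicroParams
from woodfrog.synthetic_weather import (
    WeatherConfig, generate_daily_weather, generate_pond_network,
    write_ponds_csv, write_weather_csv,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 20260926
N_YEARS = 26
START_YEAR = 1999

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    wcfg = WeatherConfig(seed=SEED)
    weather = generate_daily_weather(wcfg, n_years=N_YEARS, start_year=START_YEAR)
    ponds = generate_pond_network(64, (0.0, 0.9), 236.0, seed=SEED + 1)

    write_weather_csv(weather, OUT / "weather.csv")
    write_ponds_csv(ponds, OUT / "ponds.csv")
    save_config(OUT / "config.yaml", weather=wcfg, traits=FrogTraits(),
                micro=MicroParams(),
                network={"n_ponds": 64, "canopy_range": [0.0, 0.9],
                         "elevation_mean": 236.0, "seed": SEED + 1},
                run={"start_year": START_YEAR,
                     "end_year": START_YEAR + N_YEARS - 1,
                     "burn_in_years": 1})

    mean_t = 0.5 * (weather["tmin"] + weather["tmax"])
    print(f"wrote {len(weather)} weather days "
          f"(annual mean {mean_t.mean():.2f} °C, "
          f"total precip {weather['precip'].sum() / N_YEARS:.0f} mm/yr)")
    print(f"wrote {len(ponds)} ponds: canopy "
          f"{ponds['canopy_cover'].min():.2f}-{ponds['canopy_cover'].max():.2f}, "
          f"elevation {ponds['elevation'].mean():.0f} m (mean)")
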