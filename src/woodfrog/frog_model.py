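"""Rule-based wood frog emergence from hourly microclimate.

A single dormant frog sits at a fixed burrow depth through winter.  Its
body temperature tracks the soil temperature at the nearest depth node
(instantaneous equilibrium by default — a small buried ectotherm — or
first-order relaxation with an optional mass-scaled time constant).  The
frog is permitted to emerge at the first hour of the year at which all
of the following hold:

1. the calendar has advanced beyond an earliest day-of-year (default 65,
   earlier than any recorded activity in the study region);
2. daily minimum body temperature has been above the thaw-inflection
   threshold (default −0.16 °C, where frog tissue begins to thaw) for a
   trailing window of consecutive days (default 3, current day
   included);
3. the pond microsite has been snow-free for a trailing window of
   consecutive days (default 5, current day included);
4. aboveground conditions are favorable: air temperature has been at or
   above the frog's chosen emergence temperature for a required number
   of consecutive hours (default 1) and does not exceed the critical
   thermal maximum.

Windows are evaluated on calendar days; within a qualifying day the
first favorable hour is the emergence hour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .synthetic_weather import DAYS_PER_YEAR

MASS_REFERENCE_G = 11.6  # midpoint of the field mass range 7.6–15.6 g


@dataclass
class FrogTraits:
    mass: float = 11.6                    # g
    burrow_depth: float = 2.5             # cm below surface
    thaw_threshold_temp: float = -0.16    # °C; thaw-inflection body temperature
    thaw_consecutive_days: int = 3
    snowfree_consecutive_days: int = 5
    earliest_doy: int = 65
    emergence_air_temp: float = 5.0       # °C; chosen temperature of emergence
    favorable_consecutive_hours: int = 1
    ct_min: float = -5.0                  # °C; critical thermal minimum
    ct_max: float = 35.0                  # °C; critical thermal maximum
    thermal_time_constant: float = 0.0    # h; 0 = instantaneous equilibrium

    def validate(self) -> None:
        if self.ct_min >= self.ct_max:
            raise ValueError("ct_min must be < ct_max")
        for name in ("thaw_consecutive_days", "snowfree_consecutive_days",
                     "favorable_consecutive_hours"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.mass <= 0:
            raise ValueError("mass must be > 0")
        if self.burrow_depth < 0:
            raise ValueError("burrow_depth must be >= 0")
        if self.thermal_time_constant < 0:
            raise ValueError("thermal_time_constant must be >= 0")


@dataclass
class EmergenceRecord:
    pond_id: str
    year: int
    emergence_doy: float | None   # None/NaN when the frog never emerges
    emergence_hour: float | None

    @property
    def emerged(self) -> bool:
        d = self.emergence_doy
        return d is not None and not (isinstance(d, float) and math.isnan(d))


def burrow_node_index(depths_cm, burrow_depth: float) -> int:
    """Nearest soil node to the burrow depth (ties go to the shallower node)."""
    depths = np.asarray(depths_cm, dtype=float)
    if burrow_depth > depths[-1]:
        raise ValueError(
            f"burrow depth {burrow_depth} cm below deepest node {depths[-1]} cm")
    return int(np.argmin(np.abs(depths - burrow_depth)))


def thermal_time_constant_hours(traits: FrogTraits) -> float:
    """Mass-scaled time constant: tau * (mass / reference)^(1/3)."""
    if traits.thermal_time_constant == 0:
        return 0.0
    return traits.thermal_time_constant * (traits.mass / MASS_REFERENCE_G) ** (1.0 / 3.0)


def body_temperature(soil_temp_at_node: float, traits: FrogTraits,
                     previous_body_temp: float, dt_hours: float = 1.0) -> float:
    """Body temperature after one timestep.

    Equilibrium with the burrow-node soil when the time constant is 0;
    otherwise exact first-order relaxation over ``dt_hours``.
    """
    tau = thermal_time_constant_hours(traits)
    if tau == 0.0:
        return float(soil_temp_at_node)
    a = math.exp(-dt_hours / tau)
    return float(soil_temp_at_node + (previous_body_temp - soil_temp_at_node) * a)


def body_temperature_series(soil_series: np.ndarray, traits: FrogTraits,
                            initial: float | None = None) -> np.ndarray:
    """Hourly body temperatures along a soil-temperature series."""
    soil_series = np.asarray(soil_series, dtype=float)
    tau = thermal_time_constant_hours(traits)
    if tau == 0.0:
        return soil_series.copy()
    a = math.exp(-1.0 / tau)
    b0 = soil_series[0] if initial is None else float(initial)
    # b[t] = (1-a) * T[t] + a * b[t-1]  (exact exponential update)
    out, _ = lfilter([1.0 - a], [1.0, -a], soil_series, zi=[a * b0])
    return out


def _trailing_all(flags: np.ndarray, window: int) -> np.ndarray:
    """True where the trailing ``window`` entries (current included) are
    all True; False where history is shorter than the window."""
    flags = np.asarray(flags, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(flags) < window:
        return np.zeros(len(flags), dtype=bool)
    csum = np.convolve(flags, np.ones(window), mode="valid")
    out = np.zeros(len(flags), dtype=bool)
    out[window - 1:] = csum >= window - 1e-9
    return out


def check_gating_conditions(body_temp_history: np.ndarray,
                            snow_history: np.ndarray,
                            doy: int, traits: FrogTraits) -> bool:
    """Evaluate the three daily emergence gates at the current day.

    ``body_temp_history`` holds daily *minimum* body temperatures and
    ``snow_history`` daily snow depths, both ending at (and including)
    the current day.  Histories shorter than the required windows return
    False (insufficient evidence), not an error.
    """
    if doy <= traits.earliest_doy:
        return False
    k = int(traits.thaw_consecutive_days)
    m = int(traits.snowfree_consecutive_days)
    body = np.asarray(body_temp_history, dtype=float)
    snow = np.asarray(snow_history, dtype=float)
    if len(body) < k or len(snow) < m:
        return False
    thaw_ok = bool(np.all(body[-k:] > traits.thaw_threshold_temp))
    snow_ok = bool(np.all(snow[-m:] == 0.0))
    return thaw_ok and snow_ok


def favorable_for_activity(air_temp: float, traits: FrogTraits,
                           hours_above_count: int) -> bool:
    """Aboveground conditions permit activity at this hour.

    ``hours_above_count`` is the caller-maintained running count of
    consecutive hours (current included) with air temperature at or
    above the chosen emergence temperature.
    """
    return (hours_above_count >= int(traits.favorable_consecutive_hours)
            and air_temp <= traits.ct_max)


def _consecutive_warm_hours(air: np.ndarray, threshold: float) -> np.ndarray:
    """Running count of consecutive hours with air >= threshold."""
    warm = air >= threshold
    idx = np.arange(len(air))
    last_cold = np.maximum.accumulate(np.where(~warm, idx, -1))
    return np.where(warm, idx - last_cold, 0)


def simulate_frog_year(micro, traits: FrogTraits | None = None) -> EmergenceRecord:
    """Scan one pond-year of hourly microclimate for the emergence hour.

    ``micro`` is a MicroclimateSeries restricted to a single 365-day
    year.  Returns the first (doy, hour) at which the daily gates and
    the hourly favorability rule are simultaneously satisfied, or a
    record with missing emergence if no such hour exists.
    """
    traits = traits or FrogTraits()
    traits.validate()
    years = np.unique(micro.year)
    if len(years) != 1:
        raise ValueError("simulate_frog_year expects exactly one year of data")
    n_hours = len(micro.hour)
    if n_hours != DAYS_PER_YEAR * 24:
        raise ValueError(
            f"incomplete year: expected {DAYS_PER_YEAR * 24} hourly records, got {n_hours}")

    node = burrow_node_index(micro.depths_cm, traits.burrow_depth)
    body = body_temperature_series(micro.soil_temp[:, node], traits)

    daily_min_body = body.reshape(DAYS_PER_YEAR, 24).min(axis=1)
    daily_snowfree = (micro.snow_depth.reshape(DAYS_PER_YEAR, 24) == 0.0).all(axis=1)

    thaw_ok = _trailing_all(daily_min_body > traits.thaw_threshold_temp,
                            int(traits.thaw_consecutive_days))
    snow_ok = _trailing_all(daily_snowfree, int(traits.snowfree_consecutive_days))
    doys = np.arange(1, DAYS_PER_YEAR + 1)
    gate_day = (doys > traits.earliest_doy) & thaw_ok & snow_ok

    counts = _consecutive_warm_hours(micro.air_temp, traits.emergence_air_temp)
    favorable = ((counts >= int(traits.favorable_consecutive_hours))
                 & (micro.air_temp <= traits.ct_max))

    ok = favorable & np.repeat(gate_day, 24)
    hits = np.flatnonzero(ok)
    year = int(years[0])
    if hits.size == 0:
        return EmergenceRecord(micro.pond_id, year, None, None)
    h = int(hits[0])
    return EmergenceRecord(micro.pond_id, year,
                           emergence_doy=float(micro.doy[h]),
                           emergence_hour=float(micro.hour[h]))
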