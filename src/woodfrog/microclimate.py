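"""Hourly below-canopy microclimate from daily forcing and site descriptors.

This is a deliberately compact microclimate model for a forested pond
margin.  From daily tmin/tmax/precipitation it produces, per pond:

* hourly below-canopy air temperature at frog height, via a piecewise
  sinusoid between the daily extremes (minimum at 05:00, maximum at
  15:00 local) with the diurnal departure from the daily mean damped by
  canopy cover;
* a daily snowpack: precipitation on days with mean temperature below a
  threshold falls as snow, is reduced by canopy interception, and melts
  at a degree-day rate itself damped under canopy (shaded ponds receive
  less snow but keep it longer);
* an hourly soil temperature profile from implicit (backward-Euler)
  finite-difference integration of the 1-D heat equation
  ``dT/dt = kappa d2T/dz2`` with a Dirichlet surface boundary and a
  zero-flux bottom boundary.  Snow insulates the soil by exponentially
  decoupling the surface boundary from air temperature toward 0 °C (the
  subnivium): ``T_surface = w * T_air`` with
  ``w = exp(-snow_depth / snow_insulation_scale)``.

Radiation, humidity, wind and soil moisture are not modeled; canopy
effects enter only through amplitude damping, snowfall interception and
melt damping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .synthetic_weather import DAYS_PER_YEAR

LAPSE_RATE_C_PER_M = 0.0065  # environmental lapse rate, °C m⁻¹
HOUR_OF_TMIN = 5
HOUR_OF_TMAX = 15
SECONDS_PER_HOUR = 3600.0


@dataclass
class MicroParams:
    """Microclimate model parameters (units in field comments)."""

    snow_threshold_temp: float = 0.0        # °C; rain/snow partition on daily mean
    snowfall_multiplier: float = 1.0        # scales snowfall (microhabitat drifting)
    interception_coeff: float = 0.4         # fraction intercepted per unit canopy
    degree_day_factor: float = 3.0          # mm SWE °C⁻¹ day⁻¹
    canopy_melt_damping: float = 0.5        # melt reduction per unit canopy
    snow_density: float = 250.0             # kg m⁻³ for SWE→depth
    soil_diffusivity: float = 5.0e-7        # m² s⁻¹
    soil_depth_nodes: tuple = (0.0, 2.5, 5.0, 10.0, 20.0, 50.0)  # cm
    snow_insulation_scale: float = 7.0      # cm; e-folding of air–soil decoupling
    canopy_amplitude_damping: float = 0.5   # diurnal-range damping per unit canopy
    rain_absorption: float = 0.8            # fraction of rain entering soil moisture;
                                            # inert here (no soil-moisture budget)
    reference_elevation: float = 236.0      # m ASL; lapse-rate datum

    def validate(self) -> None:
        if self.snowfall_multiplier < 0:
            raise ValueError("snowfall_multiplier must be >= 0")
        for name in ("interception_coeff", "canopy_melt_damping",
                     "canopy_amplitude_damping", "rain_absorption"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.degree_day_factor < 0:
            raise ValueError("degree_day_factor must be >= 0")
        if self.snow_density <= 0:
            raise ValueError("snow_density must be > 0")
        if self.soil_diffusivity <= 0:
            raise ValueError("soil_diffusivity must be > 0")
        if self.snow_insulation_scale <= 0:
            raise ValueError("snow_insulation_scale must be > 0")
        nodes = np.asarray(self.soil_depth_nodes, dtype=float)
        if nodes.size < 2 or nodes[0] != 0.0 or np.any(np.diff(nodes) <= 0):
            raise ValueError(
                "soil_depth_nodes must be strictly increasing from 0 (surface)")


@dataclass
class SnowState:
    """Snowpack as water equivalent (mm) and depth (cm)."""

    swe: float = 0.0
    depth: float = 0.0

    def validate(self) -> None:
        if self.swe < 0 or self.depth < 0:
            raise ValueError("snow state must be nonnegative")
        if (self.swe == 0) != (self.depth == 0):
            raise ValueError("swe and depth must vanish together")


def swe_to_depth_cm(swe_mm: float, snow_density: float) -> float:
    """Convert SWE (mm = kg m⁻²) to snow depth (cm) at a bulk density."""
    return 100.0 * swe_mm / snow_density


def hourly_air_temperature(tmin: float, tmax: float, hour: int,
                           canopy_cover: float, params: MicroParams) -> float:
    """Below-canopy air temperature at one hour of a day.

    Piecewise sinusoid: rising half-wave from the 05:00 minimum to the
    15:00 maximum, falling half-wave through the rest of the 24-h cycle.
    Canopy damps the departure from the daily mean by
    ``1 - canopy_amplitude_damping * canopy_cover``; output always lies
    within [tmin, tmax].
    """
    if not 0 <= int(hour) <= 23:
        raise ValueError(f"hour must be in 0..23, got {hour}")
    if tmax < tmin:
        raise ValueError("tmax must be >= tmin")
    return float(_diurnal_cycle(np.array([float(tmin)]), np.array([float(tmax)]),
                                np.array([int(hour)]), canopy_cover, params)[0])


def _diurnal_cycle(tmin: np.ndarray, tmax: np.ndarray, hours: np.ndarray,
                   canopy_cover: float, params: MicroParams) -> np.ndarray:
    """Vectorized piecewise-sinusoid downscaling (same-shape inputs)."""
    mean = 0.5 * (tmin + tmax)
    amp = 0.5 * (tmax - tmin) * (1.0 - params.canopy_amplitude_damping * canopy_cover)
    h = hours.astype(float)
    rising = (h >= HOUR_OF_TMIN) & (h <= HOUR_OF_TMAX)
    # rising limb: -cos from min (05) to max (15), half-period 10 h
    phase_r = np.pi * (h - HOUR_OF_TMIN) / (HOUR_OF_TMAX - HOUR_OF_TMIN)
    # falling limb: +cos from max (15) back to min (05 next day), half-period 14 h
    since_max = np.mod(h - HOUR_OF_TMAX, 24.0)
    phase_f = np.pi * since_max / (24.0 - (HOUR_OF_TMAX - HOUR_OF_TMIN))
    return np.where(rising, mean - amp * np.cos(phase_r),
                    mean + amp * np.cos(phase_f))


def partition_precipitation(daily_mean_temp: float, precip: float,
                            params: MicroParams) -> tuple[float, float]:
    """Split daily precipitation into (rain mm, snowfall mm SWE).

    All-or-nothing on the daily mean temperature; snowfall is scaled by
    ``snowfall_multiplier`` (representing wind-drift microhabitat gain
    or loss), so water is conserved exactly when the multiplier is 1.
    """
    if precip < 0:
        raise ValueError("precip must be >= 0")
    if daily_mean_temp < params.snow_threshold_temp:
        return 0.0, precip * params.snowfall_multiplier
    return float(precip), 0.0


def step_snowpack(state: SnowState, snowfall: float, daily_mean_temp: float,
                  canopy_cover: float, params: MicroParams) -> SnowState:
    """Advance the snowpack one day: interception, accumulation, melt.

    Effective snowfall is reduced by canopy interception
    (``1 - interception_coeff * canopy``); melt is degree-day
    (``degree_day_factor * max(T, 0)``) damped under canopy and capped
    at the available SWE, so mass balance is exact.
    """
    state.validate()
    eff_snow = snowfall * (1.0 - params.interception_coeff * canopy_cover)
    potential = (params.degree_day_factor * max(daily_mean_temp, 0.0)
                 * (1.0 - params.canopy_melt_damping * canopy_cover))
    swe = state.swe + eff_snow
    melt = min(potential, swe)
    swe -= melt
    return SnowState(swe=swe, depth=swe_to_depth_cm(swe, params.snow_density))


def simulate_snowpack(daily_mean_temp: np.ndarray, precip: np.ndarray,
                      canopy_cover: float, params: MicroParams,
                      initial: SnowState | None = None):
    """Run the daily snow model over a forcing series.

    Returns ``(swe, depth, effective_snowfall, melt)`` daily arrays; the
    mass balance ``initial.swe + cumsum(effective_snowfall) - cumsum(melt)
    == swe`` holds exactly.
    """
    n = len(daily_mean_temp)
    swe_out = np.empty(n)
    eff_out = np.empty(n)
    melt_out = np.empty(n)
    swe = 0.0 if initial is None else float(initial.swe)
    icc = params.interception_coeff * canopy_cover
    mdamp = 1.0 - params.canopy_melt_damping * canopy_cover
    ddf = params.degree_day_factor
    thr = params.snow_threshold_temp
    mult = params.snowfall_multiplier
    for i in range(n):
        t = daily_mean_temp[i]
        snowfall = precip[i] * mult if t < thr else 0.0
        eff = snowfall * (1.0 - icc)
        swe += eff
        melt = min(ddf * max(t, 0.0) * mdamp, swe)
        swe -= melt
        swe_out[i] = swe
        eff_out[i] = eff
        melt_out[i] = melt
    depth = 100.0 * swe_out / params.snow_density
    return swe_out, depth, eff_out, melt_out


# ---------------------------------------------------------------------------
# soil heat conduction (implicit finite differences, nonuniform grid)


def _soil_system(depth_nodes_cm: np.ndarray, kappa: float, dt: float):
    """Backward-Euler system for the interior+bottom nodes.

    Node 0 is a Dirichlet boundary (prescribed surface temperature); the
    bottom node has a zero-flux (insulated) boundary.  Returns
    ``(Minv, coup)`` such that the update is
    ``T_new = Minv @ (T_old + coup * T_surface_new)`` for the nodes
    below the surface.
    """
    z = np.asarray(depth_nodes_cm, dtype=float) / 100.0  # m
    if z.size < 2 or z[0] != 0.0 or np.any(np.diff(z) <= 0):
        raise ValueError("depth nodes must be strictly increasing from 0")
    n = z.size - 1  # unknowns: nodes 1..N
    A = np.zeros((n, n))
    coup = np.zeros(n)
    for i in range(1, z.size):
        h_lo = z[i] - z[i - 1]
        if i < z.size - 1:
            h_hi = z[i + 1] - z[i]
            dz = 0.5 * (h_lo + h_hi)
            a = kappa * dt / (h_lo * dz)   # coupling to node i-1
            c = kappa * dt / (h_hi * dz)   # coupling to node i+1
        else:
            # zero-flux bottom: only upward coupling
            dz = h_lo
            a = kappa * dt / (h_lo * dz)
            c = 0.0
        row = i - 1
        A[row, row] = 1.0 + a + c
        if i - 1 >= 1:
            A[row, row - 1] = -a
        else:
            coup[row] = a  # couples to the Dirichlet surface node
        if c > 0.0:
            A[row, row + 1] = -c
    return np.linalg.inv(A), coup


@njit(cache=False)
def _integrate_soil(Minv, coup, top, T0):  # pragma: no cover - numba kernel
    n_steps = top.shape[0]
    k = T0.shape[0]
    out = np.empty((n_steps, k))
    T = T0.copy()
    rhs = np.empty(k)
    for t in range(n_steps):
        for j in range(k):
            rhs[j] = T[j] + coup[j] * top[t]
        T = Minv @ rhs
        for j in range(k):
            out[t, j] = T[j]
    return out


def step_soil_temperature(profile: np.ndarray, surface_air_temp: float,
                          snow_depth: float, dt: float,
                          params: MicroParams) -> np.ndarray:
    """One implicit step of soil heat conduction.

    The surface (node 0) is pinned to
    ``w * surface_air_temp`` with ``w = exp(-snow_depth /
    snow_insulation_scale)``: deep snow decouples the soil from the air
    and pins the interface toward 0 °C.  Unconditionally stable.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    profile = np.asarray(profile, dtype=float)
    nodes = np.asarray(params.soil_depth_nodes, dtype=float)
    if profile.shape != nodes.shape:
        raise ValueError("profile must have one temperature per depth node")
    if not np.all(np.isfinite(profile)):
        raise ValueError("profile must be finite")
    w = math.exp(-snow_depth / params.snow_insulation_scale)
    top = w * surface_air_temp
    Minv, coup = _soil_system(nodes, params.soil_diffusivity, dt)
    below = Minv @ (profile[1:] + coup * top)
    return np.concatenate([[top], below])


def integrate_soil_column(surface_series: np.ndarray, dt: float,
                          params: MicroParams,
                          initial_profile: np.ndarray) -> np.ndarray:
    """Integrate the soil column under a prescribed surface-temperature
    series; returns an ``(n_steps, n_nodes)`` array (node 0 = surface)."""
    nodes = np.asarray(params.soil_depth_nodes, dtype=float)
    initial_profile = np.asarray(initial_profile, dtype=float)
    if initial_profile.shape != nodes.shape:
        raise ValueError("initial profile must match depth nodes")
    Minv, coup = _soil_system(nodes, params.soil_diffusivity, dt)
    top = np.ascontiguousarray(surface_series, dtype=float)
    below = _integrate_soil(Minv, coup, top, initial_profile[1:].copy())
    return np.column_stack([top, below])


# ---------------------------------------------------------------------------
# full per-pond pipeline


@dataclass
class MicroclimateSeries:
    """Hourly microclimate state at one pond (gap-free 365-day years)."""

    pond_id: str
    year: np.ndarray        # (H,)
    doy: np.ndarray         # (H,)
    hour: np.ndarray        # (H,)
    air_temp: np.ndarray    # (H,) °C at frog height
    soil_temp: np.ndarray   # (H, n_nodes) °C
    swe: np.ndarray         # (H,) mm
    snow_depth: np.ndarray  # (H,) cm
    depths_cm: tuple        # node depths

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.year)

    def year_slice(self, year: int) -> "MicroclimateSeries":
        m = self.year == year
        if not m.any():
            raise KeyError(f"year {year} not in series")
        return MicroclimateSeries(
            pond_id=self.pond_id, year=self.year[m], doy=self.doy[m],
            hour=self.hour[m], air_temp=self.air_temp[m],
            soil_temp=self.soil_temp[m], swe=self.swe[m],
            snow_depth=self.snow_depth[m], depths_cm=self.depths_cm)

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            "pond_id": self.pond_id,
            "year": self.year,
            "doy": self.doy,
            "hour": self.hour,
            "air_temp": self.air_temp,
        }
        for j, d in enumerate(self.depths_cm):
            data[f"soil_temp_{d:g}cm"] = self.soil_temp[:, j]
        data["swe"] = self.swe
        data["snow_depth"] = self.snow_depth
        return pd.DataFrame(data)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "MicroclimateSeries":
        df = pd.read_csv(path)
        soil_cols = [c for c in df.columns if c.startswith("soil_temp_")]
        depths = tuple(float(c[len("soil_temp_"):-2]) for c in soil_cols)
        return cls(
            pond_id=str(df["pond_id"].iloc[0]),
            year=df["year"].to_numpy(),
            doy=df["doy"].to_numpy(),
            hour=df["hour"].to_numpy(),
            air_temp=df["air_temp"].to_numpy(float),
            soil_temp=df[soil_cols].to_numpy(float),
            swe=df["swe"].to_numpy(float),
            snow_depth=df["snow_depth"].to_numpy(float),
            depths_cm=depths,
        )


def _check_weather(weather: pd.DataFrame) -> pd.DataFrame:
    w = weather.sort_values(["year", "doy"]).reset_index(drop=True)
    for year, grp in w.groupby("year"):
        doys = grp["doy"].to_numpy()
        expected = np.arange(1, DAYS_PER_YEAR + 1)
        if len(doys) != DAYS_PER_YEAR or not np.array_equal(doys, expected):
            missing = sorted(set(expected) - set(doys.tolist()))
            first = missing[0] if missing else doys[len(expected):][0]
            raise ValueError(
                f"weather for year {year} is not gap-free: first problem at doy {first}")
    return w


def run_microclimate(site, weather: pd.DataFrame,
                     params: MicroParams | None = None,
                     initial_profile: np.ndarray | None = None) -> MicroclimateSeries:
    """Daily weather + site descriptors → hourly microclimate at one pond.

    ``site`` is anything with ``pond_id``, ``canopy_cover`` and
    ``elevation`` attributes (a pond-table row works).  Air temperature
    is lapse-rate adjusted by −6.5 °C km⁻¹ relative to
    ``params.reference_elevation`` before diurnal downscaling.  Snow is
    stepped daily; the soil column is stepped hourly (implicit, hence
    stable).  Fully deterministic.
    """
    params = params or MicroParams()
    params.validate()
    w = _check_weather(weather)

    canopy = float(site.canopy_cover)
    elevation = float(site.elevation)
    pond_id = str(site.pond_id)

    shift = -LAPSE_RATE_C_PER_M * (elevation - params.reference_elevation)
    tmin_d = w["tmin"].to_numpy(float) + shift
    tmax_d = w["tmax"].to_numpy(float) + shift
    precip_d = w["precip"].to_numpy(float)
    mean_d = 0.5 * (tmin_d + tmax_d)

    swe_d, depth_d, _, _ = simulate_snowpack(mean_d, precip_d, canopy, params)

    n_days = len(w)
    hours = np.tile(np.arange(24), n_days)
    tmin_h = np.repeat(tmin_d, 24)
    tmax_h = np.repeat(tmax_d, 24)
    air = _diurnal_cycle(tmin_h, tmax_h, hours, canopy, params)

    depth_h = np.repeat(depth_d, 24)
    insulation = np.exp(-depth_h / params.snow_insulation_scale)
    surface = insulation * air

    if initial_profile is None:
        nodes = np.asarray(params.soil_depth_nodes, dtype=float)
        initial_profile = np.full(nodes.shape, mean_d[0])
    soil = integrate_soil_column(surface, SECONDS_PER_HOUR, params, initial_profile)

    return MicroclimateSeries(
        pond_id=pond_id,
        year=np.repeat(w["year"].to_numpy(), 24),
        doy=np.repeat(w["doy"].to_numpy(), 24),
        hour=hours,
        air_temp=air,
        soil_temp=soil,
        swe=np.repeat(swe_d, 24),
        snow_depth=depth_h,
        depths_cm=tuple(float(d) for d in params.soil_depth_nodes),
    )
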