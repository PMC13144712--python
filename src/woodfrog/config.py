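"""YAML configuration for the pipeline (weather, network, traits, physics)."""

from __future__ import annotations

from dataclasses import asdict, fields

import yaml

from .frog_model import FrogTraits
from .microclimate import MicroParams
from .synthetic_weather import WeatherConfig


def _build(cls, mapping: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    obj = cls(**mapping)
    if hasattr(obj, "validate"):
        obj.validate()
    return obj


def load_config(path) -> dict:
    """Read a single structured config file.

    Sections (all optional): ``weather`` (WeatherConfig), ``network``
    (n_ponds, canopy_range, elevation_mean, seed), ``traits``
    (FrogTraits), ``micro`` (MicroParams), ``run`` (start_year,
    end_year, burn_in_years, elevation_override).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    if "weather" in raw:
        out["weather"] = _build(WeatherConfig, raw["weather"])
    if "traits" in raw:
        out["traits"] = _build(FrogTraits, raw["traits"])
    if "micro" in raw:
        m = dict(raw["micro"])
        if "soil_depth_nodes" in m:
            m["soil_depth_nodes"] = tuple(m["soil_depth_nodes"])
        out["micro"] = _build(MicroParams, m)
    out["network"] = raw.get("network", {})
    out["run"] = raw.get("run", {})
    return out


def save_config(path, weather: WeatherConfig | None = None,
                traits: FrogTraits | None = None,
                micro: MicroParams | None = None,
                network: dict | None = None, run: dict | None = None) -> None:
    doc = {}
    if weather is not None:
        doc["weather"] = asdict(weather)
    if traits is not None:
        doc["traits"] = asdict(traits)
    if micro is not None:
        m = asdict(micro)
        m["soil_depth_nodes"] = list(m["soil_depth_nodes"])
        doc["micro"] = m
    if network:
        doc["network"] = network
    if run:
        doc["run"] = run
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
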