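"""Human-readable (YAML) run configuration for the pipeline and CLI.

A config file describes the synthetic world (grid, years, per-variable
statistics, scenario trend shapes) plus analysis parameters (percentile
level, adaptive window, DHW settings).  Schema violations are reported
with the offending key path.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict

import numpy as np
import yaml

from .synthetic import LatProfile, ScenarioConfig, TrendSpec, VariableSpec, default_config


class ConfigError(ValueError):
    """Invalid configuration; message carries the key path."""


_VAR_KEYS = {
    "mean", "trend", "seasonal_amplitude", "seasonal_phase", "antiphase_south",
    "amplitude_trend", "ar1_rho", "noise_sd", "coupling", "units", "tail",
}


def default_dict(seed: int = 0) -> dict:
    """The default configuration as a plain YAML-ready dict."""
    cfg = default_config(seed)
    out = {
        "seed": seed,
        "grid": {
            "lat": [float(cfg.lat[0]), float(cfg.lat[-1]), len(cfg.lat)],
            "lon": [float(cfg.lon[0]), float(cfg.lon[-1]), len(cfg.lon)],
        },
        "years": {
            "daily_hist": list(cfg.years_daily_hist),
            "daily_future": list(cfg.years_daily_future),
            "monthly": list(cfg.years_monthly),
        },
        "variables": {},
        "analysis": {"level": None, "window": 100,
                     "dhw": {"pivot": 1988.2857, "level": 4.0, "count_rule": "ge"}},
    }
    for name, spec in cfg.variables.items():
        d = asdict(spec)
        d["mean"] = [spec.mean.equator, spec.mean.pole]
        d["seasonal_amplitude"] = [
            spec.seasonal_amplitude.equator, spec.seasonal_amplitude.pole
        ]
        out["variables"][name] = d
    return out


def _profile(value, path: str) -> LatProfile:
    if isinstance(value, (int, float)):
        return LatProfile(float(value), float(value))
    if isinstance(value, (list, tuple)) and len(value) == 2:
        return LatProfile(float(value[0]), float(value[1]))
    raise ConfigError(f"{path}: expected a number or [equator, pole] pair")


def _scenario_config(doc: dict, seed: int | None) -> ScenarioConfig:
    try:
        g = doc["grid"]
        lat = np.linspace(*g["lat"][:2], int(g["lat"][2]))
        lon = np.linspace(*g["lon"][:2], int(g["lon"][2]))
    except (KeyError, TypeError, IndexError) as e:
        raise ConfigError(f"grid: malformed ({e})") from e
    variables = {}
    for name, block in doc.get("variables", {}).items():
        path = f"variables.{name}"
        unknown = set(block) - _VAR_KEYS
        if unknown:
            raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
        try:
            trend = TrendSpec(**block.get("trend", {}))
            variables[name] = VariableSpec(
                mean=_profile(block["mean"], f"{path}.mean"),
                trend=trend,
                seasonal_amplitude=_profile(
                    block.get("seasonal_amplitude", 0.0), f"{path}.seasonal_amplitude"
                ),
                seasonal_phase=float(block.get("seasonal_phase", 196.0)),
                antiphase_south=bool(block.get("antiphase_south", True)),
                amplitude_trend=float(block.get("amplitude_trend", 0.0)),
                ar1_rho=float(block.get("ar1_rho", 0.0)),
                noise_sd=float(block.get("noise_sd", 0.0)),
                coupling=float(block.get("coupling", 0.0)),
                units=str(block.get("units", "1")),
                tail=str(block.get("tail", "upper")),
            )
        except ConfigError:
            raise
        except (KeyError, TypeError, ValueError) as e:
            raise ConfigError(f"{path}: {e}") from e
    years = doc.get("years", {})
    try:
        cfg = ScenarioConfig(
            lat=lat, lon=lon, variables=variables,
            years_daily_hist=tuple(years.get("daily_hist", (1975, 2014))),
            years_daily_future=tuple(years.get("daily_future", (2061, 2100))),
            years_monthly=tuple(years.get("monthly", (1850, 2100))),
            rng_seed=int(doc.get("seed", 0) if seed is None else seed),
        )
        cfg.validate()
    except (TypeError, ValueError) as e:
        raise ConfigError(f"years/seed: {e}") from e
    return cfg


def load_config(path, seed: int | None = None) -> dict:
    """Load a YAML config; returns scenario config plus analysis params.

    ``seed`` overrides the file's seed when given.
    """
    with open(path) as f:
        doc = yaml.safe_load(f)
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    scenario = _scenario_config(doc, seed)
    analysis = doc.get("analysis", {})
    return {
        "scenario": scenario,
        "level": analysis.get("level"),
        "window": int(analysis.get("window", 100)),
        "dhw": {
            "pivot": float(analysis.get("dhw", {}).get("pivot", 1988.2857)),
            "level": float(analysis.get("dhw", {}).get("level", 4.0)),
            "count_rule": str(analysis.get("dhw", {}).get("count_rule", "ge")),
        },
    }


def write_default_config(path, seed: int = 0) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(default_dict(seed), f, sort_keys=False)


def config_hash(path) -> str:
    with open(path, "rb") as f:
        return hashlib.sha256(f.read()).hexdigest()
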