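"""File-based analysis pipeline: simulate -> thresholds -> count -> coral ->
events -> report.

Each stage consumes and produces files only, so any stage can be re-run or
tested in isolation; a JSON manifest records the config hash, seed, stages
and artifacts.  Re-running with the same config and seed reproduces
bit-identical numerical outputs.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import __version__, coral, events, gridio, thresholds
from .config import config_hash, load_config
from .synthetic import generate_scenario

SCENARIOS = ["historical", "mitigation", "high"]
STAGES = ["simulate", "thresholds", "count", "coral", "events", "report"]

#: demonstration sites standing in for MPA locations (synthetic world)
DEFAULT_SITES = pd.DataFrame(
    {
        "name": ["tropical_reef", "subtropics", "midlatitude", "subpolar"],
        "lat": [7.0, 21.0, 49.0, 63.0],
        "lon": [135.0, 297.0, 189.0, 9.0],
    }
)


class PipelineError(RuntimeError):
    """Missing upstream artifact or inconsistent stage request."""


def _daily_path(out: Path, scenario: str, var: str) -> Path:
    return out / "sim" / f"{scenario}_{var}_daily.nc"


def _monthly_path(out: Path, scenario: str, var: str) -> Path:
    return out / "sim" / f"{scenario}_{var}_monthly.nc"


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage '{needed_by}' requires artifact {path.name} from stage "
            f"'{stage}'; run that stage first"
        )
    return path


def _write_mask(mask: xr.Dataset, path: Path) -> None:
    ds = mask.copy()
    ds["mask"] = ds["mask"].astype("u1")
    ds.to_netcdf(path, format="NETCDF4_CLASSIC")


def _read_mask(path: Path) -> xr.Dataset:
    with xr.open_dataset(path, decode_times=False) as ds:
        ds = ds.load()
    ds["mask"] = ds["mask"].astype(bool)
    return ds


def run_pipeline(
    config_path, out_dir, stages: list[str] | None = None, seed: int | None = None,
    sites_csv=None,
) -> dict:
    """Execute the requested stages in order and write a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = stages or STAGES
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise PipelineError(f"unknown stages {bad}; valid: {STAGES}")
    stages = [s for s in STAGES if s in stages]
    cfg = load_config(config_path, seed=seed)
    sc = cfg["scenario"]
    manifest = {
        "config": str(config_path),
        "config_sha256": config_hash(config_path),
        "seed": sc.rng_seed,
        "stages": stages,
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "artifacts": [],
    }
    art = manifest["artifacts"]

    variables = list(sc.variables)
    hist_years = sc.years_daily_hist
    fut_years = sc.years_daily_future

    if "simulate" in stages:
        (out / "sim").mkdir(exist_ok=True)
        for scen in SCENARIOS:
            fields = generate_scenario(sc, scen)
            for var, d in fields.items():
                gridio.write_field(d["daily"], _daily_path(out, scen, var))
                gridio.write_field(d["monthly"], _monthly_path(out, scen, var))
                art += [str(_daily_path(out, scen, var)), str(_monthly_path(out, scen, var))]

    if "thresholds" in stages:
        (out / "thresholds").mkdir(exist_ok=True)
        for var in variables:
            daily = gridio.read_field(
                _require(_daily_path(out, "historical", var), "simulate", "thresholds")
            )
            for method, fit in (
                ("sc-fixed", thresholds.fit_fixed_sc),
                ("sv-anomaly", thresholds.fit_fixed_sv_anomaly),
            ):
                thr = fit(daily, hist_years, cfg["level"])
                p = out / "thresholds" / f"{var}_{method}.nc"
                thr.to_dataset(name="threshold").to_netcdf(p, format="NETCDF4_CLASSIC")
                art.append(str(p))

    if "count" in stages:
        (out / "counts").mkdir(exist_ok=True)
        rows = []
        for scen in SCENARIOS:
            years = hist_years if scen == "historical" else fut_years
            target_years = np.arange(years[0], years[1] + 1)
            for var in variables:
                daily = gridio.read_field(
                    _require(_daily_path(out, scen, var), "simulate", "count")
                )
                archive = gridio.read_field(
                    _require(_monthly_path(out, scen, var), "simulate", "count")
                )
                per_method = {}
                for method in ("sc-fixed", "sv-anomaly"):
                    p = _require(
                        out / "thresholds" / f"{var}_{method}.nc", "thresholds", "count"
                    )
                    with xr.open_dataset(p, decode_times=False) as ds:
                        thr = ds["threshold"].load()
                    per_method[method] = thresholds.count_extremes(daily, thr)
                per_method["sc-adaptive"] = thresholds.count_extremes(
                    daily,
                    thresholds.adaptive_sc_thresholds(archive, target_years, cfg["window"]),
                )
                with xr.open_dataset(
                    out / "thresholds" / f"{var}_sv-anomaly.nc", decode_times=False
                ) as ds:
                    hist_sv = ds["threshold"].load()
                per_method["sv-adaptive"] = thresholds.count_extremes(
                    daily,
                    thresholds.adaptive_sv_thresholds(
                        hist_sv, archive, hist_years, target_years, cfg["window"]
                    ),
                )
                for method, mask in per_method.items():
                    rows.append({
                        "scenario": scen, "variable": var, "method": method,
                        "global_mean_percent": float(gridio.global_mean(mask["percent"])),
                    })
                    if method in ("sc-adaptive", "sv-adaptive"):
                        mp = out / "counts" / f"{scen}_{var}_{method}_mask.nc"
                        _write_mask(mask, mp)
                        art.append(str(mp))
        df = pd.DataFrame(rows)
        p = out / "counts" / "global_means.csv"
        df.to_csv(p, index=False)
        art.append(str(p))

    if "coral" in stages:
        (out / "coral").mkdir(exist_ok=True)
        archive = gridio.read_field(
            _require(_monthly_path(out, "historical", "sst"), "simulate", "coral")
        )
        clim = coral.detrended_monthly_climatology(
            archive, hist_years, cfg["dhw"]["pivot"]
        )
        mmm_field = coral.mmm(clim)
        rows = []
        for scen in SCENARIOS:
            sst = gridio.read_field(
                _require(_daily_path(out, scen, "sst"), "simulate", "coral")
            )
            dhw_series = coral.dhw(sst, mmm_field, count_rule=cfg["dhw"]["count_rule"])
            dhw_mask = coral.dhw_extreme_days(dhw_series, cfg["dhw"]["level"])
            _write_mask(dhw_mask, out / "coral" / f"{scen}_dhw_mask.nc")
            rows.append({
                "scenario": scen, "metric": f"dhw>{cfg['dhw']['level']:g}",
                "global_mean_percent": float(gridio.global_mean(dhw_mask["percent"])),
            })
            presets = {
                "omega_1": "omega", "omega_3": "omega", "hypercapnia": "pco2",
            }
            for preset, var in presets.items():
                if var not in variables:
                    continue
                daily = gridio.read_field(_daily_path(out, scen, var))
                m = coral.absolute_exceedance(daily, preset=preset)
                rows.append({
                    "scenario": scen, "metric": preset,
                    "global_mean_percent": float(gridio.global_mean(m["percent"])),
                })
                if preset == "omega_3":
                    both = events.compound([dhw_mask, m], "intersection")
                    either = events.compound([dhw_mask, m], "union")
                    rows.append({
                        "scenario": scen, "metric": "dhw_and_omega3",
                        "global_mean_percent": float(gridio.global_mean(both["percent"])),
                    })
                    rows.append({
                        "scenario": scen, "metric": "dhw_or_omega3",
                        "global_mean_percent": float(gridio.global_mean(either["percent"])),
                    })
        p = out / "coral" / "summary.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        art.append(str(p))

    if "events" in stages:
        (out / "events").mkdir(exist_ok=True)
        rows = []
        pctl = {}
        for var in variables:
            hist_daily = gridio.read_field(
                _require(_daily_path(out, "historical", var), "simulate", "events")
            )
            tail = hist_daily.attrs.get("tail", "upper")
            level = cfg["level"] or (95.0 if tail == "upper" else 5.0)
            h = events.detrended_percentile(hist_daily, hist_years, level)
            hm = events.detrended_percentile(hist_daily, hist_years, 50.0)
            for scen in ("mitigation", "high"):
                fut_daily = gridio.read_field(_daily_path(out, scen, var))
                f = events.detrended_percentile(fut_daily, fut_years, level)
                fm = events.detrended_percentile(fut_daily, fut_years, 50.0)
                s = events.change_summary(h, f)
                sm = events.change_summary(hm, fm)
                rows.append({
                    "scenario": scen, "variable": var, "level": level,
                    "percentile_change_mean": s["global_mean"],
                    "percentile_change_sd": s["spatial_sd"],
                    "median_change_mean": sm["global_mean"],
                })
                pctl[(scen, var)] = f
            pctl[("historical", var)] = h
        if {"sst", "omega"} <= set(variables):
            for scen in ("mitigation", "high"):
                rows.append({
                    "scenario": scen, "variable": "sst+omega",
                    "level": np.nan,
                    "percentile_change_mean": events.region_overlap(
                        (pctl[("historical", "sst")], pctl[("historical", "omega")]),
                        (pctl[(scen, "sst")], pctl[(scen, "omega")]),
                    ),
                    "percentile_change_sd": np.nan, "median_change_mean": np.nan,
                })
        p = out / "events" / "change_summary.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        art.append(str(p))

    if "report" in stages:
        (out / "report").mkdir(exist_ok=True)
        sites = (
            gridio.SiteSet.from_csv(sites_csv)
            if sites_csv
            else gridio.SiteSet(points=DEFAULT_SITES)
        )
        frames = []
        pairs = [("sst", "pco2"), ("sst", "omega")]
        for scen in SCENARIOS:
            for vx, vy in pairs:
                if not ({vx, vy} <= set(variables)):
                    continue
                mx = _read_mask(_require(
                    out / "counts" / f"{scen}_{vx}_sv-adaptive_mask.nc", "count", "report"
                ))
                my = _read_mask(
                    out / "counts" / f"{scen}_{vy}_sv-adaptive_mask.nc"
                )
                df = events.site_report(mx, my, sites)
                df.insert(0, "pair", f"{vx}+{vy}")
                df.insert(0, "scenario", scen)
                frames.append(df)
        p = out / "report" / "site_report.csv"
        pd.concat(frames, ignore_index=True).to_csv(p, index=False)
        art.append(str(p))

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return manifest
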