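"""Coral thermal-stress (degree heating weeks) and absolute thresholds.

Degree heating weeks follow the NOAA Coral Reef Watch construction: the
daily hotspot H is SST minus the maximum monthly mean (MMM) of a detrended
climatology, and DHW accumulates qualifying hotspots over a 12-week (84-day,
inclusive) trailing window, divided by 7 to convert to degC-weeks.  DHW > 4
is the bleaching-associated exceedance level.

By default hotspots of at least ``count_threshold`` (1 degC) accumulate,
matching the Coral Reef Watch definition; ``count_rule="le"`` instead
accumulates hotspots at or below the threshold, for sensitivity to the
alternative literal reading of the counting rule.

Absolute thresholds (spatially and temporally constant) are provided with
presets for aragonite undersaturation (omega < 1), coral habitat
suitability (omega < 3) and environmental hypercapnia (pCO2 > 1000 uatm).
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .gridio import DAYS_PER_YEAR
from .thresholds import count_extremes

DHW_PIVOT_YEAR = 1988.2857
DHW_WINDOW_DAYS = 84  # 12 weeks, "from 83 days prior up to a given day"

#: absolute-threshold presets: variable, threshold, stressful direction
ABSOLUTE_PRESETS = {
    "omega_1": ("omega", 1.0, "below"),
    "omega_3": ("omega", 3.0, "below"),
    "hypercapnia": ("pco2", 1000.0, "above"),
}


def detrended_monthly_climatology(
    archive: xr.DataArray,
    ref_years: tuple[int, int],
    pivot: float = DHW_PIVOT_YEAR,
) -> xr.DataArray:
    """12-value monthly climatology detrended relative to a pivot year.

    Per cell, an ordinary-least-squares linear fit in decimal year is
    removed from the monthly series and every value is adjusted to the
    pivot year (value + slope * (pivot - t)); month-wise means of the
    adjusted series form the climatology.  Exactly invariant to adding any
    linear-in-time field anchored at the pivot.
    """
    years = np.unique(archive["year"].values)
    wanted = np.arange(ref_years[0], ref_years[1] + 1)
    if not np.all(np.isin(wanted, years)):
        raise ValueError(f"archive missing reference years in {ref_years}")
    if len(wanted) < 2:
        raise ValueError("need at least 2 years for detrending")
    sel = np.isin(archive["year"].values, wanted)
    v = archive.values[sel]
    t = archive["time"].values[sel]
    months = archive["month"].values[sel]
    # OLS slope per cell on the full monthly series
    tc = t - t.mean()
    flat = v.reshape(len(t), -1)
    slope = tc @ flat / np.sum(tc**2)
    adjusted = flat + np.outer(pivot - t, slope)
    clim = np.empty((12, flat.shape[1]))
    for m in range(12):
        clim[m] = adjusted[months == m + 1].mean(axis=0)
    out = xr.DataArray(
        clim.reshape(12, *archive.shape[1:]),
        dims=("month", "lat", "lon"),
        coords={"month": np.arange(1, 13), "lat": archive["lat"], "lon": archive["lon"]},
        name=f"{archive.name}_climatology",
    )
    out.attrs.update(
        units=archive.attrs.get("units", "1"), pivot=pivot,
        reference=f"fixed:{ref_years[0]}-{ref_years[1]}",
    )
    return out


def mmm(climatology: xr.DataArray) -> xr.DataArray:
    """Maximum monthly mean: the warmest month of the climatology, per cell."""
    out = climatology.max("month")
    out.name = "mmm"
    out.attrs.update(climatology.attrs)
    return out


def dhw(
    daily_sst: xr.DataArray,
    mmm_field: xr.DataArray,
    window_days: int = DHW_WINDOW_DAYS,
    count_threshold: float = 1.0,
    count_rule: str = "ge",
    mask_partial: bool = False,
) -> xr.DataArray:
    """Degree heating weeks time series (degC-weeks).

    ``DHW(t) = (1/7) * sum over the window_days days ending at t of
    qualifying hotspots H = SST - MMM``.  With ``count_rule="ge"``
    (default) hotspots with ``H >= count_threshold`` qualify; ``"le"``
    accumulates ``0 < H <= count_threshold`` plus nothing else is the
    literal alternative reading — it qualifies ``H <= count_threshold``.
    The first ``window_days - 1`` days use the available partial window
    unless ``mask_partial`` is set.
    """
    if window_days > daily_sst.sizes["time"]:
        raise ValueError("DHW window longer than the daily series")
    h = daily_sst.values - mmm_field.values[None]
    if count_rule == "ge":
        q = np.where(h >= count_threshold, h, 0.0)
    elif count_rule == "le":
        q = np.where(h <= count_threshold, h, 0.0)
    else:
        raise ValueError(f"unknown count_rule {count_rule!r}")
    csum = np.concatenate([np.zeros((1, *q.shape[1:])), np.cumsum(q, axis=0)])
    n = q.shape[0]
    hi = np.arange(1, n + 1)
    lo = np.maximum(hi - window_days, 0)
    out_vals = (csum[hi] - csum[lo]) / 7.0
    if mask_partial:
        out_vals[: window_days - 1] = np.nan
    out = xr.DataArray(
        out_vals, dims=daily_sst.dims, coords=daily_sst.coords, name="dhw"
    )
    out.attrs.update(
        units="degC weeks", window_days=window_days,
        count_threshold=count_threshold, count_rule=count_rule,
        tail="upper", calendar="noleap",
    )
    return out


def dhw_extreme_days(dhw_series: xr.DataArray, level: float = 4.0) -> xr.Dataset:
    """Exceedance mask and percent-of-days for DHW > level."""
    thr = xr.DataArray(
        np.full((dhw_series.sizes["lat"], dhw_series.sizes["lon"]), float(level)),
        dims=("lat", "lon"),
        coords={"lat": dhw_series["lat"], "lon": dhw_series["lon"]},
    )
    thr.attrs.update(variable="dhw", tail="upper", method="dhw", level=float(level))
    return count_extremes(dhw_series, thr)


def absolute_exceedance(
    daily: xr.DataArray,
    threshold: float | None = None,
    direction: str | None = None,
    preset: str | None = None,
) -> xr.Dataset:
    """Exceedance of a spatially/temporally constant absolute threshold.

    Either give ``threshold`` and ``direction`` ("above"/"below"), or a
    ``preset`` name from :data:`ABSOLUTE_PRESETS`.  Exceedance is strict.
    """
    if preset is not None:
        var, threshold, direction = ABSOLUTE_PRESETS[preset]
        if str(daily.name) != var:
            raise ValueError(f"preset {preset!r} applies to {var!r}, got {daily.name!r}")
    if threshold is None or direction not in ("above", "below"):
        raise ValueError("need threshold and direction ('above'/'below'), or a preset")
    thr = xr.DataArray(
        np.full((daily.sizes["lat"], daily.sizes["lon"]), float(threshold)),
        dims=("lat", "lon"), coords={"lat": daily["lat"], "lon": daily["lon"]},
    )
    thr.attrs.update(
        variable=str(daily.name),
        tail="upper" if direction == "above" else "lower",
        method="absolute", reference=preset or "", level=float(threshold),
    )
    return count_extremes(daily, thr)
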