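"""Quantile threshold definitions: SC/SV x fixed/adaptive, and the AMM proxy.

Four permutations of percentile thresholds are implemented:

* seasonally constant (SC), fixed baseline — one percentile of all daily
  values in a static reference period;
* seasonally varying (SV), fixed baseline — either a binned day-of-year
  percentile (five-day bins, circular 10-day Gaussian smoothing) or the
  simpler seasonal-climatology-plus-anomaly-percentile variant;
* SC, adaptive — the rolling N-year mean of the annual maximum (or minimum)
  monthly mean, AMM_max/AMM_min, an empirical proxy for the ~93-94th (or
  ~6-7th) percentile of the daily distribution;
* SV, adaptive — the historical SV threshold shifted by the rolling-window
  minus historical difference in monthly climatology, interpolated to day
  of year.

Exceedance is strict (a value exactly at threshold is not extreme), keeping
the self-reference count at or below the nominal rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter1d

from .gridio import DAYS_PER_YEAR, MONTH_EDGES, MONTH_MIDPOINTS

SMOOTH_SIGMA_DAYS = 10.0


def percentile(values, p: float):
    """Order-statistic percentile with linear interpolation.

    ``p`` = 50 gives the median; ``p`` = 100 the maximum.  Missing values
    are ignored; an empty (or all-missing) input raises.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("percentile of empty input")
    return float(np.percentile(values, p, method="linear"))


def _reshape_years(daily: xr.DataArray, ref_years: tuple[int, int]) -> np.ndarray:
    """Reference-period values as (nyears, 365, lat, lon)."""
    years = daily["year"].values
    have = np.unique(years)
    wanted = np.arange(ref_years[0], ref_years[1] + 1)
    if not np.all(np.isin(wanted, have)):
        missing = sorted(set(wanted) - set(have))
        raise ValueError(f"daily field missing reference years {missing}")
    sel = daily.values[np.isin(years, wanted)]
    return sel.reshape(len(wanted), DAYS_PER_YEAR, *daily.shape[1:])


def _threshold_attrs(daily: xr.DataArray, method: str, reference: str, level: float):
    return dict(
        variable=str(daily.name),
        tail=daily.attrs.get("tail", "upper"),
        units=daily.attrs.get("units", "1"),
        method=method,
        reference=reference,
        level=float(level),
    )


def _tail_level(daily: xr.DataArray, p: float | None) -> float:
    """Default percentile level by tail: 95 upper / 5 lower."""
    if p is not None:
        return float(p)
    return 95.0 if daily.attrs.get("tail", "upper") == "upper" else 5.0


def fit_fixed_sc(
    daily: xr.DataArray, ref_years: tuple[int, int], p: float | None = None
) -> xr.DataArray:
    """Seasonally constant fixed threshold: one percentile per cell."""
    p = _tail_level(daily, p)
    v = _reshape_years(daily, ref_years)
    thr = np.percentile(v.reshape(-1, *v.shape[2:]), p, axis=0, method="linear")
    out = xr.DataArray(
        thr, dims=("lat", "lon"),
        coords={"lat": daily["lat"], "lon": daily["lon"]},
        name=f"{daily.name}_threshold",
    )
    out.attrs.update(
        _threshold_attrs(daily, "sc-fixed", f"fixed:{ref_years[0]}-{ref_years[1]}", p)
    )
    return out


def smooth_doy(values: np.ndarray, sigma: float = SMOOTH_SIGMA_DAYS) -> np.ndarray:
    """Circular Gaussian smoothing over a leading day-of-year axis."""
    return gaussian_filter1d(values, sigma=sigma, axis=0, mode="wrap", truncate=4.0)


def _sv_dataarray(daily, thr365, method, ref_years, p):
    out = xr.DataArray(
        thr365, dims=("dayofyear", "lat", "lon"),
        coords={
            "dayofyear": np.arange(1, DAYS_PER_YEAR + 1),
            "lat": daily["lat"].values, "lon": daily["lon"].values,
        },
        name=f"{daily.name}_threshold",
    )
    out.attrs.update(
        _threshold_attrs(daily, method, f"fixed:{ref_years[0]}-{ref_years[1]}", p)
    )
    return out


def fit_fixed_sv_binned(
    daily: xr.DataArray,
    ref_years: tuple[int, int],
    p: float | None = None,
    bin_days: int = 5,
    smooth_days: float = SMOOTH_SIGMA_DAYS,
) -> xr.DataArray:
    """Seasonally varying threshold from day-of-year bins.

    The year is divided into ``bin_days``-day bins, the percentile is taken
    within each bin (pooling years), and the binned levels are interpolated
    back to 365-day resolution with a circular Gaussian filter.
    """
    if DAYS_PER_YEAR % bin_days != 0:
        raise ValueError(f"bin_days={bin_days} must divide {DAYS_PER_YEAR}")
    p = _tail_level(daily, p)
    v = _reshape_years(daily, ref_years)  # (ny, 365, lat, lon)
    ny = v.shape[0]
    nb = DAYS_PER_YEAR // bin_days
    binned = v.reshape(ny, nb, bin_days, *v.shape[2:])
    pooled = binned.transpose(1, 0, 2, *range(3, binned.ndim)).reshape(
        nb, ny * bin_days, *v.shape[2:]
    )
    levels = np.percentile(pooled, p, axis=1, method="linear")  # (nb, lat, lon)
    thr365 = np.repeat(levels, bin_days, axis=0)
    thr365 = smooth_doy(thr365, smooth_days)
    return _sv_dataarray(daily, thr365, "sv-binned", ref_years, p)


def seasonal_climatology(
    daily: xr.DataArray,
    ref_years: tuple[int, int],
    smooth_days: float = SMOOTH_SIGMA_DAYS,
) -> np.ndarray:
    """Day-of-year mean climatology, circularly Gaussian-smoothed (365, lat, lon)."""
    v = _reshape_years(daily, ref_years)
    return smooth_doy(v.mean(axis=0), smooth_days)


def fit_fixed_sv_anomaly(
    daily: xr.DataArray, ref_years: tuple[int, int], p: float | None = None
) -> xr.DataArray:
    """Seasonally varying threshold as climatology + single anomaly percentile.

    The mean seasonal cycle is removed and one percentile of the anomalies
    (pooled over the whole reference period, irrespective of time of year)
    is added back onto the climatology.
    """
    p = _tail_level(daily, p)
    v = _reshape_years(daily, ref_years)
    clim = seasonal_climatology(daily, ref_years)
    anom = v - clim[None]
    anom_p = np.percentile(
        anom.reshape(-1, *v.shape[2:]), p, axis=0, method="linear"
    )
    return _sv_dataarray(daily, clim + anom_p[None], "sv-anomaly", ref_years, p)


# ---------------------------------------------------------------------------
# exceedance counting
# ---------------------------------------------------------------------------


def _threshold_at_times(daily: xr.DataArray, threshold: xr.DataArray) -> np.ndarray:
    """Broadcast a threshold field onto the daily time axis."""
    thr = threshold
    vals = thr.values
    idx: list = []
    if "year" in thr.dims:
        yr_map = {int(y): i for i, y in enumerate(thr["year"].values)}
        years = daily["year"].values
        missing = sorted({int(y) for y in np.unique(years)} - set(yr_map))
        if missing:
            raise ValueError(f"threshold missing target years {missing}")
        idx.append(np.array([yr_map[int(y)] for y in years]))
    if "dayofyear" in thr.dims:
        idx.append(daily["doy"].values - 1)
    if not idx:
        return np.broadcast_to(vals, daily.shape)
    if len(idx) == 1:
        return vals[idx[0]]
    return vals[idx[0], idx[1]]


def count_extremes(daily: xr.DataArray, threshold: xr.DataArray) -> xr.Dataset:
    """Daily exceedance mask plus percent-of-days summary per cell.

    Exceedance is strict: value > threshold for upper-tail variables,
    value < threshold for lower-tail.  Missing daily values are excluded
    from both numerator and denominator.
    """
    tail = threshold.attrs.get("tail", daily.attrs.get("tail", "upper"))
    tv = threshold.attrs.get("variable", daily.name)
    if tv is not None and str(tv) != str(daily.name):
        raise ValueError(f"threshold for {tv!r} applied to {daily.name!r}")
    thr_t = _threshold_at_times(daily, threshold)
    vals = daily.values
    ok = np.isfinite(vals)
    if tail == "upper":
        mask = ok & (vals > thr_t)
    else:
        mask = ok & (vals < thr_t)
    denom = ok.sum(axis=0)
    percent = np.where(denom > 0, 100.0 * mask.sum(axis=0) / np.maximum(denom, 1), np.nan)
    ds = xr.Dataset(
        {
            "mask": (("time", "lat", "lon"), mask),
            "percent": (("lat", "lon"), percent),
        },
        coords=daily.coords,
    )
    ds.attrs.update(
        variable=str(daily.name),
        tail=tail,
        method=threshold.attrs.get("method", "absolute"),
        reference=threshold.attrs.get("reference", ""),
        level=threshold.attrs.get("level", np.nan),
    )
    return ds


# ---------------------------------------------------------------------------
# AMM proxy and adaptive thresholds
# ---------------------------------------------------------------------------


def _monthly_by_year(archive: xr.DataArray) -> tuple[np.ndarray, np.ndarray]:
    years = np.unique(archive["year"].values)
    v = archive.values.reshape(len(years), 12, *archive.shape[1:])
    return years, v


def amm_series(archive: xr.DataArray, mode: str | None = None) -> xr.DataArray:
    """Annual maximum (AMM_max) or minimum (AMM_min) of the 12 monthly means.

    ``mode`` defaults from the variable's tail: upper -> "max",
    lower -> "min".
    """
    if mode is None:
        mode = "max" if archive.attrs.get("tail", "upper") == "upper" else "min"
    years, v = _monthly_by_year(archive)
    if archive.sizes["time"] != len(years) * 12:
        raise ValueError("archive has partial years")
    ext = v.max(axis=1) if mode == "max" else v.min(axis=1)
    out = xr.DataArray(
        ext, dims=("year", "lat", "lon"),
        coords={"year": years, "lat": archive["lat"], "lon": archive["lon"]},
        name=f"{archive.name}_amm_{mode}",
    )
    out.attrs.update(mode=mode, variable=str(archive.name),
                     tail=archive.attrs.get("tail", "upper"))
    return out


def calibrate_amm_percentile(
    daily: xr.DataArray, archive: xr.DataArray, mode: str | None = None
) -> tuple[int, pd.DataFrame]:
    """Which integer percentile the AMM proxy tracks best.

    For every integer percentile, the RMSE and bias of AMM versus that
    year's daily percentile are pooled over cells and overlap years; the
    argmin-RMSE percentile is returned together with the full table.
    """
    if mode is None:
        mode = "max" if daily.attrs.get("tail", "upper") == "upper" else "min"
    amm = amm_series(archive, mode)
    dy = np.unique(daily["year"].values)
    overlap = np.intersect1d(dy, amm["year"].values)
    if overlap.size == 0:
        raise ValueError("no overlapping daily/monthly years")
    v = _reshape_years(daily, (int(overlap[0]), int(overlap[-1])))
    a = amm.sel(year=overlap).values  # (ny, lat, lon)
    ps = np.arange(1, 100)
    qs = np.percentile(v, ps, axis=1, method="linear")  # (99, ny, lat, lon)
    err = a[None] - qs
    rmse = np.sqrt((err**2).mean(axis=(1, 2, 3)))
    bias = err.mean(axis=(1, 2, 3))
    table = pd.DataFrame({"percentile": ps, "rmse": rmse, "bias": bias})
    best = int(ps[np.argmin(rmse)])
    return best, table


def idealized_amm_percentile(phase_offset: float, mode: str = "max") -> float:
    """Percentile rank attained by the AMM of a pure daily sinusoid.

    One unit-amplitude 365-day year ``cos(2 pi (d - phase)/365)`` is
    averaged within calendar months; the maximum (or minimum) monthly mean
    is ranked within the year's 365 daily values as
    ``100 * #{v <= AMM} / 365`` (``>=`` for the minimum).  The rank is
    invariant to amplitude scaling.
    """
    d = np.arange(1, DAYS_PER_YEAR + 1)
    v = np.cos(2.0 * np.pi * (d - phase_offset) / DAYS_PER_YEAR)
    mm = np.array([v[MONTH_EDGES[i]:MONTH_EDGES[i + 1]].mean() for i in range(12)])
    if mode == "max":
        return 100.0 * np.sum(v <= mm.max()) / DAYS_PER_YEAR
    return 100.0 * np.sum(v < mm.min()) / DAYS_PER_YEAR


def idealized_amm_sweep(mode: str = "max", n_phases: int = DAYS_PER_YEAR) -> dict:
    """Min/max/mean of the idealized AMM percentile over a uniform phase sweep."""
    phases = np.arange(n_phases) * (DAYS_PER_YEAR / n_phases)
    ranks = np.array([idealized_amm_percentile(p, mode) for p in phases])
    return {"mean": float(ranks.mean()), "min": float(ranks.min()),
            "max": float(ranks.max()), "n_phases": int(n_phases)}


def _check_window(amm_years: np.ndarray, target_year: int, n_years: int) -> np.ndarray:
    wanted = np.arange(target_year - n_years, target_year)
    if not np.all(np.isin(wanted, amm_years)):
        missing = sorted(set(wanted) - set(amm_years.tolist()))
        raise ValueError(
            f"archive does not cover the {n_years}-year window before "
            f"{target_year} (missing {missing[:3]}...)"
        )
    return wanted


def adaptive_sc_threshold(
    archive: xr.DataArray, target_year: int, n_years: int = 100,
    mode: str | None = None,
) -> xr.DataArray:
    """Adaptive SC threshold: mean AMM over the preceding ``n_years`` years.

    The window ``[target_year - N, target_year - 1]`` excludes the target
    year; an archive too short for the full window raises (no silent
    shortening).  The AMM window mean is used directly as the threshold
    level (effective ~93-94th / ~6-7th percentile).
    """
    amm = amm_series(archive, mode)
    wanted = _check_window(amm["year"].values, target_year, n_years)
    out = amm.sel(year=wanted).mean("year")
    out.name = f"{archive.name}_threshold"
    out.attrs.update(
        variable=str(archive.name), tail=archive.attrs.get("tail", "upper"),
        units=archive.attrs.get("units", "1"),
        method="sc-adaptive", reference=f"adaptive:N={n_years},target={target_year}",
        level=np.nan,
    )
    return out


def adaptive_sc_thresholds(
    archive: xr.DataArray, target_years, n_years: int = 100, mode: str | None = None
) -> xr.DataArray:
    """Per-year adaptive SC thresholds, dims (year, lat, lon)."""
    amm = amm_series(archive, mode)
    ayears = amm["year"].values
    target_years = np.asarray(target_years)
    for ty in (target_years[0], target_years[-1]):
        _check_window(ayears, int(ty), n_years)
    csum = np.concatenate(
        [np.zeros((1, *amm.shape[1:])), np.cumsum(amm.values, axis=0)]
    )
    i0 = np.searchsorted(ayears, target_years - n_years)
    i1 = np.searchsorted(ayears, target_years)  # exclusive of target year
    vals = (csum[i1] - csum[i0]) / n_years
    out = xr.DataArray(
        vals, dims=("year", "lat", "lon"),
        coords={"year": target_years, "lat": archive["lat"], "lon": archive["lon"]},
        name=f"{archive.name}_threshold",
    )
    out.attrs.update(
        variable=str(archive.name), tail=archive.attrs.get("tail", "upper"),
        units=archive.attrs.get("units", "1"),
        method="sc-adaptive", reference=f"adaptive:N={n_years}", level=np.nan,
    )
    return out


def monthly_climatology(archive: xr.DataArray, years: tuple[int, int]) -> np.ndarray:
    """Mean of each calendar month over a span of years, (12, lat, lon)."""
    ayears, v = _monthly_by_year(archive)
    wanted = np.arange(years[0], years[1] + 1)
    if not np.all(np.isin(wanted, ayears)):
        raise ValueError(f"archive missing years in {years}")
    return v[np.isin(ayears, wanted)].mean(axis=0)


def interp_month_to_doy(monthly_vals: np.ndarray) -> np.ndarray:
    """Periodic linear interpolation from 12 month-midpoint anchors to 365 days.

    The interpolant passes through each monthly value at that month's
    midpoint and wraps December -> January.
    """
    mid = MONTH_MIDPOINTS
    x = np.concatenate([[mid[-1] - DAYS_PER_YEAR], mid, [mid[0] + DAYS_PER_YEAR]])
    flat = monthly_vals.reshape(12, -1)
    y = np.concatenate([flat[-1:], flat, flat[:1]], axis=0)
    d = np.arange(1, DAYS_PER_YEAR + 1, dtype=float)
    out = np.empty((DAYS_PER_YEAR, flat.shape[1]))
    for j in range(flat.shape[1]):
        out[:, j] = np.interp(d, x, y[:, j])
    return out.reshape(DAYS_PER_YEAR, *monthly_vals.shape[1:])


def adaptive_sv_threshold(
    hist_sv: xr.DataArray,
    archive: xr.DataArray,
    hist_years: tuple[int, int],
    target_year: int,
    n_years: int = 100,
) -> xr.DataArray:
    """Adaptive SV threshold for one target year.

    Adds to the historical SV threshold the difference in monthly-mean
    climatology between the rolling ``[target-N, target-1]`` window and the
    historical reference, interpolated to day of year.
    """
    window_clim = monthly_climatology(
        archive, (target_year - n_years, target_year - 1)
    )
    hist_clim = monthly_climatology(archive, hist_years)
    delta = interp_month_to_doy(window_clim - hist_clim)
    out = hist_sv + delta
    out.name = hist_sv.name
    out.attrs.update(hist_sv.attrs)
    out.attrs.update(
        method="sv-adaptive", reference=f"adaptive:N={n_years},target={target_year}"
    )
    return out


def adaptive_sv_thresholds(
    hist_sv: xr.DataArray,
    archive: xr.DataArray,
    hist_years: tuple[int, int],
    target_years,
    n_years: int = 100,
) -> xr.DataArray:
    """Per-year adaptive SV thresholds, dims (year, dayofyear, lat, lon)."""
    ayears, v = _monthly_by_year(archive)  # v: (ny, 12, lat, lon)
    target_years = np.asarray(target_years)
    for ty in (target_years[0], target_years[-1]):
        _check_window(ayears, int(ty), n_years)
    hist_clim = monthly_climatology(archive, hist_years)
    csum = np.concatenate([np.zeros((1, *v.shape[1:])), np.cumsum(v, axis=0)])
    i0 = np.searchsorted(ayears, target_years - n_years)
    i1 = np.searchsorted(ayears, target_years)
    window_clims = (csum[i1] - csum[i0]) / n_years  # (nt, 12, lat, lon)
    thr = np.empty((len(target_years), DAYS_PER_YEAR, *v.shape[2:]))
    base = hist_sv.values
    for k in range(len(target_years)):
        thr[k] = base + interp_month_to_doy(window_clims[k] - hist_clim)
    out = xr.DataArray(
        thr, dims=("year", "dayofyear", "lat", "lon"),
        coords={
            "year": target_years,
            "dayofyear": np.arange(1, DAYS_PER_YEAR + 1),
            "lat": archive["lat"].values, "lon": archive["lon"].values,
        },
        name=hist_sv.name,
    )
    out.attrs.update(hist_sv.attrs)
    out.attrs.update(method="sv-adaptive", reference=f"adaptive:N={n_years}")
    return out
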