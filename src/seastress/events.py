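"""Compound-event accounting and distribution-change statistics.

Compound events combine per-variable extreme-day masks day-wise
(intersection = simultaneous stress, union = either stressor).  The
percentile-change statistic measures how far the (detrended,
midpoint-anchored) 95th/5th percentile of each variable shifts between the
historical and end-of-century periods; the joint-distribution analysis
summarizes how completely future per-cell (SST, OA) percentile conditions
separate from historical ones over the global ocean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from . import gridio


def compound(masks: list[xr.Dataset], mode: str = "intersection") -> xr.Dataset:
    """Day-wise AND (intersection) or OR (union) of extreme-day masks."""
    if mode not in ("intersection", "union"):
        raise ValueError(f"mode must be intersection|union, got {mode!r}")
    if not masks:
        raise ValueError("no masks given")
    first = masks[0]
    acc = first["mask"].values.copy()
    for m in masks[1:]:
        if m["mask"].shape != acc.shape or not np.allclose(
            m["time"].values, first["time"].values
        ):
            raise ValueError("masks are not aligned in time/grid")
        if mode == "intersection":
            acc &= m["mask"].values
        else:
            acc |= m["mask"].values
    percent = 100.0 * acc.mean(axis=0)
    out = xr.Dataset(
        {"mask": (("time", "lat", "lon"), acc), "percent": (("lat", "lon"), percent)},
        coords=first.coords,
    )
    out.attrs.update(
        variable="+".join(str(m.attrs.get("variable", "?")) for m in masks),
        method=f"{mode}(" + ",".join(str(m.attrs.get("method", "?")) for m in masks) + ")",
    )
    return out


def detrended_percentile(
    daily: xr.DataArray,
    period: tuple[int, int],
    level: float,
    midpoint_year: float | None = None,
) -> xr.DataArray:
    """Per-cell percentile of the detrended series, anchored at the midpoint.

    Per cell an OLS linear trend in decimal year is fit over the period;
    the percentile is taken of (residuals + fitted value at the midpoint),
    so a pure midpoint-anchored trend leaves the result unchanged.  The
    seasonal cycle is not removed.
    """
    years = daily["year"].values
    wanted = np.arange(period[0], period[1] + 1)
    if not np.all(np.isin(wanted, np.unique(years))):
        raise ValueError(f"daily field missing years in {period}")
    if midpoint_year is None:
        midpoint_year = 0.5 * (period[0] + period[1] + 1)
    sel = np.isin(years, wanted)
    v = daily.values[sel]
    t = daily["time"].values[sel]
    if len(t) < 2:
        raise ValueError("need at least 2 time points to detrend")
    tc = t - t.mean()
    flat = v.reshape(len(t), -1)
    slope = tc @ flat / np.sum(tc**2)
    # residual + fitted value at the midpoint == v - slope*(t - midpoint)
    adjusted = flat - np.outer(t - midpoint_year, slope)
    q = np.percentile(adjusted, level, axis=0, method="linear")
    out = xr.DataArray(
        q.reshape(daily.shape[1:]), dims=("lat", "lon"),
        coords={"lat": daily["lat"], "lon": daily["lon"]},
        name=f"{daily.name}_p{level:g}",
    )
    out.attrs.update(
        variable=str(daily.name), level=float(level),
        midpoint_year=float(midpoint_year),
        period=f"{period[0]}-{period[1]}", units=daily.attrs.get("units", "1"),
    )
    return out


def change_summary(hist: xr.DataArray, future: xr.DataArray) -> dict:
    """Change map plus area-weighted global statistics.

    Returns the per-cell change (future - historical), its area-weighted
    global mean and spatial standard deviation.  When both inputs carry a
    companion ``mean_change`` comparison is wanted, use
    :func:`amplification` with the mean-change map.
    """
    if hist.shape != future.shape:
        raise ValueError("grid mismatch between periods")
    change = future - hist
    change.name = f"{hist.attrs.get('variable', hist.name)}_change"
    change.attrs.update(hist.attrs)
    gm = float(gridio.global_mean(change))
    sd = gridio.global_std(change)
    return {"change": change, "global_mean": gm, "spatial_sd": sd}


def amplification(percentile_change: xr.DataArray, mean_change: xr.DataArray) -> xr.DataArray:
    """How much more the percentile shifts than the mean (per cell)."""
    out = percentile_change - mean_change
    out.name = "amplification"
    return out


def joint_distribution(
    x_percentiles: xr.DataArray,
    y_percentiles: xr.DataArray,
    coverage: float = 0.90,
    bins: int = 60,
    range_: tuple | None = None,
) -> dict:
    """Area-weighted 2-d histogram with a highest-density coverage region.

    The coverage region is the smallest set of bins (greatest density
    first) whose area-weighted count reaches the coverage fraction.
    Returns the histogram, bin edges and the boolean region.
    """
    x = np.asarray(x_percentiles.values).ravel()
    y = np.asarray(y_percentiles.values).ravel()
    lat = x_percentiles["lat"].values
    w = (np.cos(np.deg2rad(lat))[:, None] * np.ones((1, x_percentiles.shape[-1]))).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    if not np.any(ok):
        raise ValueError("empty domain")
    h, xe, ye = np.histogram2d(x[ok], y[ok], bins=bins, range=range_, weights=w[ok])
    h = h / h.sum()
    order = np.argsort(h, axis=None)[::-1]
    csum = np.cumsum(h.ravel()[order])
    k = int(np.searchsorted(csum, coverage)) + 1
    region = np.zeros(h.size, dtype=bool)
    region[order[:k]] = True
    # only populated bins belong to the region
    region &= h.ravel() > 0
    return {"hist": h, "x_edges": xe, "y_edges": ye,
            "region": region.reshape(h.shape)}


def region_overlap(
    period_a: tuple[xr.DataArray, xr.DataArray],
    period_b: tuple[xr.DataArray, xr.DataArray],
    coverage: float = 0.90,
    bins: int = 60,
) -> float:
    """Jaccard overlap of the two periods' coverage regions on shared bins.

    Identical periods give 1; a future shifted far beyond the historical
    spread gives ~0.
    """
    xs = np.concatenate([period_a[0].values.ravel(), period_b[0].values.ravel()])
    ys = np.concatenate([period_a[1].values.ravel(), period_b[1].values.ravel()])
    rng = ((np.nanmin(xs), np.nanmax(xs)), (np.nanmin(ys), np.nanmax(ys)))
    ra = joint_distribution(*period_a, coverage=coverage, bins=bins, range_=rng)["region"]
    rb = joint_distribution(*period_b, coverage=coverage, bins=bins, range_=rng)["region"]
    union = np.sum(ra | rb)
    if union == 0:
        return 1.0
    return float(np.sum(ra & rb) / union)


def site_report(
    mask_x: xr.Dataset, mask_y: xr.Dataset, sites: gridio.SiteSet
) -> pd.DataFrame:
    """Mutually exclusive stress-day categories per site, summing to 100%.

    Categories: extreme in X only, in Y only, in both, or neither.
    """
    latc = mask_x["lat"].values
    lonc = mask_x["lon"].values
    rows = []
    for _, row in sites.points.iterrows():
        i, j = gridio.nearest_cell(latc, lonc, float(row["lat"]), float(row["lon"]))
        mx = mask_x["mask"].values[:, i, j]
        my = mask_y["mask"].values[:, i, j]
        n = mx.size
        rows.append({
            "site": row["name"],
            "only_x": 100.0 * np.sum(mx & ~my) / n,
            "only_y": 100.0 * np.sum(~mx & my) / n,
            "both": 100.0 * np.sum(mx & my) / n,
            "neither": 100.0 * np.sum(~mx & ~my) / n,
        })
    df = pd.DataFrame(rows)
    df.attrs["x"] = str(mask_x.attrs.get("variable", "x"))
    df.attrs["y"] = str(mask_y.attrs.get("variable", "y"))
    return df
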