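"""Gridded-field containers, calendar helpers, netCDF I/O and site extraction.

Fields are :class:`xarray.DataArray` objects on a 365-day "noleap" calendar
with dimensions ``(time, lat, lon)``.  The time coordinate is decimal years,
``year + (doy - 0.5) / 365`` for daily data and the month-midpoint equivalent
for monthly data, with integer auxiliary coordinates ``year`` and ``doy`` (or
``month``).  Variable metadata lives in ``attrs``:

``units``
    physical units string (``degC``, ``mol/kg``, ``uatm``, ``1``).
``tail``
    which tail of the distribution is stressful: ``"upper"`` (SST, H+, pCO2)
    or ``"lower"`` (aragonite saturation state).
``calendar``
    always ``"noleap"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

DAYS_PER_YEAR = 365
MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
#: first day-of-year (0-based offset) of each month
MONTH_EDGES = np.concatenate([[0], np.cumsum(MONTH_LENGTHS)])
#: decimal day-of-year of each month's midpoint (1-based day centers)
MONTH_MIDPOINTS = (MONTH_EDGES[:-1] + MONTH_EDGES[1:] + 1) / 2.0

#: default tail direction per variable
VARIABLE_TAILS = {"sst": "upper", "hplus": "upper", "pco2": "upper", "omega": "lower"}
VARIABLE_UNITS = {"sst": "degC", "hplus": "mol/kg", "pco2": "uatm", "omega": "1"}


class CalendarError(ValueError):
    """Raised for calendars other than the 365-day noleap convention."""


def decimal_year_daily(years: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Daily decimal-year axis plus integer year/doy for a span of years."""
    years = np.asarray(years)
    yy = np.repeat(years, DAYS_PER_YEAR)
    doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), len(years))
    return yy + (doy - 0.5) / DAYS_PER_YEAR, yy, doy


def decimal_year_monthly(years: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Monthly (month-midpoint) decimal-year axis plus year/month integers."""
    years = np.asarray(years)
    yy = np.repeat(years, 12)
    mm = np.tile(np.arange(1, 13), len(years))
    return yy + (MONTH_MIDPOINTS[mm - 1] - 0.5) / DAYS_PER_YEAR, yy, mm


def daily_field(
    values: np.ndarray,
    years: np.ndarray,
    lat: np.ndarray,
    lon: np.ndarray,
    variable: str,
    units: str | None = None,
    tail: str | None = None,
) -> xr.DataArray:
    """Wrap a ``(time, lat, lon)`` array of daily values as a DailyField."""
    years = np.asarray(years)
    t, yy, doy = decimal_year_daily(years)
    if values.shape[0] != t.size:
        raise ValueError(
            f"expected {t.size} daily steps for years {years[0]}-{years[-1]}, "
            f"got {values.shape[0]}"
        )
    da = xr.DataArray(
        values,
        dims=("time", "lat", "lon"),
        coords={
            "time": t,
            "lat": np.asarray(lat, dtype=float),
            "lon": np.asarray(lon, dtype=float),
            "year": ("time", yy),
            "doy": ("time", doy),
        },
        name=variable,
    )
    da.attrs.update(
        units=units or VARIABLE_UNITS.get(variable, "1"),
        tail=tail or VARIABLE_TAILS.get(variable, "upper"),
        calendar="noleap",
        frequency="daily",
    )
    return da


def monthly_archive(
    values: np.ndarray,
    years: np.ndarray,
    lat: np.ndarray,
    lon: np.ndarray,
    variable: str,
    units: str | None = None,
    tail: str | None = None,
) -> xr.DataArray:
    """Wrap a ``(month, lat, lon)`` array of monthly means as a MonthlyArchive."""
    years = np.asarray(years)
    t, yy, mm = decimal_year_monthly(years)
    if values.shape[0] != t.size:
        raise ValueError(
            f"expected {t.size} months for years {years[0]}-{years[-1]}, "
            f"got {values.shape[0]}"
        )
    da = xr.DataArray(
        values,
        dims=("time", "lat", "lon"),
        coords={
            "time": t,
            "lat": np.asarray(lat, dtype=float),
            "lon": np.asarray(lon, dtype=float),
            "year": ("time", yy),
            "month": ("time", mm),
        },
        name=variable,
    )
    da.attrs.update(
        units=units or VARIABLE_UNITS.get(variable, "1"),
        tail=tail or VARIABLE_TAILS.get(variable, "upper"),
        calendar="noleap",
        frequency="monthly",
    )
    return da


def monthly_means_from_daily(daily: xr.DataArray) -> xr.DataArray:
    """Calendar-month means of a daily field, as a MonthlyArchive."""
    _validate_daily(daily)
    years = np.unique(daily["year"].values)
    v = daily.values.reshape(len(years), DAYS_PER_YEAR, *daily.shape[1:])
    out = np.empty((len(years), 12, *daily.shape[1:]), dtype=daily.dtype)
    for m in range(12):
        out[:, m] = v[:, MONTH_EDGES[m]:MONTH_EDGES[m + 1]].mean(axis=1)
    return monthly_archive(
        out.reshape(len(years) * 12, *daily.shape[1:]),
        years,
        daily["lat"].values,
        daily["lon"].values,
        daily.name,
        units=daily.attrs.get("units"),
        tail=daily.attrs.get("tail"),
    )


def _validate_daily(da: xr.DataArray) -> None:
    t = da["time"].values
    if t.size % DAYS_PER_YEAR != 0:
        raise CalendarError(
            f"unsupported calendar: daily field length {t.size} is not a "
            f"whole number of {DAYS_PER_YEAR}-day years"
        )
    if not np.all(np.diff(t) > 0):
        raise ValueError("time axis must be strictly increasing")


def _validate_monthly(da: xr.DataArray) -> None:
    t = da["time"].values
    if t.size % 12 != 0:
        raise ValueError("monthly archive must contain 12 entries per year")
    if not np.all(np.diff(t) > 0):
        raise ValueError("time axis must be strictly increasing")


def write_field(da: xr.DataArray, path) -> None:
    """Write a field to a netCDF classic-model file, one variable per file."""
    ds = da.to_dataset(name=da.name)
    ds["time"].attrs.update(units="decimal_year", calendar="noleap")
    ds.to_netcdf(path, format="NETCDF4_CLASSIC")


def read_field(path, variable: str | None = None) -> xr.DataArray:
    """Read a daily or monthly field written by :func:`write_field`.

    Rejects leap calendars and non-monotone time axes; round-trips values
    and metadata losslessly at 64-bit precision.
    """
    with xr.open_dataset(path, decode_times=False) as ds:
        ds = ds.load()
    cal = ds["time"].attrs.get("calendar", "")
    if cal not in ("noleap", "365_day"):
        raise CalendarError(f"unsupported calendar {cal!r}: expected 'noleap'")
    if variable is None:
        candidates = [v for v in ds.data_vars if set(ds[v].dims) == {"time", "lat", "lon"}]
        if len(candidates) != 1:
            raise ValueError(f"cannot infer variable among {list(ds.data_vars)}")
        variable = candidates[0]
    da = ds[variable]
    da.attrs.setdefault("calendar", "noleap")
    if da.attrs.get("frequency") == "daily" or "doy" in da.coords:
        _validate_daily(da)
    else:
        _validate_monthly(da)
    return da


def area_weights(lat_centers, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-cell area weights proportional to cos(latitude), normalized to 1.

    ``mask`` may flag cells (True = included); excluded or all-missing cells
    get weight zero.  Returns a ``(lat, lon)`` array when a mask is given or
    a ``(lat,)`` vector otherwise (normalized so that expanding across
    longitudes sums to 1).
    """
    lat = np.asarray(lat_centers, dtype=float)
    if np.any(np.abs(lat) > 90):
        raise ValueError("latitudes must lie in [-90, 90]")
    w = np.cos(np.deg2rad(lat))
    if mask is None:
        s = w.sum()
        if s <= 0:
            raise ValueError("all-missing domain: no positive weights")
        return w / s
    w2 = np.broadcast_to(w[:, None], mask.shape).copy()
    w2[~mask] = 0.0
    s = w2.sum()
    if s <= 0:
        raise ValueError("all-missing domain: no cells selected")
    return w2 / s


def global_mean(field: xr.DataArray | np.ndarray, lat_centers=None) -> float | np.ndarray:
    """Area-weighted global mean over (lat, lon), renormalizing around NaNs.

    Accepts a 2-d map or anything with trailing (lat, lon) dims; missing
    cells are dropped with weight renormalization.
    """
    if isinstance(field, xr.DataArray):
        lat = field["lat"].values if lat_centers is None else np.asarray(lat_centers)
        vals = field.values
    else:
        if lat_centers is None:
            raise ValueError("lat_centers required for plain arrays")
        lat = np.asarray(lat_centers)
        vals = np.asarray(field)
    w = np.cos(np.deg2rad(lat))[:, None] * np.ones((1, vals.shape[-1]))
    ok = np.isfinite(vals)
    wfull = np.broadcast_to(w, vals.shape)
    denom = np.where(ok, wfull, 0.0).sum(axis=(-2, -1))
    if np.any(denom <= 0):
        raise ValueError("all-missing domain in global mean")
    return np.where(ok, wfull * vals, 0.0).sum(axis=(-2, -1)) / denom


def global_std(field2d: np.ndarray | xr.DataArray, lat_centers=None) -> float:
    """Area-weighted spatial standard deviation of a 2-d map."""
    m = global_mean(field2d, lat_centers)
    if isinstance(field2d, xr.DataArray):
        lat = field2d["lat"].values if lat_centers is None else np.asarray(lat_centers)
        vals = field2d.values
    else:
        lat = np.asarray(lat_centers)
        vals = np.asarray(field2d)
    var = global_mean((vals - m) ** 2, lat)
    return float(np.sqrt(var))


@dataclass
class SiteSet:
    """Named point locations and/or named boolean cell masks.

    Points map to the nearest grid cell center (rectangular lat/lon
    distance; ties broken toward the lower index).
    """

    points: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["name", "lat", "lon"])
    )
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_csv(cls, path) -> "SiteSet":
        df = pd.read_csv(path)
        required = {"name", "lat", "lon"}
        if not required.issubset(df.columns):
            raise ValueError(f"site table must have columns {sorted(required)}")
        return cls(points=df[["name", "lat", "lon"]])


def nearest_cell(lat_centers, lon_centers, lat: float, lon: float) -> tuple[int, int]:
    """Index of the grid cell whose center is nearest (rectangular metric)."""
    latc = np.asarray(lat_centers, dtype=float)
    lonc = np.asarray(lon_centers, dtype=float)
    # half the largest grid spacing; a single-cell axis accepts any point
    half_lat = np.diff(latc).max() / 2 if latc.size > 1 else np.inf
    half_lon = np.diff(lonc).max() / 2 if lonc.size > 1 else np.inf
    if not (latc.min() - half_lat <= lat <= latc.max() + half_lat):
        raise ValueError(f"latitude {lat} outside grid bounds")
    if not (lonc.min() - half_lon <= lon <= lonc.max() + half_lon):
        raise ValueError(f"longitude {lon} outside grid bounds")
    # np.argmin returns the first (lower-index) minimizer, the documented tie-break
    return int(np.argmin(np.abs(latc - lat))), int(np.argmin(np.abs(lonc - lon)))


def extract_sites(field: xr.DataArray, sites: SiteSet):
    """Per-site time series for points; per-mask cell collections for masks.

    Returns ``(point_series, mask_cells)`` where ``point_series`` maps site
    name to a 1-d time series and ``mask_cells`` maps mask name to a
    ``(time, ncells)`` array of the flagged cells' series.
    """
    latc = field["lat"].values
    lonc = field["lon"].values
    series = {}
    for _, row in sites.points.iterrows():
        i, j = nearest_cell(latc, lonc, float(row["lat"]), float(row["lon"]))
        series[row["name"]] = field.isel(lat=i, lon=j)
    cells = {}
    for name, mask in sites.masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (latc.size, lonc.size):
            raise ValueError(f"mask {name!r} shape {mask.shape} does not match grid")
        cells[name] = field.values[..., mask]
    return series, cells
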