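"""Synthetic multi-scenario generator for daily/monthly ocean stressor fields.

Emulates the statistical structure the extreme-day analysis assumes from an
Earth-system model: per cell, each variable is

    value = mean(lat) + trend(t; scenario) + seasonal(lat, doy, t)
            + coupling * SST_anomaly + AR(1) noise,

on a 365-day noleap calendar.  Sea surface temperature (SST) is generated
first; the carbonate-system variables (H+, pCO2) couple positively and
aragonite saturation state (omega) negatively to the SST anomaly (seasonal
cycle plus noise), reproducing the observed anticorrelation of omega and SST
seasonality.  Scenario trajectories share a single trend until the
divergence year (default 2040) and then either relax to a plateau
(mitigation) or accelerate quadratically (high emissions).

Daily output covers two 40-year segments (historical and end-of-century);
a long monthly archive is produced directly at monthly resolution outside
those segments and as exact calendar-month means of the daily fields inside
them, so adaptive (rolling-baseline) thresholds have a deep past to draw on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from . import gridio
from .gridio import DAYS_PER_YEAR, MONTH_EDGES

VARIABLE_ORDER = ["sst", "hplus", "pco2", "omega"]


class UnknownScenarioError(KeyError):
    """Requested scenario label is not configured."""


@dataclass(frozen=True)
class LatProfile:
    """Linear-in-|latitude| profile between an equator and a pole value."""

    equator: float
    pole: float

    def __call__(self, lat: np.ndarray) -> np.ndarray:
        lat = np.asarray(lat, dtype=float)
        return self.equator + (self.pole - self.equator) * np.abs(lat) / 90.0


def _as_profile(x) -> LatProfile:
    if isinstance(x, LatProfile):
        return x
    return LatProfile(float(x), float(x))


@dataclass(frozen=True)
class TrendSpec:
    """Scenario trajectory: common ramp, then plateau or acceleration.

    The common trajectory is zero before ``ramp_start`` and linear at
    ``base_rate`` (units/decade) up to ``divergence_year``.  After
    divergence the ``plateau`` branch relaxes exponentially toward an extra
    ``plateau_rise`` (slope-continuous: timescale = rise / rate), while the
    ``accelerating`` branch adds ``accel`` (units/decade^2) quadratically.
    All branches are continuous across the divergence year.
    """

    base_rate: float = 0.0
    ramp_start: float = 1950.0
    divergence_year: float = 2040.0
    plateau_rise: float = 0.0
    accel: float = 0.0

    def value(self, t, kind: str) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        r = self.base_rate / 10.0
        d = self.divergence_year
        f = r * np.clip(t - self.ramp_start, 0.0, None)
        if kind == "linear":
            return f
        fd = r * (d - self.ramp_start)
        dt = np.clip(t - d, 0.0, None)
        if kind == "plateau":
            if self.plateau_rise == 0.0 or r == 0.0:
                post = fd
            else:
                tau = self.plateau_rise / r
                post = fd + self.plateau_rise * (1.0 - np.exp(-dt / tau))
            return np.where(t <= d, f, post)
        if kind == "accelerating":
            post = fd + r * dt + (self.accel / 100.0) * dt**2
            return np.where(t <= d, f, post)
        raise ValueError(f"unknown trend kind {kind!r}")


@dataclass(frozen=True)
class VariableSpec:
    """Statistical description of one stressor variable.

    ``seasonal_phase`` is the day-of-year of the seasonal maximum in the
    northern hemisphere; with ``antiphase_south`` the southern-hemisphere
    phase is shifted by half a year.  ``amplitude_trend`` grows the seasonal
    amplitude by a fraction per decade after the trend's ramp start.
    ``coupling`` multiplies the SST anomaly (seasonal + noise).
    """

    mean: LatProfile
    trend: TrendSpec
    seasonal_amplitude: LatProfile
    seasonal_phase: float = 196.0
    antiphase_south: bool = True
    amplitude_trend: float = 0.0
    ar1_rho: float = 0.0
    noise_sd: float = 0.0
    coupling: float = 0.0
    units: str = "1"
    tail: str = "upper"

    def __post_init__(self):
        object.__setattr__(self, "mean", _as_profile(self.mean))
        object.__setattr__(
            self, "seasonal_amplitude", _as_profile(self.seasonal_amplitude)
        )
        if not abs(self.ar1_rho) < 1:
            raise ValueError("|ar1_rho| must be < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of a synthetic multi-variable, multi-scenario world."""

    lat: np.ndarray
    lon: np.ndarray
    variables: dict[str, VariableSpec]
    years_daily_hist: tuple[int, int] = (1975, 2014)
    years_daily_future: tuple[int, int] = (2061, 2100)
    years_monthly: tuple[int, int] = (1850, 2100)
    scenario_kinds: dict[str, str] = field(
        default_factory=lambda: {
            "historical": "linear",
            "mitigation": "plateau",
            "high": "accelerating",
        }
    )
    rng_seed: int = 0

    def validate(self) -> None:
        if gridio.MONTH_LENGTHS.sum() != DAYS_PER_YEAR:
            raise AssertionError("noleap month lengths must sum to 365")
        for name in self.variables:
            if name not in VARIABLE_ORDER:
                raise ValueError(f"unknown variable {name!r}")
        if self.years_monthly[0] > self.years_daily_hist[0]:
            raise ValueError("monthly archive must start before the daily segments")


def default_config(seed: int = 0) -> ScenarioConfig:
    """Default 10 x 20 cell world with realistic stressor magnitudes.

    Means are preindustrial baselines; trends give end-of-century anomalies
    of roughly +1.8 degC (mitigation) / +3.1 degC (high) for SST, ~455 /
    ~650 uatm pCO2, and omega declines of ~0.75 / ~1.4, in line with
    strongly-mitigating vs high-emission pathway magnitudes.
    """
    lat = np.linspace(-63.0, 63.0, 10)
    lon = np.linspace(9.0, 351.0, 20)
    variables = {
        "sst": VariableSpec(
            mean=LatProfile(28.0, -2.0),
            trend=TrendSpec(base_rate=0.15, plateau_rise=0.45, accel=0.024),
            seasonal_amplitude=LatProfile(1.0, 6.0),
            ar1_rho=0.85,
            noise_sd=0.4,
            units="degC",
            tail="upper",
        ),
        "hplus": VariableSpec(
            mean=LatProfile(6.8e-9, 6.8e-9),
            trend=TrendSpec(base_rate=6e-10, plateau_rise=1.8e-9, accel=1.6e-10),
            seasonal_amplitude=LatProfile(0.0, 0.0),
            ar1_rho=0.85,
            noise_sd=2e-10,
            coupling=2e-10,
            units="mol/kg",
            tail="upper",
        ),
        "pco2": VariableSpec(
            mean=LatProfile(280.0, 280.0),
            trend=TrendSpec(base_rate=15.0, plateau_rise=45.0, accel=4.0),
            seasonal_amplitude=LatProfile(10.0, 10.0),
            amplitude_trend=0.03,
            ar1_rho=0.85,
            noise_sd=4.0,
            coupling=9.0,
            units="uatm",
            tail="upper",
        ),
        "omega": VariableSpec(
            mean=LatProfile(4.0, 1.6),
            trend=TrendSpec(base_rate=-0.07, plateau_rise=-0.1, accel=-0.01),
            seasonal_amplitude=LatProfile(0.0, 0.0),
            ar1_rho=0.9,
            noise_sd=0.04,
            coupling=-0.05,
            units="1",
            tail="lower",
        ),
    }
    return ScenarioConfig(lat=lat, lon=lon, variables=variables, rng_seed=seed)


def ph_to_hplus(ph):
    """Hydrogen-ion concentration (mol/kg) from pH: ``10**(-pH)``.

    Vectorizes over arrays; non-finite inputs propagate as missing (NaN);
    finite values outside (0, 14) raise.
    """
    ph = np.asarray(ph, dtype=float)
    finite = np.isfinite(ph)
    if np.any((ph[finite] <= 0) | (ph[finite] >= 14)):
        raise ValueError("pH must lie in (0, 14)")
    out = np.where(finite, np.power(10.0, -np.where(finite, ph, 0.0)), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# noise streams
# ---------------------------------------------------------------------------


def _rng(seed: int, var: str, stream: int) -> np.random.Generator:
    # spawn keys fixed by variable identity so adding a variable never
    # reshuffles another variable's stream
    idx = VARIABLE_ORDER.index(var)
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(idx, stream))
    return np.random.Generator(np.random.PCG64(ss))


def _ar1(rng, rho: float, sd: float, shape: tuple[int, ...]) -> np.ndarray:
    """Stationary AR(1) series along axis 0 with marginal sd ``sd``."""
    if sd == 0.0:
        return np.zeros(shape)
    x0 = rng.normal(0.0, sd, size=shape[1:])
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), size=shape)
    zi = (rho * x0)[None]
    y, _ = lfilter([1.0], [1.0, -rho], eps, axis=0, zi=zi)
    return y


def monthly_mean_sd(rho: float, sd: float, n: int = 30) -> float:
    """Standard deviation of an n-day mean of a stationary AR(1) process."""
    if sd == 0.0:
        return 0.0
    k = np.arange(1, n)
    var = sd**2 * (n + 2.0 * np.sum((n - k) * rho**k)) / n**2
    return float(np.sqrt(var))


def _daily_noise(config: ScenarioConfig, var: str) -> tuple[np.ndarray, np.ndarray]:
    """AR(1) daily noise over both daily segments (hist then future).

    Generated once per variable from a label-independent stream so every
    scenario shares it bitwise.  The AR recursion restarts (stationary
    draw) at the future segment boundary.
    """
    spec = config.variables[var]
    shape2 = (len(config.lat), len(config.lon))
    ny_h = config.years_daily_hist[1] - config.years_daily_hist[0] + 1
    ny_f = config.years_daily_future[1] - config.years_daily_future[0] + 1
    rng = _rng(config.rng_seed, var, 0)
    hist = _ar1(rng, spec.ar1_rho, spec.noise_sd, (ny_h * DAYS_PER_YEAR, *shape2))
    fut = _ar1(rng, spec.ar1_rho, spec.noise_sd, (ny_f * DAYS_PER_YEAR, *shape2))
    return hist, fut


def _monthly_noise(config: ScenarioConfig, var: str) -> np.ndarray:
    """Direct monthly-resolution noise over the full archive span.

    Matches the variance of a 30-day mean of the daily AR(1) process and
    carries the (usually tiny) residual month-to-month autocorrelation
    ``rho**(365/12)``.
    """
    spec = config.variables[var]
    ny = config.years_monthly[1] - config.years_monthly[0] + 1
    shape = (ny * 12, len(config.lat), len(config.lon))
    rho_m = spec.ar1_rho ** (365.0 / 12.0)
    sd_m = monthly_mean_sd(spec.ar1_rho, spec.noise_sd)
    rng = _rng(config.rng_seed, var, 1)
    return _ar1(rng, rho_m, sd_m, shape)


# ---------------------------------------------------------------------------
# deterministic structure
# ---------------------------------------------------------------------------


def _phase(spec: VariableSpec, lat: np.ndarray) -> np.ndarray:
    p = np.full(len(lat), spec.seasonal_phase)
    if spec.antiphase_south:
        p = np.where(np.asarray(lat) < 0, spec.seasonal_phase + DAYS_PER_YEAR / 2.0, p)
    return p


def _seasonal(spec: VariableSpec, lat, t, doy) -> np.ndarray:
    """Seasonal cycle (time, lat) with optional amplitude growth."""
    amp0 = spec.seasonal_amplitude(lat)
    growth = 1.0 + spec.amplitude_trend * np.clip(
        np.asarray(t) - spec.trend.ramp_start, 0.0, None
    ) / 10.0
    growth = np.clip(growth, 0.0, None)
    phase = _phase(spec, lat)
    cyc = np.cos(2.0 * np.pi * (np.asarray(doy)[:, None] - phase[None, :]) / DAYS_PER_YEAR)
    return amp0[None, :] * growth[:, None] * cyc


def _deterministic_daily(
    config: ScenarioConfig, var: str, kind: str, years: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(mean+trend, seasonal) parts at daily resolution, shapes (t, lat)."""
    spec = config.variables[var]
    t, _, doy = gridio.decimal_year_daily(years)
    base = spec.mean(config.lat)[None, :] + spec.trend.value(t, kind)[:, None]
    return base, _seasonal(spec, config.lat, t, doy)


def _monthly_average_daily(arr: np.ndarray, nyears: int) -> np.ndarray:
    """Calendar-month means along axis 0 of a (nyears*365, ...) array."""
    v = arr.reshape(nyears, DAYS_PER_YEAR, *arr.shape[1:])
    out = np.empty((nyears, 12, *arr.shape[1:]))
    for m in range(12):
        out[:, m] = v[:, MONTH_EDGES[m]:MONTH_EDGES[m + 1]].mean(axis=1)
    return out.reshape(nyears * 12, *arr.shape[1:])


# ---------------------------------------------------------------------------
# top-level generation
# ---------------------------------------------------------------------------


def generate_scenario(config: ScenarioConfig, scenario_label: str) -> dict:
    """Generate all variables for one scenario.

    Returns ``{var: {"daily": DailyField, "monthly": MonthlyArchive}}``.
    Daily fields cover the historical segment for the ``historical`` label
    and the future segment otherwise; the monthly archive runs from the
    archive start to the end of the scenario's coverage, with archive months
    equal to exact calendar-month means of the daily field wherever both
    exist.  Identical config and seed give bit-identical output, and
    scenarios are bitwise identical before the divergence year.
    """
    config.validate()
    if scenario_label not in config.scenario_kinds:
        raise UnknownScenarioError(
            f"unknown scenario {scenario_label!r}; configured: "
            f"{sorted(config.scenario_kinds)}"
        )
    kind = config.scenario_kinds[scenario_label]
    historical = scenario_label == "historical"
    seg = config.years_daily_hist if historical else config.years_daily_future
    seg_years = np.arange(seg[0], seg[1] + 1)
    arch_end = config.years_daily_hist[1] if historical else config.years_monthly[1]
    arch_years = np.arange(config.years_monthly[0], arch_end + 1)

    nlat, nlon = len(config.lat), len(config.lon)
    variables = [v for v in VARIABLE_ORDER if v in config.variables]

    # daily and monthly noise, label-independent
    dnoise = {}
    mnoise = {}
    for var in variables:
        hist_n, fut_n = _daily_noise(config, var)
        dnoise[var] = hist_n if historical else fut_n
        full = _monthly_noise(config, var)
        mnoise[var] = full[: len(arch_years) * 12]

    t_m, _, month = gridio.decimal_year_monthly(arch_years)
    out = {}
    sst_anom_daily = None
    sst_anom_monthly = None
    for var in variables:
        spec = config.variables[var]
        base_d, seas_d = _deterministic_daily(config, var, kind, seg_years)
        daily_vals = (
            base_d[:, :, None]
            + seas_d[:, :, None]
            + np.broadcast_to(dnoise[var], (len(seg_years) * DAYS_PER_YEAR, nlat, nlon))
        ).copy()
        # monthly deterministic structure: month-means of the daily formula
        base_m_full, seas_m_full = _deterministic_daily(config, var, kind, arch_years)
        base_m = _monthly_average_daily(base_m_full, len(arch_years))
        seas_m = _monthly_average_daily(seas_m_full, len(arch_years))
        monthly_vals = base_m[:, :, None] + seas_m[:, :, None] + mnoise[var]

        anom_d = seas_d[:, :, None] + dnoise[var]
        anom_m = seas_m[:, :, None] + mnoise[var]
        if var == "sst":
            sst_anom_daily = anom_d
            sst_anom_monthly = anom_m
        elif spec.coupling != 0.0:
            daily_vals += spec.coupling * sst_anom_daily
            monthly_vals = monthly_vals + spec.coupling * sst_anom_monthly

        daily = gridio.daily_field(
            daily_vals, seg_years, config.lat, config.lon, var,
            units=spec.units, tail=spec.tail,
        )
        # exact consistency on overlap years: overwrite with daily month-means
        monthly_vals = np.asarray(monthly_vals)
        in_seg = (t_m >= seg_years[0]) & (t_m < seg_years[-1] + 1)
        monthly_vals[in_seg] = _monthly_average_daily(daily_vals, len(seg_years))
        monthly = gridio.monthly_archive(
            monthly_vals, arch_years, config.lat, config.lon, var,
            units=spec.units, tail=spec.tail,
        )
        out[var] = {"daily": daily, "monthly": monthly}
    return out


def with_seed(config: ScenarioConfig, seed: int) -> ScenarioConfig:
    """Copy of ``config`` with a different master seed."""
    return replace(config, rng_seed=seed)
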