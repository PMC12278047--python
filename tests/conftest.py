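import numpy as np
import pytest
from hypothesis import settings

from seastress import synthetic
from seastress.gridio import daily_field
from seastress.synthetic import (
    LatProfile,
    ScenarioConfig,
    TrendSpec,
    VariableSpec,
    generate_scenario,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


def small_config(seed=0, nlat=3, nlon=4, variables=None, **kwargs):
    """Tiny synthetic world for fast unit tests."""
    if variables is None:
        variables = {
            "sst": VariableSpec(
                mean=LatProfile(20.0, 10.0),
                trend=TrendSpec(base_rate=0.15, plateau_rise=0.45, accel=0.024),
                seasonal_amplitude=LatProfile(2.0, 4.0),
                ar1_rho=0.8,
                noise_sd=0.5,
                units="degC",
                tail="upper",
            )
        }
    return ScenarioConfig(
        lat=np.linspace(-60.0, 60.0, nlat),
        lon=np.linspace(0.0, 330.0, nlon),
        variables=variables,
        rng_seed=seed,
        **kwargs,
    )


def make_daily(values, years=(2000, 2000), lat=(0.0,), lon=(0.0,), variable="sst",
               tail="upper"):
    """Wrap a raw (time[, lat, lon]) array as a DailyField on a tiny grid."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None, None]
    yy = np.arange(years[0], years[1] + 1)
    return daily_field(values, yy, np.asarray(lat), np.asarray(lon), variable,
                       tail=tail)


@pytest.fixture(scope="session")
def world():
    """Default-configuration scenarios (the study conditions), seed 1."""
    cfg = synthetic.default_config(1)
    return {
        "config": cfg,
        "historical": generate_scenario(cfg, "historical"),
        "mitigation": generate_scenario(cfg, "mitigation"),
        "high": generate_scenario(cfg, "high"),
    }
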