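import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dendrowue.synthetic import (  # noqa: E402
    ClimateNoise,
    GrowthParams,
    SiteConfig,
    gen_daily_climate,
    gen_tree_rings,
)

NOISELESS = ClimateNoise(
    sigma_t_daily=0.0,
    sigma_t_annual=0.0,
    sigma_hr=0.0,
    sigma_rh_daily=0.0,
    sigma_rh_annual=0.0,
)


@pytest.fixture(scope="session")
def site():
    return SiteConfig("TST", 45.0, 1000.0, 9.0, 900.0)


@pytest.fixture(scope="session")
def climate_50y(site):
    """One seeded 50-year daily climate table reused across tests."""
    return gen_daily_climate(site, (1965, 2014), seed=7)


@pytest.fixture(scope="session")
def monthly_50y(climate_50y):
    from dendrowue.climate import monthly_aggregate

    return monthly_aggregate(climate_50y, 45.0)


@pytest.fixture(scope="session")
def stand_20(site):
    """20 even-aged trees (germinated 1945) with moderate climate signal."""
    clim = gen_daily_climate(site, (1945, 2014), seed=11)
    gp = GrowthParams(beta_t=0.08, beta_vpd=-0.13, beta_p=0.04, phi=0.3, sigma=0.15)
    return clim, gen_tree_rings(clim, gp, 20, [1945] * 20, seed=12)
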