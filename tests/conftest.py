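import numpy as np
import pandas as pd
import pytest

from cancerburden import SimulationConfig, simulate_inputs
from cancerburden.bands import SITE_SCHEMAS, STAGES


@pytest.fixture(scope="session")
def default_bundle():
    """Default synthetic registry bundle, fixed seed."""
    return simulate_inputs(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_bundle():
    """Small fast bundle for end-to-end checks."""
    cfg = SimulationConfig(seed=7, n_counties=5, years=(2015, 2020),
                           population_scale=80_000.0)
    return simulate_inputs(cfg)


def random_staged_incidence(rng, n_counties=10, sites=("BC", "CxCa", "OC", "CRC"),
                            years=(2010, 2015, 2018, 2019)) -> pd.DataFrame:
    """Random staged incidence table covering every band and stage."""
    rows = []
    for c in range(n_counties):
        for site in sites:
            sex = "female" if site in ("BC", "CxCa") else "all"
            for lo, hi in SITE_SCHEMAS[site].bands:
                for year in years:
                    for stage in STAGES:
                        rows.append({
                            "county": f"C{c:02d}", "cancer_site": site, "sex": sex,
                            "year": year, "age_lo": lo, "age_hi": hi,
                            "kind": "incidence", "stage": stage,
                            "count": float(rng.gamma(2.0, 10.0)),
                        })
    return pd.DataFrame(rows)


def random_deaths(rng, n_counties=12, sites=("BC", "CxCa", "OC", "CRC"),
                  years=(2010, 2015, 2018, 2019, 2020)) -> pd.DataFrame:
    rows = []
    for c in range(n_counties):
        for site in sites:
            sex = "female" if site in ("BC", "CxCa") else "all"
            for lo, hi in SITE_SCHEMAS[site].bands:
                for year in years:
                    rows.append({
                        "county": f"C{c:02d}", "cancer_site": site, "sex": sex,
                        "year": year, "age_lo": lo, "age_hi": hi,
                        "kind": "deaths", "count": float(rng.poisson(25.0)),
                    })
    return pd.DataFrame(rows)
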