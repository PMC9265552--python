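import pandas as pd
import pytest

from hetspot import standardization as st
from hetspot import synthetic_county as sc


@pytest.fixture(scope="session")
def small_null_county():
    """A ~50-village county with no planted clusters (RR=1 everywhere)."""
    return sc.generate(sc.small_config(seed=11))


@pytest.fixture(scope="session")
def small_cluster_county():
    """A ~50-village county with one RR=5 cluster centered at (5000, 5000)."""
    cfg = sc.small_config(
        seed=7, rr_clusters=(sc.RRCluster((5000.0, 5000.0), 1500.0, 5.0),)
    )
    return sc.generate(cfg)


def expected_background(county):
    """Standardization chain: village pops -> standard rates -> background."""
    vpop = county.village_pop()
    rates = st.compute_standard_rates(county.cases_by_stratum(), vpop.sum(axis=0))
    exp = st.compute_expected_cases(vpop, rates, county.cases_by_village())
    bg = st.expected_surface(exp, county.partition, county.population.total_surface())
    return exp, bg


@pytest.fixture(scope="session")
def null_background(small_null_county):
    return expected_background(small_null_county)


@pytest.fixture(scope="session")
def cluster_background(small_cluster_county):
    return expected_background(small_cluster_county)


# The printed reference rate table: label -> (gender, 5-year cases, population).
REFERENCE_ROWS = {
    "M0-34": ("male", 56, 132_002),
    "M35-44": ("male", 221, 50_022),
    "M45-54": ("male", 365, 39_633),
    "M55-64": ("male", 648, 30_662),
    "M65-74": ("male", 550, 15_604),
    "M75+": ("male", 287, 6_565),
    "F0-44": ("female", 126, 157_764),
    "F45-54": ("female", 183, 38_891),
    "F55-64": ("female", 310, 29_847),
    "F65-79": ("female", 435, 20_262),
    "F80+": ("female", 115, 3_547),
}

REFERENCE_CRUDE_RATES = {
    "M0-34": 42.42,
    "M35-44": 441.81,
    "M45-54": 920.95,
    "M55-64": 2113.37,
    "M65-74": 3524.74,
    "M75+": 4371.67,
    "F0-44": 79.87,
    "F45-54": 470.55,
    "F55-64": 1038.63,
    "F65-79": 2146.88,
    "F80+": 3242.18,
}

ANNUAL_COUNTS = {2009: 457, 2010: 725, 2011: 657, 2012: 746, 2013: 711}
TOTAL_CASES = 3296


@pytest.fixture()
def reference_table():
    cases = pd.Series({k: v[1] for k, v in REFERENCE_ROWS.items()}, dtype=float)
    pop = pd.Series({k: v[2] for k, v in REFERENCE_ROWS.items()}, dtype=float)
    return cases, pop
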