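"""Crude rates and indirect gender-age standardization.

Cancer risk rises steeply with age and differs by sex, so raw case counts
mostly map demography.  Indirect standardization removes that: county-wide
stratum-specific rates ("standard rates") are applied to each village's
stratum populations to get the cases the village *would* record if it
behaved like the county average.  The observed/expected ratio is the
standardized incidence ratio (SIR), and the expected-case raster is the
heterogeneous background every later stage is measured against.

Rates are carried internally as proportions; the per-100,000 scaling is
presentation only.  The defining property of the construction — county
totals of expected and observed cases agree exactly whenever the standard
rates come from the pooled data — is enforced by the tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import Surface
from .spatial_prep import VillagePartition, rasterize_by_village

__all__ = [
    "compute_crude_rates",
    "merge_strata_by_rate",
    "compute_standard_rates",
    "compute_expected_cases",
    "expected_surface",
    "PER_100K",
]

PER_100K = 100_000.0


def compute_crude_rates(cases_by_stratum, pop_by_stratum) -> pd.DataFrame:
    """Stratum crude rates per 100,000.

    Parameters are mappings or Series keyed by stratum label.  Returns a
    DataFrame indexed by stratum with columns ``cases``, ``population``,
    ``crude_rate`` (per 100,000) and ``rate`` (proportion).
    """
    cases = pd.Series(cases_by_stratum, dtype=float)
    pop = pd.Series(pop_by_stratum, dtype=float).reindex(cases.index)
    if pop.isna().any():
        raise ValueError("population missing for some strata")
    bad = (pop <= 0) & (cases > 0)
    if bad.any():
        raise ValueError(
            f"strata with cases but no population: {list(cases.index[bad])}"
        )
    rate = np.where(pop > 0, cases / pop.replace(0, np.nan), 0.0)
    rate = pd.Series(np.nan_to_num(rate), index=cases.index)
    return pd.DataFrame(
        {
            "cases": cases,
            "population": pop,
            "rate": rate,
            "crude_rate": rate * PER_100K,
        }
    )


def merge_strata_by_rate(
    table: pd.DataFrame, ratio_threshold: float = 1.5
) -> pd.DataFrame:
    """Greedily merge contiguous age bands with similar crude rates.

    ``table`` must be a crude-rate table (as from :func:`compute_crude_rates`)
    whose index is ordered by age within each gender; an optional ``gender``
    column restricts merging to within-gender runs.  Adjacent bands are
    merged while the larger/smaller ratio of their crude rates is below
    ``ratio_threshold``; merged cases and populations are summed and the
    rate recomputed.  This mirrors forming coarse gender-age groups by
    pooling five-year bands with similar risk.
    """
    if ratio_threshold <= 1.0:
        raise ValueError("ratio_threshold must exceed 1")
    if table.empty:
        raise ValueError("empty rate table")
    gender = table["gender"] if "gender" in table.columns else pd.Series(
        "all", index=table.index
    )
    groups: list[dict] = []
    for _, sub in table.groupby(gender, sort=False):
        current = None
        for label, row in sub.iterrows():
            if current is None:
                current = {
                    "labels": [label],
                    "cases": row["cases"],
                    "population": row["population"],
                    "gender": gender.loc[label],
                }
            else:
                r_cur = current["cases"] / max(current["population"], 1.0)
                r_new = row["cases"] / max(row["population"], 1.0)
                lo, hi = sorted([r_cur, r_new])
                similar = lo <= 0 and hi <= 0 or (lo > 0 and hi / lo < ratio_threshold)
                if similar:
                    current["labels"].append(label)
                    current["cases"] += row["cases"]
                    current["population"] += row["population"]
                else:
                    groups.append(current)
                    current = {
                        "labels": [label],
                        "cases": row["cases"],
                        "population": row["population"],
                        "gender": gender.loc[label],
                    }
        if current is not None:
            groups.append(current)
    labels = ["+".join(map(str, g["labels"])) for g in groups]
    out = compute_crude_rates(
        {l: g["cases"] for l, g in zip(labels, groups)},
        {l: g["population"] for l, g in zip(labels, groups)},
    )
    out["gender"] = [g["gender"] for g in groups]
    return out


def compute_standard_rates(
    county_cases_by_stratum, county_pop_by_stratum
) -> pd.DataFrame:
    """County-wide stratum rates used as the indirect-standardization benchmark.

    Numerically identical to crude rates on the pooled county totals; kept
    as a distinct operation because downstream stages depend on the *pooled*
    provenance (it is what makes Σ expected = Σ observed hold).
    """
    return compute_crude_rates(county_cases_by_stratum, county_pop_by_stratum)


def compute_expected_cases(
    village_pop_by_stratum: pd.DataFrame,
    standard_rates: pd.DataFrame,
    observed_by_village,
) -> pd.DataFrame:
    """Indirectly standardized expected cases and SIR per village.

    Parameters
    ----------
    village_pop_by_stratum : DataFrame
        Villages × strata population counts (wide).
    standard_rates : DataFrame
        Output of :func:`compute_standard_rates`; its ``rate`` column (a
        proportion) is applied stratum-wise.
    observed_by_village : mapping/Series
        Total observed cases per village.

    Returns a DataFrame indexed by village with columns ``observed``,
    ``expected``, ``population`` and ``sir`` (NaN where expected is 0).
    """
    pop = village_pop_by_stratum
    missing = set(pop.columns) - set(standard_rates.index)
    if missing:
        raise ValueError(f"no standard rate for strata: {sorted(missing)[:5]}")
    rates = standard_rates["rate"].reindex(pop.columns)
    expected = pop.to_numpy(dtype=float) @ rates.to_numpy(dtype=float)
    observed = pd.Series(observed_by_village, dtype=float).reindex(pop.index)
    if observed.isna().any():
        raise ValueError("observed cases missing for some villages")
    expected = pd.Series(expected, index=pop.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        sir = observed / expected
    sir[expected == 0] = np.nan
    return pd.DataFrame(
        {
            "observed": observed,
            "expected": expected,
            "population": pop.sum(axis=1),
            "sir": sir,
        }
    )


def expected_surface(
    expected_cases: pd.DataFrame,
    partition: VillagePartition,
    population: Surface,
) -> Surface:
    """Rasterize village expected cases onto the analysis grid.

    Within each village the expected mass is apportioned to cells in
    proportion to their population, so the background raster puts expected
    risk where people actually live.  Totals are conserved per village and
    county-wide.
    """
    bad = expected_cases.index[
        (expected_cases["expected"] > 0) & (expected_cases["population"] <= 0)
    ]
    if len(bad):
        raise ValueError(f"villages with expected cases but zero population: {list(bad)[:5]}")
    return rasterize_by_village(
        expected_cases["expected"].to_dict(), partition, population.grid, population
    )
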