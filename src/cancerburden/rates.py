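"""Age-specific and directly age-standardized rates per 100,000.

Crude comparisons across counties confound incidence/mortality/burden with
age structure; direct standardization re-weights the age-specific rates by
a fixed standard population so every county is scored against the same age
composition.  The default standard is the WHO world standard population's
5-year weights, shipped with the package and collapsed onto each cancer's
coarse surveillance bands (then renormalized to sum exactly to one).
"""

from __future__ import annotations

import importlib.resources
import math

import numpy as np
import pandas as pd

from .bands import AgeBandSchema, SITE_SCHEMAS
from .tables import (
    BAND_KEY,
    RATE_COLUMNS,
    TableValidationError,
    validate_population_table,
    validate_rate_table,
    validate_standard_population,
)

__all__ = [
    "load_who_standard",
    "collapse_standard_to_schema",
    "standard_for_sites",
    "age_specific_rate",
    "age_standardized_rate",
    "PER_100K",
]

PER_100K = 100_000.0

_GROUP_KEY = ["county", "cancer_site", "sex", "year", "measure"]

#: event 'kind' -> rate 'measure'
_KIND_TO_MEASURE = {"incidence": "incidence", "deaths": "mortality"}


def load_who_standard() -> pd.DataFrame:
    """WHO world standard population weights in 5-year bands (fractions)."""
    ref = importlib.resources.files("cancerburden.data") / "who_standard_population.csv"
    with importlib.resources.as_file(ref) as path:
        std = pd.read_csv(path)
    std["age_hi"] = std["age_hi"].fillna(math.inf)
    return std


def collapse_standard_to_schema(std: pd.DataFrame, schema: AgeBandSchema) -> pd.DataFrame:
    """Sum fine-grained standard weights into a schema's bands, then normalize.

    Each fine band is assigned to the schema band containing its lower
    bound; normalization happens after collapsing so the working weights
    always sum to exactly one even if the source weights carry rounding
    (the published WHO weights sum to 1.0003).
    """
    lowers = schema.lowers
    idx = np.searchsorted(lowers, std["age_lo"].to_numpy(float), side="right") - 1
    if (idx < 0).any():
        raise TableValidationError("standard population has bands below the schema")
    out = pd.DataFrame({
        "age_lo": lowers[idx],
        "age_hi": schema.uppers[idx],
        "weight": std["weight"].to_numpy(float),
    })
    out = out.groupby(BAND_KEY, as_index=False)["weight"].sum()
    out["weight"] /= out["weight"].sum()
    out = out.sort_values("age_lo", ignore_index=True)
    return validate_standard_population(out)


def standard_for_sites(sites: list[str] | None = None,
                       std: pd.DataFrame | None = None) -> pd.DataFrame:
    """Standard-population weights per cancer site, on each site's schema.

    Returns a frame with a ``cancer_site`` column, suitable for
    :func:`age_standardized_rate` over mixed-site rate tables.
    """
    if std is None:
        std = load_who_standard()
    sites = list(SITE_SCHEMAS) if sites is None else sites
    parts = []
    for site in sites:
        part = collapse_standard_to_schema(std, SITE_SCHEMAS[site])
        part.insert(0, "cancer_site", site)
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def _numerator_long(numerator: pd.DataFrame) -> pd.DataFrame:
    """Normalize an event or burden table to (stratum, measure, value)."""
    if "kind" in numerator.columns:
        out = numerator.rename(columns={"count": "value"}).copy()
        out["measure"] = out.pop("kind").map(_KIND_TO_MEASURE)
        if out["measure"].isna().any():
            raise TableValidationError("unknown event kind in rate numerator")
        return out
    if "daly" in numerator.columns:
        out = numerator.copy()
        out["measure"] = "daly"
        out["value"] = out["daly"].astype(float)
        return out
    raise TableValidationError(
        "rate numerator must be an event table (kind/count) or burden table (daly)"
    )


def age_specific_rate(numerator: pd.DataFrame, population: pd.DataFrame) -> pd.DataFrame:
    """Events (or DALYs) per 100,000 mid-year population, by age band.

    Female-only sites carry ``sex = 'female'`` through the stratum key, so
    their denominators are the female population.  A stratum whose
    population is missing or zero is a hard error — silent zeros would mask
    a broken join.
    """
    validate_population_table(population)
    num = _numerator_long(numerator)
    merged = num.merge(
        population[["county", "sex", "year", "age_lo", "age_hi", "population"]],
        on=["county", "sex", "year", "age_lo", "age_hi"],
        how="left", validate="many_to_one",
    )
    bad = merged["population"].isna() | (merged["population"] <= 0)
    if bad.any():
        row = merged.loc[bad].iloc[0]
        raise TableValidationError(
            "no (positive) mid-year population for stratum "
            f"(county={row['county']}, sex={row['sex']}, year={row['year']}, "
            f"band={row['age_lo']:g}-{row['age_hi']:g})"
        )
    merged["rate"] = merged["value"].astype(float) / merged["population"] * PER_100K
    out = merged[RATE_COLUMNS].sort_values(_GROUP_KEY + BAND_KEY, ignore_index=True)
    return validate_rate_table(out)


def age_standardized_rate(age_rates: pd.DataFrame, std: pd.DataFrame) -> pd.DataFrame:
    """Directly standardized rate: sum of age-specific rates x standard weights.

    ``std`` carries weights per band, optionally per ``cancer_site`` (use
    :func:`standard_for_sites` when the rate table mixes cancers whose band
    schemas differ).  Weights must cover every band present and sum to one
    within each site.  Output rows have no age band (``age_lo/age_hi`` NaN).
    """
    validate_rate_table(age_rates)
    site_specific = "cancer_site" in std.columns
    if site_specific:
        for site, grp in std.groupby("cancer_site"):
            validate_standard_population(grp[BAND_KEY + ["weight"]],
                                         name=f"standard population [{site}]")
        merged = age_rates.merge(std, on=["cancer_site"] + BAND_KEY, how="left")
    else:
        validate_standard_population(std[BAND_KEY + ["weight"]])
        merged = age_rates.merge(std[BAND_KEY + ["weight"]], on=BAND_KEY, how="left")
    miss = merged["weight"].isna()
    if miss.any():
        row = merged.loc[miss].iloc[0]
        raise TableValidationError(
            f"standard population has no weight for band "
            f"{row['age_lo']:g}-{row['age_hi']:g} (site {row['cancer_site']})"
        )
    merged["rate"] = merged["rate"] * merged["weight"]
    out = merged.groupby(_GROUP_KEY, as_index=False)["rate"].sum()
    out["age_lo"] = np.nan
    out["age_hi"] = np.nan
    out = out[RATE_COLUMNS].sort_values(_GROUP_KEY, ignore_index=True)
    return validate_rate_table(out)
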