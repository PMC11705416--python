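"""Tabular domain types and their invariant checks.

Every table in the pipeline is a plain :class:`pandas.DataFrame` with a
fixed column contract; the functions here validate those contracts and the
domain invariants (non-negative counts, female-only sites, unique stratum
keys, stage mixes summing to one, ...).  Validation failures raise
:class:`TableValidationError` naming the offending rows so broken inputs
surface at the boundary rather than as silent join losses downstream.

Open-ended upper age bounds are represented as ``inf`` in memory (empty
string on disk), so band columns join and group like ordinary floats.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bands import CANCER_SITES, FEMALE_SITES, SITE_SCHEMAS, STAGES

# Stratum key of event/burden tables (age band carried as lo/hi pair).
STRATUM_KEY = ["county", "cancer_site", "sex", "year", "age_lo", "age_hi"]
BAND_KEY = ["age_lo", "age_hi"]

EVENT_COLUMNS = STRATUM_KEY + ["kind", "count"]
STAGED_EVENT_COLUMNS = STRATUM_KEY + ["kind", "stage", "count"]
BURDEN_COLUMNS = STRATUM_KEY + ["yll", "yld", "daly"]
POPULATION_COLUMNS = ["county", "sex", "year", "age_lo", "age_hi", "population"]
LIFE_TABLE_COLUMNS = ["sex", "age", "ex"]
STAGE_MIX_COLUMNS = ["cancer_site", "age_lo", "age_hi", "stage", "proportion"]
TREATMENT_COLUMNS = ["cancer_site", "age_lo", "age_hi", "stage", "p_treated", "s_cured"]
NATURAL_HISTORY_COLUMNS = [
    "cancer_site",
    "dw_diag", "dw_rem", "dw_metast", "dw_term",
    "dur_diag", "dur_rem_cured", "dur_rem_fatal", "dur_metast", "dur_term",
]
STANDARD_POP_COLUMNS = ["age_lo", "age_hi", "weight"]
SCREENING_COLUMNS = ["county", "cancer_site", "year", "screening_rate"]
RATE_COLUMNS = ["county", "cancer_site", "sex", "year", "measure", "age_lo", "age_hi", "rate"]


class TableValidationError(ValueError):
    """A table violates its column contract or a domain invariant."""


def _rows(mask: pd.Series | np.ndarray, limit: int = 5) -> str:
    idx = [int(i) for i in np.flatnonzero(np.asarray(mask))[:limit]]
    return f"rows {idx}"


def _require_columns(df: pd.DataFrame, columns: Sequence[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableValidationError(f"{name}: missing columns {missing}")


def _check_unique(df: pd.DataFrame, key: Sequence[str], name: str) -> None:
    dup = df.duplicated(subset=list(key), keep=False)
    if dup.any():
        pair = [int(i) for i in np.flatnonzero(dup.to_numpy())[:4]]
        raise TableValidationError(
            f"{name}: duplicated key {list(key)} at rows {pair}"
        )


def _check_sites(df: pd.DataFrame, name: str) -> None:
    bad = ~df["cancer_site"].isin(CANCER_SITES)
    if bad.any():
        raise TableValidationError(
            f"{name}: unknown cancer_site {sorted(df.loc[bad, 'cancer_site'].unique())} "
            f"({_rows(bad)})"
        )


def _check_bands(df: pd.DataFrame, name: str) -> None:
    """Every (cancer_site, age_lo, age_hi) must be a band of the site schema."""
    for site, grp in df.groupby("cancer_site", sort=False):
        schema = SITE_SCHEMAS[site]
        valid = set(schema.bands)
        pairs = set(zip(grp["age_lo"].astype(float), grp["age_hi"].astype(float)))
        bad = pairs - valid
        if bad:
            raise TableValidationError(
                f"{name}: bands {sorted(bad)} not in the {site} schema "
                f"{list(schema.bands)}"
            )


def _check_female_sites(df: pd.DataFrame, name: str) -> None:
    bad = df["cancer_site"].isin(FEMALE_SITES) & (df["sex"] != "female")
    if bad.any():
        raise TableValidationError(
            f"{name}: breast/cervical strata must have sex='female' ({_rows(bad)})"
        )


def _check_fraction(df: pd.DataFrame, col: str, name: str) -> None:
    bad = ~df[col].between(0.0, 1.0) | df[col].isna()
    if bad.any():
        raise TableValidationError(
            f"{name}: column '{col}' outside [0, 1] ({_rows(bad)})"
        )


def validate_event_table(df: pd.DataFrame, name: str = "events") -> pd.DataFrame:
    _require_columns(df, EVENT_COLUMNS, name)
    bad_kind = ~df["kind"].isin(("incidence", "deaths"))
    if bad_kind.any():
        raise TableValidationError(f"{name}: kind must be incidence/deaths ({_rows(bad_kind)})")
    neg = (df["count"] < 0) | df["count"].isna()
    if neg.any():
        raise TableValidationError(f"{name}: negative or missing count ({_rows(neg)})")
    _check_sites(df, name)
    _check_bands(df, name)
    _check_female_sites(df, name)
    _check_unique(df, STRATUM_KEY + ["kind"], name)
    return df


def validate_staged_event_table(df: pd.DataFrame, name: str = "staged events") -> pd.DataFrame:
    _require_columns(df, STAGED_EVENT_COLUMNS, name)
    bad = ~df["stage"].astype(str).isin(STAGES)
    if bad.any():
        raise TableValidationError(f"{name}: unknown stage ({_rows(bad)})")
    neg = (df["count"] < 0) | df["count"].isna()
    if neg.any():
        raise TableValidationError(f"{name}: negative or missing count ({_rows(neg)})")
    _check_sites(df, name)
    _check_bands(df, name)
    _check_female_sites(df, name)
    _check_unique(df, STRATUM_KEY + ["kind", "stage"], name)
    return df


def validate_burden_table(df: pd.DataFrame, name: str = "burden") -> pd.DataFrame:
    _require_columns(df, BURDEN_COLUMNS, name)
    for col in ("yll", "yld", "daly"):
        neg = (df[col] < 0) | df[col].isna()
        if neg.any():
            raise TableValidationError(f"{name}: negative or missing {col} ({_rows(neg)})")
    resid = (df["daly"] - df["yll"] - df["yld"]).abs()
    bad = resid > 1e-9
    if bad.any():
        raise TableValidationError(
            f"{name}: daly != yll + yld beyond 1e-9 ({_rows(bad)})"
        )
    _check_sites(df, name)
    _check_female_sites(df, name)
    _check_unique(df, STRATUM_KEY, name)
    return df


def validate_population_table(df: pd.DataFrame, name: str = "population") -> pd.DataFrame:
    _require_columns(df, POPULATION_COLUMNS, name)
    bad = (df["population"] <= 0) | df["population"].isna()
    if bad.any():
        raise TableValidationError(f"{name}: population must be > 0 ({_rows(bad)})")
    _check_unique(df, ["county", "sex", "year", "age_lo", "age_hi"], name)
    return df


def validate_life_table(df: pd.DataFrame, name: str = "life table") -> pd.DataFrame:
    _require_columns(df, LIFE_TABLE_COLUMNS, name)
    bad = (df["ex"] <= 0) | df["ex"].isna()
    if bad.any():
        raise TableValidationError(
            f"{name}: remaining life expectancy must be > 0 ({_rows(bad)})"
        )
    _check_unique(df, ["sex", "age"], name)
    return df


def validate_stage_mix(df: pd.DataFrame, name: str = "stage mix", atol: float = 1e-9) -> pd.DataFrame:
    _require_columns(df, STAGE_MIX_COLUMNS, name)
    _check_sites(df, name)
    _check_bands(df, name)
    _check_fraction(df, "proportion", name)
    group_cols = ["cancer_site", "age_lo", "age_hi"]
    if "year" in df.columns:
        group_cols = group_cols + ["year"]
    _check_unique(df, group_cols + ["stage"], name)
    sums = df.groupby(group_cols, dropna=False)["proportion"].sum()
    off = sums[(sums - 1.0).abs() > atol]
    if not off.empty:
        raise TableValidationError(
            f"{name}: stage proportions do not sum to 1 for {list(off.index[:4])} "
            f"(sums {off.values[:4].round(6).tolist()})"
        )
    return df


def validate_treatment_params(df: pd.DataFrame, name: str = "treatment params") -> pd.DataFrame:
    _require_columns(df, TREATMENT_COLUMNS, name)
    _check_sites(df, name)
    _check_bands(df, name)
    _check_fraction(df, "p_treated", name)
    _check_fraction(df, "s_cured", name)
    _check_unique(df, ["cancer_site", "age_lo", "age_hi", "stage"], name)
    # full coverage: every band x stage combination for each site present
    for site, grp in df.groupby("cancer_site", sort=False):
        want = {(lo, hi, st) for lo, hi in SITE_SCHEMAS[site].bands for st in STAGES}
        have = set(zip(grp["age_lo"].astype(float), grp["age_hi"].astype(float),
                       grp["stage"].astype(str)))
        missing = want - have
        if missing:
            raise TableValidationError(
                f"{name}: {site} missing (band, stage) combinations {sorted(missing)[:4]}"
            )
    return df


def validate_natural_history(df: pd.DataFrame, name: str = "natural history") -> pd.DataFrame:
    _require_columns(df, NATURAL_HISTORY_COLUMNS, name)
    _check_sites(df, name)
    _check_unique(df, ["cancer_site"], name)
    for col in NATURAL_HISTORY_COLUMNS[1:5]:
        _check_fraction(df, col, name)
    for col in NATURAL_HISTORY_COLUMNS[5:]:
        bad = (df[col] < 0) | df[col].isna()
        if bad.any():
            raise TableValidationError(f"{name}: duration '{col}' must be >= 0 ({_rows(bad)})")
    return df


def validate_standard_population(df: pd.DataFrame, name: str = "standard population",
                                 atol: float = 1e-9) -> pd.DataFrame:
    _require_columns(df, STANDARD_POP_COLUMNS, name)
    _check_fraction(df, "weight", name)
    _check_unique(df, BAND_KEY, name)
    total = df["weight"].sum()
    if abs(total - 1.0) > atol:
        raise TableValidationError(f"{name}: weights sum to {total!r}, expected 1")
    return df


def validate_screening_series(df: pd.DataFrame, name: str = "screening") -> pd.DataFrame:
    _require_columns(df, SCREENING_COLUMNS, name)
    _check_sites(df, name)
    _check_fraction(df, "screening_rate", name)
    _check_unique(df, ["county", "cancer_site", "year"], name)
    return df


def validate_rate_table(df: pd.DataFrame, name: str = "rates") -> pd.DataFrame:
    _require_columns(df, RATE_COLUMNS, name)
    bad = (df["rate"] < 0) | df["rate"].isna()
    if bad.any():
        raise TableValidationError(f"{name}: negative or missing rate ({_rows(bad)})")
    bad_measure = ~df["measure"].isin(("incidence", "mortality", "daly"))
    if bad_measure.any():
        raise TableValidationError(
            f"{name}: measure must be incidence/mortality/daly ({_rows(bad_measure)})"
        )
    return df


def sites_in(df: pd.DataFrame) -> list[str]:
    """Cancer sites present, in canonical order."""
    present = set(df["cancer_site"].unique())
    return [s for s in CANCER_SITES if s in present]
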