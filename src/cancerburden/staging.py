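"""Allocation of unstaged incident counts across AJCC stages.

County-level registries publish incidence without stage detail; the
national stage distribution (per cancer site and age band) is applied
uniformly to every county, the working assumption being that the county
stage mix mirrors the national one.  Allocation is purely multiplicative,
yields fractional counts by design, and conserves totals exactly.
"""

from __future__ import annotations

import pandas as pd

from .tables import (
    STRATUM_KEY,
    TableValidationError,
    validate_event_table,
    validate_stage_mix,
    validate_staged_event_table,
)

__all__ = ["allocate_stages"]

_MIX_KEY = ["cancer_site", "age_lo", "age_hi"]


def allocate_stages(incidence: pd.DataFrame, mix: pd.DataFrame) -> pd.DataFrame:
    """Split unstaged incidence into per-stage counts.

    ``staged count = unstaged count x national stage proportion``.  The mix
    may carry an optional ``year`` column; year-specific rows take
    precedence over pooled (year-less) rows for the same site and band.

    Raises
    ------
    TableValidationError
        If mix proportions do not sum to one within a band, or any
        (site, band) — or (site, band, year) when only year-specific rows
        exist — present in the incidence lacks mix coverage.
    """
    validate_event_table(incidence, "incidence")
    validate_stage_mix(mix)
    if not (incidence["kind"] == "incidence").all():
        raise TableValidationError("allocate_stages expects kind == 'incidence'")

    has_year = "year" in mix.columns
    if has_year:
        yearly = mix[mix["year"].notna()].copy()
        pooled = mix[mix["year"].isna()].drop(columns=["year"])
    else:
        yearly = mix.iloc[0:0]
        pooled = mix

    staged = None
    if not yearly.empty:
        staged = incidence.merge(
            yearly[_MIX_KEY + ["year", "stage", "proportion"]],
            on=_MIX_KEY + ["year"], how="left",
        )
    if staged is None:
        staged = incidence.merge(
            pooled[_MIX_KEY + ["stage", "proportion"]], on=_MIX_KEY, how="left"
        )
    elif not pooled.empty:
        # fill strata with no year-specific mix from the pooled mix
        unmatched = staged["proportion"].isna()
        if unmatched.any():
            fallback = (
                staged.loc[unmatched, incidence.columns.tolist()]
                .drop_duplicates()
                .merge(pooled[_MIX_KEY + ["stage", "proportion"]], on=_MIX_KEY, how="left")
            )
            staged = pd.concat([staged.loc[~unmatched], fallback], ignore_index=True)

    uncovered = staged["proportion"].isna()
    if uncovered.any():
        row = staged.loc[uncovered, _MIX_KEY + ["year"]].iloc[0]
        raise TableValidationError(
            "stage mix does not cover "
            f"(site={row['cancer_site']}, band={row['age_lo']:g}-{row['age_hi']:g}, "
            f"year={row['year']})"
        )

    staged["count"] = staged["count"].astype(float) * staged["proportion"]
    staged = staged.drop(columns=["proportion"])
    staged = staged.sort_values(STRATUM_KEY + ["stage"], ignore_index=True)
    cols = STRATUM_KEY + ["kind", "stage", "count"]
    return validate_staged_event_table(staged[cols])
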