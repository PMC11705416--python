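"""DALY computation: years of life lost, years lived with disability.

The burden of each cancer stratum (county x site x sex x year x age band)
decomposes as ``DALY = YLL + YLD``:

* **YLL** — deaths multiplied by the remaining life expectancy at a
  representative age of the band, taken from a national (sex-matched) life
  table.  No discounting and no age-weighting are applied.
* **YLD** — incident cases, split by AJCC stage, multiplied by an expected
  per-case disability burden derived from a three-pathway natural-history
  model of cancer: treated-and-cured cases accrue disability through
  diagnosis/primary therapy and remission; treated-but-fatal cases
  additionally pass through a (shorter) remission, a pre-terminal
  metastatic phase and a terminal phase; untreated cases accrue only the
  metastatic and terminal phases.

Phase disability weights are dimensionless severities in [0, 1] and phase
durations are in years; both are site-specific.  The proportion treated
varies by age band and stage, the cure fraction (5-year survival) by stage
only.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bands import RepresentativeAgeRule, midpoint_representative_age
from .tables import (
    STRATUM_KEY,
    TableValidationError,
    validate_burden_table,
    validate_event_table,
    validate_life_table,
    validate_natural_history,
    validate_staged_event_table,
    validate_treatment_params,
)

logger = logging.getLogger(__name__)

__all__ = [
    "compute_ylls",
    "yld_per_case",
    "compute_ylds",
    "compute_dalys",
    "yll_fraction",
]


def _life_expectancy_at(life_table: pd.DataFrame, sexes: pd.Series,
                        ages: np.ndarray) -> np.ndarray:
    """Remaining life expectancy at fractional ages, linearly interpolated.

    Ages outside a sex's tabulated range are a hard error: extrapolating a
    life table silently would fabricate YLL.
    """
    out = np.empty(len(ages), dtype=float)
    for sex in pd.unique(sexes):
        sub = life_table.loc[life_table["sex"] == sex].sort_values("age")
        mask = (sexes == sex).to_numpy()
        if sub.empty:
            raise TableValidationError(f"life table has no rows for sex='{sex}'")
        lo, hi = sub["age"].iloc[0], sub["age"].iloc[-1]
        need = ages[mask]
        off = (need < lo) | (need > hi)
        if off.any():
            raise TableValidationError(
                f"life table for sex='{sex}' does not cover age "
                f"{need[off][0]:g} (covers {lo:g}-{hi:g})"
            )
        out[mask] = np.interp(need, sub["age"].to_numpy(float), sub["ex"].to_numpy(float))
    return out


def compute_ylls(
    deaths: pd.DataFrame,
    life_table: pd.DataFrame,
    representative_age: RepresentativeAgeRule = midpoint_representative_age,
) -> pd.DataFrame:
    """Years of life lost: deaths x remaining life expectancy per stratum.

    Parameters
    ----------
    deaths
        Event table with ``kind == 'deaths'``.
    life_table
        Columns ``sex, age, ex``; must cover every representative age used.
    representative_age
        Maps a band ``(age_lo, age_hi)`` to the single age at which the
        life table is read (default: band midpoint; open band lower + 7.5).

    Returns
    -------
    Burden table with ``yll`` filled and ``yld = 0``.
    """
    validate_event_table(deaths, "deaths")
    validate_life_table(life_table)
    if not (deaths["kind"] == "deaths").all():
        raise TableValidationError("compute_ylls expects kind == 'deaths' throughout")

    out = deaths.drop(columns=["kind"]).copy()
    rep = np.array([
        representative_age(lo, hi)
        for lo, hi in zip(out["age_lo"].astype(float), out["age_hi"].astype(float))
    ])
    ex = _life_expectancy_at(life_table, out["sex"], rep)
    out["yll"] = out.pop("count").to_numpy(float) * ex
    out["yld"] = 0.0
    out["daly"] = out["yll"]
    return validate_burden_table(out[STRATUM_KEY + ["yll", "yld", "daly"]])


def yld_per_case(p_treated, s_cured, *, dw_diag, dw_rem, dw_metast, dw_term,
                 dur_diag, dur_rem_cured, dur_rem_fatal, dur_metast, dur_term):
    """Expected years lived with disability for one incident case.

    Sums disability-weight x duration over the three natural-history
    pathways, weighted by their probabilities::

        P*S     : diagnosis + remission(cured)
        P*(1-S) : diagnosis + remission(fatal) + metastatic + terminal
        (1-P)   : metastatic + terminal

    Accepts scalars or equal-length arrays; fully vectorized.
    """
    p = np.asarray(p_treated, dtype=float)
    s = np.asarray(s_cured, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any((s < 0) | (s > 1)):
        raise ValueError("p_treated and s_cured must lie in [0, 1]")
    weights = [np.asarray(w, dtype=float) for w in (dw_diag, dw_rem, dw_metast, dw_term)]
    if any(np.any((w < 0) | (w > 1)) for w in weights):
        raise ValueError("disability weights must lie in [0, 1]")
    durations = [np.asarray(d, dtype=float)
                 for d in (dur_diag, dur_rem_cured, dur_rem_fatal, dur_metast, dur_term)]
    if any(np.any(d < 0) for d in durations):
        raise ValueError("phase durations must be >= 0")
    d_d, d_r, d_m, d_t = weights
    l_d, l_r1, l_r2, l_m, l_t = durations

    cured = d_d * l_d + d_r * l_r1
    fatal_treated = d_d * l_d + d_r * l_r2 + d_m * l_m + d_t * l_t
    untreated = d_m * l_m + d_t * l_t
    result = p * s * cured + p * (1.0 - s) * fatal_treated + (1.0 - p) * untreated
    return result if result.ndim else float(result)


def compute_ylds(
    incidence: pd.DataFrame,
    params: pd.DataFrame,
    natural_history: pd.DataFrame,
    stage_sum_warn_tol: float = 1e-6,
    unstaged: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Years lived with disability from staged incidence.

    Each staged count is multiplied by the per-case expectation from
    :func:`yld_per_case` under that (site, band, stage)'s treated/cured
    proportions, then stages are collapsed back to the stratum level.

    ``unstaged``, when given, is the pre-allocation incidence table; stage
    sums are compared against it and discrepancies beyond
    ``stage_sum_warn_tol`` logged as warnings.
    """
    validate_staged_event_table(incidence, "incidence")
    validate_treatment_params(params)
    validate_natural_history(natural_history)
    if not (incidence["kind"] == "incidence").all():
        raise TableValidationError("compute_ylds expects kind == 'incidence' throughout")

    merged = incidence.merge(
        params, on=["cancer_site", "age_lo", "age_hi", "stage"], how="left",
        validate="many_to_one",
    )
    missing = merged["p_treated"].isna()
    if missing.any():
        key = merged.loc[missing, ["cancer_site", "age_lo", "age_hi", "stage"]].iloc[0]
        raise TableValidationError(
            "no treatment/cure parameters for "
            f"(site={key['cancer_site']}, band={key['age_lo']:g}-{key['age_hi']:g}, "
            f"stage={key['stage']})"
        )
    merged = merged.merge(natural_history, on="cancer_site", how="left",
                          validate="many_to_one")
    if merged["dw_diag"].isna().any():
        site = merged.loc[merged["dw_diag"].isna(), "cancer_site"].iloc[0]
        raise TableValidationError(f"no natural-history parameters for site {site}")

    per_case = yld_per_case(
        merged["p_treated"], merged["s_cured"],
        dw_diag=merged["dw_diag"], dw_rem=merged["dw_rem"],
        dw_metast=merged["dw_metast"], dw_term=merged["dw_term"],
        dur_diag=merged["dur_diag"], dur_rem_cured=merged["dur_rem_cured"],
        dur_rem_fatal=merged["dur_rem_fatal"], dur_metast=merged["dur_metast"],
        dur_term=merged["dur_term"],
    )
    merged["yld"] = merged["count"].to_numpy(float) * per_case

    out = (
        merged.groupby(STRATUM_KEY, as_index=False, dropna=False, sort=True)
        .agg(yld=("yld", "sum"), staged_count=("count", "sum"))
    )

    if unstaged is not None:
        ref = unstaged.rename(columns={"count": "unstaged_count"})
        chk = out.merge(ref[STRATUM_KEY + ["unstaged_count"]], on=STRATUM_KEY, how="left")
        gap = (chk["staged_count"] - chk["unstaged_count"]).abs()
        bad = gap > stage_sum_warn_tol
        if bad.any():
            logger.warning(
                "stage sums differ from unstaged counts in %d strata (max gap %.3g)",
                int(bad.sum()), float(gap.max()),
            )

    out = out.drop(columns=["staged_count"])
    out["yll"] = 0.0
    out["daly"] = out["yld"]
    return validate_burden_table(out[STRATUM_KEY + ["yll", "yld", "daly"]])


def compute_dalys(ylls: pd.DataFrame, ylds: pd.DataFrame) -> pd.DataFrame:
    """Merge YLL and YLD tables into DALYs per stratum.

    Strata present on one side only are zero-filled on the other: a
    county-year can legitimately record deaths with no incident cases (or
    vice versa).  Duplicate stratum keys on either side are an error.
    """
    for df, name in ((ylls, "ylls"), (ylds, "ylds")):
        dup = df.duplicated(subset=STRATUM_KEY, keep=False)
        if dup.any():
            raise TableValidationError(f"{name}: duplicate stratum keys")
    merged = ylls[STRATUM_KEY + ["yll"]].merge(
        ylds[STRATUM_KEY + ["yld"]], on=STRATUM_KEY, how="outer",
    )
    merged["yll"] = merged["yll"].fillna(0.0)
    merged["yld"] = merged["yld"].fillna(0.0)
    merged["daly"] = merged["yll"] + merged["yld"]
    merged = merged.sort_values(STRATUM_KEY, ignore_index=True)
    return validate_burden_table(merged[STRATUM_KEY + ["yll", "yld", "daly"]])


def yll_fraction(burden: pd.DataFrame, groupby: Sequence[str]) -> pd.DataFrame:
    """Share of DALYs due to premature mortality, per group.

    Returns the group keys plus summed ``yll``/``daly`` and
    ``yll_fraction = yll / daly`` in [0, 1]; groups with zero DALY get
    ``NaN`` (undefined), never a silent zero.
    """
    validate_burden_table(burden)
    out = burden.groupby(list(groupby), as_index=False, dropna=False).agg(
        yll=("yll", "sum"), daly=("daly", "sum")
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = out["yll"] / out["daly"]
    out["yll_fraction"] = frac.where(out["daly"] > 0, np.nan)
    return out
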