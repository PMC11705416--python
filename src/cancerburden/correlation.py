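"""Pearson correlation between county burden rates and screening uptake.

An ecological check, not a causal model: for each cancer site, counties'
age-standardized DALY rates are paired with their screening rates and a
Pearson correlation (r, r-squared, exact two-sided p from the t-transform
with n - 2 degrees of freedom) is reported.  Defaults pair county-level
multi-year means; per-year pairing is available through ``pairing``.
Degenerate inputs (fewer than three pairs, zero variance) yield an
explicitly flagged undefined result rather than a silent drop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import validate_rate_table, validate_screening_series

__all__ = ["CorrelationResult", "pearson_burden_screening", "correlate_all_sites"]

MIN_PAIRS = 3


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation summary for one cancer site."""

    cancer_site: str
    n: int
    r: float
    r_squared: float
    p_two_sided: float
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.undefined_reason is None

    def as_row(self) -> dict:
        return {
            "cancer_site": self.cancer_site,
            "n": self.n,
            "r": self.r,
            "r2": self.r_squared,
            "p": self.p_two_sided,
            "undefined_reason": self.undefined_reason or "",
        }


def _undefined(site: str, n: int, reason: str) -> CorrelationResult:
    return CorrelationResult(site, n, np.nan, np.nan, np.nan, undefined_reason=reason)


def pearson_burden_screening(
    burden_rates: pd.DataFrame,
    screening: pd.DataFrame,
    pairing: Sequence[str] = ("county",),
) -> CorrelationResult:
    """Correlate standardized DALY rates with screening rates for one site.

    Both tables are averaged within the ``pairing`` key (default: by county,
    i.e. multi-year county means), inner-joined, and the Pearson r of the
    matched pairs computed.

    ``burden_rates`` must contain a single cancer site with
    ``measure == 'daly'`` (standardized rows, no age band).
    """
    validate_rate_table(burden_rates)
    validate_screening_series(screening)
    sites = burden_rates["cancer_site"].unique()
    if len(sites) != 1:
        raise ValueError("pearson_burden_screening expects a single cancer site")
    site = sites[0]
    pairing = list(pairing)

    daly = burden_rates[burden_rates["measure"] == "daly"]
    x = daly.groupby(pairing, as_index=False)["rate"].mean()
    y = (screening[screening["cancer_site"] == site]
         .groupby(pairing, as_index=False)["screening_rate"].mean())
    pairs = x.merge(y, on=pairing, how="inner")
    n = len(pairs)
    if n < MIN_PAIRS:
        return _undefined(site, n, f"only {n} matched pairs (need >= {MIN_PAIRS})")
    a = pairs["rate"].to_numpy(float)
    b = pairs["screening_rate"].to_numpy(float)
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return _undefined(site, n, "zero variance")

    r, p = stats.pearsonr(a, b)
    return CorrelationResult(site, n, float(r), float(r) ** 2, float(p))


def correlate_all_sites(
    burden_rates: pd.DataFrame,
    screening: pd.DataFrame,
    pairing: Sequence[str] = ("county",),
) -> pd.DataFrame:
    """One-row-per-site correlation summary (n, r, r2, p)."""
    rows = []
    for site in sorted(burden_rates["cancer_site"].unique()):
        res = pearson_burden_screening(
            burden_rates[burden_rates["cancer_site"] == site], screening, pairing
        )
        rows.append(res.as_row())
    return pd.DataFrame(rows)
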