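"""Synthetic registry-style inputs for the burden pipeline.

Real county cancer-registry extracts (incidence and death counts by county,
site, age band and year; mid-year populations; national life tables; stage
distributions; treatment parameters; screening uptake) are not publicly
packaged.  This module generates tables with the same structure and the
statistical features the analysis assumes:

* Poisson event counts with age-increasing baseline rates,
* cancer-specific age-band schemas and stage mixes,
* female-only sites (breast, cervical) restricted to the female population,
* county-level rate heterogeneity (log-normal multiplicative effects),
* an optional link between county screening uptake and case fatality (or
  incidence), so the downstream burden-vs-screening correlation has a known
  generative sign.

Deaths are drawn independently of the simulated incident cases (a period
approach, matching cross-sectional registry use), not by cohort follow-up.
Each output table, and each county within it, draws from its own random
substream spawned from the master seed, so enlarging the simulation never
perturbs existing counties' draws.

All parameter *fixtures* here are synthetic: boundary values of the
treated/cured tables follow published Taiwan-registry figures, interior
cells are monotone interpolations, and disability weights/durations carry
GBD-flavoured magnitudes without reproducing any source table.
"""

from __future__ import annotations

import math
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .bands import CANCER_SITES, FEMALE_SITES, SITE_SCHEMAS, STAGES
from .tables import (
    validate_event_table,
    validate_life_table,
    validate_natural_history,
    validate_population_table,
    validate_screening_series,
    validate_stage_mix,
    validate_treatment_params,
)

__all__ = ["SimulationConfig", "simulate_inputs", "default_parameter_fixtures"]

_MAX_AGE = 99

# Substream ids (spawn keys off the master seed), one per stochastic table.
_STREAM_POPULATION = 0
_STREAM_COUNTY_EFFECT = 1
_STREAM_SCREENING = 2
_STREAM_INCIDENCE = 3
_STREAM_DEATHS = 4

# Default per-site baseline incidence per 100,000 (all-ages scale anchor)
# and case fatality, in the ballpark of Taiwanese screening-programme sites.
_DEFAULT_BASELINE = {"BC": 80.0, "CxCa": 11.0, "OC": 25.0, "CRC": 44.0}
_DEFAULT_FATALITY = {"BC": 0.16, "CxCa": 0.35, "OC": 0.40, "CRC": 0.33}
# Mean screening uptake per site (programme-level anchors).
_DEFAULT_SCREENING_MEAN = {"BC": 0.356, "CxCa": 0.556, "OC": 0.44, "CRC": 0.37}
# Age-band rate multipliers (young -> old), per site band schema.
_DEFAULT_AGE_MULT = {
    "OC": (0.1, 2.0, 5.0),
    "CRC": (0.1, 2.0, 6.0),
    "BC": (0.05, 1.5, 3.0, 4.0),
    "CxCa": (0.05, 1.0, 2.5, 3.5),
}
# National stage mix (stage 0..IV), constant across age bands by default.
_DEFAULT_STAGE_MIX = {
    "BC": (0.15, 0.35, 0.28, 0.15, 0.07),
    "CxCa": (0.30, 0.30, 0.15, 0.15, 0.10),
    "OC": (0.05, 0.25, 0.15, 0.25, 0.30),
    "CRC": (0.08, 0.22, 0.27, 0.27, 0.16),
}


class SimulationConfig(BaseModel):
    """Parameters of the synthetic registry bundle (validated up front)."""

    seed: int = 0
    n_counties: int = Field(default=19, ge=1)
    years: tuple[int, ...] = (2010, 2015, 2018, 2019, 2020)
    cancer_sites: tuple[str, ...] = CANCER_SITES
    baseline_incidence_per_100k: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_BASELINE))
    age_rate_multipliers: dict[str, tuple[float, ...]] = Field(
        default_factory=lambda: {k: tuple(v) for k, v in _DEFAULT_AGE_MULT.items()})
    county_effect_sd: float = Field(default=0.2, ge=0.0)
    case_fatality: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_FATALITY))
    screening_effect: float = -1.0
    screening_target: Literal["fatality", "incidence"] = "fatality"
    screening_sd: float = Field(default=0.08, ge=0.0)
    population_scale: float = Field(default=300_000.0, gt=0.0)

    @field_validator("cancer_sites")
    @classmethod
    def _known_sites(cls, v):
        bad = [s for s in v if s not in CANCER_SITES]
        if bad:
            raise ValueError(f"unknown cancer sites {bad}")
        if len(set(v)) != len(v):
            raise ValueError("duplicate cancer sites")
        return v

    @model_validator(mode="after")
    def _coherent(self):
        for site in self.cancer_sites:
            if self.baseline_incidence_per_100k.get(site, -1.0) < 0:
                raise ValueError(f"baseline incidence missing or negative for {site}")
            cf = self.case_fatality.get(site)
            if cf is None or not (0.0 <= cf <= 1.0):
                raise ValueError(f"case fatality for {site} must be in [0, 1]")
            mult = self.age_rate_multipliers.get(site)
            n_bands = len(SITE_SCHEMAS[site].bands)
            if mult is None or len(mult) != n_bands:
                raise ValueError(
                    f"age_rate_multipliers[{site}] must have {n_bands} entries")
            if any(m <= 0 for m in mult):
                raise ValueError(f"age multipliers for {site} must be positive")
        return self


def _rng(cfg: SimulationConfig, stream: int, county: int | None = None) -> np.random.Generator:
    key = (stream,) if county is None else (stream, county)
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=key))


def _age_density() -> np.ndarray:
    """Single-year age density 0..99: flat working ages, logistic roll-off."""
    ages = np.arange(_MAX_AGE + 1, dtype=float)
    w = 1.0 / (1.0 + np.exp((ages - 78.0) / 7.0))
    return w / w.sum()


def _band_population_fractions(bands) -> np.ndarray:
    dens = _age_density()
    fracs = []
    for lo, hi in bands:
        top = _MAX_AGE if math.isinf(hi) else int(hi)
        fracs.append(dens[int(lo): top + 1].sum())
    return np.asarray(fracs)


def _county_names(n: int) -> list[str]:
    return [f"C{i + 1:02d}" for i in range(n)]


def synthetic_life_table() -> pd.DataFrame:
    """Synthetic national life table (single ages 0-99, sexes all/female).

    Remaining life expectancy declines smoothly from a life expectancy at
    birth of 80 (all) / 84 (female) years toward a small old-age floor; the
    shape is a stand-in for a national period table, not a fit to one.
    """
    ages = np.arange(_MAX_AGE + 1, dtype=float)
    rows = []
    for sex, e0 in (("all", 80.0), ("female", 84.0)):
        omega = e0 + 28.0
        ex = (omega - ages) * (e0 / omega) + 1.5 * (ages / omega)
        rows.append(pd.DataFrame({"sex": sex, "age": ages.astype(int), "ex": ex}))
    return validate_life_table(pd.concat(rows, ignore_index=True))


def default_stage_mix(sites: Sequence[str] = CANCER_SITES) -> pd.DataFrame:
    rows = []
    for site in sites:
        for lo, hi in SITE_SCHEMAS[site].bands:
            for stage, prop in zip(STAGES, _DEFAULT_STAGE_MIX[site]):
                rows.append({"cancer_site": site, "age_lo": lo, "age_hi": hi,
                             "stage": stage, "proportion": prop})
    return validate_stage_mix(pd.DataFrame(rows))


def _linear_by_stage(first: float, last: float) -> np.ndarray:
    return np.linspace(first, last, num=len(STAGES))


def _linear_by_band(first: float, last: float, n_bands: int) -> np.ndarray:
    return np.linspace(first, last, num=n_bands)


# Stage-specific cure fractions (5-year survival).  Printed boundary
# anchors: OC 0.780 -> 0.359 (stages 0 -> IV); BC stage 0 = 0.990; CxCa
# stage 0 = 0.981, stage IV = 0.214; CRC stage IV = 0.129.  The remaining
# endpoints (BC stage IV, CRC stage 0) and all interiors are synthetic
# monotone interpolations.
_CURE_ANCHORS = {
    "OC": (0.780, 0.359),
    "BC": (0.990, 0.350),
    "CxCa": (0.981, 0.214),
    "CRC": (0.950, 0.129),
}

# Proportion treated: high (0.95-0.99) in early stages; stage IV declines
# with age.  Printed anchors: OC stage IV 0.96 -> 0.93; CRC stage IV
# 0.93 -> 0.76; BC stage IV 0.82 -> 0.68.  CxCa's gradient is synthetic.
_TREATED_STAGE4_BY_BAND = {
    "OC": (0.96, 0.93),
    "CRC": (0.93, 0.76),
    "BC": (0.82, 0.68),
    "CxCa": (0.90, 0.85),
}
_TREATED_EARLY_STAGES = {
    "OC": (0.99, 0.98, 0.97, 0.95),  # stages 0..III
    "CRC": (0.97, 0.96, 0.95, 0.94),
    "BC": (0.98, 0.97, 0.96, 0.94),
    "CxCa": (0.98, 0.97, 0.96, 0.94),
}


def default_parameter_fixtures(sites: Sequence[str] = CANCER_SITES) -> dict[str, pd.DataFrame]:
    """Treatment/cure and natural-history fixture tables.

    Returns ``{"params": ..., "nh": ...}``.  Cure fractions are stage-only
    (replicated across age bands); treated proportions vary by band only in
    stage IV, where treatment uptake drops with age.
    """
    rows = []
    for site in sites:
        bands = SITE_SCHEMAS[site].bands
        cure = _linear_by_stage(*_CURE_ANCHORS[site])
        p4 = _linear_by_band(*_TREATED_STAGE4_BY_BAND[site], len(bands))
        early = _TREATED_EARLY_STAGES[site]
        for b, (lo, hi) in enumerate(bands):
            for z, stage in enumerate(STAGES):
                p = p4[b] if stage == "IV" else early[z]
                rows.append({
                    "cancer_site": site, "age_lo": lo, "age_hi": hi, "stage": stage,
                    "p_treated": float(p), "s_cured": float(cure[z]),
                })
    params = validate_treatment_params(pd.DataFrame(rows))

    # Disability weights ~ GBD cancer-phase magnitudes (diagnosis/primary
    # therapy, controlled/remission, metastatic, terminal); durations in
    # years.  Synthetic fixtures with small per-site variation.
    nh_rows = {
        #        site   D_dw  R_dw  M_dw  T_dw  L_D   L_R1  L_R2  L_M   L_T
        "BC":   (0.288, 0.049, 0.451, 0.540, 0.40, 4.60, 1.00, 0.50, 0.25),
        "CxCa": (0.288, 0.049, 0.451, 0.540, 0.35, 4.65, 1.00, 0.50, 0.25),
        "OC":   (0.288, 0.060, 0.451, 0.540, 0.40, 4.60, 0.90, 0.45, 0.25),
        "CRC":  (0.288, 0.049, 0.451, 0.540, 0.45, 4.55, 0.90, 0.50, 0.25),
    }
    nh = pd.DataFrame(
        [(site, *nh_rows[site]) for site in sites],
        columns=["cancer_site", "dw_diag", "dw_rem", "dw_metast", "dw_term",
                 "dur_diag", "dur_rem_cured", "dur_rem_fatal", "dur_metast",
                 "dur_term"],
    )
    return {"params": params, "nh": validate_natural_history(nh)}


def simulate_inputs(cfg: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Generate the full input bundle for one simulated registry.

    Returns a dict with keys ``incidence``, ``deaths``, ``population``,
    ``stage_mix``, ``life_table``, ``screening``, ``params``, ``nh``.
    Identical configs (including seed) give identical outputs.
    """
    counties = _county_names(cfg.n_counties)
    sites = list(cfg.cancer_sites)

    # county total populations (constant across study years)
    totals = {}
    for ci, county in enumerate(counties):
        g = _rng(cfg, _STREAM_POPULATION, ci)
        totals[county] = cfg.population_scale * float(g.lognormal(mean=0.0, sigma=0.3))

    # per-county multiplicative rate effects, one per site
    county_effect = {}
    for ci, county in enumerate(counties):
        g = _rng(cfg, _STREAM_COUNTY_EFFECT, ci)
        for site in CANCER_SITES:
            county_effect[(county, site)] = float(
                g.lognormal(mean=0.0, sigma=cfg.county_effect_sd))

    # screening uptake: county-level anchor + small yearly jitter
    scr_rows = []
    screening_rate = {}
    for ci, county in enumerate(counties):
        g = _rng(cfg, _STREAM_SCREENING, ci)
        for site in CANCER_SITES:
            anchor = np.clip(
                _DEFAULT_SCREENING_MEAN[site] + g.normal(0.0, cfg.screening_sd),
                0.02, 0.98)
            for year in cfg.years:
                rate = float(np.clip(anchor + g.normal(0.0, 0.01), 0.01, 0.99))
                screening_rate[(county, site, year)] = rate
                if site in sites:
                    scr_rows.append({"county": county, "cancer_site": site,
                                     "year": year, "screening_rate": rate})
    screening = validate_screening_series(pd.DataFrame(scr_rows))

    # mid-year population per band: union of all site schemas, sexes all+female
    band_union = sorted({b for s in CANCER_SITES for b in SITE_SCHEMAS[s].bands})
    pop_rows = []
    pop_lookup = {}
    for county in counties:
        for lo, hi in band_union:
            frac = _band_population_fractions([(lo, hi)])[0]
            for sex, share in (("all", 1.0), ("female", 0.5)):
                n = totals[county] * frac * share
                for year in cfg.years:
                    pop_rows.append({"county": county, "sex": sex, "year": year,
                                     "age_lo": lo, "age_hi": hi, "population": n})
                pop_lookup[(county, sex, lo, hi)] = n
    population = validate_population_table(pd.DataFrame(pop_rows))

    def _mean_events(county: str, site: str, lo: float, hi: float, year: int,
                     kind: str) -> float:
        sex = "female" if site in FEMALE_SITES else "all"
        n = pop_lookup[(county, sex, lo, hi)]
        band_idx = SITE_SCHEMAS[site].bands.index((lo, hi))
        mu = (n * cfg.baseline_incidence_per_100k[site] / 1e5
              * cfg.age_rate_multipliers[site][band_idx]
              * county_effect[(county, site)])
        shift = screening_rate[(county, site, year)] - _DEFAULT_SCREENING_MEAN[site]
        if kind == "incidence":
            if cfg.screening_target == "incidence":
                mu *= math.exp(cfg.screening_effect * shift)
            return mu
        mu *= cfg.case_fatality[site]
        if cfg.screening_target == "fatality":
            mu *= math.exp(cfg.screening_effect * shift)
        return mu

    event_tables = {}
    for kind, stream in (("incidence", _STREAM_INCIDENCE), ("deaths", _STREAM_DEATHS)):
        rows = []
        for ci, county in enumerate(counties):
            g = _rng(cfg, stream, ci)
            for site in sites:
                sex = "female" if site in FEMALE_SITES else "all"
                for lo, hi in SITE_SCHEMAS[site].bands:
                    for year in cfg.years:
                        mu = _mean_events(county, site, lo, hi, year, kind)
                        rows.append({
                            "county": county, "cancer_site": site, "sex": sex,
                            "year": year, "age_lo": lo, "age_hi": hi,
                            "kind": kind, "count": float(g.poisson(mu)),
                        })
        event_tables[kind] = validate_event_table(pd.DataFrame(rows), kind)

    fixtures = default_parameter_fixtures(sites)
    return {
        "incidence": event_tables["incidence"],
        "deaths": event_tables["deaths"],
        "population": population,
        "stage_mix": default_stage_mix(sites),
        "life_table": synthetic_life_table(),
        "screening": screening,
        "params": fixtures["params"],
        "nh": fixtures["nh"],
    }
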