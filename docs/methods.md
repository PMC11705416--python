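# Methods

## Burden model

The package estimates cancer burden per stratum (county × cancer site ×
sex × year × age band) as `DALY = YLL + YLD`.

**YLL.** Deaths in a band are multiplied by the remaining life expectancy
`ex` read from a national period life table at a *representative age* of
the band. The representative-age rule is configurable; the default is the
midpoint of the covered year-interval (band `[lo, hi]` in completed years
covers `[lo, hi+1)`, so e.g. 40–59 → age 50) and `lo + 7.5` years for the
open terminal band, for which a midpoint is undefined. `ex` is linearly
interpolated between tabulated single ages; an age outside the table's
coverage is a hard error rather than an extrapolation. Oral and colorectal
cancer use the all-population table; breast and cervical cancer the female
table. No discounting and no age-weighting are applied — some burden-of-
disease variants include a 3% time discount and non-uniform age weights,
and the choice materially changes YLL levels, so it is stated explicitly.
Phase durations are *not* capped by remaining life expectancy; for elderly
bands this can slightly overstate YLD, but YLD is a few percent of DALY
here, so the effect is second-order.

**YLD.** Incident cases are first split across AJCC stages 0–IV by the
national stage mix (below). Each staged case contributes the expected
disability of the three-pathway natural history: treated-and-cured cases
(probability `P·S`) pass through diagnosis/primary therapy and a long
remission; treated-but-fatal cases (`P·(1−S)`) through diagnosis, a shorter
remission, a pre-terminal metastatic phase and a terminal phase; untreated
cases (`1−P`) through the metastatic and terminal phases only. Each phase
has a disability weight in [0, 1] and a duration in years. `P` varies by
age band and stage; `S` (the cure fraction, operationalized as 5-year
survival) is indexed by stage only — the parameter table still carries age
columns with replicated values so all joins stay uniform. All burden
quantities are linear in event counts, and `DALY = YLL + YLD` holds per
stratum and under every aggregation (a conservation law the tests enforce
at 1e-9).

**Stage allocation.** County stage-specific counts are not published; the
national stage distribution per (site, age band) is applied uniformly:
`staged = unstaged × proportion`. Counts stay fractional — integerizing
would break conservation and nothing downstream needs whole cases. A mix
may be supplied per year or pooled; year-specific rows take precedence.
This uniformity assumption can over- or under-state burden in counties
whose true stage mix differs (e.g. low-screening counties likely present
later); it is the model's main structural simplification.

**Rates.** Age-specific rate = events (or DALYs) / mid-year population ×
100,000, with female denominators for breast and cervical cancer. Direct
standardization multiplies band rates by standard-population weights and
sums. The default standard is the WHO world standard population's 5-year
weight table (packaged CSV, overridable); weights are collapsed onto each
cancer's band schema by summing fine bands within each coarse band and
*then* normalized, so working weights sum to exactly 1 even though the
published weights total 1.0003. A zero or missing denominator is an error,
never a silent zero rate. Standardized rates are convex combinations of
band rates, invariant to jointly rescaling counts and populations, and
collapse to the crude rate when the standard equals the county's own
structure — all tested.

**Screening correlation.** Pearson r between county age-standardized DALY
rates and screening uptake, by default on county multi-year means (19
points in the default configuration); per-year pairing is available. p is
the exact two-sided value from `t = r·sqrt((n−2)/(1−r²))` with n−2 df
(scipy's implementation), unadjusted for multiple testing. Fewer than 3
pairs or zero variance yields a result flagged undefined with its reason.
This is an ecological association across counties, not a causal estimate.

## Synthetic registry generator

`simulate_inputs` emulates the structure of registry extracts:

* **Counts.** Incidence ~ Poisson(population × baseline rate × age-band
  multiplier × county effect × screening modifier); deaths ~ Poisson(mean
  incidence × case fatality × screening modifier). Deaths are drawn
  independently of the sampled incident cases (a period approach mirroring
  cross-sectional registry use), not by cohort follow-up — so simulated
  deaths are not a subset of simulated cases, which the analysis never
  requires.
* **Defaults** (chosen once as realistic for the study setting): 19
  counties; study years 2010, 2015, 2018, 2019, 2020; baseline incidence
  anchors 80/11/25/44 per 100k for BC/CxCa/OC/CRC with case fatality
  0.16/0.35/0.40/0.33; age multipliers rising steeply with age per site;
  county effects log-normal with σ = 0.2; county screening uptake centred
  on programme-level means (0.356/0.556/0.44/0.37) with σ = 0.08; county
  populations log-normal around 300,000 with a logistic-roll-off age
  pyramid; `screening_effect = −1` on log case fatality.
* **Determinism.** Every table, and every county within a table, draws
  from its own `SeedSequence(seed, spawn_key=...)` substream, so the same
  seed is byte-reproducible and adding counties never perturbs existing
  counties' draws.
* **Parameter fixtures.** Cure fractions anchor published Taiwan-registry
  boundary values (OC 78.0% → 35.9% across stages 0→IV; BC stage 0 99.0%;
  CxCa stage 0 98.1%, stage IV 21.4%; CRC stage IV 12.9%) and interpolate
  interior stages linearly; the unpublished endpoints (BC stage IV, CRC
  stage 0) are synthetic. Treated proportions are high (0.94–0.99) with
  the published stage-IV age declines (OC 96→93%, CRC 93→76%, BC 82→68%);
  the cervical stage-IV gradient is synthetic. Disability weights use
  GBD-flavoured cancer-phase magnitudes (diagnosis/therapy 0.288,
  remission ≈0.05, metastatic 0.451, terminal 0.540) with durations of
  roughly 0.35–0.45 y diagnosis, 4.6 y cured remission (5-year follow-up
  horizon), ~1 y fatal remission, ~0.5 y metastatic and 0.25 y terminal.
  These are fixtures, not a reproduction of any supplementary table.

What the generator does **not** emulate: real county population sizes and
age pyramids, cohort linkage between cases and deaths, stage mixes varying
by county or year, secular trends within the study period, or uncertainty
in disability weights. Passing tests therefore demonstrate the
*computational* correctness and invariances of the pipeline on data with
the right structure — not agreement with any real jurisdiction's burden
levels.

## Numerical and test-design choices

* Tolerances: identities (conservation, oracle equivalence) at 1e-9;
  scalar formula checks (per-case YLD, Pearson) at 1e-12. Stage-sum
  mismatches ≤ 1e-6 against the unstaged table are treated as allocation
  residue; larger ones log a warning and proceed.
* Joins validate `many_to_one` and missing keys are hard errors naming the
  stratum; `compute_dalys` outer-joins with zero-fill because a county-year
  with deaths but no incident cases (or vice versa) is legitimate.
* Open-ended age bands are `inf` in memory and an empty `age_hi` on disk,
  so band columns behave as ordinary floats in joins and group-bys.
* Problem sizes in the test and acceptance suites (bundles of 4–19
  counties, oracle tables of a few thousand rows, 20-seed sign-recovery
  runs) were chosen so each brute-force oracle is feasible while remaining
  a genuine stress of the vectorized paths.
* The sign-recovery check runs the cervical-cancer pipeline at
  metropolitan-scale county populations (10⁶): cervical-cancer deaths are
  rare, and at small populations per-county Poisson noise (a handful of
  deaths a year) would dominate the screening-fatality signal, making the
  check a test of sampling noise rather than of the pipeline. A Fisher-z
  power calculation at that scale puts the per-seed sign-error probability
  below 1%.

## Known limitations

* The national-stage-mix assumption and the uncapped phase durations, as
  discussed above.
* The representative-age rule approximates within-band death-age
  distributions; with wide bands (0–39) and steeply age-varying mortality
  the midpoint can misstate YLL for that band.
* Cure is a binary 5-year-survival dichotomy; there is no survival
  modelling beyond `S`, and no uncertainty propagation for disability
  weights (point estimates only).
* The correlation module quantifies association only; county screening
  and burden share many confounders (demography, access, deprivation).
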