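"""Core burden model: YLL, three-pathway YLD, DALY merge, YLL fractions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cancerburden import (
    TableValidationError,
    compute_dalys,
    compute_ylds,
    compute_ylls,
    default_parameter_fixtures,
    yld_per_case,
    yll_fraction,
)
from cancerburden.tables import STRATUM_KEY

from conftest import random_staged_incidence


def oc_deaths(counts):
    """Deaths over the three oral-cancer bands for one county-year."""
    bands = [(0.0, 39.0), (40.0, 59.0), (60.0, math.inf)]
    return pd.DataFrame([
        {"county": "C01", "cancer_site": "OC", "sex": "all", "year": 2020,
         "age_lo": lo, "age_hi": hi, "kind": "deaths", "count": float(n)}
        for (lo, hi), n in zip(bands, counts)
    ])


# Piecewise-linear life table whose interpolated remaining life expectancy
# at the OC band representative ages (20, 50, 67.5) is exactly (50, 25, 10).
PIECEWISE_LIFE = pd.DataFrame({
    "sex": "all",
    "age": [0, 20, 50, 67, 68, 100],
    "ex": [70.0, 50.0, 25.0, 10.5, 9.5, 1.0],
})


class TestComputeYlls:
    def test_zero_deaths_give_zero_yll(self):
        out = compute_ylls(oc_deaths([0, 0, 0]), PIECEWISE_LIFE)
        assert (out["yll"] == 0).all() and (out["daly"] == 0).all()

    def test_deaths_times_life_expectancy(self):
        out = compute_ylls(oc_deaths([0, 2, 0]), PIECEWISE_LIFE)
        # 2 deaths in 40-59, representative age 50, ex = 25 -> 50 YLL... but
        # the band midpoint of [40, 59] is (40 + 59 + 1)/2 = 50 exactly.
        band = out[out["age_lo"] == 40.0]
        assert band["yll"].iloc[0] == pytest.approx(2 * 25.0, abs=1e-12)

    def test_matches_per_row_loop_oracle(self):
        counts = (1, 2, 4)
        out = compute_ylls(oc_deaths(counts), PIECEWISE_LIFE)
        # independent per-row sum: 1*50 + 2*25 + 4*10
        assert out["yll"].sum() == pytest.approx(140.0, abs=1e-9)

    def test_missing_life_table_age_is_hard_error(self):
        short = PIECEWISE_LIFE[PIECEWISE_LIFE["age"] <= 50]
        with pytest.raises(TableValidationError, match="sex='all'"):
            compute_ylls(oc_deaths([1, 1, 1]), short)

    def test_negative_count_is_hard_error(self):
        bad = oc_deaths([1, 1, -1])
        with pytest.raises(TableValidationError, match="negative"):
            compute_ylls(bad, PIECEWISE_LIFE)

    def test_custom_representative_age_rule(self):
        out = compute_ylls(oc_deaths([1, 0, 0]), PIECEWISE_LIFE,
                           representative_age=lambda lo, hi: 0.0)
        assert out["yll"].iloc[0] == pytest.approx(70.0)


NH = dict(dw_diag=0.3, dw_rem=0.05, dw_metast=0.5, dw_term=0.8,
          dur_diag=0.25, dur_rem_cured=2.0, dur_rem_fatal=1.0,
          dur_metast=0.5, dur_term=0.25)


class TestYldPerCase:
    def test_cured_with_zero_weights_is_zero(self):
        assert yld_per_case(1.0, 1.0, **{**NH, "dw_diag": 0.0, "dw_rem": 0.0}) == 0.0

    def test_untreated_branch_only(self):
        v = yld_per_case(0.0, 0.7, dw_diag=0.9, dw_rem=0.9, dw_metast=0.5,
                         dw_term=0.8, dur_diag=9.0, dur_rem_cured=9.0,
                         dur_rem_fatal=9.0, dur_metast=1.0, dur_term=0.5)
        assert v == pytest.approx(0.5 * 1.0 + 0.8 * 0.5, abs=1e-15)

    def test_matches_pathway_enumeration_oracle(self):
        # Frozen from an independent three-pathway enumeration:
        #   P*S*(0.3*0.25 + 0.05*2)                           = 0.07875
        #   P*(1-S)*(0.3*0.25 + 0.05*1 + 0.5*0.5 + 0.8*0.25)  = 0.25875
        #   (1-P)*(0.5*0.5 + 0.8*0.25)                        = 0.045
        v = yld_per_case(0.9, 0.5, **NH)
        assert v == pytest.approx(0.3825, abs=1e-12)

    @pytest.mark.parametrize("bad", [
        {"p_treated": -0.1}, {"p_treated": 1.1}, {"s_cured": 2.0},
        {"dw_term": 1.5}, {"dur_metast": -1.0},
    ])
    def test_out_of_range_parameters_rejected(self, bad):
        kwargs = {"p_treated": 0.5, "s_cured": 0.5, **NH}
        kwargs.update(bad)
        p, s = kwargs.pop("p_treated"), kwargs.pop("s_cured")
        with pytest.raises(ValueError):
            yld_per_case(p, s, **kwargs)

    @given(
        p=st.sampled_from([0.0, 1.0]), s=st.sampled_from([0.0, 1.0]),
        dws=st.lists(st.floats(0, 1), min_size=4, max_size=4),
        durs=st.lists(st.floats(0, 10), min_size=5, max_size=5),
    )
    @settings(max_examples=100, derandomize=True)
    def test_reduces_to_single_pathway_at_corners(self, p, s, dws, durs):
        d_d, d_r, d_m, d_t = dws
        l_d, l_r1, l_r2, l_m, l_t = durs
        v = yld_per_case(p, s, dw_diag=d_d, dw_rem=d_r, dw_metast=d_m,
                         dw_term=d_t, dur_diag=l_d, dur_rem_cured=l_r1,
                         dur_rem_fatal=l_r2, dur_metast=l_m, dur_term=l_t)
        if p == 0.0:
            expect = d_m * l_m + d_t * l_t
        elif s == 1.0:
            expect = d_d * l_d + d_r * l_r1
        else:
            expect = d_d * l_d + d_r * l_r2 + d_m * l_m + d_t * l_t
        assert v == pytest.approx(expect, abs=1e-12)
        bound = max(dws) * (l_d + max(l_r1, l_r2) + l_m + l_t)
        assert 0.0 <= v <= bound + 1e-12


def pathway_oracle(p, s, nh_row):
    """Scalar three-pathway enumeration, independent of the implementation."""
    d_d, d_r, d_m, d_t = (nh_row["dw_diag"], nh_row["dw_rem"],
                          nh_row["dw_metast"], nh_row["dw_term"])
    cured = d_d * nh_row["dur_diag"] + d_r * nh_row["dur_rem_cured"]
    fatal = (d_d * nh_row["dur_diag"] + d_r * nh_row["dur_rem_fatal"]
             + d_m * nh_row["dur_metast"] + d_t * nh_row["dur_term"])
    untreated = d_m * nh_row["dur_metast"] + d_t * nh_row["dur_term"]
    return p * s * cured + p * (1 - s) * fatal + (1 - p) * untreated


@pytest.fixture(scope="module")
def fixtures():
    return default_parameter_fixtures()


class TestComputeYlds:

    def test_zero_incidence_gives_zero_yld(self, fixtures):
        staged = random_staged_incidence(np.random.default_rng(0), n_counties=2)
        staged["count"] = 0.0
        out = compute_ylds(staged, fixtures["params"], fixtures["nh"])
        assert (out["yld"] == 0).all()

    def test_single_case_equals_per_case_value(self, fixtures):
        staged = random_staged_incidence(np.random.default_rng(0), n_counties=1,
                                         sites=("CRC",), years=(2020,))
        staged["count"] = 0.0
        pick = (staged["stage"] == "II") & (staged["age_lo"] == 50.0)
        staged.loc[pick, "count"] = 1.0
        out = compute_ylds(staged, fixtures["params"], fixtures["nh"])
        prow = fixtures["params"].query(
            "cancer_site == 'CRC' and age_lo == 50 and stage == 'II'").iloc[0]
        nhrow = fixtures["nh"].set_index("cancer_site").loc["CRC"]
        expect = pathway_oracle(prow["p_treated"], prow["s_cured"], nhrow)
        assert out["yld"].sum() == pytest.approx(expect, abs=1e-12)

    def test_matches_triple_loop_oracle(self, fixtures):
        staged = random_staged_incidence(np.random.default_rng(12345), n_counties=4,
                                         sites=("OC",), years=(2018,))
        out = compute_ylds(staged, fixtures["params"], fixtures["nh"])
        prm = fixtures["params"].set_index(["cancer_site", "age_lo", "stage"])
        nhrow = fixtures["nh"].set_index("cancer_site").loc["OC"]
        expected = {}
        for _, row in staged.iterrows():  # brute-force per-row accumulation
            key = tuple(row[k] for k in STRATUM_KEY)
            p = prm.loc[("OC", row["age_lo"], row["stage"])]
            expected.setdefault(key, 0.0)
            expected[key] += row["count"] * pathway_oracle(
                p["p_treated"], p["s_cured"], nhrow)
        got = out.set_index(STRATUM_KEY)["yld"]
        for key, val in expected.items():
            assert got.loc[key] == pytest.approx(val, abs=1e-9)

    def test_missing_parameter_row_is_hard_error(self, fixtures):
        staged = random_staged_incidence(np.random.default_rng(0), n_counties=1,
                                         sites=("BC",), years=(2020,))
        params = fixtures["params"].query("cancer_site != 'BC'")
        with pytest.raises(TableValidationError, match="BC"):
            compute_ylds(staged, params, fixtures["nh"])

    def test_linearity_in_counts(self, fixtures):
        staged = random_staged_incidence(np.random.default_rng(3), n_counties=3)
        out1 = compute_ylds(staged, fixtures["params"], fixtures["nh"])
        doubled = staged.assign(count=staged["count"] * 2.0)
        out2 = compute_ylds(doubled, fixtures["params"], fixtures["nh"])
        np.testing.assert_allclose(out2["yld"], out1["yld"] * 2.0, rtol=0, atol=1e-9)


def burden_frame(rows):
    base = {"county": "C01", "cancer_site": "OC", "sex": "all", "year": 2020}
    out = []
    for i, (yll, yld) in enumerate(rows):
        band = [(0.0, 39.0), (40.0, 59.0), (60.0, math.inf)][i % 3]
        out.append({**base, "year": 2010 + i // 3, "age_lo": band[0],
                    "age_hi": band[1], "yll": yll, "yld": yld, "daly": yll + yld})
    return pd.DataFrame(out)


class TestComputeDalys:
    def test_zero_yll_side_reproduces_yld_table(self):
        ylds = burden_frame([(0.0, 3.5), (0.0, 1.25)])
        ylls = ylds.assign(yll=0.0, yld=0.0, daly=0.0)
        out = compute_dalys(ylls, ylds)
        np.testing.assert_allclose(out["daly"], ylds["daly"])

    def test_daly_is_sum(self):
        out = compute_dalys(burden_frame([(140.0, 0.0)]),
                            burden_frame([(0.0, 12.5)]))
        assert out["daly"].iloc[0] == pytest.approx(152.5, abs=1e-12)

    def test_outer_join_zero_fills_disjoint_strata(self):
        ylls = burden_frame([(10.0, 0.0)])
        ylds = burden_frame([(0.0, 1.0), (0.0, 2.0)]).iloc[[1]]
        out = compute_dalys(ylls, ylds)
        assert len(out) == 2
        assert out["daly"].sum() == pytest.approx(12.0)

    def test_duplicate_keys_are_hard_error(self):
        ylls = pd.concat([burden_frame([(1.0, 0.0)])] * 2, ignore_index=True)
        with pytest.raises(TableValidationError, match="duplicate"):
            compute_dalys(ylls, burden_frame([(0.0, 1.0)]))

    def test_grand_total_additivity_random_tables(self):
        rng = np.random.default_rng(99)
        vals = [(float(a), 0.0) for a in rng.gamma(3, 20, size=9)]
        ylls = burden_frame(vals)
        ylds = burden_frame([(0.0, float(b)) for b in rng.gamma(2, 5, size=9)])
        out = compute_dalys(ylls, ylds)
        assert out["daly"].sum() == pytest.approx(
            ylls["yll"].sum() + ylds["yld"].sum(), abs=1e-9)


class TestYllFraction:
    def test_pure_mortality_gives_one(self):
        out = yll_fraction(burden_frame([(10.0, 0.0), (5.0, 0.0)]), ["cancer_site"])
        assert out["yll_fraction"].iloc[0] == pytest.approx(1.0)

    def test_pure_disability_gives_zero(self):
        out = yll_fraction(burden_frame([(0.0, 10.0)]), ["cancer_site"])
        assert out["yll_fraction"].iloc[0] == pytest.approx(0.0)

    def test_ratio_arithmetic(self):
        out = yll_fraction(burden_frame([(90.0, 10.0)]), ["county"])
        assert out["yll_fraction"].iloc[0] == pytest.approx(0.9)

    def test_zero_daly_group_is_undefined_not_zero(self):
        out = yll_fraction(burden_frame([(0.0, 0.0)]), ["year"])
        assert math.isnan(out["yll_fraction"].iloc[0])
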