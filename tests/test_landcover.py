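"""Composition, crosswalk, change accounting and ESA summaries, including
checks against the packaged class-area table of the study territory."""

import numpy as np
import pandas as pd
import pytest

from seedscape.datasets import load_nebrodi_landcover
from seedscape.landcover import (
    DEFAULT_AFFECTED_CLASSES,
    ESA_CLASSES,
    LandcoverValidationError,
    apply_crosswalk,
    change_matrix,
    composition,
    esa_summary,
    rollup_level1,
    validate_esa,
    validate_landcover,
)


def small_table():
    rows = []
    for year, areas in {2000: (60, 30, 10), 2010: (50, 30, 20)}.items():
        for code, a in zip(("2.1.1", "3.1.1", "5.1.2"), areas):
            rows.append({"class_code": code, "class_name": code, "year": year, "area_ha": a})
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def nebrodi():
    return load_nebrodi_landcover()


class TestValidation:
    def test_duplicate_class_year_rejected(self):
        df = small_table()
        dup = pd.concat([df, df.iloc[[0]]])
        with pytest.raises(LandcoverValidationError, match="duplicate"):
            validate_landcover(dup)

    def test_negative_area_rejected(self):
        df = small_table()
        df.loc[0, "area_ha"] = -1
        with pytest.raises(LandcoverValidationError, match="non-negative"):
            validate_landcover(df)


class TestCrosswalk:
    def test_identity_map_unchanged(self):
        df = small_table()
        out = apply_crosswalk(df, {c: c for c in df["class_code"]})
        merged = out.merge(df, on=["class_code", "year"], suffixes=("_o", "_i"))
        assert (merged["area_ha_o"] == merged["area_ha_i"]).all()

    def test_many_to_one_sums_and_conserves(self):
        df = pd.DataFrame(
            [
                {"class_code": "seminativo", "class_name": "arable", "year": 1958, "area_ha": 100.0},
                {"class_code": "colture legnose", "class_name": "orchard", "year": 1958, "area_ha": 50.0},
            ]
        )
        out = apply_crosswalk(df, {"seminativo": "2.1.1", "colture legnose": "2.1.1"})
        assert len(out) == 1
        assert out.loc[0, "area_ha"] == pytest.approx(150.0)

    def test_unmapped_class_listed(self):
        df = small_table()
        with pytest.raises(LandcoverValidationError, match="5.1.2"):
            apply_crosswalk(df, {"2.1.1": "2.1.1", "3.1.1": "3.1.1"})


class TestComposition:
    def test_shares_sum_to_100(self, nebrodi):
        for year in sorted(nebrodi["year"].unique()):
            comp = composition(nebrodi, year)
            assert comp["share_pct"].sum(skipna=True) == pytest.approx(100.0, abs=0.1)

    def test_single_class_table(self):
        df = pd.DataFrame(
            [{"class_code": "3.1.1", "class_name": "forest", "year": 2000, "area_ha": 5.0}]
        )
        assert composition(df, 2000).loc[0, "share_pct"] == pytest.approx(100.0)

    def test_missing_year_rejected(self, nebrodi):
        with pytest.raises(LandcoverValidationError, match="1999"):
            composition(nebrodi, 1999)

    def test_printed_shares_reproduced(self, nebrodi):
        c90 = composition(nebrodi, 1990).set_index("class_code")["share_pct"]
        assert round(c90["3.1.1"], 1) == 21.5   # broad-leaved forest
        assert round(c90["2.2.2"], 1) == 20.4   # fruit plantations
        c18 = composition(nebrodi, 2018).set_index("class_code")["share_pct"]
        assert round(c18["2.4.3"], 1) == 30.2   # agriculture with natural vegetation

    def test_na_not_counted_as_zero(self, nebrodi):
        c58 = composition(nebrodi, 1958)
        assert c58["missing"].sum() == 13
        assert c58.loc[~c58["missing"], "share_pct"].sum() == pytest.approx(100.0)


class TestRollup:
    def test_2018_level1_groups(self, nebrodi):
        r = rollup_level1(nebrodi, 2018, rounded_shares=True)
        assert r["2 (agricultural)"] == pytest.approx(40.3)
        assert r["3 (forest_semi_natural)"] == pytest.approx(58.1)

    def test_one_class_per_group_equals_composition(self):
        df = small_table()
        r = rollup_level1(df, 2000)
        comp = composition(df, 2000).set_index("class_code")["share_pct"]
        assert r["2 (agricultural)"] == pytest.approx(comp["2.1.1"])

    def test_non_clc_codes_rejected(self):
        df = pd.DataFrame(
            [{"class_code": "seminativo", "class_name": "x", "year": 2000, "area_ha": 1.0}]
        )
        with pytest.raises(LandcoverValidationError, match="crosswalk"):
            rollup_level1(df, 2000)

    def test_rollup_sums_to_composition_total(self, nebrodi):
        r = rollup_level1(nebrodi, 1990)
        assert r.sum() == pytest.approx(100.0, abs=1e-9)


class TestChangeMatrix:
    def test_fruit_plantation_collapse(self, nebrodi):
        ch = change_matrix(nebrodi, 2012, 2018).set_index("class_code")
        assert ch.loc["2.2.2", "delta_pp"] == pytest.approx(-22.0, abs=0.05)

    def test_antisymmetry(self, nebrodi):
        ab = change_matrix(nebrodi, 1990, 2018).set_index("class_code")
        ba = change_matrix(nebrodi, 2018, 1990).set_index("class_code")
        assert np.allclose(ab["delta_ha"], -ba["delta_ha"])
        assert np.allclose(ab["delta_pp"], -ba["delta_pp"])

    def test_identical_years_rejected(self, nebrodi):
        with pytest.raises(LandcoverValidationError, match="distinct"):
            change_matrix(nebrodi, 1990, 1990)

    def test_class_missing_in_one_year_flagged(self, nebrodi):
        ch = change_matrix(nebrodi, 2012, 2018).set_index("class_code")
        assert bool(ch.loc["3.3.3", "missing_data"])  # n.a. in 2012
        assert ch.loc["3.3.3", "delta_pp"] == pytest.approx(13.6, abs=0.05)

    def test_unchanged_class_zero_delta(self):
        df = small_table()
        ch = change_matrix(df, 2000, 2010).set_index("class_code")
        assert ch.loc["3.1.1", "delta_ha"] == 0.0


def esa_frame(shares_by_year):
    rows = []
    for year, shares in shares_by_year.items():
        for cls, s in zip(ESA_CLASSES, shares):
            rows.append({"esa_class": cls, "year": year, "share_percent": s})
    return pd.DataFrame(rows)


class TestEsa:
    def test_not_affected_halving(self):
        df = esa_frame(
            {
                2000: (70, 5, 5, 5, 5, 4, 3, 3),
                2020: (35, 10, 12, 11, 10, 8, 7, 7),
            }
        )
        s = esa_summary(df)
        assert s["per_class_deltas"][(2000, 2020)]["not affected"] == pytest.approx(-35.0)
        # affected aggregate = fragile + critical subset sums
        # 2000: 5+5+5+4+3+3 = 25; 2020: 12+11+10+8+7+7 = 55
        assert s["affected_share_by_year"][2000] == pytest.approx(25.0)
        assert s["affected_share_by_year"][2020] == pytest.approx(55.0)
        assert s["affected_delta"] == pytest.approx(30.0)

    def test_all_in_one_class_no_change(self):
        df = esa_frame({2000: (100, 0, 0, 0, 0, 0, 0, 0), 2020: (100, 0, 0, 0, 0, 0, 0, 0)})
        s = esa_summary(df)
        assert all(v == 0 for v in s["per_class_deltas"][(2000, 2020)].values())

    def test_configurable_subset(self):
        df = esa_frame({2000: (70, 5, 5, 5, 5, 4, 3, 3), 2020: (35, 10, 12, 11, 10, 8, 7, 7)})
        s = esa_summary(df, affected_classes=("critical 1", "critical 2", "critical 3"))
        assert s["affected_share_by_year"][2000] == pytest.approx(10.0)

    def test_bad_sum_warns_and_renormalizes(self):
        df = esa_frame({2000: (60, 5, 5, 5, 5, 4, 3, 3), 2020: (35, 10, 12, 11, 10, 8, 7, 7)})
        assert validate_esa(df)  # warning recorded
        s = esa_summary(df, renormalize=True)
        assert s["warnings"]
        assert s["affected_share_by_year"][2000] == pytest.approx(100 * 25 / 90)

    def test_unknown_class_rejected(self):
        df = pd.DataFrame([{"esa_class": "bogus", "year": 2000, "share_percent": 100.0}])
        with pytest.raises(LandcoverValidationError, match="bogus"):
            validate_esa(df)

    def test_default_affected_subset_is_fragile_plus_critical(self):
        assert set(DEFAULT_AFFECTED_CLASSES) == {
            "fragile 1", "fragile 2", "fragile 3",
            "critical 1", "critical 2", "critical 3",
        }
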