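"""Deduplication, age handling, drug matching and the exclusion policy."""

import math

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from faerspv import (
    convert_age,
    bucket_age,
    deduplicate,
    match_drugs,
    apply_exclusions,
    build_cases,
)
from faerspv.preprocess import DrugDictionary, ExclusionEntry, ExclusionPolicy

from conftest import demo_frame, drug_frame, reac_frame, outc_frame


# --- deduplication ---------------------------------------------------------


def test_latest_fda_dt_wins():
    demo = demo_frame([("1", "c1", "20200101", "F", "30", "YR", "US"),
                       ("2", "c1", "20210101", "F", "30", "YR", "US")])
    kept, log = deduplicate(demo)
    assert list(kept["primaryid"]) == ["2"]
    assert log[-1]["removed"] == 1


def test_fda_dt_tie_broken_by_numeric_primaryid():
    # 120 > 12 numerically although "120" < "12" is false lexicographically
    demo = demo_frame([("11", "c1", "20200101", "F", "", "", "US"),
                       ("12", "c1", "20200101", "F", "", "", "US"),
                       ("120", "c1", "20200101", "F", "", "", "US")])
    kept, _ = deduplicate(demo)
    assert list(kept["primaryid"]) == ["120"]


def test_missing_date_sorts_earliest():
    demo = demo_frame([("9", "c1", "", "F", "", "", "US"),
                       ("1", "c1", "20180101", "F", "", "", "US")])
    kept, _ = deduplicate(demo)
    assert list(kept["primaryid"]) == ["1"]


def test_dedup_idempotent_and_unique_input_unchanged():
    demo = demo_frame([("1", "c1", "20200101", "F", "", "", "US"),
                       ("2", "c2", "20200101", "M", "", "", "US")])
    once, _ = deduplicate(demo)
    twice, _ = deduplicate(once)
    assert once.equals(twice)
    assert len(once) == 2


def test_missing_caseid_dropped_and_logged():
    demo = demo_frame([("1", "c1", "20200101", "F", "", "", "US")])
    demo.loc[1] = demo.loc[0]
    demo.loc[1, "primaryid"] = "2"
    demo.loc[1, "caseid"] = pd.NA
    kept, log = deduplicate(demo)
    assert len(kept) == 1
    assert log[0] == {"rule": "drop_missing_caseid", "removed": 1, "remaining": 1}


@given(st.permutations(list(range(6))))
def test_dedup_order_independent(perm):
    rows = [("101", "c1", "20200101"), ("102", "c1", "20200301"),
            ("103", "c2", "20200101"), ("104", "c2", "20200101"),
            ("105", "c3", ""), ("106", "c3", "20190101")]
    demo = demo_frame([rows[i] for i in perm])
    kept, _ = deduplicate(demo)
    assert sorted(kept["primaryid"]) == ["102", "104", "106"]


# --- age -------------------------------------------------------------------


@pytest.mark.parametrize("value,code,expected", [
    (360, "MON", 30.0),
    (5, "DEC", 50.0),
    (40, "YR", 40.0),
    (40, "", 40.0),              # blank unit code defaults to years
    (365.25, "DY", 1.0),
    (52.1775, "WK", 1.0),
    (8766, "HR", 1.0),
])
def test_convert_age_units(value, code, expected):
    assert convert_age(value, code) == pytest.approx(expected)


@pytest.mark.parametrize("value,code", [
    (200, "YR"),      # implausible
    (-1, "YR"),       # negative
    (30, "XX"),       # unknown unit
    (None, "YR"),     # missing value
    ("abc", "YR"),    # unparseable
])
def test_convert_age_missing_cases(value, code):
    assert math.isnan(convert_age(value, code))


@pytest.mark.parametrize("age,bucket", [
    (0.0, "<18"), (17.9, "<18"),
    (18.0, "18–45"), (44.99, "18–45"),
    (45.0, "45–65"), (64.99, "45–65"),   # boundary goes to the upper bucket
    (65.0, ">65"), (100.0, ">65"),
    (math.nan, "Unknown"), (None, "Unknown"),
])
def test_bucket_age_half_open_convention(age, bucket):
    assert bucket_age(age) == bucket


# --- drug matching ---------------------------------------------------------


def _dict():
    return DrugDictionary({"erenumab": ["erenumab", "aimovig"],
                           "fremanezumab": ["fremanezumab", "ajovy"]})


def test_brand_substring_matches():
    drug = drug_frame([("1", "1", "PS", "AIMOVIG (ERENUMAB)", "")])
    assert match_drugs(drug, _dict()) == {"1": {"erenumab"}}


def test_concomitant_role_not_matched_by_default():
    drug = drug_frame([("1", "1", "C", "AIMOVIG", "")])
    assert match_drugs(drug, _dict()) == {}
    assert match_drugs(drug, _dict(), roles=None) == {"1": {"erenumab"}}


def test_case_matches_multiple_targets():
    drug = drug_frame([("1", "1", "PS", "AIMOVIG", ""),
                       ("1", "2", "SS", "AJOVY", "")])
    assert match_drugs(drug, _dict()) == {"1": {"erenumab", "fremanezumab"}}


def test_prod_ai_also_searched():
    drug = drug_frame([("1", "1", "PS", "UNKNOWN BIOLOGIC", "ERENUMAB")])
    assert match_drugs(drug, _dict()) == {"1": {"erenumab"}}


def test_empty_dictionary_rejected():
    with pytest.raises(ValueError):
        DrugDictionary({})


# --- exclusions ------------------------------------------------------------


def test_default_policy_families(policy, pt_soc):
    retained, removed = apply_exclusions(
        ["Off label use", "Constipation", "Migraine", "Product quality issue"],
        policy, pt_soc,
    )
    assert retained == ["Constipation"]
    reasons = dict(removed)
    assert reasons["Off label use"] == "off-label"
    assert reasons["Migraine"] == "indication"
    assert reasons["Product quality issue"] == "product-problem"


def test_soc_level_exclusion():
    pol = ExclusionPolicy(excluded_socs=["Product issues"])
    retained, removed = apply_exclusions(
        ["Product dose omission issue"], pol, {"product dose omission issue": "Product issues"}
    )
    assert retained == [] and removed[0][1] == "soc:Product issues"


@given(st.lists(st.sampled_from(
    ["Constipation", "Off label use", "Migraine", "Nausea", "Medication error"]), max_size=12))
def test_exclusion_partitions_input(pts):
    from faerspv import default_exclusion_policy

    pol = default_exclusion_policy()
    retained, removed = apply_exclusions(pts, pol, {})
    assert len(retained) + len(removed) == len(pts)
    # nothing outside the policy closure is removed
    assert all(pol.classify(pt, None) is not None for pt, _ in removed)


# --- case assembly ---------------------------------------------------------


def test_build_cases_invariants(policy, pt_soc):
    demo = demo_frame([("11", "c1", "20200601", "F", "360", "MON", "US"),
                       ("12", "c1", "20200701", "F", "360", "MON", "US"),
                       ("21", "c2", "20210101", "M", "", "", "DE"),
                       ("31", "c3", "20190315", "X", "45", "YR", "US")])
    drug = drug_frame([("12", "1", "PS", "AIMOVIG", ""),
                       ("21", "1", "PS", "EMGALITY", ""),
                       ("31", "1", "PS", "IBUPROFEN", "")])
    reac = reac_frame([("12", "Constipation"), ("12", "Migraine"),
                       ("21", "Alopecia"), ("31", "Nausea")])
    outc = outc_frame([("12", "HO"), ("21", "DE")])
    from faerspv import default_drug_dictionary

    cases, log = build_cases(demo, drug, reac, outc,
                             default_drug_dictionary(), policy, pt_soc)
    assert cases["caseid"].is_unique and len(cases) == 3
    c1 = cases[cases["caseid"] == "c1"].iloc[0]
    assert c1["primaryid"] == "12"                 # dedup kept the later report
    assert c1["age_years"] == pytest.approx(30.0)
    assert c1["age_bucket"] == "18–45"
    assert c1["reporting_year"] == 2020
    assert c1["pts"] == ("Constipation",)          # Migraine excluded as indication
    assert c1["drug_hits"] == frozenset({"erenumab"})
    assert c1["outcomes"] == frozenset({"HO"})
    c2 = cases[cases["caseid"] == "c2"].iloc[0]
    assert math.isnan(c2["age_years"]) and c2["age_bucket"] == "Unknown"
    c3 = cases[cases["caseid"] == "c3"].iloc[0]
    assert c3["sex"] == "UNK" and c3["drug_hits"] == frozenset()
    # age missing <=> bucket Unknown, across all cases
    for _, row in cases.iterrows():
        assert math.isnan(row["age_years"]) == (row["age_bucket"] == "Unknown")
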