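"""Eligibility, Gleason/stage resolution, classification and Table-1 summary."""

import itertools

import numpy as np
import pandas as pd
import pytest

from geoaft import cohort, graphs
from geoaft.cohort import (
    apply_eligibility,
    classify_aggressiveness,
    classify_region,
    describe_cohort,
    resolve_cases,
    resolve_gleason_and_stage,
)
from conftest import toy_cases


class TestResolveGleasonStage:
    def test_pathology_takes_precedence(self):
        rec = {"gleason_path_primary": 4, "gleason_path_secondary": 4,
               "gleason_clin_primary": 3, "gleason_clin_secondary": 3,
               "stage_path": "T3", "stage_clin": "T1"}
        g, s = resolve_gleason_and_stage(rec)
        assert g == (8, 4, 4)
        assert s == "T3"

    def test_clinical_fallback(self):
        rec = {"gleason_path_primary": np.nan, "gleason_path_secondary": np.nan,
               "gleason_clin_primary": 3, "gleason_clin_secondary": 4,
               "stage_path": "unknown", "stage_clin": "T2"}
        g, s = resolve_gleason_and_stage(rec)
        assert g == (7, 3, 4)
        assert s == "T2"

    def test_both_missing(self):
        rec = {"gleason_path_primary": np.nan, "gleason_path_secondary": np.nan,
               "gleason_clin_primary": np.nan, "gleason_clin_secondary": np.nan,
               "stage_path": "unknown", "stage_clin": "unknown"}
        g, s = resolve_gleason_and_stage(rec)
        assert g is None
        assert s == "unknown"


class TestEligibility:
    def test_age_rule(self):
        df = toy_cases([{"age_at_dx": 39}])
        g = graphs.make_county_graph(4, "grid", 0)
        elig, tally = apply_eligibility(resolve_cases(df, g))
        assert len(elig) == 0
        assert tally["age_or_missing_age"] == 1

    def test_missing_gs_with_t3_included(self):
        df = toy_cases([{
            "gleason_clin_primary": np.nan, "gleason_clin_secondary": np.nan,
            "stage_clin": "T3", "age_at_dx": 65,
        }])
        g = graphs.make_county_graph(4, "grid", 0)
        elig, tally = apply_eligibility(resolve_cases(df, g))
        assert len(elig) == 1
        assert sum(tally.values()) == 0

    def test_ten_record_toy_tally(self):
        """2 GS<6, 3 missing-GS/T2, 1 underage, 4 clean -> 4 eligible."""
        rows = (
            [{"gleason_clin_primary": 2, "gleason_clin_secondary": 3}] * 2
            + [{"gleason_clin_primary": np.nan, "gleason_clin_secondary": np.nan,
                "stage_clin": "T2"}] * 3
            + [{"age_at_dx": 38}]
            + [{}] * 4
        )
        g = graphs.make_county_graph(4, "grid", 0)
        elig, tally = apply_eligibility(resolve_cases(toy_cases(rows), g))
        assert len(elig) == 4
        assert tally == {"age_or_missing_age": 1, "gs_below_6": 2,
                         "missing_gs_not_t34": 3}

    def test_precedence_age_over_gleason(self):
        df = toy_cases([{"age_at_dx": 35, "gleason_clin_primary": 2,
                         "gleason_clin_secondary": 2}])
        g = graphs.make_county_graph(4, "grid", 0)
        _, tally = apply_eligibility(resolve_cases(df, g))
        assert tally["age_or_missing_age"] == 1
        assert tally["gs_below_6"] == 0

    def test_counts_conserved(self, sim_cohort, grid16):
        cases, _ = sim_cohort
        resolved = resolve_cases(cases, grid16)
        elig, tally = apply_eligibility(resolved)
        assert len(elig) + sum(tally.values()) == len(cases)


class TestAggressiveness:
    @pytest.mark.parametrize("gleason,stage,meta,expected", [
        ((7, 3, 4), "T2", "no", "less"),
        ((7, 4, 3), "T1", "no", "more"),
        (None, "T3", "unknown", "more"),
        ((6, 3, 3), "T1", "no", "less"),
        ((9, 4, 5), "T1", "no", "more"),
        ((6, 3, 3), "unknown", "no", "unknown"),
        ((6, 3, 3), "T2", "unknown", "unknown"),
        ((6, 3, 3), "T2", "yes", "more"),
    ])
    def test_rules(self, gleason, stage, meta, expected):
        assert classify_aggressiveness(gleason, stage, meta) == expected

    def test_total_over_domain(self):
        """Every combination maps to exactly one of the three labels."""
        gleasons = [None] + [(p + s, p, s) for p, s in
                             itertools.product([3, 4, 5], repeat=2)]
        for g, st, m in itertools.product(
                gleasons, ["T1", "T2", "T3", "T4", "unknown"],
                ["yes", "no", "unknown"]):
            assert classify_aggressiveness(g, st, m) in {"less", "more", "unknown"}


class TestRegion:
    @pytest.mark.parametrize("app,rucc,expected", [
        (True, 6, "rural_appalachia"),
        (False, 2, "urban_non_appalachia"),
        (True, 3, "urban_appalachia"),
        (False, 7, "rural_non_appalachia"),
    ])
    def test_rucc_cross(self, app, rucc, expected):
        assert classify_region(app, rucc) == expected

    def test_unknown_county_raises(self, grid16):
        df = toy_cases([{"county_fips": "nope"}])
        with pytest.raises(KeyError):
            resolve_cases(df, grid16)


class TestDescribe:
    def test_identical_groups_chi2_zero(self, grid16):
        rows = [{"county_fips": "g00000", "race": r} for r in
                ["white"] * 5 + ["black"] * 5]
        rows += [{"county_fips": "g00001", "race": r} for r in
                 ["white"] * 5 + ["black"] * 5]
        df = resolve_cases(toy_cases(rows), grid16)
        df["eligible"] = True
        d = describe_cohort(df, grouping="catchment", continuous=(),
                            categorical=("race",))
        assert d["tests"]["race"]["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_2x2_chi2_hand_value(self, grid16):
        # table (10,20 / 20,10): chi-square = sum (O-E)^2/E = 6.67 uncorrected
        rows = [{"county_fips": "g00000", "race": r} for r in
                ["white"] * 10 + ["black"] * 20]
        rows += [{"county_fips": "g00001", "race": r} for r in
                 ["white"] * 20 + ["black"] * 10]
        df = resolve_cases(toy_cases(rows), grid16)
        d = describe_cohort(df, grouping="catchment", continuous=(),
                            categorical=("race",))
        assert d["tests"]["race"]["statistic"] == pytest.approx(20 / 3, abs=0.01)
        assert d["tests"]["race"]["df"] == 1

    def test_equal_means_f_near_zero(self, grid16):
        rows = [{"county_fips": c, "age_at_dx": a}
                for c in ("g00000", "g00001") for a in (60, 65, 70)]
        df = resolve_cases(toy_cases(rows), grid16)
        d = describe_cohort(df, grouping="catchment",
                            continuous=("age_at_dx",), categorical=())
        assert d["tests"]["age_at_dx"]["F"] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_variance_reported_not_raised(self, grid16):
        rows = [{"county_fips": c, "age_at_dx": 65}
                for c in ("g00000", "g00001") for _ in range(3)]
        df = resolve_cases(toy_cases(rows), grid16)
        d = describe_cohort(df, grouping="catchment",
                            continuous=("age_at_dx",), categorical=())
        assert d["tests"]["age_at_dx"].get("degenerate") is True

    def test_column_percentages_sum_100(self, sim_cohort, grid16):
        cases, _ = sim_cohort
        elig, _ = apply_eligibility(resolve_cases(cases, grid16))
        d = describe_cohort(elig, grouping="catchment")
        summ = d["summary"]
        for var in ("race", "treatment"):
            block = summ[summ["variable"] == var]
            for col in block.columns[2:]:
                pct = block[col].str.extract(r"\(([\d.]+)\)")[0].astype(float)
                assert pct.sum() == pytest.approx(100.0, abs=0.1)

    def test_unknowns_dropped_from_tests(self, grid16):
        # unknown-insurance counts differ wildly between groups, but the
        # known levels are identically distributed -> statistic ~ 0
        rows = [{"county_fips": "g00000", "insurance": x} for x in
                ["insured"] * 5 + ["uninsured"] * 5 + ["unknown"] * 20]
        rows += [{"county_fips": "g00001", "insurance": x} for x in
                 ["insured"] * 5 + ["uninsured"] * 5]
        df = resolve_cases(toy_cases(rows), grid16)
        d = describe_cohort(df, grouping="catchment", continuous=(),
                            categorical=("insurance",))
        assert d["tests"]["insurance"]["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_groups_raises(self, grid16):
        df = resolve_cases(toy_cases([{"county_fips": "g00000"}] * 4), grid16)
        with pytest.raises(ValueError):
            describe_cohort(df, grouping="catchment")
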