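"""Ingest, deduplication, vocabulary mapping and summarization."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pvsignal as pv
from pvsignal.report_store import parse_flexible_date, standardize_drug_name

from conftest import make_reportset


CANONICAL_REPORTS = """case_id,sex,age_years,weight_kg,country,event_date,report_date,indications
A1,male,63.0,80.0,US,2020-02-04,2020-03-01,NON-SMALL CELL LUNG CANCER
A2,female,55.0,,JP,,2021-06-15,
A3,,70.0,62.0,FR,2019-11-30,2019-12-20,LUNG NEOPLASM MALIGNANT
"""
CANONICAL_DRUGS = """case_id,drug_name,role,start_date
A1,CRIZOTINIB,suspect,2020-01-01
A3,alectinib,suspect,2019-10-01
"""
CANONICAL_EVENTS = """case_id,pt,soc
A1,NAUSEA,
A1,RASH,
A2,FATIGUE,
A3,NAUSEA,
"""


@pytest.fixture
def canonical_dir(tmp_path):
    (tmp_path / "reports.csv").write_text(CANONICAL_REPORTS)
    (tmp_path / "drugs.csv").write_text(CANONICAL_DRUGS)
    (tmp_path / "events.csv").write_text(CANONICAL_EVENTS)
    return tmp_path


class TestLoading:
    def test_canonical_csv_counts(self, canonical_dir):
        rs = pv.load_reports([canonical_dir], dialect="canonical_csv")
        assert (rs.n_reports, len(rs.drugs), len(rs.events)) == (3, 2, 4)
        assert rs.drugs["drug_name_std"].tolist() == ["CRIZOTINIB", "ALECTINIB"]

    def test_blank_sex_becomes_unknown(self, canonical_dir):
        rs = pv.load_reports([canonical_dir], dialect="canonical_csv")
        assert rs.reports.set_index("case_id").loc["A3", "sex"] == "unknown"
        summ = pv.summarize_demographics(rs)
        assert int(summ.sex.set_index("sex").loc["unknown", "count"]) == 1

    def test_empty_events_warns(self, canonical_dir):
        (canonical_dir / "events.csv").write_text("case_id,pt,soc\n")
        with pytest.warns(UserWarning, match="zero events"):
            rs = pv.load_reports([canonical_dir], dialect="canonical_csv")
        assert rs.n_reports == 3 and len(rs.events) == 0

    def test_missing_mandatory_table_names_it(self, canonical_dir):
        (canonical_dir / "drugs.csv").unlink()
        with pytest.raises(FileNotFoundError, match="drugs.csv"):
            pv.load_reports([canonical_dir], dialect="canonical_csv")

    def test_faers_ascii(self, tmp_path):
        (tmp_path / "DEMO25Q1.txt").write_text(
            "primaryid$caseid$caseversion$event_dt$fda_dt$sex$age$age_cod$wt$wt_cod$occr_country\n"
            "101$C1$1$20200204$20200301$M$63$YR$176$LBS$US\n"
            "102$C2$1$2021$20210615$F$660$MON$$$JP\n"
            "bad$line\n")
        (tmp_path / "DRUG25Q1.txt").write_text(
            "primaryid$caseid$drug_seq$role_cod$drugname\n"
            "101$C1$1$PS$Crizotinib\n102$C2$1$SS$ALECTINIB\n")
        (tmp_path / "REAC25Q1.txt").write_text(
            "primaryid$caseid$pt\n101$C1$Nausea\n101$C1$Rash\n102$C2$Fatigue\n")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rs = pv.load_reports([tmp_path], dialect="faers_ascii")
        assert rs.n_reports == 2
        assert rs.meta["n_malformed_rows"] == 1
        rep = rs.reports.set_index("case_id")
        assert rep.loc["C1", "sex"] == "male"
        assert rep.loc["C1", "weight_kg"] == pytest.approx(79.8, abs=0.1)
        # month-coded age converts to years; partial event date -> missing
        assert rep.loc["C2", "age_years"] == pytest.approx(55.0)
        assert pd.isna(rep.loc["C2", "event_date"])
        assert rs.drugs["role"].tolist() == ["suspect", "suspect"]
        assert rs.events["pt"].tolist() == ["NAUSEA", "RASH", "FATIGUE"]

    def test_faers_missing_mandatory_table(self, tmp_path):
        (tmp_path / "DEMO.txt").write_text("caseid$sex\nC1$M\n")
        with pytest.raises(FileNotFoundError, match="DRUG"):
            pv.load_reports([tmp_path], dialect="faers_ascii")

    def test_roundtrip_lossless(self, canonical_dir, tmp_path):
        rs = pv.load_reports([canonical_dir], dialect="canonical_csv")
        out1 = tmp_path / "w1"
        out2 = tmp_path / "w2"
        pv.write_reports(rs, out1)
        pv.write_reports(pv.load_reports([out1]), out2)
        for name in ("reports.csv", "drugs.csv", "events.csv"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()


@pytest.mark.parametrize("raw, full, year", [
    ("20200204", "2020-02-04", 2020),
    ("202002", None, 2020),
    ("2020", None, 2020),
    ("2020-02-04", "2020-02-04", 2020),
    ("", None, None),
    ("garbage", None, None),
])
def test_parse_flexible_date(raw, full, year):
    ts, yr = parse_flexible_date(raw)
    assert (None if pd.isna(ts) else str(ts.date())) == full
    assert (None if np.isnan(yr) else int(yr)) == year


def test_standardize_drug_name_synonyms():
    assert standardize_drug_name("  xalkori ", {"XALKORI": "CRIZOTINIB"}) == "CRIZOTINIB"
    assert standardize_drug_name("Crizotinib  250mg") == "CRIZOTINIB 250MG"


class TestDeduplicate:
    def test_all_distinct_identity(self):
        rs = make_reportset([
            {"case_id": "A", "sex": "male", "age_years": 60, "country": "US",
             "report_date": "2020-01-01"},
            {"case_id": "B", "sex": "female", "age_years": 50, "country": "JP",
             "report_date": "2020-01-02"},
        ])
        out, log = pv.deduplicate(rs)
        assert out.n_reports == 2 and len(log.removed) == 0

    def test_same_case_id_keeps_latest_version(self):
        rs = make_reportset([
            {"case_id": "A", "age_years": 60, "report_date": "2020-01-01", "file_seq": 0},
            {"case_id": "A", "age_years": 61, "report_date": "2020-06-01", "file_seq": 1},
        ])
        out, log = pv.deduplicate(rs)
        assert out.n_reports == 1
        assert out.reports.iloc[0]["age_years"] == 61
        assert log.n_stage1 == 1

    def test_cross_id_duplicates_hand_count(self):
        # 10 reports; C8/C9 clone C0/C1 demographics -> 8 survive
        base = [{"case_id": f"C{i}", "sex": "male", "age_years": 40 + i,
                 "country": "US", "report_date": "2021-03-01"} for i in range(8)]
        clones = [dict(base[0], case_id="C8"), dict(base[1], case_id="C9")]
        out, log = pv.deduplicate(make_reportset(base + clones))
        assert out.n_reports == 8
        assert log.removed_ids() == {"C8", "C9"}
        assert set(log.removed["stage"]) == {2}

    def test_incomplete_fields_never_collapse(self):
        # same tuple except age missing on both -> stage 2 must not touch them
        rs = make_reportset([
            {"case_id": "A", "sex": "male", "country": "US", "report_date": "2020-01-01"},
            {"case_id": "B", "sex": "male", "country": "US", "report_date": "2020-01-01"},
        ])
        out, _ = pv.deduplicate(rs)
        assert out.n_reports == 2

    def test_survivor_is_most_complete_then_smallest_id(self):
        shared = {"sex": "female", "age_years": 55, "country": "JP",
                  "report_date": "2022-05-05"}
        rs = make_reportset([
            dict(shared, case_id="B", weight_kg=60.0),
            dict(shared, case_id="A"),
            dict(shared, case_id="C", weight_kg=60.0),
        ])
        out, log = pv.deduplicate(rs)
        # B and C are equally complete and beat A; B wins on case_id
        assert out.reports["case_id"].tolist() == ["B"]
        assert log.removed_ids() == {"A", "C"}

    def test_idempotent_and_logged(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(40):
            rows.append({"case_id": f"R{i:02d}", "sex": rng.choice(["male", "female"]),
                         "age_years": float(rng.integers(30, 35)),
                         "country": rng.choice(["US", "JP"]),
                         "report_date": "2020-07-01"})
        rs = make_reportset(rows)
        once, log = pv.deduplicate(rs)
        twice, log2 = pv.deduplicate(once)
        pd.testing.assert_frame_equal(once.reports, twice.reports)
        assert len(log2.removed) == 0
        removed = set(rs.reports["case_id"]) - set(once.reports["case_id"])
        assert removed == log.removed_ids()
        assert once.n_reports <= rs.n_reports


class TestMapMeddra:
    def test_lookup_and_unmapped(self):
        rs = make_reportset([{"case_id": "A"}], events=[
            {"case_id": "A", "pt": "NAUSEA"}, {"case_id": "A", "pt": "WEIRDNESS"}])
        out = pv.map_meddra(rs, {"NAUSEA": "Gastrointestinal disorders"})
        by_pt = out.events.set_index("pt")["soc"]
        assert by_pt["NAUSEA"] == "Gastrointestinal disorders"
        assert pd.isna(by_pt["WEIRDNESS"])
        assert out.meta["n_unmapped_events"] == 1

    def test_empty_events(self):
        rs = make_reportset([{"case_id": "A"}])
        out = pv.map_meddra(rs, {"NAUSEA": "GI"})
        assert out.meta["n_unmapped_events"] == 0

    def test_conflicting_vocabulary_rejected(self):
        rs = make_reportset([{"case_id": "A"}], events=[{"case_id": "A", "pt": "NAUSEA"}])
        vocab = pd.DataFrame({"pt": ["NAUSEA", "NAUSEA"], "soc": ["GI", "Cardiac"]})
        with pytest.raises(ValueError, match="conflicting"):
            pv.map_meddra(rs, vocab)


class TestFilterByDrug:
    @pytest.fixture
    def five_case_rs(self):
        return make_reportset(
            [{"case_id": f"P{i}"} for i in range(5)],
            drugs=[{"case_id": "P0", "drug_name_std": "CRIZOTINIB", "role": "suspect"},
                   {"case_id": "P1", "drug_name_std": "CRIZOTINIB", "role": "suspect"},
                   {"case_id": "P2", "drug_name_std": "CRIZOTINIB", "role": "concomitant"},
                   {"case_id": "P3", "drug_name_std": "OTHER", "role": "suspect"}])

    def test_suspect_only(self, five_case_rs):
        out = pv.filter_by_drug(five_case_rs, {"crizotinib"})
        assert set(out.reports["case_id"]) == {"P0", "P1"}

    def test_role_union(self, five_case_rs):
        out = pv.filter_by_drug(five_case_rs, {"CRIZOTINIB"}, {"suspect", "concomitant"})
        assert set(out.reports["case_id"]) == {"P0", "P1", "P2"}

    def test_no_match_empty_and_subset(self, five_case_rs):
        out = pv.filter_by_drug(five_case_rs, {"NOSUCHDRUG"})
        assert out.n_reports == 0
        out2 = pv.filter_by_drug(five_case_rs, {"OTHER"})
        assert set(out2.reports["case_id"]) <= set(five_case_rs.reports["case_id"])


class TestDemographics:
    def test_age_binning(self):
        rs = make_reportset([{"case_id": "A", "age_years": 10},
                             {"case_id": "B", "age_years": 30},
                             {"case_id": "C", "age_years": 70},
                             {"case_id": "D"}])
        summ = pv.summarize_demographics(rs)
        counts = summ.age.set_index("bin")["count"]
        assert counts.tolist() == [1, 1, 1, 0, 1]
        assert counts.sum() == summ.total

    def test_empty_reportset(self):
        summ = pv.summarize_demographics(make_reportset([]))
        assert summ.total == 0
        assert summ.sex["count"].sum() == 0

    def test_categories_sum_to_total(self):
        rng = np.random.default_rng(1)
        rows = [{"case_id": f"X{i}",
                 "sex": rng.choice(["male", "female", "unknown"]),
                 "age_years": float(rng.integers(5, 95)) if rng.random() > 0.3 else np.nan,
                 "weight_kg": float(rng.integers(40, 120)) if rng.random() > 0.5 else np.nan}
                for i in range(57)]
        summ = pv.summarize_demographics(make_reportset(rows))
        for frame in (summ.sex, summ.age, summ.weight):
            assert frame["count"].sum() == 57
            assert frame["percent"].sum() == pytest.approx(100.0)


class TestAnnualTrend:
    def test_perfect_linear(self):
        fit = pv.fit_annual_trend({2015: 10, 2016: 20, 2017: 30, 2018: 40}, degree=1)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_closed_form_simple_regression(self):
        years = np.arange(2015, 2020, dtype=float)
        counts = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        fit = pv.fit_annual_trend(dict(zip(years.astype(int), counts)), degree=1)
        # closed-form least squares: slope = Sxy/Sxx, R^2 = r^2
        sxx = np.sum((years - years.mean()) ** 2)
        sxy = np.sum((years - years.mean()) * (counts - counts.mean()))
        syy = np.sum((counts - counts.mean()) ** 2)
        assert fit.r_squared == pytest.approx(sxy ** 2 / (sxx * syy), rel=1e-12)
        assert fit.coefficients[1] == pytest.approx(sxy / sxx, rel=1e-9)

    def test_constant_counts_defined_r2(self):
        with pytest.warns(UserWarning, match="zero total variance"):
            fit = pv.fit_annual_trend({2015: 7, 2016: 7, 2017: 7, 2018: 7}, degree=1)
        assert fit.r_squared == 1.0

    def test_insufficient_years(self):
        with pytest.raises(ValueError, match="distinct years"):
            pv.fit_annual_trend({2015: 1, 2016: 2}, degree=1)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_dedup_never_increases_and_is_idempotent(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 25))
    rows = [{"case_id": f"H{rng.integers(0, n)}",
             "sex": rng.choice(["male", "female"]),
             "age_years": float(rng.integers(40, 44)),
             "country": "US",
             "report_date": "2020-01-01",
             "file_seq": i} for i in range(n)]
    rs = make_reportset(rows)
    once, log = pv.deduplicate(rs)
    twice, _ = pv.deduplicate(once)
    assert once.n_reports <= rs.n_reports
    assert once.n_reports == twice.n_reports
    assert len(log.removed) == rs.n_reports - once.n_reports
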