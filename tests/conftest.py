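"""Shared fixtures: hand-built report sets and brute-force counting oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pvsignal.report_store import (REPORT_COLUMNS, DRUG_COLUMNS, EVENT_COLUMNS,
                                   ReportSet, _coerce_report_dtypes,
                                   _coerce_drug_dtypes, _coerce_event_dtypes)

REPORT_DEFAULTS = {"sex": "unknown", "age_years": np.nan, "weight_kg": np.nan,
                   "country": np.nan, "event_date": pd.NaT, "report_date": pd.NaT,
                   "report_year": np.nan, "indications": "", "file_seq": None}


def make_reportset(reports, drugs=(), events=(), provenance="test") -> ReportSet:
    """Build a ReportSet from row dicts, filling unspecified fields."""
    rep_rows = []
    for i, r in enumerate(reports):
        row = dict(REPORT_DEFAULTS, **r)
        if row["file_seq"] is None:
            row["file_seq"] = i
        if pd.isna(row["report_year"]) and not pd.isna(row["report_date"]):
            row["report_year"] = pd.Timestamp(row["report_date"]).year
        rep_rows.append(row)
    rep = pd.DataFrame(rep_rows, columns=REPORT_COLUMNS)
    dr = pd.DataFrame([{"drug_name_raw": d.get("drug_name_std", ""),
                        "role": "suspect", "start_date": pd.NaT, **d}
                       for d in drugs], columns=DRUG_COLUMNS)
    ev = pd.DataFrame([{"soc": np.nan, **e} for e in events], columns=EVENT_COLUMNS)
    return ReportSet(_coerce_report_dtypes(rep), _coerce_drug_dtypes(dr),
                     _coerce_event_dtypes(ev), provenance)


def brute_contingency(rs: ReportSet, drug: str, event: str, level: str = "PT"
                      ) -> tuple[int, int, int, int]:
    """Exhaustive nested-loop 2×2 count over report–distinct-term pairs."""
    col = "pt" if level == "PT" else "soc"
    exposed = set()
    for _, d in rs.drugs.iterrows():
        if d["drug_name_std"] == drug.upper() and d["role"] == "suspect":
            exposed.add(d["case_id"])
    a = b = c = d_ = 0
    for _, r in rs.reports.iterrows():
        cid = r["case_id"]
        terms = set()
        for _, e in rs.events.iterrows():
            if e["case_id"] == cid and not pd.isna(e[col]):
                terms.add(e[col])
        for term in terms:
            if cid in exposed:
                if term == event.upper() if col == "pt" else term == event:
                    a += 1
                else:
                    b += 1
            else:
                if term == event.upper() if col == "pt" else term == event:
                    c += 1
                else:
                    d_ += 1
    return a, b, c, d_


def brute_sex_table(rs: ReportSet, drug: str, pt: str) -> tuple[int, int, int, int]:
    """Exhaustive tally of the male/female PT pair counts within a drug."""
    exposed = {d["case_id"] for _, d in rs.drugs.iterrows()
               if d["drug_name_std"] == drug.upper() and d["role"] == "suspect"}
    sex_of = {r["case_id"]: r["sex"] for _, r in rs.reports.iterrows()}
    a_m = b_m = c_f = d_f = 0
    for cid in exposed:
        terms = {e["pt"] for _, e in rs.events.iterrows() if e["case_id"] == cid}
        for term in terms:
            if sex_of.get(cid) == "male":
                if term == pt.upper():
                    a_m += 1
                else:
                    b_m += 1
            elif sex_of.get(cid) == "female":
                if term == pt.upper():
                    c_f += 1
                else:
                    d_f += 1
    return a_m, b_m, c_f, d_f


@pytest.fixture
def six_report_rs() -> ReportSet:
    """Six reports, mixed exposure and PT multiplicity, for oracle checks."""
    return make_reportset(
        reports=[{"case_id": f"R{i}", "sex": s}
                 for i, s in enumerate(["male", "female", "male", "female", "male", "unknown"])],
        drugs=[{"case_id": "R0", "drug_name_std": "TARGET", "role": "suspect"},
               {"case_id": "R1", "drug_name_std": "TARGET", "role": "suspect"},
               {"case_id": "R2", "drug_name_std": "TARGET", "role": "concomitant"},
               {"case_id": "R2", "drug_name_std": "OTHER", "role": "suspect"},
               {"case_id": "R3", "drug_name_std": "OTHER", "role": "suspect"},
               {"case_id": "R4", "drug_name_std": "TARGET", "role": "suspect"},
               {"case_id": "R5", "drug_name_std": "OTHER", "role": "suspect"}],
        events=[{"case_id": "R0", "pt": "NAUSEA"},
                {"case_id": "R0", "pt": "NAUSEA"},      # repeated mention
                {"case_id": "R0", "pt": "RASH"},
                {"case_id": "R1", "pt": "NAUSEA"},
                {"case_id": "R1", "pt": "VOMITING"},
                {"case_id": "R2", "pt": "NAUSEA"},
                {"case_id": "R3", "pt": "RASH"},
                {"case_id": "R4", "pt": "VOMITING"},
                {"case_id": "R5", "pt": "NAUSEA"}],
    )


def random_reportset(rng: np.random.Generator, n_reports: int = 30) -> ReportSet:
    """Small random ReportSet for oracle-equivalence batteries."""
    drugs_pool = ["TARGET", "OTHER_A", "OTHER_B"]
    pts_pool = ["NAUSEA", "RASH", "VOMITING", "FATIGUE", "COUGH"]
    reports, drugs, events = [], [], []
    for i in range(n_reports):
        cid = f"S{i:03d}"
        reports.append({"case_id": cid,
                        "sex": rng.choice(["male", "female", "unknown"], p=[0.45, 0.45, 0.1])})
        for dn in drugs_pool:
            if rng.random() < 0.4:
                drugs.append({"case_id": cid, "drug_name_std": dn,
                              "role": rng.choice(["suspect", "concomitant"], p=[0.8, 0.2])})
        for pt in pts_pool:
            if rng.random() < 0.35:
                events.append({"case_id": cid, "pt": pt})
    return make_reportset(reports, drugs, events)
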