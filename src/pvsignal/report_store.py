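"""Loading, standardization, deduplication and summarization of spontaneous
adverse-event report databases.

A :class:`ReportSet` holds three aligned tables — case reports, drug records
and PT-coded event records — in the shape shared by FAERS-style quarterly
extracts and by the package's canonical CSV dialect.  All downstream signal
statistics operate on a deduplicated, vocabulary-mapped ``ReportSet``.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("male", "female", "unknown")
ROLES = ("suspect", "concomitant", "interacting", "unknown")

#: FAERS role_cod values -> canonical role names (PS/SS both count as suspect).
_FAERS_ROLE_MAP = {"PS": "suspect", "SS": "suspect", "C": "concomitant", "I": "interacting"}
_FAERS_SEX_MAP = {"M": "male", "F": "female"}

REPORT_COLUMNS = [
    "case_id", "sex", "age_years", "weight_kg", "country",
    "event_date", "report_date", "report_year", "indications", "file_seq",
]
DRUG_COLUMNS = ["case_id", "drug_name_raw", "drug_name_std", "role", "start_date"]
EVENT_COLUMNS = ["case_id", "pt", "soc"]


def parse_flexible_date(value) -> tuple[pd.Timestamp, float]:
    """Parse a date that may be full, partial (year or year-month) or missing.

    Accepts ``YYYYMMDD`` / ``YYYYMM`` / ``YYYY`` (FAERS) and ISO
    ``YYYY-MM-DD`` / ``YYYY-MM`` forms.  Returns ``(timestamp, year)`` where a
    partial date yields ``(NaT, year)`` — partial dates count for annual
    trends but are treated as missing everywhere a full calendar date is
    required (stage-2 dedup, time-to-onset).
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return pd.NaT, np.nan
    s = str(value).strip().replace("-", "")
    if not s or s.lower() in {"nan", "nat", "none"}:
        return pd.NaT, np.nan
    if not s.isdigit():
        return pd.NaT, np.nan
    if len(s) == 8:
        ts = pd.to_datetime(s, format="%Y%m%d", errors="coerce")
        return (ts, float(ts.year)) if ts is not pd.NaT else (pd.NaT, np.nan)
    if len(s) == 6:  # YYYYMM
        return pd.NaT, float(s[:4])
    if len(s) == 4:  # YYYY
        return pd.NaT, float(s)
    return pd.NaT, np.nan


def standardize_drug_name(name: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Case-fold and strip a verbatim drug name, then apply a synonym table.

    The synonym table maps already-standardized names (e.g. brand names) onto
    preferred generic names.  No fuzzy matching is attempted.
    """
    std = " ".join(str(name).upper().split())
    if synonyms:
        std = synonyms.get(std, std)
    return std


@dataclass
class ReportSet:
    """Case reports plus their drug and event records.

    ``reports`` has one row per case report; ``drugs`` and ``events`` attach
    to it by ``case_id``.  ``meta`` carries bookkeeping counters (parse
    warnings, unmapped PTs) that operations accumulate.
    """

    reports: pd.DataFrame
    drugs: pd.DataFrame
    events: pd.DataFrame
    provenance: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for frame, cols in ((self.reports, REPORT_COLUMNS),
                            (self.drugs, DRUG_COLUMNS),
                            (self.events, EVENT_COLUMNS)):
            missing = [c for c in cols if c not in frame.columns]
            if missing:
                raise ValueError(f"ReportSet frame missing columns {missing}")

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    def copy(self) -> "ReportSet":
        return ReportSet(self.reports.copy(), self.drugs.copy(), self.events.copy(),
                         self.provenance, dict(self.meta))

    def validate(self) -> None:
        """Check referential integrity and case-id uniqueness."""
        ids = set(self.reports["case_id"])
        if len(ids) != len(self.reports):
            raise ValueError("duplicate case_id in reports")
        for name, frame in (("drugs", self.drugs), ("events", self.events)):
            orphans = set(frame["case_id"]) - ids
            if orphans:
                raise ValueError(f"{name} rows reference unknown case_ids: {sorted(orphans)[:5]}")


def _empty_reports() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in REPORT_COLUMNS})
    return _coerce_report_dtypes(df)


def _coerce_report_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["case_id"] = df["case_id"].astype(str)
    df["sex"] = df["sex"].where(df["sex"].isin(SEXES), "unknown")
    for col in ("age_years", "weight_kg", "report_year"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("event_date", "report_date"):
        df[col] = pd.to_datetime(df[col], errors="coerce")
    df["country"] = df["country"].astype(object).where(df["country"].notna() & (df["country"] != ""), np.nan)
    df["indications"] = df["indications"].fillna("").astype(str)
    df["file_seq"] = pd.to_numeric(df["file_seq"], errors="coerce").fillna(0).astype(int)
    bad_age = df["age_years"] < 0
    if bad_age.any():
        logger.warning("%d negative ages set to missing", int(bad_age.sum()))
        df.loc[bad_age, "age_years"] = np.nan
    bad_wt = df["weight_kg"] <= 0
    if bad_wt.any():
        df.loc[bad_wt, "weight_kg"] = np.nan
    return df


def _coerce_drug_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["case_id"] = df["case_id"].astype(str)
    df["drug_name_raw"] = df["drug_name_raw"].astype(str)
    df["drug_name_std"] = df["drug_name_std"].astype(str)
    df["role"] = df["role"].where(df["role"].isin(ROLES), "unknown")
    df["start_date"] = pd.to_datetime(df["start_date"], errors="coerce")
    return df


def _coerce_event_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["case_id"] = df["case_id"].astype(str)
    df["pt"] = df["pt"].astype(str).str.strip().str.upper()
    if "soc" not in df.columns:
        df["soc"] = np.nan
    return df


# ---------------------------------------------------------------------------
# Loading


def _read_delimited(path: Path, delimiter: str) -> tuple[pd.DataFrame, int]:
    """Read a delimited text table, skipping malformed rows with a warning.

    Returns the frame plus the number of rows dropped for having the wrong
    field count.
    """
    with open(path, newline="", encoding="utf-8", errors="replace") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            return pd.DataFrame(), 0
        header = [h.strip().lower() for h in header]
        rows, bad = [], 0
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                logger.warning("%s line %d: expected %d fields, got %d — row skipped",
                               path.name, lineno, len(header), len(row))
                bad += 1
                continue
            rows.append(row)
    df = pd.DataFrame(rows, columns=header).replace("", np.nan)
    return df, bad


def _find_table(paths: Sequence[Path], prefix: str) -> Path | None:
    for p in paths:
        if p.name.upper().startswith(prefix):
            return p
    return None


def _first(df: pd.DataFrame, *names: str) -> pd.Series:
    for n in names:
        if n in df.columns:
            return df[n]
    return pd.Series(np.nan, index=df.index)


def _load_faers_ascii(paths: Sequence[Path], synonyms: Mapping[str, str] | None) -> ReportSet:
    meta: dict = {"n_malformed_rows": 0}
    tables = {}
    for prefix in ("DEMO", "DRUG", "REAC", "THER", "INDI"):
        p = _find_table(paths, prefix)
        if p is None:
            if prefix in ("DEMO", "DRUG", "REAC"):
                raise FileNotFoundError(f"mandatory FAERS table {prefix} not found among inputs")
            tables[prefix] = None
            continue
        df, bad = _read_delimited(p, "$")
        meta["n_malformed_rows"] += bad
        tables[prefix] = df

    demo = tables["DEMO"]
    if demo.empty:
        raise ValueError("DEMO table is empty")
    case_id = _first(demo, "caseid", "primaryid", "isr").astype(str)

    event_parsed = _first(demo, "event_dt").map(parse_flexible_date)
    report_raw = _first(demo, "fda_dt", "rept_dt", "init_fda_dt")
    report_parsed = report_raw.map(parse_flexible_date)

    age = pd.to_numeric(_first(demo, "age"), errors="coerce")
    age_cod = _first(demo, "age_cod").astype(str).str.upper()
    factor = age_cod.map({"YR": 1.0, "DEC": 10.0, "MON": 1 / 12, "WK": 1 / 52.18, "DY": 1 / 365.25}).fillna(1.0)
    age_years = age * factor

    wt = pd.to_numeric(_first(demo, "wt"), errors="coerce")
    wt_cod = _first(demo, "wt_cod").astype(str).str.upper()
    wt_kg = wt * wt_cod.map({"KG": 1.0, "KGS": 1.0, "LBS": 0.4536, "GMS": 0.001}).fillna(1.0)

    sex = _first(demo, "sex", "gndr_cod").astype(str).str.strip().str.upper().map(_FAERS_SEX_MAP).fillna("unknown")

    indi = tables.get("INDI")
    ind_map: dict[str, str] = {}
    if indi is not None and not indi.empty:
        icase = _first(indi, "caseid", "primaryid").astype(str)
        ipt = _first(indi, "indi_pt").astype(str).str.strip().str.upper()
        ind_map = {cid: ";".join(sorted(set(g))) for cid, g in ipt.groupby(icase)}

    caseversion = pd.to_numeric(_first(demo, "caseversion"), errors="coerce").fillna(0)
    reports = pd.DataFrame({
        "case_id": case_id,
        "sex": sex,
        "age_years": age_years,
        "weight_kg": wt_kg,
        "country": _first(demo, "occr_country", "reporter_country"),
        "event_date": [d for d, _ in event_parsed],
        "report_date": [d for d, _ in report_parsed],
        "report_year": [y for _, y in report_parsed],
        "indications": case_id.map(ind_map).fillna(""),
        # FAERS caseversion folds into the file-order component of the
        # version key so the latest amendment wins stage-1 dedup.
        "file_seq": np.arange(len(demo)) + caseversion.to_numpy() * len(demo),
    })

    drug = tables["DRUG"]
    dcase = _first(drug, "caseid", "primaryid").astype(str)
    raw = _first(drug, "drugname", "drug_name").astype(str)
    drugs = pd.DataFrame({
        "case_id": dcase,
        "drug_name_raw": raw,
        "drug_name_std": raw.map(lambda s: standardize_drug_name(s, synonyms)),
        "role": _first(drug, "role_cod").astype(str).str.strip().str.upper().map(_FAERS_ROLE_MAP).fillna("unknown"),
        "start_date": pd.NaT,
    })

    ther = tables.get("THER")
    if ther is not None and not ther.empty:
        tcase = _first(ther, "caseid", "primaryid").astype(str)
        tstart = _first(ther, "start_dt").map(lambda v: parse_flexible_date(v)[0])
        start_map = pd.Series(list(tstart), index=tcase).groupby(level=0).min()
        drugs["start_date"] = drugs["case_id"].map(start_map)

    reac = tables["REAC"]
    if reac.empty:
        warnings.warn("REAC table has no rows: ReportSet carries zero events")
        events = pd.DataFrame(columns=EVENT_COLUMNS)
    else:
        events = pd.DataFrame({
            "case_id": _first(reac, "caseid", "primaryid").astype(str),
            "pt": _first(reac, "pt").astype(str),
            "soc": np.nan,
        })

    return ReportSet(_coerce_report_dtypes(reports), _coerce_drug_dtypes(drugs),
                     _coerce_event_dtypes(events), provenance="faers_ascii", meta=meta)


def _load_canonical_csv(paths: Sequence[Path], synonyms: Mapping[str, str] | None) -> ReportSet:
    files = {}
    for name in ("reports.csv", "drugs.csv", "events.csv"):
        match = [p for p in paths if p.name == name]
        if not match:
            raise FileNotFoundError(f"mandatory canonical_csv table {name} not found among inputs")
        files[name] = match[0]

    rep = pd.read_csv(files["reports.csv"], dtype={"case_id": str}, keep_default_na=True)
    needed = {"case_id", "sex", "age_years", "weight_kg", "country",
              "event_date", "report_date", "indications"}
    missing = needed - set(rep.columns)
    if missing:
        raise ValueError(f"reports.csv missing columns {sorted(missing)}")

    ev_parsed = rep["event_date"].map(parse_flexible_date)
    rp_parsed = rep["report_date"].map(parse_flexible_date)
    reports = pd.DataFrame({
        "case_id": rep["case_id"],
        "sex": rep["sex"].fillna("unknown"),
        "age_years": rep["age_years"],
        "weight_kg": rep["weight_kg"],
        "country": rep["country"],
        "event_date": [d for d, _ in ev_parsed],
        "report_date": [d for d, _ in rp_parsed],
        "report_year": [y for _, y in rp_parsed],
        "indications": rep["indications"],
        "file_seq": np.arange(len(rep)),
    })

    dr = pd.read_csv(files["drugs.csv"], dtype={"case_id": str})
    drugs = pd.DataFrame({
        "case_id": dr["case_id"],
        "drug_name_raw": dr["drug_name"],
        "drug_name_std": dr["drug_name"].map(lambda s: standardize_drug_name(s, synonyms)),
        "role": dr["role"],
        "start_date": dr["start_date"].map(lambda v: parse_flexible_date(v)[0]) if "start_date" in dr else pd.NaT,
    })

    evf = files["events.csv"]
    ev = pd.read_csv(evf, dtype={"case_id": str})
    if ev.empty:
        warnings.warn("events.csv has no rows: ReportSet carries zero events")
        events = pd.DataFrame(columns=EVENT_COLUMNS)
    else:
        events = pd.DataFrame({"case_id": ev["case_id"], "pt": ev["pt"],
                               "soc": ev["soc"] if "soc" in ev else np.nan})

    return ReportSet(_coerce_report_dtypes(reports), _coerce_drug_dtypes(drugs),
                     _coerce_event_dtypes(events), provenance="canonical_csv")


def load_reports(paths: Iterable[str | Path], dialect: str = "canonical_csv",
                 synonyms: Mapping[str, str] | None = None) -> ReportSet:
    """Load a spontaneous-report database.

    Parameters
    ----------
    paths
        Files (or directories, which are expanded) holding the tables.
    dialect
        ``"faers_ascii"`` — '$'-delimited DEMO/DRUG/REAC (+ optional
        THER/INDI) quarterly files; ``"canonical_csv"`` — the package's
        three-file reports/drugs/events CSV dialect.
    synonyms
        Optional standardized-name synonym table (brand -> generic).
    """
    expanded: list[Path] = []
    for p in paths:
        p = Path(p)
        if p.is_dir():
            expanded.extend(sorted(q for q in p.iterdir() if q.is_file()))
        else:
            expanded.append(p)
    for p in expanded:
        if not p.exists():
            raise FileNotFoundError(str(p))
    if dialect == "faers_ascii":
        return _load_faers_ascii(expanded, synonyms)
    if dialect == "canonical_csv":
        return _load_canonical_csv(expanded, synonyms)
    raise ValueError(f"unknown dialect {dialect!r}")


def _format_date_col(dates: pd.Series, years: pd.Series | None = None) -> pd.Series:
    """Render dates as ISO strings, falling back to bare year for partials."""
    out = dates.dt.strftime("%Y-%m-%d")
    if years is not None:
        partial = dates.isna() & years.notna()
        out = out.where(~partial, years.map(lambda y: "" if pd.isna(y) else str(int(y))))
    return out.fillna("")


def write_reports(rs: ReportSet, out_dir: str | Path) -> dict[str, Path]:
    """Write a ReportSet in the canonical_csv dialect (the round-trip format)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rep = rs.reports
    reports = pd.DataFrame({
        "case_id": rep["case_id"],
        "sex": rep["sex"],
        "age_years": rep["age_years"],
        "weight_kg": rep["weight_kg"],
        "country": rep["country"],
        "event_date": _format_date_col(rep["event_date"]),
        "report_date": _format_date_col(rep["report_date"], rep["report_year"]),
        "indications": rep["indications"],
    })
    drugs = pd.DataFrame({
        "case_id": rs.drugs["case_id"],
        "drug_name": rs.drugs["drug_name_std"],
        "role": rs.drugs["role"],
        "start_date": _format_date_col(rs.drugs["start_date"]),
    })
    events = rs.events[["case_id", "pt", "soc"]]
    written = {}
    for name, frame in (("reports.csv", reports), ("drugs.csv", drugs), ("events.csv", events)):
        path = out / name
        frame.to_csv(path, index=False, lineterminator="\n")
        written[name] = path
    return written


# ---------------------------------------------------------------------------
# Deduplication


@dataclass
class DedupLog:
    """Which case_ids deduplication removed, and at which stage.

    Stage 1 collapses identical case identifiers (keeping the maximal version
    key); stage 2 collapses distinct identifiers that agree on report date,
    age, sex and reporting country — the cross-reference used to catch
    resubmitted versions of the same patient event.
    """

    removed: pd.DataFrame  # columns: case_id, stage, kept_case_id

    @property
    def n_stage1(self) -> int:
        return int((self.removed["stage"] == 1).sum())

    @property
    def n_stage2(self) -> int:
        return int((self.removed["stage"] == 2).sum())

    def removed_ids(self) -> set[str]:
        return set(self.removed["case_id"])


def _completeness(df: pd.DataFrame) -> pd.Series:
    score = (
        df["age_years"].notna().astype(int)
        + df["weight_kg"].notna().astype(int)
        + df["country"].notna().astype(int)
        + df["event_date"].notna().astype(int)
        + df["report_date"].notna().astype(int)
        + (df["sex"] != "unknown").astype(int)
        + (df["indications"].str.len() > 0).astype(int)
    )
    return score


def deduplicate(rs: ReportSet) -> tuple[ReportSet, DedupLog]:
    """Two-stage deduplication of a loaded ReportSet.

    Stage 1: one row per ``case_id``, keeping the maximal version key
    (report date, then file position).  Stage 2: rows that share a fully
    observed (report_date, age_years, sex, country) tuple are collapsed to a
    single survivor — the most complete row, ties broken toward the
    lexicographically smallest case_id.  Drug and event rows of removed
    reports are dropped with them.
    """
    df = rs.reports.copy()
    removed_records = []

    # stage 1 — identical case identifiers
    order_date = df["report_date"].fillna(pd.Timestamp.min)
    df = df.assign(_vk_date=order_date).sort_values(
        ["case_id", "_vk_date", "file_seq"], kind="mergesort")
    keep_mask = ~df.duplicated("case_id", keep="last")
    for cid in df.loc[~keep_mask, "case_id"]:
        removed_records.append((cid, 1, cid))
    # stage-1 losers share the survivor's case_id, so drop by row not id
    df = df.loc[keep_mask].drop(columns="_vk_date")

    # stage 2 — cross-reference demographics: all four fields must be present
    eligible = (
        df["report_date"].notna()
        & df["age_years"].notna()
        & (df["sex"] != "unknown")
        & df["country"].notna()
    )
    sub = df.loc[eligible].copy()
    if not sub.empty:
        sub["_complete"] = _completeness(sub)
        sub = sub.sort_values(["_complete", "case_id"], ascending=[False, True], kind="mergesort")
        # case_ids are unique after stage 1, so the group's first case_id
        # identifies the survivor directly
        kept = sub.groupby(["report_date", "age_years", "sex", "country"],
                           sort=False)["case_id"].transform("first")
        loser_mask = (sub["case_id"] != kept).to_numpy()
        if loser_mask.any():
            for cid, kid in zip(sub.loc[loser_mask, "case_id"], kept[loser_mask]):
                removed_records.append((cid, 2, kid))
            df = df.drop(index=sub.index[loser_mask])

    df = df.sort_values("file_seq", kind="mergesort").reset_index(drop=True)
    keep_ids = set(df["case_id"])
    out = ReportSet(
        df,
        rs.drugs[rs.drugs["case_id"].isin(keep_ids)].reset_index(drop=True),
        rs.events[rs.events["case_id"].isin(keep_ids)].reset_index(drop=True),
        rs.provenance,
        dict(rs.meta, deduplicated=True),
    )
    log = DedupLog(pd.DataFrame(removed_records, columns=["case_id", "stage", "kept_case_id"]))
    return out, log


# ---------------------------------------------------------------------------
# Vocabulary mapping


def load_vocabulary(path: str | Path) -> pd.DataFrame:
    """Read a PT->SOC vocabulary CSV with columns ``pt,soc``."""
    vocab = pd.read_csv(path)
    if not {"pt", "soc"} <= set(vocab.columns):
        raise ValueError("vocabulary CSV must have columns pt,soc")
    return vocab


def map_meddra(rs: ReportSet, vocabulary: pd.DataFrame | Mapping[str, str]) -> ReportSet:
    """Attach a SOC to every event record from a PT->SOC vocabulary.

    PTs absent from the vocabulary keep a missing SOC and are counted in
    ``meta["n_unmapped_pts"]`` (distinct terms) / ``meta["n_unmapped_events"]``
    (rows).  A PT appearing twice in the vocabulary with conflicting SOCs is
    a hard error: the mapping must be a function.
    """
    if isinstance(vocabulary, Mapping):
        vocab = pd.DataFrame({"pt": list(vocabulary), "soc": list(vocabulary.values())})
    else:
        vocab = vocabulary.copy()
    vocab["pt"] = vocab["pt"].astype(str).str.strip().str.upper()
    conflicts = vocab.groupby("pt")["soc"].nunique()
    if (conflicts > 1).any():
        bad = conflicts[conflicts > 1].index.tolist()
        raise ValueError(f"vocabulary maps PT(s) {bad} to conflicting SOCs")
    lookup = vocab.drop_duplicates("pt").set_index("pt")["soc"]

    out = rs.copy()
    if len(out.events):
        out.events["soc"] = out.events["pt"].map(lookup)
        unmapped = out.events["soc"].isna()
        out.meta["n_unmapped_events"] = int(unmapped.sum())
        out.meta["n_unmapped_pts"] = int(out.events.loc[unmapped, "pt"].nunique())
    else:
        out.meta["n_unmapped_events"] = 0
        out.meta["n_unmapped_pts"] = 0
    return out


# ---------------------------------------------------------------------------
# Filtering and summaries


def filter_by_drug(rs: ReportSet, drug_names: Iterable[str],
                   role_filter: Iterable[str] = ("suspect",)) -> ReportSet:
    """Restrict to cases with at least one matching drug record.

    ``drug_names`` are compared against standardized names (case-folded).
    The default role filter keeps suspect drugs only, matching the usual
    exposure definition in disproportionality work.
    """
    names = {standardize_drug_name(n) for n in drug_names}
    if not names:
        raise ValueError("drug_names must be non-empty")
    roles = set(role_filter)
    hit = rs.drugs[rs.drugs["drug_name_std"].isin(names) & rs.drugs["role"].isin(roles)]
    keep = set(hit["case_id"])
    return ReportSet(
        rs.reports[rs.reports["case_id"].isin(keep)].reset_index(drop=True),
        rs.drugs[rs.drugs["case_id"].isin(keep)].reset_index(drop=True),
        rs.events[rs.events["case_id"].isin(keep)].reset_index(drop=True),
        rs.provenance,
        dict(rs.meta),
    )


AGE_BINS = ((0.0, 18.0, "<18"), (18.0, 65.0, "18-65"), (65.0, 85.0, "65-85"),
            (85.0, np.inf, ">85"))
WEIGHT_BINS = ((0.0, 50.0, "<50"), (50.0, 100.0, "50-100"), (100.0, np.inf, ">=100"))


@dataclass
class DemographicSummary:
    """Table-1-style cohort description: counts and percentages by sex, age
    bin, weight bin, top indications and countries, plus annual report
    counts.  Bin edges are half-open on the left ([lo, hi))."""

    total: int
    sex: pd.DataFrame
    age: pd.DataFrame
    weight: pd.DataFrame
    top_indications: pd.DataFrame
    top_countries: pd.DataFrame
    annual_counts: dict[int, int]


def _binned(values: pd.Series, bins, total: int) -> pd.DataFrame:
    rows = []
    for lo, hi, label in bins:
        n = int(((values >= lo) & (values < hi)).sum())
        rows.append((label, n))
    rows.append(("missing", int(values.isna().sum())))
    df = pd.DataFrame(rows, columns=["bin", "count"])
    df["percent"] = 100.0 * df["count"] / total if total else 0.0
    return df


def summarize_demographics(rs: ReportSet, top_k: int = 5) -> DemographicSummary:
    """Summarize a (deduplicated) ReportSet the way cohort tables report it."""
    rep = rs.reports
    total = len(rep)
    sex_rows = [(s, int((rep["sex"] == s).sum())) for s in ("female", "male", "unknown")]
    sex = pd.DataFrame(sex_rows, columns=["sex", "count"])
    sex["percent"] = 100.0 * sex["count"] / total if total else 0.0

    age = _binned(rep["age_years"], AGE_BINS, total)
    weight = _binned(rep["weight_kg"], WEIGHT_BINS, total)

    ind = rep["indications"].str.split(";").explode()
    ind = ind[ind.astype(str).str.len() > 0]
    top_ind = ind.value_counts().head(top_k).rename_axis("indication").reset_index(name="count")
    top_ind["percent"] = 100.0 * top_ind["count"] / total if total else 0.0

    ctry = rep["country"].dropna()
    top_ctry = ctry.value_counts().head(top_k).rename_axis("country").reset_index(name="count")
    top_ctry["percent"] = 100.0 * top_ctry["count"] / total if total else 0.0

    years = rep["report_year"].dropna().astype(int)
    annual = {int(y): int(n) for y, n in years.value_counts().sort_index().items()}
    return DemographicSummary(total, sex, age, weight, top_ind, top_ctry, annual)


@dataclass
class TrendFit:
    """Least-squares polynomial fit of annual report counts."""

    degree: int
    coefficients: np.ndarray  # ascending powers, in raw (year, count) space
    r_squared: float

    def predict(self, years) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(years, float), self.coefficients)


def fit_annual_trend(annual_counts: Mapping[int, int], degree: int = 2) -> TrendFit:
    """Fit count-versus-year with an ordinary polynomial and report R².

    A constant series has zero total variance; the fit is then trivially
    perfect and R² is defined as 1.0 (with a warning).
    """
    years = np.array(sorted(annual_counts), dtype=float)
    counts = np.array([annual_counts[int(y)] for y in years], dtype=float)
    if len(years) < degree + 2:
        raise ValueError(f"need at least degree+2={degree + 2} distinct years, got {len(years)}")
    series = np.polynomial.Polynomial.fit(years, counts, degree)
    coeffs = series.convert().coef
    fitted = series(years)
    ss_res = float(np.sum((counts - fitted) ** 2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant annual counts: zero total variance, R² defined as 1.0")
        r2 = 1.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return TrendFit(degree, coeffs, r2)
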