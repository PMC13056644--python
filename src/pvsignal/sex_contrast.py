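"""Between-sex comparative disproportionality (relative ROR).

Within the reports of one drug, each PT gets a sex-stratified 2×2 table —
male pairs with/without the PT against female pairs with/without it — and
the contrast rROR(m/f) = (a_m·d_f)/(b_m·c_f).  Inference is on the log
scale (Wald), p-values are BH-FDR adjusted within the drug's PT list, and
each pair is called male-enriched, female-enriched or not significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .report_store import ReportSet, standardize_drug_name

__all__ = [
    "SexStratifiedTable", "SexContrastResult", "build_sex_tables",
    "rror_estimate", "bh_fdr", "classify_enrichment", "sex_contrast_table",
    "load_table2_counts",
]


@dataclass(frozen=True)
class SexStratifiedTable:
    """Male/female PT counts within one drug's reports.

    ``a_m``/``b_m``: male report–PT pairs with the PT / with any other PT;
    ``c_f``/``d_f``: the female analogues.  Unknown-sex reports contribute
    to no cell.
    """

    drug: str
    pt: str
    a_m: int
    b_m: int
    c_f: int
    d_f: int

    def __post_init__(self):
        for name in ("a_m", "b_m", "c_f", "d_f"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer")


@dataclass(frozen=True)
class SexContrastResult:
    table: SexStratifiedTable
    rror: float
    ci_lo: float
    ci_hi: float
    p: float
    p_fdr: float = float("nan")
    call: str = ""
    zero_corrected: bool = False


def build_sex_tables(rs: ReportSet, drug: str,
                     pts: Sequence[str]) -> list[SexStratifiedTable]:
    """Tally sex-stratified PT tables within the target drug's reports.

    The universe is every deduplicated report carrying the drug in suspect
    role; pairs are (report, distinct PT).  For each requested PT, b_m is
    the male pairs with *any other* PT, so a_m + b_m equals the total male
    pair count for the drug (and likewise for females).
    """
    drug_std = standardize_drug_name(drug)
    exposed = set(rs.drugs.loc[(rs.drugs["drug_name_std"] == drug_std)
                               & (rs.drugs["role"] == "suspect"), "case_id"])
    rep = rs.reports[rs.reports["case_id"].isin(exposed)]
    sex_of = rep.set_index("case_id")["sex"]
    pairs = rs.events[rs.events["case_id"].isin(exposed)][["case_id", "pt"]].drop_duplicates()
    pairs = pairs.assign(sex=pairs["case_id"].map(sex_of))
    male = pairs[pairs["sex"] == "male"]
    female = pairs[pairs["sex"] == "female"]
    t_m, t_f = len(male), len(female)
    male_counts = male["pt"].value_counts()
    female_counts = female["pt"].value_counts()
    tables = []
    for pt in pts:
        key = str(pt).strip().upper()
        a_m = int(male_counts.get(key, 0))
        c_f = int(female_counts.get(key, 0))
        tables.append(SexStratifiedTable(drug_std, key, a_m, t_m - a_m, c_f, t_f - c_f))
    return tables


def rror_estimate(t: SexStratifiedTable, alpha_level: float = 0.05) -> SexContrastResult:
    """rROR(m/f) with log-scale Wald CI and two-sided p-value.

    Zero cells get the +0.5 correction on all four cells (flagged).  An
    rROR of exactly 1 is defined to have p = 1 (no contrast).
    """
    cells = (t.a_m, t.b_m, t.c_f, t.d_f)
    if all(v == 0 for v in cells):
        raise ValueError("all-zero sex-stratified table")
    corrected = any(v == 0 for v in cells)
    a, b, c, d = ((v + 0.5 for v in cells) if corrected else map(float, cells))
    a, b, c, d = float(a), float(b), float(c), float(d)
    rror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z_crit = stats.norm.ppf(1 - alpha_level / 2)
    lo = rror * math.exp(-z_crit * se)
    hi = rror * math.exp(z_crit * se)
    if rror == 1.0:
        p = 1.0
    else:
        p = 2.0 * stats.norm.sf(abs(math.log(rror)) / se)
    return SexContrastResult(t, rror, lo, hi, float(p), zero_corrected=corrected)


def bh_fdr(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_enrichment(results: Sequence[SexContrastResult],
                        q: float = 0.05) -> list[SexContrastResult]:
    """Attach BH-FDR adjusted p-values and enrichment calls.

    male_enriched iff rROR > 1 with p_fdr < q; female_enriched iff rROR < 1
    with p_fdr < q; otherwise not_significant.
    """
    adj = bh_fdr([r.p for r in results])
    out = []
    for r, p_fdr in zip(results, adj):
        if p_fdr < q and r.rror > 1:
            call = "male_enriched"
        elif p_fdr < q and r.rror < 1:
            call = "female_enriched"
        else:
            call = "not_significant"
        out.append(SexContrastResult(r.table, r.rror, r.ci_lo, r.ci_hi, r.p,
                                     float(p_fdr), call, r.zero_corrected))
    return out


def _results_frame(results: Sequence[SexContrastResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "drug": r.table.drug, "pt": r.table.pt,
        "a_m": r.table.a_m, "b_m": r.table.b_m,
        "c_f": r.table.c_f, "d_f": r.table.d_f,
        "rror": r.rror, "ci_lo": r.ci_lo, "ci_hi": r.ci_hi,
        "p": r.p, "p_fdr": r.p_fdr, "call": r.call,
    } for r in results])


def sex_contrast_table(rs: ReportSet, drug: str, pts: Sequence[str],
                       q: float = 0.05, alpha_level: float = 0.05) -> pd.DataFrame:
    """End-to-end sex-contrast analysis for one drug: tidy result table."""
    tables = build_sex_tables(rs, drug, pts)
    results = classify_enrichment([rror_estimate(t, alpha_level) for t in tables], q)
    return _results_frame(results)


def sex_contrast_from_counts(counts: pd.DataFrame, q: float = 0.05,
                             alpha_level: float = 0.05) -> pd.DataFrame:
    """Run the rROR analysis from pre-tabulated counts.

    ``counts`` needs columns drug, pt, a_m, b_m, c_f, d_f; BH adjustment is
    applied within each drug across its listed PTs.
    """
    frames = []
    for drug, grp in counts.groupby("drug", sort=False):
        tables = [SexStratifiedTable(drug, row.pt, int(row.a_m), int(row.b_m),
                                     int(row.c_f), int(row.d_f))
                  for row in grp.itertuples()]
        results = classify_enrichment([rror_estimate(t, alpha_level) for t in tables], q)
        frames.append(_results_frame(results))
    return pd.concat(frames, ignore_index=True)


def load_table2_counts() -> pd.DataFrame:
    """Packaged sex-stratified counts for three ALK inhibitors (20 PTs each).

    Columns: drug, pt, a_m, b_m, c_f, d_f plus the published rROR, CI
    bounds, raw p and FDR-adjusted p for regression testing.
    """
    with resources.files("pvsignal.data").joinpath("table2_counts.csv").open("rb") as fh:
        return pd.read_csv(fh)
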