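"""Synthetic spontaneous-report databases with known ground truth.

The generator emulates the statistical structure a disproportionality
analysis assumes: independent drug exposures, per-(drug, event) reporting
probabilities inflated by a reporting-rate ratio ρ for planted signals,
sex-specific multipliers (planted true rRORs), Weibull-distributed onset
times converted to calendar dates, field-level missingness, and exact-clone
duplicate injection to exercise stage-2 deduplication.  Every draw flows
from one seed, so the emitted canonical CSV files are byte-identical across
runs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .report_store import ReportSet, _coerce_report_dtypes, _coerce_drug_dtypes, \
    _coerce_event_dtypes, write_reports

__all__ = ["SimConfig", "GroundTruth", "default_config", "generate_reports",
           "truth_vs_estimates"]

_COUNTRIES = ("US", "JP", "CN", "FR", "IN")
_COUNTRY_P = (0.45, 0.20, 0.15, 0.10, 0.10)
_INDICATIONS = ("NON-SMALL CELL LUNG CANCER", "LUNG NEOPLASM MALIGNANT",
                "PRODUCT USED FOR UNKNOWN INDICATION")
_INDICATION_P = (0.55, 0.30, 0.15)


@dataclass
class SimConfig:
    """Everything the generator needs; see :func:`default_config` for the
    reference setting.

    ``drugs`` maps drug name -> marginal exposure probability; ``events``
    lists (pt, soc, background reporting probability); ``effects`` plants a
    reporting-rate ratio ρ on a (drug, pt) pair; ``sex_effects`` plants a
    male multiplier (the true rROR) on a pair; ``tto_params`` gives the
    (scale α in days, shape β) of the onset distribution for reports exposed
    to that drug; ``missingness`` is the per-field probability of a missing
    value; ``duplicate_rate`` is the fraction of reports cloned under a
    fresh case id.
    """

    n_reports: int = 20_000
    drugs: dict[str, float] = field(default_factory=dict)
    events: list[tuple[str, str, float]] = field(default_factory=list)
    effects: dict[tuple[str, str], float] = field(default_factory=dict)
    sex_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    sex_split: float = 0.45  # P(male) before sex missingness
    tto_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    default_tto: tuple[float, float] = (90.0, 1.0)
    missingness: dict[str, float] = field(default_factory=lambda: {
        "age": 0.25, "weight": 0.75, "country": 0.05,
        "event_date": 0.20, "sex": 0.10,
    })
    duplicate_rate: float = 0.02
    start_window: tuple[str, str] = ("2011-01-01", "2025-06-30")
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if not self.drugs or not self.events:
            raise ValueError("config needs at least one drug and one event")
        probs = list(self.drugs.values()) + [bg for _, _, bg in self.events] \
            + list(self.missingness.values()) + [self.sex_split, self.duplicate_rate]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(r <= 0 for r in self.effects.values()):
            raise ValueError("reporting-rate ratios must be positive")
        if any(m <= 0 for m in self.sex_effects.values()):
            raise ValueError("sex multipliers must be positive")
        for a, b in list(self.tto_params.values()) + [self.default_tto]:
            if a <= 0 or b <= 0:
                raise ValueError("Weibull scale and shape must be positive")


def default_config(seed: int = 0, n_reports: int = 20_000) -> SimConfig:
    """Reference configuration: one target drug against a background of
    three comparators, twenty PTs over five SOCs, early-failure onsets
    (β = 0.7) for the target — the regime the downstream analyses assume."""
    drugs = {"DRUG_A": 0.10, "DRUG_B": 0.25, "DRUG_C": 0.25, "DRUG_D": 0.25}
    backgrounds = np.geomspace(0.005, 0.05, 20)
    events = [(f"PT_{i + 1:02d}", f"SOC_{i % 5 + 1}", float(b))
              for i, b in enumerate(backgrounds)]
    return SimConfig(n_reports=n_reports, drugs=drugs, events=events,
                     tto_params={"DRUG_A": (100.0, 0.7)}, seed=seed)


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    effects: dict[tuple[str, str], float]
    sex_effects: dict[tuple[str, str], float]
    tto_params: dict[str, tuple[float, float]]
    duplicate_pairs: list[tuple[str, str]]  # (clone case_id, source case_id)
    onsets: dict[str, np.ndarray]  # continuous onset draws per tto drug
    n_capped: int
    seed: int

    def duplicate_ids(self) -> set[str]:
        return {clone for clone, _ in self.duplicate_pairs}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "n_capped": self.n_capped,
            "effects": {f"{d}|{p}": v for (d, p), v in self.effects.items()},
            "sex_effects": {f"{d}|{p}": v for (d, p), v in self.sex_effects.items()},
            "tto_params": {d: list(v) for d, v in self.tto_params.items()},
            "duplicate_pairs": [list(t) for t in self.duplicate_pairs],
            "onsets": {d: np.asarray(v).tolist() for d, v in self.onsets.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def vocabulary_frame(config: SimConfig) -> pd.DataFrame:
    """The PT->SOC vocabulary implied by the config (for map_meddra)."""
    return pd.DataFrame([(pt, soc) for pt, soc, _ in config.events], columns=["pt", "soc"])


def generate_reports(config: SimConfig, out_dir: str | Path | None = None
                     ) -> tuple[ReportSet, GroundTruth]:
    """Draw a full synthetic database; optionally write canonical_csv +
    ``ground_truth.json`` to ``out_dir``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drug_names = list(config.drugs)
    pts = [pt for pt, _, _ in config.events]
    socs = {pt: soc for pt, soc, _ in config.events}
    backgrounds = np.array([bg for _, _, bg in config.events])

    male = rng.random(n) < config.sex_split
    sex = np.where(male, "male", "female").astype(object)
    age = np.clip(rng.normal(62.0, 15.0, n), 1.0, 95.0).round(1)
    weight = np.clip(rng.normal(70.0, 16.0, n), 35.0, 150.0).round(1)
    country = rng.choice(_COUNTRIES, size=n, p=_COUNTRY_P)
    indication = rng.choice(_INDICATIONS, size=n, p=_INDICATION_P)

    w0 = pd.Timestamp(config.start_window[0])
    w1 = pd.Timestamp(config.start_window[1])
    start_offset = rng.integers(0, (w1 - w0).days + 1, n)
    start = w0 + pd.to_timedelta(start_offset, unit="D")

    # exposures: independent Bernoulli per drug; a report with no configured
    # drug gets a filler BACKGROUND record so every case carries a drug row
    # without disturbing the configured marginals
    exposure = rng.random((n, len(drug_names))) < np.array(list(config.drugs.values()))
    filler = ~exposure.any(axis=1)

    # event probabilities: background × planted ρ × male multiplier, capped
    prob = np.tile(backgrounds, (n, 1))
    for (drug, pt), rho in config.effects.items():
        j = pts.index(pt)
        mask = exposure[:, drug_names.index(drug)]
        prob[mask, j] *= rho
    for (drug, pt), mult in config.sex_effects.items():
        j = pts.index(pt)
        mask = exposure[:, drug_names.index(drug)] & male
        prob[mask, j] *= mult
    n_capped = int((prob > 1.0).sum())
    if n_capped:
        warnings.warn(f"{n_capped} report-event probabilities exceeded 1 and were capped")
        prob = np.minimum(prob, 1.0)
    reported = rng.random((n, len(pts))) < prob
    has_event = reported.any(axis=1)

    # onset: Weibull of the first exposed drug that has tto parameters
    onset = config.default_tto[0] * rng.weibull(config.default_tto[1], n)
    onset_drug = np.full(n, "", object)
    for drug, (al, be) in config.tto_params.items():
        mask = exposure[:, drug_names.index(drug)] & (onset_drug == "")
        onset[mask] = al * rng.weibull(be, int(mask.sum()))
        onset_drug[mask] = drug
    onset_days = np.ceil(onset).astype(int)  # day resolution, >= 1
    event_date = start + pd.to_timedelta(onset_days, unit="D")
    report_lag = rng.integers(1, 61, n)
    report_date = event_date + pd.to_timedelta(report_lag, unit="D")

    case_id = np.array([f"C{i:07d}" for i in range(n)], dtype=object)

    miss = {f: rng.random(n) < p for f, p in config.missingness.items()}
    sex = np.where(miss.get("sex", np.zeros(n, bool)), "unknown", sex)
    age = np.where(miss.get("age", np.zeros(n, bool)), np.nan, age)
    weight = np.where(miss.get("weight", np.zeros(n, bool)), np.nan, weight)
    country = np.where(miss.get("country", np.zeros(n, bool)), None, country)
    event_date = pd.Series(event_date).where(
        ~(miss.get("event_date", np.zeros(n, bool)) | ~has_event), pd.NaT)

    reports = pd.DataFrame({
        "case_id": case_id, "sex": sex, "age_years": age, "weight_kg": weight,
        "country": country, "event_date": event_date.to_numpy(),
        "report_date": report_date, "report_year": report_date.year.astype(float),
        "indications": indication, "file_seq": np.arange(n),
    })

    ridx, didx = np.nonzero(exposure)
    fidx = np.where(filler)[0]
    drugs = pd.DataFrame({
        "case_id": np.concatenate([case_id[ridx], case_id[fidx]]),
        "drug_name_raw": np.concatenate([np.array(drug_names, object)[didx],
                                         np.full(len(fidx), "BACKGROUND", object)]),
        "drug_name_std": np.concatenate([np.array(drug_names, object)[didx],
                                         np.full(len(fidx), "BACKGROUND", object)]),
        "role": "suspect",
        "start_date": np.concatenate([start[ridx], start[fidx]]),
    }).sort_values("case_id", kind="mergesort").reset_index(drop=True)
    eidx, pidx = np.nonzero(reported)
    events = pd.DataFrame({
        "case_id": case_id[eidx],
        "pt": np.array(pts, object)[pidx],
        "soc": np.array([socs[p] for p in pts], object)[pidx],
    })

    # duplicate injection: exact clones of demographically complete reports
    # under a fresh (lexicographically larger) case id, so stage-2 dedup has
    # to find them through the cross-reference, not the identifier
    dup_pairs: list[tuple[str, str]] = []
    k = int(round(config.duplicate_rate * n))
    if k > 0:
        complete = (~pd.isna(age)) & (sex != "unknown") & pd.notna(pd.Series(country))
        pool = np.where(complete)[0]
        if len(pool) < k:
            k = len(pool)
        chosen = rng.choice(pool, size=k, replace=False)
        chosen.sort()
        clones = reports.iloc[chosen].copy()
        clone_ids = clones["case_id"] + "X"
        dup_pairs = list(zip(clone_ids, clones["case_id"]))
        clones["case_id"] = clone_ids
        clones["file_seq"] = np.arange(n, n + k)
        reports = pd.concat([reports, clones], ignore_index=True)
        clone_drugs = drugs[drugs["case_id"].isin(set(clones["case_id"].str[:-1]))].copy()
        clone_drugs["case_id"] = clone_drugs["case_id"] + "X"
        drugs = pd.concat([drugs, clone_drugs], ignore_index=True)
        clone_events = events[events["case_id"].isin(set(clones["case_id"].str[:-1]))].copy()
        clone_events["case_id"] = clone_events["case_id"] + "X"
        events = pd.concat([events, clone_events], ignore_index=True)

    rs = ReportSet(_coerce_report_dtypes(reports), _coerce_drug_dtypes(drugs),
                   _coerce_event_dtypes(events), provenance="synthetic")

    onsets = {drug: onset[(onset_drug == drug) & has_event]
              for drug in config.tto_params}
    gt = GroundTruth(dict(config.effects), dict(config.sex_effects),
                     dict(config.tto_params), dup_pairs, onsets, n_capped,
                     config.seed)
    if out_dir is not None:
        out = Path(out_dir)
        write_reports(rs, out)
        gt.to_json(out / "ground_truth.json")
    return rs, gt


def truth_vs_estimates(gt: GroundTruth, results: Mapping[str, object]) -> pd.DataFrame:
    """Tabulate estimate − truth for every planted quantity.

    ``results`` may hold ``"ror"`` (frame with drug, event, ror, ror_lo,
    ror_hi), ``"rror"`` (frame with drug, pt, rror, ci_lo, ci_hi) and
    ``"weibull"`` (mapping drug -> WeibullFit).  Planted pairs absent from
    the supplied results raise a KeyError naming them.
    """
    rows = []
    missing = []

    if gt.effects:
        ror = results.get("ror")
        for (drug, pt), rho in gt.effects.items():
            hit = None
            if ror is not None:
                sel = ror[(ror["drug"] == drug) & (ror["event"] == pt)]
                hit = sel.iloc[0] if len(sel) else None
            if hit is None:
                missing.append(("ror", drug, pt))
                continue
            rows.append({"quantity": "ror", "drug": drug, "event": pt,
                         "truth": rho, "estimate": hit["ror"],
                         "lo": hit["ror_lo"], "hi": hit["ror_hi"],
                         "covered": bool(hit["ror_lo"] <= rho <= hit["ror_hi"])})

    if gt.sex_effects:
        rr = results.get("rror")
        for (drug, pt), mult in gt.sex_effects.items():
            hit = None
            if rr is not None:
                sel = rr[(rr["drug"] == drug) & (rr["pt"] == pt)]
                hit = sel.iloc[0] if len(sel) else None
            if hit is None:
                missing.append(("rror", drug, pt))
                continue
            rows.append({"quantity": "rror", "drug": drug, "event": pt,
                         "truth": mult, "estimate": hit["rror"],
                         "lo": hit["ci_lo"], "hi": hit["ci_hi"],
                         "covered": bool(hit["ci_lo"] <= mult <= hit["ci_hi"])})

    wb = results.get("weibull", {})
    for drug, (al, be) in gt.tto_params.items():
        fit = wb.get(drug) if wb else None
        if fit is None:
            missing.append(("weibull", drug, ""))
            continue
        rows.append({"quantity": "weibull_alpha", "drug": drug, "event": "",
                     "truth": al, "estimate": fit.alpha,
                     "lo": fit.alpha_ci[0], "hi": fit.alpha_ci[1],
                     "covered": bool(fit.alpha_ci[0] <= al <= fit.alpha_ci[1])})
        rows.append({"quantity": "weibull_beta", "drug": drug, "event": "",
                     "truth": be, "estimate": fit.beta,
                     "lo": fit.beta_ci[0], "hi": fit.beta_ci[1],
                     "covered": bool(fit.beta_ci[0] <= be <= fit.beta_ci[1])})

    if missing:
        raise KeyError(f"results missing planted pairs: {missing}")
    return pd.DataFrame(rows)
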