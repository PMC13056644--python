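"""Cross-database signal concordance.

Signal tables from two spontaneous-report databases (e.g. a US and a
Canadian system) are joined on normalized (drug, event) keys; concordance
is summarized as the fraction of pairs whose statistics sit on the same
side of 1 (direction agreement, ties at exactly 1 excluded) and the
Pearson correlation of the log statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PairedSignal", "ConcordanceSummary", "align_signals", "concordance"]


@dataclass(frozen=True)
class PairedSignal:
    drug: str
    event: str
    stat_a: float
    stat_b: float
    present_in_both: bool = True


@dataclass
class ConcordanceSummary:
    n_paired: int
    n_ties: int
    direction_agreement: float
    log_log_correlation: float
    correlation_defined: bool
    discordant: list[tuple[str, str]] = field(default_factory=list)


def _norm_key(s: pd.Series) -> pd.Series:
    return s.astype(str).str.upper().str.split().str.join(" ")


def align_signals(results_a: pd.DataFrame, results_b: pd.DataFrame,
                  stat: str = "ror") -> tuple[list[PairedSignal], pd.DataFrame, pd.DataFrame]:
    """Inner-join two signal tables on normalized (drug, event).

    Normalization case-folds and collapses whitespace.  Returns the paired
    signals plus the unmatched rows of each side.
    """
    frames = []
    for df in (results_a, results_b):
        need = {"drug", "event", stat}
        if not need <= set(df.columns):
            raise ValueError(f"signal table needs columns {sorted(need)}")
        f = df.copy()
        f["key_drug_"] = _norm_key(f["drug"])
        f["key_event_"] = _norm_key(f["event"])
        frames.append(f)
    fa, fb = frames
    merged = fa.merge(fb, on=["key_drug_", "key_event_"], suffixes=("_a", "_b"))
    pairs = [PairedSignal(r.key_drug_, r.key_event_,
                          float(getattr(r, f"{stat}_a")), float(getattr(r, f"{stat}_b")))
             for r in merged.itertuples()]
    keys = set(zip(merged["key_drug_"], merged["key_event_"]))
    only_a = fa[~fa.set_index(["key_drug_", "key_event_"]).index.isin(keys)].drop(
        columns=["key_drug_", "key_event_"])
    only_b = fb[~fb.set_index(["key_drug_", "key_event_"]).index.isin(keys)].drop(
        columns=["key_drug_", "key_event_"])
    return pairs, only_a, only_b


def concordance(pairs: list[PairedSignal], method: str = "pearson") -> ConcordanceSummary:
    """Direction agreement and log-scale correlation of paired signals.

    A pair agrees when both statistics are on the same side of 1; a
    statistic of exactly 1 carries no direction and drops out of the
    agreement denominator.  Correlation is Pearson on (ln a, ln b) by
    default (Spearman available), undefined below 3 pairs or with zero
    variance on either axis.
    """
    sa = np.array([p.stat_a for p in pairs], float)
    sb = np.array([p.stat_b for p in pairs], float)
    if np.any(sa <= 0) or np.any(sb <= 0):
        raise ValueError("signal statistics must be positive")
    tie = (sa == 1.0) | (sb == 1.0)
    eff_a, eff_b = sa[~tie], sb[~tie]
    agree_mask = (eff_a - 1.0) * (eff_b - 1.0) > 0
    n_eff = len(eff_a)
    agreement = float(agree_mask.mean()) if n_eff else float("nan")
    discordant = [(p.drug, p.event) for p, t in zip(pairs, tie)
                  if not t and (p.stat_a - 1.0) * (p.stat_b - 1.0) < 0]

    la, lb = np.log(sa), np.log(sb)
    defined = len(pairs) >= 3 and np.ptp(la) > 0 and np.ptp(lb) > 0
    if defined:
        if method == "pearson":
            corr = float(stats.pearsonr(la, lb).statistic)
        elif method == "spearman":
            corr = float(stats.spearmanr(la, lb).statistic)
        else:
            raise ValueError(f"unknown correlation method {method!r}")
    else:
        corr = float("nan")
    return ConcordanceSummary(len(pairs), int(tie.sum()), agreement, corr,
                              defined, discordant)
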