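"""Time-to-onset extraction and Weibull failure-pattern modeling.

Onset is the number of days from the earliest start of the target drug to
the adverse event date.  The onset sample is fit with an uncensored
two-parameter Weibull (scale α in days, shape β); the shape's confidence
interval classifies the temporal risk pattern: a CI entirely below 1 means
a decreasing hazard ("early failure" — events cluster at treatment start),
a CI containing 1 a constant hazard ("random"), and a CI above 1 an
increasing hazard ("wear-out").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .report_store import ReportSet, standardize_drug_name

__all__ = ["TTOSample", "WeibullFit", "extract_tto", "median_tto",
           "weibull_mle", "classify_failure"]


@dataclass
class TTOSample:
    """Positive onset times (days) for one drug, optionally one PT.

    ``day_resolution`` marks samples tallied from calendar dates, where an
    onset of k whole days stands for a true onset in the interval (k−1, k];
    the Weibull fit then uses the interval midpoint k − 0.5, which removes
    most of the discretization bias the day grid would otherwise put on the
    shape estimate.
    """

    drug: str
    pt_filter: Optional[str]
    values: np.ndarray
    n_excluded_nonpositive: int = 0
    n_excluded_missing: int = 0
    day_resolution: bool = False

    @property
    def n(self) -> int:
        return len(self.values)


def extract_tto(rs: ReportSet, drug: str, pt_filter: str | None = None,
                include_day0_as_half: bool = False) -> TTOSample:
    """Collect onset days for every case exposed to the drug (suspect role).

    Onset = event_date − earliest start_date of the target drug's records
    for the case.  Cases missing either date (including partial dates, which
    parse to missing) are tallied in ``n_excluded_missing``; non-positive
    onsets in ``n_excluded_nonpositive``.  With ``include_day0_as_half`` an
    onset of exactly 0 days is mapped to 0.5 instead of excluded.
    """
    drug_std = standardize_drug_name(drug)
    dr = rs.drugs[(rs.drugs["drug_name_std"] == drug_std) & (rs.drugs["role"] == "suspect")]
    starts = dr.groupby("case_id")["start_date"].min()
    rep = rs.reports[rs.reports["case_id"].isin(starts.index)]
    if pt_filter is not None:
        key = str(pt_filter).strip().upper()
        with_pt = set(rs.events.loc[rs.events["pt"] == key, "case_id"])
        rep = rep[rep["case_id"].isin(with_pt)]

    start = rep["case_id"].map(starts)
    onset = (rep["event_date"] - start).dt.days
    missing = onset.isna()
    onset_valid = onset[~missing].astype(float)
    if include_day0_as_half:
        onset_valid = onset_valid.replace(0.0, 0.5)
    nonpositive = onset_valid <= 0
    values = onset_valid[~nonpositive].to_numpy(float)
    return TTOSample(drug_std, pt_filter, values,
                     int(nonpositive.sum()), int(missing.sum()),
                     day_resolution=True)


def median_tto(sample: TTOSample) -> float:
    """Empirical median onset; even sample sizes average the two central
    order statistics (hence half-integer medians on day-resolved data)."""
    if sample.n == 0:
        raise ValueError("empty TTO sample")
    return float(np.median(sample.values))


@dataclass
class WeibullFit:
    """MLE of the two-parameter Weibull with log-scale Wald intervals."""

    alpha: float  # scale, days
    beta: float   # shape
    alpha_ci: tuple[float, float]
    beta_ci: tuple[float, float]
    median_tto: float
    n: int
    failure_type: str
    loglik: float


def _profile_score(beta: float, x: np.ndarray, logx: np.ndarray, mean_log: float) -> float:
    xb = x ** beta
    return float(np.sum(xb * logx) / np.sum(xb) - 1.0 / beta - mean_log)


def scale_given_shape(x: np.ndarray, beta: float) -> float:
    """Closed-form MLE of the scale for a fixed shape (β=1 gives the sample
    mean: the exponential submodel)."""
    x = np.asarray(x, float)
    return float(np.mean(x ** beta) ** (1.0 / beta))


def weibull_loglik(alpha: float, beta: float, x: np.ndarray) -> float:
    n = len(x)
    z = x / alpha
    return float(n * math.log(beta / alpha) + (beta - 1) * np.sum(np.log(z)) - np.sum(z ** beta))


def weibull_mle(sample: TTOSample, alpha_level: float = 0.05) -> WeibullFit:
    """Fit Weibull(α, β) by maximum likelihood.

    The shape solves the one-dimensional profile score equation (strictly
    monotone in β, solved by bracketed root-finding); the scale then has the
    closed form α = (Σ xᵢ^β / n)^{1/β}.  Confidence intervals come from the
    observed information on (ln α, ln β), exponentiated, so bounds are
    always positive.
    """
    x = np.asarray(sample.values, float)
    if len(x) < 3:
        raise ValueError("need at least 3 onset values")
    if np.any(x <= 0):
        raise ValueError("onset values must be positive")
    if sample.day_resolution:
        whole = (x == np.floor(x)) & (x >= 1)
        x = np.where(whole, x - 0.5, x)
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all onset values identical")
    logx = np.log(x)
    mean_log = float(np.mean(logx))

    lo, hi = 1e-3, 1.0
    while _profile_score(hi, x, logx, mean_log) < 0:
        hi *= 2
        if hi > 1e4:
            raise RuntimeError("shape root bracket failure")
    beta = optimize.brentq(_profile_score, lo, hi, args=(x, logx, mean_log),
                           xtol=1e-12, rtol=1e-12)
    alpha = scale_given_shape(x, beta)

    # observed information on (ln alpha, ln beta) by central differences
    def nll(theta):
        return -weibull_loglik(math.exp(theta[0]), math.exp(theta[1]), x)

    theta_hat = np.array([math.log(alpha), math.log(beta)])
    h = 1e-4
    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.eye(2)[i] * h
            ej = np.eye(2)[j] * h
            hess[i, j] = (nll(theta_hat + ei + ej) - nll(theta_hat + ei - ej)
                          - nll(theta_hat - ei + ej) + nll(theta_hat - ei - ej)) / (4 * h * h)
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    z = stats.norm.ppf(1 - alpha_level / 2)
    alpha_ci = (alpha * math.exp(-z * se[0]), alpha * math.exp(z * se[0]))
    beta_ci = (beta * math.exp(-z * se[1]), beta * math.exp(z * se[1]))
    fit = WeibullFit(alpha, beta, alpha_ci, beta_ci,
                     alpha * math.log(2) ** (1.0 / beta), len(x), "",
                     weibull_loglik(alpha, beta, x))
    fit.failure_type = classify_failure(fit)
    return fit


def classify_failure(fit: "WeibullFit | tuple[float, float]") -> str:
    """Shape-CI hazard classification: early / random / wear_out.

    ``early`` when the β CI lies entirely below 1 (decreasing hazard),
    ``wear_out`` entirely above 1, ``random`` when the CI contains 1.
    """
    lo, hi = fit.beta_ci if isinstance(fit, WeibullFit) else fit
    if hi < 1.0:
        return "early"
    if lo > 1.0:
        return "wear_out"
    return "random"
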