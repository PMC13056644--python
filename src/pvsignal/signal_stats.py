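"""Drug–event 2×2 contingency tables and the four classical
disproportionality statistics.

The counting unit throughout is the (report, distinct event term) pair, not
the whole report: a report listing five PTs contributes five pairs at PT
level.  Against a full-database comparator ("all reports without the target
drug in suspect role") the four algorithms are

* **ROR** — reporting odds ratio ``ad/(bc)`` with a Woolf log-scale CI;
* **PRR** — proportional reporting ratio with a Pearson χ²;
* **BCPNN IC** — information component ``log2`` of the observed-to-expected
  reporting probability under a Bayesian model with Beta priors, summarized
  by the posterior moment formulas (IC025 = E[IC] − 2√V[IC]);
* **MGPS EBGM** — empirical-Bayes geometric mean of the shrunken relative
  reporting rate ``λ`` for ``a ~ Poisson(λE)`` under the DuMouchel
  two-component gamma mixture prior, with EB05 its 5th posterior percentile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .report_store import ReportSet

__all__ = [
    "ContingencyTable", "GammaMixturePrior", "ThresholdConfig", "SignalResult",
    "build_contingency", "ror_estimate", "prr_estimate", "bcpnn_ic",
    "mgps_ebgm", "fit_gamma_mixture", "evaluate_signal", "signal_table",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 drug–event counts.

    ``a``: target drug & target event; ``b``: target drug, other events;
    ``c``: other drugs, target event; ``d``: other drugs, other events.
    """

    a: int
    b: int
    c: int
    d: int
    drug: str = ""
    event: str = ""
    level: str = "PT"

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of cell a under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def build_contingency(rs: ReportSet, drug: str, event: str, level: str = "PT",
                      strata: Callable[[pd.DataFrame], pd.Series] | None = None,
                      ) -> ContingencyTable:
    """Count report–distinct-term pairs into a 2×2 table.

    A report is exposed if it carries the target drug in suspect role.  Each
    report contributes one pair per *distinct* term at the requested level
    (PT string, or mapped SOC), so repeated PT mentions within a report count
    once.  ``strata`` optionally restricts the report universe first, e.g.
    to a given indication, and receives the reports frame, returning a
    boolean mask.
    """
    if level not in ("PT", "SOC"):
        raise ValueError("level must be 'PT' or 'SOC'")
    reports = rs.reports
    if strata is not None:
        mask = strata(reports)
        reports = reports[np.asarray(mask, bool)]
    universe = set(reports["case_id"])
    if not universe:
        raise ValueError("empty universe")

    drug_std = " ".join(drug.upper().split())
    exposed = set(rs.drugs.loc[
        (rs.drugs["drug_name_std"] == drug_std) & (rs.drugs["role"] == "suspect"),
        "case_id"]) & universe

    col = "pt" if level == "PT" else "soc"
    ev = rs.events[rs.events["case_id"].isin(universe)]
    ev = ev.dropna(subset=[col])
    pairs = ev[["case_id", col]].drop_duplicates()

    term = event.strip().upper() if level == "PT" else event
    is_exposed = pairs["case_id"].isin(exposed)
    is_event = pairs[col] == term
    a = int((is_exposed & is_event).sum())
    b = int((is_exposed & ~is_event).sum())
    c = int((~is_exposed & is_event).sum())
    d = int((~is_exposed & ~is_event).sum())
    if a + b + c + d == 0:
        raise ValueError("empty universe")
    return ContingencyTable(a, b, c, d, drug=drug_std, event=term, level=level)


# ---------------------------------------------------------------------------
# ROR / PRR


@dataclass(frozen=True)
class RorResult:
    ror: float
    ci_lo: float
    ci_hi: float
    zero_corrected: bool = False


def _halve_if_zero(cells: Sequence[float]) -> tuple[tuple[float, ...], bool]:
    if any(v == 0 for v in cells):
        return tuple(v + 0.5 for v in cells), True
    return tuple(float(v) for v in cells), False


def ror_estimate(t: ContingencyTable, alpha_level: float = 0.05) -> RorResult:
    """Reporting odds ratio with Woolf (log-scale) confidence interval.

    Any zero cell triggers the Haldane–Anscombe correction (+0.5 to all four
    cells, estimation only) and flags the result.  A table with the drug or
    the comparator entirely absent has no defined odds ratio.
    """
    if (t.a == 0 and t.b == 0) or (t.c == 0 and t.d == 0):
        raise ValueError("ROR undefined: drug or comparator margin is empty")
    (a, b, c, d), corrected = _halve_if_zero(t.cells())
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha_level / 2)
    return RorResult(ror, ror * math.exp(-z * se), ror * math.exp(z * se), corrected)


@dataclass(frozen=True)
class PrrResult:
    prr: float
    chi2: float


def prr_estimate(t: ContingencyTable, yates: bool = False) -> PrrResult:
    """Proportional reporting ratio and Pearson χ² (Yates optional).

    A zero c cell with a > 0 yields an infinite PRR, returned as ``inf``
    rather than raised: the comparator simply never reported the event.
    """
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise ValueError("PRR undefined: drug or comparator margin is empty")
    p_drug = t.a / (t.a + t.b)
    if t.c == 0:
        prr = math.inf if t.a > 0 else float("nan")
    else:
        prr = p_drug / (t.c / (t.c + t.d))
    n = t.n
    r1, r2, c1, c2 = t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d
    if c1 == 0 or c2 == 0:
        chi2 = 0.0
    else:
        dev = abs(t.a * t.d - t.b * t.c)
        if yates:
            dev = max(dev - n / 2, 0.0)
        chi2 = n * dev * dev / (r1 * r2 * c1 * c2)
    return PrrResult(prr, chi2)


# ---------------------------------------------------------------------------
# BCPNN information component


@dataclass(frozen=True)
class IcResult:
    ic: float
    ic025: float
    ic_sd: float


def bcpnn_ic(t: ContingencyTable) -> IcResult:
    """Closed-form posterior moments of the information component.

    Beta priors (all hyperparameters at their customary defaults: γ11 = 1,
    α1 = β1 = 1, α = β = 2) are updated with the observed margins; γ is
    chosen so that the prior expectation of the joint probability equals the
    product of the marginal expectations.  E[IC] is log2 of the ratio of
    posterior means; V[IC] sums the exact log-variances of the three
    independent Beta posteriors (trigamma differences).  The lower
    credibility bound is the common two-standard-deviation rule
    IC025 = E[IC] − 2√V[IC].
    """
    if t.n <= 0:
        raise ValueError("empty table")
    a, b, c, n = float(t.a), float(t.b), float(t.c), float(t.n)
    g11, a1, b1, al, be = 1.0, 1.0, 1.0, 2.0, 2.0
    gamma = g11 * (n + al) * (n + be) / ((a + b + a1) * (a + c + b1))
    e_ic = math.log2((a + g11) * (n + al) * (n + be)
                     / ((n + gamma) * (a + b + a1) * (a + c + b1)))
    # V[IC] is the sum of the three independent Beta log-variances; the
    # trigamma form is the exact value of the usual x/(y(1+z)) approximation
    v_ic = (1 / math.log(2) ** 2) * (
        special.polygamma(1, a + g11) - special.polygamma(1, n + gamma)
        + special.polygamma(1, a + b + a1) - special.polygamma(1, n + al)
        + special.polygamma(1, a + c + b1) - special.polygamma(1, n + be)
    )
    sd = math.sqrt(float(v_ic))
    return IcResult(e_ic, e_ic - 2 * sd, sd)


# ---------------------------------------------------------------------------
# MGPS / gamma-Poisson shrinkage


@dataclass(frozen=True)
class GammaMixturePrior:
    """Two-component gamma mixture prior on the relative reporting rate λ.

    Components are Gamma(shape=αj, rate=βj); ``w`` is the weight of the
    first component.  The default is the canonical DuMouchel starting prior
    (one diffuse component near small λ, one concentrated near λ ≈ 0.5–1).
    """

    alpha1: float = 0.2
    beta1: float = 0.1
    alpha2: float = 2.0
    beta2: float = 4.0
    w: float = 1.0 / 3.0
    converged: bool = True

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not 0 <= self.w <= 1:
            raise ValueError("mixture weight must lie in [0,1]")


def _nb_logpmf(a: float, shape: float, rate: float, e: float) -> float:
    """log P(a) marginally: negative binomial from Gamma(shape, rate) × Poisson(λE)."""
    p = rate / (rate + e)
    return stats.nbinom.logpmf(a, shape, p)


def _posterior_mixture(a: int, e: float, prior: GammaMixturePrior
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior of λ | a: gamma mixture with updated parameters and weights."""
    shapes = np.array([prior.alpha1 + a, prior.alpha2 + a])
    rates = np.array([prior.beta1 + e, prior.beta2 + e])
    logw = np.array([
        math.log(prior.w) + _nb_logpmf(a, prior.alpha1, prior.beta1, e) if prior.w > 0 else -np.inf,
        math.log1p(-prior.w) + _nb_logpmf(a, prior.alpha2, prior.beta2, e) if prior.w < 1 else -np.inf,
    ])
    logw -= special.logsumexp(logw)
    return shapes, rates, np.exp(logw)


@dataclass(frozen=True)
class EbgmResult:
    ebgm: float
    eb05: float


def mgps_ebgm(t: ContingencyTable, prior: GammaMixturePrior | None = None) -> EbgmResult:
    """Empirical-Bayes geometric mean and 5th percentile of the shrunken rate.

    With ``a ~ Poisson(λE)``, ``E = (a+b)(a+c)/N``, the posterior of λ under
    the gamma-mixture prior is again a gamma mixture; EBGM = exp(E[ln λ | a])
    and EB05 solves the posterior mixture CDF at 0.05 by bracketed
    root-finding (the CDF is strictly increasing).
    """
    prior = prior or GammaMixturePrior()
    e = t.expected
    if e <= 0:
        raise ValueError("expected count E must be positive")
    shapes, rates, q = _posterior_mixture(t.a, e, prior)
    mean_log = float(np.sum(q * (special.digamma(shapes) - np.log(rates))))
    ebgm = math.exp(mean_log)

    def cdf(lam: float) -> float:
        return float(np.sum(q * stats.gamma.cdf(lam, shapes, scale=1.0 / rates)))

    lo, hi = 1e-12, 1.0
    while cdf(hi) < 0.05:
        hi *= 4
        if hi > 1e12:
            raise RuntimeError("EB05 bracket failure")
    eb05 = optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, xtol=1e-12, rtol=1e-12)
    return EbgmResult(ebgm, float(eb05))


def fit_gamma_mixture(tables: Iterable[ContingencyTable],
                      start: GammaMixturePrior | None = None) -> GammaMixturePrior:
    """Empirical-Bayes fit of the gamma-mixture prior across many tables.

    Maximizes the marginal likelihood — each (a, E) contributes a mixture of
    negative binomial masses — over log hyperparameters and the logit weight
    with L-BFGS-B from the canonical start.  On failure the canonical prior
    is returned with ``converged=False`` and a warning.
    """
    tables = list(tables)
    if len(tables) < 50:
        raise ValueError("need at least 50 tables for a stable prior fit")
    a = np.array([t.a for t in tables], float)
    e = np.array([t.expected for t in tables], float)
    if np.any(e <= 0):
        raise ValueError("all tables must have positive expected counts")
    start = start or GammaMixturePrior()

    def negloglik(theta: np.ndarray) -> float:
        la1, lb1, la2, lb2, logit_w = theta
        a1, b1 = math.exp(la1), math.exp(lb1)
        a2, b2 = math.exp(la2), math.exp(lb2)
        w = 1.0 / (1.0 + math.exp(-logit_w))
        p1 = b1 / (b1 + e)
        p2 = b2 / (b2 + e)
        l1 = stats.nbinom.logpmf(a, a1, p1) + math.log(w)
        l2 = stats.nbinom.logpmf(a, a2, p2) + math.log1p(-w)
        return -float(np.sum(special.logsumexp(np.stack([l1, l2]), axis=0)))

    x0 = np.array([math.log(start.alpha1), math.log(start.beta1),
                   math.log(start.alpha2), math.log(start.beta2),
                   math.log(start.w / (1 - start.w))])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(negloglik, x0, method="L-BFGS-B",
                                bounds=[(-7, 7)] * 4 + [(-10, 10)])
    if not res.success or not np.all(np.isfinite(res.x)):
        warnings.warn("gamma-mixture fit did not converge; canonical prior returned")
        return replace(start, converged=False)
    la1, lb1, la2, lb2, lw = res.x
    return GammaMixturePrior(math.exp(la1), math.exp(lb1), math.exp(la2),
                             math.exp(lb2), 1.0 / (1.0 + math.exp(-lw)), True)


# ---------------------------------------------------------------------------
# Combined evaluation


@dataclass(frozen=True)
class ThresholdConfig:
    """Signal-flag thresholds (all overridable; defaults are the dominant
    conventions in FAERS disproportionality work)."""

    min_a: int = 3
    ror_lo_gt: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_gt: float = 0.0
    eb05_gt: float = 2.0
    alpha_level: float = 0.05
    yates: bool = False


@dataclass(frozen=True)
class SignalResult:
    """All four disproportionality statistics plus per-algorithm flags."""

    table: ContingencyTable
    ror: RorResult
    prr: PrrResult
    ic: IcResult
    ebgm: EbgmResult
    flag_ror: bool
    flag_prr: bool
    flag_bcpnn: bool
    flag_mgps: bool
    call: str  # robust | nominal | none


def evaluate_signal(t: ContingencyTable, config: ThresholdConfig | None = None,
                    prior: GammaMixturePrior | None = None) -> SignalResult:
    """Compute all four statistics and the configured threshold flags.

    The combined call is ``robust`` when all four algorithms flag,
    ``nominal`` when ROR flags without four-way agreement, ``none``
    otherwise.  No flag fires with a below the minimum count, whatever the
    intervals say.
    """
    cfg = config or ThresholdConfig()
    ror = ror_estimate(t, cfg.alpha_level)
    prr = prr_estimate(t, cfg.yates)
    ic = bcpnn_ic(t)
    eb = mgps_ebgm(t, prior)
    enough = t.a >= cfg.min_a
    f_ror = enough and ror.ci_lo > cfg.ror_lo_gt
    f_prr = enough and prr.prr >= cfg.prr_min and prr.chi2 >= cfg.chi2_min
    f_ic = ic.ic025 > cfg.ic025_gt
    f_eb = eb.eb05 > cfg.eb05_gt
    call = "robust" if (f_ror and f_prr and f_ic and f_eb) else ("nominal" if f_ror else "none")
    return SignalResult(t, ror, prr, ic, eb, f_ror, f_prr, f_ic, f_eb, call)


def signal_table(rs: ReportSet, drug: str, events: Iterable[str] | None = None,
                 level: str = "PT", config: ThresholdConfig | None = None,
                 prior: GammaMixturePrior | None = None,
                 strata: Callable[[pd.DataFrame], pd.Series] | None = None) -> pd.DataFrame:
    """Tidy one-row-per-event signal table for a drug.

    ``events=None`` scans every term (at the requested level) occurring in
    at least one exposed report.
    """
    col = "pt" if level == "PT" else "soc"
    if events is None:
        drug_std = " ".join(drug.upper().split())
        exposed = set(rs.drugs.loc[(rs.drugs["drug_name_std"] == drug_std)
                                   & (rs.drugs["role"] == "suspect"), "case_id"])
        events = sorted(rs.events.loc[rs.events["case_id"].isin(exposed), col].dropna().unique())
    rows = []
    for event in events:
        t = build_contingency(rs, drug, event, level=level, strata=strata)
        r = evaluate_signal(t, config, prior)
        rows.append({
            "drug": t.drug, "event": t.event, "level": level,
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "ror": r.ror.ror, "ror_lo": r.ror.ci_lo, "ror_hi": r.ror.ci_hi,
            "prr": r.prr.prr, "chi2": r.prr.chi2,
            "ic": r.ic.ic, "ic025": r.ic.ic025,
            "ebgm": r.ebgm.ebgm, "eb05": r.ebgm.eb05,
            "flag_ror": r.flag_ror, "flag_prr": r.flag_prr,
            "flag_bcpnn": r.flag_bcpnn, "flag_mgps": r.flag_mgps,
            "call": r.call,
        })
    return pd.DataFrame(rows)
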