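# Methods

This note documents the statistical models behind `pvsignal`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions that matter for reproducing results.

## Data model and deduplication

A report database is three tables keyed by `case_id`: case reports
(sex/age/weight/country/dates/indications), drug records (standardized name,
role, start date) and PT-coded event records. Dates may be partial
(year or year-month, as in FAERS extracts); partial dates count toward
annual report tallies but are treated as missing wherever a full calendar
date is required (duplicate cross-referencing, time-to-onset).

Spontaneous databases contain both literal duplicates (the same case
identifier re-submitted across quarters) and hidden ones (the same patient
event re-entered under a new identifier). Deduplication therefore runs in
two stages:

1. per `case_id`, keep the row with the maximal version key
   (report date, then file position — FAERS `caseversion` folds into the
   file-order component when present);
2. group remaining reports on (report date, age, sex, country) *with all
   four fields observed*, and keep one survivor per group — the most
   complete row (count of non-missing fields), ties broken toward the
   lexicographically smallest `case_id`.

Requiring all four match fields prevents the mass collapse of incomplete
reports: two reports that merely share "age missing, sex missing" are not
evidence of duplication. Deduplication is idempotent, never increases the
report count, and every removal is named in the returned log.

Demographic summaries bin age at [0,18), [18,65), [65,85), [85,∞) years and
weight at [0,50), [50,100), [100,∞) kg. Published cohort tables often print
overlapping labels ("18-65", "65-85"); the half-open-left convention makes
the binning deterministic. The annual-trend fit is an ordinary least-squares
polynomial on (year, count) with R² = 1 − SSres/SStot; a constant series has
zero total variance and R² is then defined as 1.0 with a warning, since the
fit is trivially perfect.

## Disproportionality statistics

The counting unit is the **report–distinct-term pair**, not the whole
report: a report listing five distinct PTs contributes five pairs (repeated
mentions of the same PT count once). This matters because published
sex-stratified counts for these drugs exceed their report totals — the
columns count PT mentions. The comparator is the full remaining database:
every deduplicated report without the target drug in suspect role. At SOC
level the same distinct-term rule applies to mapped SOC strings.

For a table (a, b, c, d) with N = a+b+c+d and E = (a+b)(a+c)/N:

- **ROR** = ad/(bc); 95% CI = exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)) (Woolf).
  Any zero cell triggers the Haldane–Anscombe +0.5 on all four cells
  (estimation only; the result is flagged, and signal flags never fire
  below the minimum count anyway). A table whose drug or comparator margin
  is entirely empty has no defined odds ratio and raises.
- **PRR** = [a/(a+b)]/[c/(c+d)]; the accompanying χ² is the Pearson
  statistic N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), with the Yates continuity
  correction behind a flag (both conventions circulate; uncorrected is the
  default). c = 0 with a > 0 returns an infinite PRR rather than raising —
  the comparator simply never reported the event.
- **BCPNN IC**: Beta priors with the customary hyperparameters
  (γ11 = 1, α1 = β1 = 1, α = β = 2); γ is set so that the prior expectation
  of the joint reporting probability equals the product of the marginal
  expectations, γ = γ11(N+α)(N+β)/((a+b+α1)(a+c+β1)). E[IC] is log₂ of the
  ratio of posterior means:
  E[IC] = log₂[(a+γ11)(N+α)(N+β)/((N+γ)(a+b+α1)(a+c+β1))].
  V[IC] sums the log-variances of the three independent Beta posteriors.
  The customary closed form writes each term as the second-order
  approximation x/(y(1+z)); this package uses the exact value of the same
  quantity, ψ′(α) − ψ′(α+β) per Beta term, because the approximation
  visibly narrows the bound at small a (about 0.01 bits of standard
  deviation at a = 10) while the trigamma form agrees with Monte-Carlo
  posterior sampling to sampling error. IC025 = E[IC] − 2√V[IC], the common
  two-standard-deviation convention; an exact posterior quantile is not the
  default because the moment form is what the field reports.
- **MGPS EBGM**: a ~ Poisson(λE) with a two-component gamma mixture prior
  on λ (shapes/rates α1 = 0.2, β1 = 0.1, α2 = 2.0, β2 = 4.0, weight
  w = 1/3 — the canonical starting prior). The posterior is again a gamma
  mixture with weights proportional to the negative-binomial marginals;
  EBGM = exp(E[ln λ | a]) via digamma, and EB05 solves the posterior CDF at
  0.05 by bracketed root-finding (the CDF is strictly increasing, so brentq
  on an expanding bracket is exact to tolerance). An empirical-Bayes fit of
  the prior (`fit_gamma_mixture`) maximizes the marginal likelihood over
  log-hyperparameters and logit weight with L-BFGS-B from the canonical
  start; non-convergence returns the canonical prior flagged. The canonical
  prior is the default so that desk-scale results are reproducible without
  a database-wide fit; fitting is opt-in.

Signal flags default to the dominant conventions: ROR — a ≥ 3 and CI lower
bound > 1; PRR — PRR ≥ 2, χ² ≥ 4, a ≥ 3; BCPNN — IC025 > 0; MGPS —
EB05 > 2. All thresholds are configurable. The combined call is `robust`
when all four flag, `nominal` when ROR flags without four-way agreement,
`none` otherwise; the conjunction rule is a package convention (per-drug
published tables report algorithms separately without one).

## Sex contrast (rROR)

Within the reports of one drug, each PT gets a 2×2 table of male pairs
with/without the PT against female pairs with/without it; unknown-sex
reports join no cell. rROR(m/f) = a_m·d_f/(b_m·c_f), with the same log-scale
Wald machinery as the ROR: SE = √(1/a_m+1/b_m+1/c_f+1/d_f), two-sided
p from z = ln(rROR)/SE, and p = 1 by convention at rROR exactly 1. The +0.5
zero-cell rule applies, flagged. BH-FDR is applied within each drug across
the analyst-supplied PT list (m = list length — the published analysis used
top-20 lists per drug; list selection is externalized to the caller).
Calls: male-enriched iff rROR > 1 with adjusted p < q, female-enriched iff
rROR < 1 with adjusted p < q, default q = 0.05.

The packaged `table2_counts.csv` transcribes the published counts and
statistics for the three ALK inhibitors. Recomputation from the printed
counts reproduces 56/60 rRORs to three decimals; the remaining four rows
(and sixteen rows of CI digits) are internally inconsistent in the source —
their printed p-values agree with the printed rROR but not with the printed
counts — and are not treated as ground truth.

## Time-to-onset and Weibull modeling

Onset is event date minus the earliest start date of the target drug for
the case, in days; cases missing either date are tallied as excluded, as
are non-positive onsets (a 0-day onset can optionally be mapped to 0.5 for
sensitivity analysis). There is no censoring model: spontaneous reports
contain only cases where the event occurred, so event-free follow-up does
not exist in these data, and no upper truncation is applied.

The two-parameter Weibull is fit by maximum likelihood: the shape β solves
the strictly monotone profile score equation
Σxᵢ^β ln xᵢ / Σxᵢ^β − 1/β − mean(ln x) = 0 by bracketed root-finding, after
which the scale has the closed form α = (Σxᵢ^β/n)^{1/β} (β = 1 recovers the
exponential submodel with α the sample mean). Confidence intervals come
from the observed information on (ln α, ln β), exponentiated, so bounds are
always positive. Samples extracted from calendar dates are whole days; a
recorded onset of k days stands for a true onset in (k−1, k], and the fit
uses the interval midpoint k − 0.5. Without this, the day grid inflates the
shape estimate by about +4% at β = 0.7 (mass below one day collapses onto
day 1); with it the residual bias is about +1.4%. Medians are computed on
the raw day values (even n averages the central order statistics, hence
half-integer medians).

Failure classification uses the shape CI only: upper bound < 1 → early
failure (decreasing hazard, events cluster at treatment start), CI
containing 1 → random (constant hazard), lower bound > 1 → wear-out.
Published interval notation for these fits is internally inconsistent in
the source table (point estimates outside their own printed intervals), so
printed intervals are not used as numeric targets; the rule is applied as
stated.

## Cross-database concordance

Signal tables from two databases are joined on case-folded,
whitespace-collapsed (drug, event) keys. Direction agreement is the
fraction of pairs with both statistics on the same side of 1; a statistic
of exactly 1 carries no direction and leaves the denominator. Correlation
is Pearson on the log statistics (the published comparison plots on a log
scale), Spearman behind a flag; it is undefined below 3 pairs or with zero
variance on either axis. Both summaries are symmetric in the databases and
invariant to positive power transforms of the statistics. No numeric
concordance target exists in the source — property-based behavior only.

## Synthetic generator

The generator emulates the structure the analyses assume: independent
Bernoulli drug exposures at configured marginals; per-(drug, event)
reporting probabilities background·ρ·(male multiplier), capped at 1 with a
warning count; onsets drawn Weibull(α, β) per exposed drug and converted to
event dates at day resolution (ceiling, so onsets are ≥ 1 day); report date
= event date + 1–60 day lag; per-field missingness; and exact-clone
duplicates under fresh, lexicographically larger case ids drawn from
demographically complete reports so that stage-2 deduplication must find
them through the cross-reference. Reports with no sampled drug receive a
filler `BACKGROUND` record so every case has a drug row without disturbing
configured marginals. All draws flow from one seed; output files are
byte-identical across runs.

Reference conditions (`default_config`): 20,000 reports; one target drug at
10% exposure against three 25% comparators; twenty PTs over five SOCs with
backgrounds geometric from 0.5% to 5%; 45% male; missingness 25% age,
75% weight, 5% country, 20% event date, 10% sex (matching the order of
missingness seen in public cohort tables for these drugs); 2% duplicates;
onset Weibull(α = 100 d, β = 0.7) for the target (the early-failure regime
the published fits report, β ≈ 0.6–0.9, α ≈ 40–240 d). The end-to-end
recovery runs add one common adverse event at 15% background to carry the
planted sex contrast, sized a priori so the male/female cells support the
stated tolerance at 50,000 reports.

What the generator does **not** emulate: within-report PT correlation
(events are independent given exposure, matching the 2×2 analysis
assumptions), stimulated/notoriety reporting waves, drug-name misspellings,
or partial-date patterns. Passing recovery tests therefore show that the
estimators invert the generator's mechanism at realistic sizes — not that
real spontaneous data satisfy that mechanism.

## Problem sizes used in checks

The shipped batteries use 200 replicates per cell of the Weibull
(β, n) ∈ {0.5, 0.7, 1.0, 1.5} × {100, 1000} grid (coverage assessed pooled
across the battery, since a 92–98% band at 200 replicates per cell has
±1.6% Monte-Carlo error), 500 replicates for ROR CI coverage at 20,000
pairs, one 50,000-report ground-truth run, and 200 null replicates of 1,500
reports for the false-robust-call rate. Monte-Carlo oracles use 10⁵
posterior draws; quadrature oracles use 10⁶-point grids.

## Known limitations

- Drug-name standardization is case-folding plus a user synonym table; no
  fuzzy matching or NLP normalization.
- No MedDRA dictionary ships with the package; the PT→SOC vocabulary is
  user-supplied.
- No stratified (Mantel–Haenszel) pooling, regression-based signal
  detection, multi-item MGPS itemsets, or confounder adjustment in the sex
  contrast — the underlying analysis performs none.
- Wald intervals on log parameters undercover slightly at small samples
  (measured ~94–95% at n = 100–1000 for the Weibull shape).
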