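# Methods

## The scientific question

A noninferiority (NI) trial compares a new treatment against an active
control without a placebo arm; its margin is typically derived from the
active control's historical effect over placebo. That derivation leans on
the *constancy assumption*: the effect seen in historical placebo-controlled
trials still holds today. `metaconstancy` implements a meta-epidemiological
pipeline for interrogating that assumption across a corpus of meta-analyses
of placebo-controlled trials: does the most recent trial in each
meta-analysis show a smaller effect than the pooled historical trials, and
does the effect (or the placebo response) trend with calendar time?

## Effect harmonization

Every trial is reduced to a standardized mean difference (SMD) oriented so
that positive values favour the active arm clinically.

* Continuous outcomes: Cohen's d with the pooled SD,
  `d = (m_a - m_p) / s_pooled`, `s_pooled^2 = ((n_a-1)s_a^2 + (n_p-1)s_p^2)/(n_a+n_p-2)`.
  The Hedges small-sample correction `J = 1 - 3/(4·df - 1)` is applied by
  default (small historical trials are common; a flag restores plain d).
  Sampling variance: `(n_a+n_p)/(n_a·n_p) + d^2/(2(n_a+n_p))`.
* Binary outcomes: all of RR/OR/RD-declared results are recomputed from the
  2x2 table through the log odds ratio and the logistic mapping
  `smd = ln(OR)·sqrt(3)/pi`, `var = (1/a + 1/b + 1/c + 1/d)·3/pi^2`. One
  consistent route keeps the conversion exact from arm counts regardless of
  the measure a review reported. 0.5 is added to all four cells only when a
  cell is zero (standard continuity practice; non-degenerate tables stay
  exact).
* Direction: for harm-direction outcomes (death, relapse, pain) the SMD and
  its CI are negated so that "benefit-positive" holds corpus-wide. The
  transform is applied *before* correlating or pooling.
* "Placebo response" and "active response" are the raw arm mean (continuous)
  or event proportion (binary), with no flip and no continuity correction.
  Only arm summaries exist in the data model, so change-from-baseline or
  standardized responses are out of reach; this is a documented choice, and
  trend results for arm responses should be read accordingly.
* All CIs at the effect level use the normal 1.96 multiplier.

## Pooling and the recency split

Within a review, SMDs are pooled by inverse variance, either common-effect
(`fixed`, weights `1/v_i`) or DerSimonian–Laird random-effects
(`random_dl`, the default, Cochrane convention): `tau^2 = max(0, (Q-df)/C)`
with `C = Σw - Σw²/Σw`, weights `1/(v_i + tau^2)`,
`I² = max(0, (Q-df)/Q)·100`.

The *recency split* partitions each review at its latest publication year:
all trials tied at the maximum year form the "last" set (publication year is
the only time resolution, so ties are treated as simultaneous), the rest are
the historical meta-analysis. Three pooled quantities result: all trials,
historical-only, and last-set-only. A review enters the regression only if
it has at least 4 trials and at least 3 remain after deletion, so the
historical estimate is never driven by fewer than 3 trials; reviews that
fail the rule are flagged and logged, never silently dropped. Reviews whose
trials all share one year carry no time signal and are rejected outright.

Two year gaps are tracked: the span between oldest and latest *historical*
trial (`year_diff`, the regression default) and the gap between the last set
and the latest historical trial (`gap_after_deletion`). The span within the
historical set is the default because that is the quantity available to
someone planning from the historical meta-analysis alone.

## Time trends

Per review (minimum 3 trials spanning at least 2 distinct years — 2-point
correlations are always ±1 and would distort category counts), publication
year is correlated (Pearson and Spearman) with the harmonized SMD, the raw
arm responses, and total sample size. Strength bands follow the convention
weak |r| < 0.3, moderate 0.3 ≤ |r| ≤ 0.5, strong |r| > 0.5, crossed with
sign for six categories; r = 0 lands in weak_positive. The boundary values
0.3 and 0.5 are assigned to moderate so that every |r| has exactly one
class. Constant series yield an *undefined* correlation (not zero) and are
excluded from that variable's denominators, with the exclusion count
reported.

Corpus aggregation reports per variable the percent negative, median, mean,
and a t-based 95% CI for the mean of plain r across reviews (means of r, not
Fisher-z, are the reported scale; a z-transform variant is available by
flag).

## The constancy regression

Across eligible reviews:

    SMDlt_j = b0 + b1·SMDdl_j + b2·year_diff_j + b3·year_last_j + e_j,
    Var(e_j) = sigma^2 / w_j,

with `SMDlt` the last set's pooled SMD, `SMDdl` the historical pooled SMD,
and weight `w_j` the historical meta-analysis's total sample size (WLS).
Weights are used as supplied; WLS estimates are invariant to weight scaling
(tested). Calendar year enters uncentered by default so the intercept is on
the same footing as published fits of this kind; a centering flag changes
only the intercept.

Covariate selection is deterministic stepwise around the forced predictor
`SMDdl` (the model's core question is its slope, so it is never subject to
removal): forward entry at p < 0.05, backward removal at p > 0.10, ties
broken by candidate order — a common default in mainstream statistical
packages, chosen for reproducibility since many conventions exist. SEs come
from the model-based weighted coefficient covariance, CIs use the t
multiplier on n − p − 1 df, adjusted R² is computed on the weighted
(whitened) scale. A saturated fit (rows = parameters) returns exact
coefficients with NaN inference.

**Prediction.** For a future trial, the point prediction is the linear
combination at the query covariates; the 95% prediction interval adds the
coefficient-covariance term at the query point and `sigma^2 / w0`, where the
future trial's implied weight `w0` defaults to the fitting corpus's median
(a typical future review resembles a typical historical one; override as
needed).

**NI discount.** The attenuation `1 − b1` is the proportional shrinkage a
historical meta-analytic effect deserves when carried forward to a new
trial; a slope of 0.88 means new-trial effects run 12% smaller, and a
putative-placebo margin derived from history should be discounted by that
factor. Note that `SMDdl` is itself an estimate: the slope conflates true
drift with regression dilution, so the discount is a planning quantity, not
a causal drift rate. Errors-in-variables corrections are out of scope.

## The synthetic corpus generator

Real corpora of this kind are assembled from systematic-review databases and
are rarely redistributable, so validation runs on synthetic corpora with
recorded ground truth. Review j draws a true base effect
θ_j ~ Normal(0.4, 0.25) (benefit-positive); trial i at year t has true SMD
θ_j + δ·(t − t0) + Normal(0, τ), with δ the effect drift per year (0 by
default: constancy true), τ = 0.15 the between-trial SD, and t0 the start of
the year range. Continuous arms draw sample means and chi-square SDs around
unit-SD populations; binary arms drift on the logit scale with the active
logit offset by `true_SMD·pi/sqrt(3)`, so the true SMD under the lnOR
mapping is exact by construction. Publication year doubles as conduct year
(the same proxy the analysis itself uses); no separate conduct year is
modeled.

Defaults are calibrated once to the descriptive statistics of a large
published corpus of placebo-controlled Cochrane meta-analyses:

| quantity | target | generator |
|---|---|---|
| reviews | 236 | `n_reviews = 236` |
| trials/review | min 4, median 7, mean 9.9, max 51 | 4 + NegBin(r = 0.7, mean 5.9), truncated at 51 |
| years | 1931–2016 | uniform windows of span 4–60 within the range |
| harm-direction share | 65.4% | `harm_fraction = 0.654` |
| binary share | 68% (55.3% RR + 11.4% OR + 1.2% RD) | `prop_binary = 0.68` |
| meta-analysis size | median 1160, IQR 494–2229 | per-arm n = 42·e^{0.01·(t−t0)}·LogN(0, 0.6)_review·LogN(0, 0.65)_trial |

Every default is overridable; infeasible settings (e.g. a logit drift that
forces event probabilities against 0 or 1 over the year range) raise a
validation error naming the parameter. A single root seed spawns per-review
child seeds, so corpora are bit-reproducible.

The generator deliberately does **not** emulate publication bias or
small-study effects, conditional trial sequences, therapeutic-area
covariates, or time-to-event outcomes. Passing tests therefore show the
pipeline behaves correctly under drift, heterogeneity and noise — not that
real corpora are free of selection effects.

`simulate_regression_rows` generates review-level rows directly from a known
linear model with noise variance `noise_sd²·median(w)/w`, so the weighted
fit is exactly correctly specified; it is the workhorse for parameter
recovery and selection calibration.

## Validation experiments and their sizes

The test suite runs, among others: exact agreement of pooling and WLS with
independently coded brute-force formulas (100 and 50 random instances);
parameter recovery of a published-style generating model (intercept 36.14,
SMDdl slope 0.88, year difference −0.009, year −0.018; 5,000 rows, 12
replicate seeds, each coefficient within 3 Monte-Carlo SEs); selection
calibration at 500 rows (null year term retained ≲ 10%, type-I error of the
year test 2.5–7.5% over 400 replicates on the row-level generator); a
corpus-level null-calibration experiment (200 corpora × 200 reviews, zero
drift); and a drift-detection experiment (50 corpora × 600 reviews at
δ = −0.02/year over 1966–2016 — 600 reviews chosen so detection power
exceeds 95%).

## Known limitations

* **Sample-size weighting is only a proxy for precision.** The response
  `SMDlt` is usually a single trial, so its variance is that trial's
  sampling variance plus τ², neither of which is proportional to the
  historical meta-analysis's total n that supplies the weight. Under
  realistic heterogeneity the model-based SEs of the year covariates are
  therefore anticonservative at the corpus level: in the suite's
  null-calibration experiment the nominal 5% year test rejects in roughly
  9–12% of zero-drift corpora, while the same test on the correctly weighted
  row-level generator holds its 5% size. Corpus-level year-coefficient
  p-values from this design should be read with that inflation in mind
  (robust/sandwich SEs would be the natural extension).
* Differential regression dilution: reviews with fewer or smaller historical
  trials have noisier `SMDdl`, so a single common slope leaves residual
  structure correlated with precision proxies (trial count, year span).
* The attenuation estimate conflates drift and dilution (above); the
  discount is interpretable for margin planning, not as a drift rate.
* Publication year is a proxy for conduct year at both generation and
  analysis level.
* Binary conversions assume the logistic model behind `ln(OR)·sqrt(3)/pi`;
  rare-event tables lean on the 0.5 continuity correction.
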