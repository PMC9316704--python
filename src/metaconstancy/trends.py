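"""Per-review and corpus-wide time trends in effects, responses and sizes.

For each review with at least three trials, publication year is correlated
(Pearson and Spearman) with the benefit-positive per-trial SMD, the raw
placebo-arm response, the raw active-arm response, and the total sample size.
Correlation strength is banded as weak (|r| < 0.3), moderate (0.3 <= |r| <=
0.5) or strong (|r| > 0.5), with the sign kept, giving six categories per
variable.  Corpus-wide aggregation reports the share of negative correlations,
the median and mean correlation with a t-based 95% CI, and the six-category
counts.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .effects import TrialRecord, ValidationError, arm_responses, trial_effect

__all__ = [
    "CATEGORIES",
    "TREND_VARIABLES",
    "VariableTrend",
    "TrendSummary",
    "review_trend",
    "classify_correlation",
    "aggregate_trends",
]

#: Six-level strength-by-sign categories, ordered as reported.
CATEGORIES = (
    "strong_negative",
    "moderate_negative",
    "weak_negative",
    "weak_positive",
    "moderate_positive",
    "strong_positive",
)

#: Variables correlated against publication year, in report order.
TREND_VARIABLES = ("smd", "placebo", "active", "sample_size")


def classify_correlation(r: float) -> str:
    """Band a correlation coefficient by strength and sign.

    Strength from |r|: weak below 0.3, moderate in [0.3, 0.5], strong above
    0.5; the sign of r picks the negative/positive half.  r = 0 is
    weak_positive by convention.
    """
    if not -1.0 <= r <= 1.0:
        raise ValidationError(f"correlation {r} outside [-1, 1]")
    a = abs(r)
    if a < 0.3:
        strength = "weak"
    elif a <= 0.5:
        strength = "moderate"
    else:
        strength = "strong"
    return f"{strength}_{'negative' if r < 0 else 'positive'}"


@dataclass(frozen=True)
class VariableTrend:
    """Year-correlation of one variable within one review."""

    pearson: float
    spearman: float
    defined: bool
    category: Optional[str]


@dataclass(frozen=True)
class TrendSummary:
    """Year-trend correlations for one review, per variable."""

    review_id: str
    k: int
    smd: VariableTrend
    placebo: VariableTrend
    active: VariableTrend
    sample_size: VariableTrend

    def variable(self, name: str) -> VariableTrend:
        if name not in TREND_VARIABLES:
            raise ValidationError(f"unknown trend variable {name!r}")
        return getattr(self, name)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def _corr_pair(x: np.ndarray, y: np.ndarray) -> VariableTrend:
    # A constant series has zero variance: the correlation is undefined rather
    # than zero, and the review is excluded from that variable's aggregation.
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return VariableTrend(math.nan, math.nan, False, None)
    pear = _pearson(x, y)
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    spear = _pearson(rx, ry) if (np.ptp(rx) > 0 and np.ptp(ry) > 0) else math.nan
    pear = min(1.0, max(-1.0, pear))
    return VariableTrend(pear, spear, True, classify_correlation(pear))


def review_trend(
    trials: Sequence[TrialRecord],
    small_sample_correction: bool = True,
    min_trials: int = 3,
) -> TrendSummary:
    """Correlate publication year against SMD, arm responses and sample size.

    SMDs are harmonized to the benefit-positive scale before correlating, so
    a negative SMD-year correlation always means a shrinking treatment effect.
    Arm responses stay on the raw outcome scale (no flip).  At least three
    trials spanning at least two distinct years are required: a two-point
    correlation is always +/-1 and would distort the category counts.
    """
    if len(trials) < min_trials:
        raise ValidationError(
            f"review needs >= {min_trials} trials for a trend, got {len(trials)}"
        )
    years = np.array([t.pub_year for t in trials], dtype=float)
    if np.ptp(years) == 0:
        raise ValidationError("all trials share one publication year")
    smds = np.array(
        [trial_effect(t, small_sample_correction).smd for t in trials], dtype=float
    )
    resp = [arm_responses(t) for t in trials]
    placebo = np.array([r[0] for r in resp], dtype=float)
    active = np.array([r[1] for r in resp], dtype=float)
    n_tot = np.array([t.n_total for t in trials], dtype=float)
    return TrendSummary(
        review_id=trials[0].review_id,
        k=len(trials),
        smd=_corr_pair(years, smds),
        placebo=_corr_pair(years, placebo),
        active=_corr_pair(years, active),
        sample_size=_corr_pair(years, n_tot),
    )


def _t_mean_ci(values: Sequence[float], level: float = 0.95) -> tuple[float, float, float]:
    mean = statistics.mean(values)
    n = len(values)
    if n < 2:
        return mean, math.nan, math.nan
    half = stats.t.ppf(0.5 + level / 2.0, n - 1) * statistics.stdev(values) / math.sqrt(n)
    return mean, mean - half, mean + half


def aggregate_trends(
    summaries: Sequence[TrendSummary],
    use_fisher_z: bool = False,
    which: str = "pearson",
) -> dict:
    """Corpus-level trend report across reviews.

    For each variable: percent of reviews with a negative correlation, median
    and mean correlation with a t-based 95% CI, and counts per six-level
    category.  Reviews whose correlation is undefined (constant series) are
    excluded from that variable's denominator; the exclusion count is
    reported.  ``use_fisher_z`` averages on the Fisher-z scale and transforms
    the mean and CI back (means of plain r are the default).
    """
    if len(summaries) < 2:
        raise ValidationError("need >= 2 reviews to aggregate trends")
    if which not in ("pearson", "spearman"):
        raise ValidationError(f"unknown coefficient kind {which!r}")
    report: dict = {"coefficient": which, "n_reviews": len(summaries), "variables": {}}
    for var in TREND_VARIABLES:
        vals, cats = [], []
        n_undefined = 0
        for s in summaries:
            vt = s.variable(var)
            if not vt.defined:
                n_undefined += 1
                continue
            vals.append(getattr(vt, which))
            cats.append(classify_correlation(getattr(vt, which)))
        entry: dict = {"n": len(vals), "n_undefined": n_undefined}
        if vals:
            if use_fisher_z:
                z = [math.atanh(min(0.999999, max(-0.999999, v))) for v in vals]
                mean_z, lo_z, hi_z = _t_mean_ci(z)
                mean, lo, hi = math.tanh(mean_z), math.tanh(lo_z), math.tanh(hi_z)
            else:
                mean, lo, hi = _t_mean_ci(vals)
            entry.update(
                percent_negative=100.0 * sum(v < 0 for v in vals) / len(vals),
                median=float(statistics.median(vals)),
                mean=float(mean),
                ci_low=float(lo),
                ci_high=float(hi),
                counts={c: cats.count(c) for c in CATEGORIES},
            )
        report["variables"][var] = entry
    return report
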