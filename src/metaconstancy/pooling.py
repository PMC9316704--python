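"""Inverse-variance meta-analysis pooling and the three-way recency split.

For each review the pipeline needs three pooled standardized mean differences:
the pooled SMD of all trials, the pooled SMD after deleting the most recent
trial(s) (the "historical" meta-analysis), and the SMD of the most recent
trial(s) themselves.  All trials published in the review's latest calendar
year form the "last" set, since publication year is the only time resolution
available and ties are common.

Pooling supports a common-effect (fixed) model with weights ``1/v_i`` and the
DerSimonian-Laird random-effects model with ``tau^2 = max(0, (Q - df)/C)``,
``C = sum(w) - sum(w^2)/sum(w)`` and weights ``1/(v_i + tau^2)``.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .effects import Z95, EffectEstimate, TrialRecord, ValidationError, trial_effect

__all__ = [
    "PooledEstimate",
    "RecencySplit",
    "pool",
    "recency_split",
    "corpus_summary",
]

PoolingMethod = Literal["fixed", "random_dl"]


@dataclass(frozen=True)
class PooledEstimate:
    """Inverse-variance pooled SMD with heterogeneity statistics."""

    smd: float
    se: float
    ci_low: float
    ci_high: float
    k: int
    n_total: int
    q: float
    tau2: float
    i2: float
    method: PoolingMethod

    @property
    def var(self) -> float:
        return self.se * self.se


def pool(effects: Sequence[EffectEstimate], method: PoolingMethod = "random_dl") -> PooledEstimate:
    """Pool per-trial SMDs by inverse-variance weighting.

    With a single input either method returns that input's SMD and variance;
    Q is then 0 and tau^2 = I^2 = 0.  ``tau2`` is always reported (it is 0
    under the fixed model by definition of the estimator's use there).
    """
    if len(effects) == 0:
        raise ValidationError("cannot pool an empty list of effects")
    if method not in ("fixed", "random_dl"):
        raise ValidationError(f"unknown pooling method {method!r}")
    y = np.array([e.smd for e in effects], dtype=float)
    v = np.array([e.var for e in effects], dtype=float)
    if np.any(v <= 0):
        raise ValidationError("all sampling variances must be positive")
    w = 1.0 / v
    sw = w.sum()
    mu_fixed = float((w * y).sum() / sw)
    df = len(effects) - 1
    q = float((w * (y - mu_fixed) ** 2).sum())
    if df > 0:
        c = sw - (w**2).sum() / sw
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
        i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    else:
        tau2, i2 = 0.0, 0.0
    if method == "random_dl":
        w_star = 1.0 / (v + tau2)
        mu = float((w_star * y).sum() / w_star.sum())
        se = math.sqrt(1.0 / w_star.sum())
        tau2_out = tau2
    else:
        mu = mu_fixed
        se = math.sqrt(1.0 / sw)
        tau2_out = 0.0
    n_total = int(sum(e.n_total for e in effects))
    return PooledEstimate(
        smd=mu,
        se=se,
        ci_low=mu - Z95 * se,
        ci_high=mu + Z95 * se,
        k=len(effects),
        n_total=n_total,
        q=q,
        tau2=tau2_out,
        i2=i2,
        method=method,
    )


@dataclass(frozen=True)
class RecencySplit:
    """A review's pooled SMD triple: all trials, historical set, last set.

    ``year_diff`` is the span (latest minus oldest publication year) within
    the historical set; ``gap_after_deletion`` is the gap between the last
    set's year and the latest historical trial.  A review is eligible for the
    constancy regression when it has at least 4 trials in total and at least
    3 remain after deleting the last set, so the historical pooled SMD is
    never driven by fewer than 3 trials.
    """

    review_id: str
    smd_all: PooledEstimate
    smd_dl: PooledEstimate
    smd_lt: PooledEstimate
    first_year: int
    last_year: int
    year_diff: int
    year_of_last: int
    gap_after_deletion: int
    k_last: int
    eligible: bool

    @property
    def k_all(self) -> int:
        return self.smd_all.k


def recency_split(
    trials: Sequence[TrialRecord],
    method: PoolingMethod = "random_dl",
    small_sample_correction: bool = True,
    min_trials: int = 4,
    min_historical: int = 3,
) -> RecencySplit:
    """Split a review at its most recent publication year and pool each part.

    All trials tied at the maximum publication year form the last set.  SMDs
    are direction-harmonized (benefit-positive) before pooling.  Reviews whose
    trials all share one year carry no time signal and are rejected.
    """
    if len(trials) == 0:
        raise ValidationError("review has no trials")
    review_ids = {t.review_id for t in trials}
    if len(review_ids) != 1:
        raise ValidationError(f"trials span multiple reviews: {sorted(review_ids)}")
    years = [t.pub_year for t in trials]
    year_of_last = max(years)
    if min(years) == year_of_last:
        raise ValidationError(
            f"review {trials[0].review_id!r}: all trials share year {year_of_last} "
            "(same-year reviews are excluded)"
        )
    last = [t for t in trials if t.pub_year == year_of_last]
    hist = [t for t in trials if t.pub_year != year_of_last]
    eff = lambda ts: [trial_effect(t, small_sample_correction) for t in ts]
    hist_years = [t.pub_year for t in hist]
    return RecencySplit(
        review_id=trials[0].review_id,
        smd_all=pool(eff(trials), method),
        smd_dl=pool(eff(hist), method),
        smd_lt=pool(eff(last), method),
        first_year=min(hist_years),
        last_year=max(hist_years),
        year_diff=max(hist_years) - min(hist_years),
        year_of_last=year_of_last,
        gap_after_deletion=year_of_last - max(hist_years),
        k_last=len(last),
        eligible=(len(trials) >= min_trials and len(hist) >= min_historical),
    )


def corpus_summary(splits: Iterable[RecencySplit]) -> dict:
    """Descriptive statistics for a corpus of recency splits."""
    splits = list(splits)
    if not splits:
        raise ValidationError("empty corpus")
    ks = [s.k_all for s in splits]
    return {
        "n_reviews": len(splits),
        "n_trials": int(sum(ks)),
        "median_trials": float(statistics.median(ks)),
        "mean_trials": float(statistics.mean(ks)),
        "min_trials": int(min(ks)),
        "max_trials": int(max(ks)),
        "min_year": int(min(s.first_year for s in splits)),
        "max_year": int(max(s.year_of_last for s in splits)),
        "n_eligible": int(sum(s.eligible for s in splits)),
        "n_ineligible": int(sum(not s.eligible for s in splits)),
    }
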