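"""Trial-level effect sizes on a harmonized standardized-mean-difference scale.

A corpus of placebo-controlled trials mixes continuous outcomes (arm means and
SDs) with binary outcomes (arm event counts), and mixes outcomes where a larger
raw value is good (benefit) with outcomes where it is bad (harm).  This module
converts every trial to a single scale: a standardized mean difference (SMD)
oriented so that a positive value always favours the active arm clinically.

Continuous outcomes use Cohen's d with the pooled SD, optionally with the
Hedges small-sample correction.  Binary outcomes are converted through the
log-odds ratio using the logistic-distribution mapping ``smd = ln(OR)*sqrt(3)/pi``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

__all__ = [
    "ValidationError",
    "TrialRecord",
    "EffectEstimate",
    "smd_continuous",
    "smd_binary",
    "harmonize_direction",
    "arm_responses",
    "trial_effect",
]

#: 95% confidence-interval multiplier (normal quantile), fixed by convention.
Z95 = 1.959963984540054

OutcomeKind = Literal["continuous", "binary"]
Direction = Literal["benefit", "harm"]

_MEASURES = ("MD", "SMD", "RR", "OR", "RD")


class ValidationError(ValueError):
    """Raised when trial-level inputs violate the data model."""


@dataclass(frozen=True)
class TrialRecord:
    """One placebo-controlled trial's per-arm summaries.

    ``direction`` states whether a larger raw outcome value is clinically good
    (``benefit``: e.g. healing, improvement) or bad (``harm``: e.g. death,
    relapse, pain intensity).  Exactly one of the continuous field group
    (means/SDs) or the binary field group (event counts) must be populated,
    matching ``outcome_kind``.
    """

    review_id: str
    trial_id: str
    pub_year: int
    outcome_kind: OutcomeKind
    direction: Direction
    declared_measure: str
    active_n: int
    placebo_n: int
    active_mean: Optional[float] = None
    active_sd: Optional[float] = None
    placebo_mean: Optional[float] = None
    placebo_sd: Optional[float] = None
    active_events: Optional[int] = None
    placebo_events: Optional[int] = None

    def __post_init__(self) -> None:
        if self.outcome_kind not in ("continuous", "binary"):
            raise ValidationError(f"unknown outcome_kind {self.outcome_kind!r}")
        if self.direction not in ("benefit", "harm"):
            raise ValidationError(f"unknown direction {self.direction!r}")
        if self.declared_measure not in _MEASURES:
            raise ValidationError(
                f"declared_measure must be one of {_MEASURES}, got {self.declared_measure!r}"
            )
        if not (1900 <= self.pub_year <= 2100):
            raise ValidationError(f"pub_year {self.pub_year} outside [1900, 2100]")
        if self.active_n <= 0 or self.placebo_n <= 0:
            raise ValidationError("arm sizes must be positive")
        cont = (self.active_mean, self.active_sd, self.placebo_mean, self.placebo_sd)
        binr = (self.active_events, self.placebo_events)
        if self.outcome_kind == "continuous":
            if any(v is None for v in cont):
                raise ValidationError("continuous trial missing mean/sd fields")
            if any(v is not None for v in binr):
                raise ValidationError("continuous trial must not carry event counts")
            if self.active_sd <= 0 or self.placebo_sd <= 0:  # type: ignore[operator]
                raise ValidationError("arm SDs must be positive")
        else:
            if any(v is None for v in binr):
                raise ValidationError("binary trial missing event counts")
            if any(v is not None for v in cont):
                raise ValidationError("binary trial must not carry means/SDs")
            if not (0 <= self.active_events <= self.active_n):  # type: ignore[operator]
                raise ValidationError(
                    f"active_events {self.active_events} outside [0, {self.active_n}]"
                )
            if not (0 <= self.placebo_events <= self.placebo_n):  # type: ignore[operator]
                raise ValidationError(
                    f"placebo_events {self.placebo_events} outside [0, {self.placebo_n}]"
                )

    @property
    def n_total(self) -> int:
        return self.active_n + self.placebo_n


@dataclass(frozen=True)
class EffectEstimate:
    """A standardized mean difference with its sampling variance and 95% CI."""

    smd: float
    var: float
    ci_low: float = field(default=math.nan)
    ci_high: float = field(default=math.nan)
    n_total: int = 0

    def __post_init__(self) -> None:
        if not self.var > 0:
            raise ValidationError(f"sampling variance must be positive, got {self.var}")
        if math.isnan(self.ci_low) or math.isnan(self.ci_high):
            half = Z95 * math.sqrt(self.var)
            object.__setattr__(self, "ci_low", self.smd - half)
            object.__setattr__(self, "ci_high", self.smd + half)

    @property
    def se(self) -> float:
        return math.sqrt(self.var)


def hedges_j(df: int) -> float:
    """Hedges' small-sample bias-correction factor ``J = 1 - 3/(4*df - 1)``."""
    if df < 1:
        raise ValidationError(f"degrees of freedom must be >= 1, got {df}")
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def smd_continuous(
    active_mean: float,
    active_sd: float,
    active_n: int,
    placebo_mean: float,
    placebo_sd: float,
    placebo_n: int,
    small_sample_correction: bool = True,
) -> EffectEstimate:
    """SMD from two-arm means and SDs (Cohen's d / Hedges' g).

    The pooled SD is ``sqrt(((n1-1)*s1^2 + (n2-1)*s2^2) / (n1+n2-2))`` and the
    returned SMD is positive when the active mean is larger; the clinical
    direction is applied separately by :func:`harmonize_direction`.  The
    sampling variance is ``(n1+n2)/(n1*n2) + smd^2/(2*(n1+n2))``.
    """
    if active_n < 2:
        raise ValidationError(f"active arm needs n >= 2, got {active_n}")
    if placebo_n < 2:
        raise ValidationError(f"placebo arm needs n >= 2, got {placebo_n}")
    if active_sd <= 0:
        raise ValidationError(f"active arm SD must be positive, got {active_sd}")
    if placebo_sd <= 0:
        raise ValidationError(f"placebo arm SD must be positive, got {placebo_sd}")
    n1, n2 = active_n, placebo_n
    df = n1 + n2 - 2
    s_pooled = math.sqrt(((n1 - 1) * active_sd**2 + (n2 - 1) * placebo_sd**2) / df)
    d = (active_mean - placebo_mean) / s_pooled
    if small_sample_correction:
        d *= hedges_j(df)
    n = n1 + n2
    var = n / (n1 * n2) + d * d / (2.0 * n)
    return EffectEstimate(smd=d, var=var, n_total=n)


def smd_binary(
    active_events: int,
    active_n: int,
    placebo_events: int,
    placebo_n: int,
) -> EffectEstimate:
    """SMD from a 2x2 table via the log-odds-ratio route.

    ``smd = ln(OR) * sqrt(3)/pi`` with ``var = (1/a + 1/b + 1/c + 1/d) * 3/pi^2``,
    where a..d are the four cells.  If any cell is zero, 0.5 is added to all
    four cells of that table before computation (standard continuity
    correction); non-degenerate tables are left exact.  The SMD is positive
    when the active arm has the higher odds of the raw event.
    """
    if active_n <= 0 or placebo_n <= 0:
        raise ValidationError("arm sizes must be positive")
    if not (0 <= active_events <= active_n):
        raise ValidationError(f"active_events {active_events} outside [0, {active_n}]")
    if not (0 <= placebo_events <= placebo_n):
        raise ValidationError(f"placebo_events {placebo_events} outside [0, {placebo_n}]")
    a = float(active_events)
    b = float(active_n - active_events)
    c = float(placebo_events)
    d = float(placebo_n - placebo_events)
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ln_or = math.log(a * d / (b * c))
    var_ln_or = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    k = math.sqrt(3.0) / math.pi
    return EffectEstimate(
        smd=ln_or * k,
        var=var_ln_or * 3.0 / math.pi**2,
        n_total=active_n + placebo_n,
    )


def harmonize_direction(e: EffectEstimate, direction: Direction) -> EffectEstimate:
    """Orient an SMD so that positive values always mean clinical benefit.

    For harm-direction outcomes (larger raw value is worse) the SMD and CI are
    negated, with the CI bounds swapped; benefit-direction estimates pass
    through unchanged.  The variance is unaffected.
    """
    if direction == "benefit":
        return e
    if direction == "harm":
        return EffectEstimate(
            smd=-e.smd, var=e.var, ci_low=-e.ci_high, ci_high=-e.ci_low, n_total=e.n_total
        )
    raise ValidationError(f"unknown direction {direction!r}")


def arm_responses(t: TrialRecord) -> tuple[float, float]:
    """Raw per-arm responses ``(placebo, active)`` on the outcome's own scale.

    Continuous outcomes return the two arm means; binary outcomes return the
    event proportions.  No benefit/harm flip and no continuity correction is
    applied: this is the raw arm summary, used for placebo-response and
    active-response time trends.
    """
    if t.outcome_kind == "continuous":
        return float(t.placebo_mean), float(t.active_mean)  # type: ignore[arg-type]
    return t.placebo_events / t.placebo_n, t.active_events / t.active_n  # type: ignore[operator]


def trial_effect(
    t: TrialRecord,
    small_sample_correction: bool = True,
    harmonize: bool = True,
) -> EffectEstimate:
    """Benefit-positive SMD for one trial, dispatching on its outcome kind."""
    if t.outcome_kind == "continuous":
        e = smd_continuous(
            t.active_mean, t.active_sd, t.active_n,  # type: ignore[arg-type]
            t.placebo_mean, t.placebo_sd, t.placebo_n,  # type: ignore[arg-type]
            small_sample_correction=small_sample_correction,
        )
    else:
        e = smd_binary(t.active_events, t.active_n, t.placebo_events, t.placebo_n)  # type: ignore[arg-type]
    return harmonize_direction(e, t.direction) if harmonize else e
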