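"""Weighted constancy regression: predicting a future trial from history.

The noninferiority constancy question is whether the effect a historical
meta-analysis reports still holds for a new trial.  Across reviews, the model
regresses the SMD of each review's most recent trial(s) (``smd_lt``) on the
pooled SMD of the earlier trials (``smd_dl``), with the historical year span
and the calendar year of the predicted trial as optional covariates:

    smd_lt = b0 + b1*smd_dl + b2*year_diff + b3*year_last + e

Each review is weighted by the total sample size of its historical
meta-analysis (weighted least squares), so Var(e_i) = sigma^2 / w_i.  A slope
``b1`` below 1 quantifies attenuation: ``1 - b1`` is the proportional discount
a historical meta-analytic effect deserves when carried forward to a new
trial, e.g. when sizing a noninferiority margin from a putative placebo.
Covariate selection is deterministic stepwise (forward entry p < 0.05,
backward removal p > 0.10) with ``smd_dl`` always kept in the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .effects import ValidationError
from .pooling import RecencySplit

__all__ = [
    "CANDIDATE_COVARIATES",
    "RegressionRow",
    "ConstancyFit",
    "regression_rows",
    "fit_wls",
    "stepwise_select",
    "predict_future",
    "ni_discount",
]

#: Covariates that may accompany the forced historical-SMD predictor.
CANDIDATE_COVARIATES = ("year_diff", "year_last")


@dataclass(frozen=True)
class RegressionRow:
    """One review's contribution to the constancy regression."""

    review_id: str
    smd_lt: float
    smd_dl: float
    year_diff: float
    year_last: float
    weight: float

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise ValidationError(
                f"review {self.review_id!r}: weight must be positive, got {self.weight}"
            )
        if self.year_diff < 0:
            raise ValidationError(
                f"review {self.review_id!r}: year_diff must be >= 0, got {self.year_diff}"
            )


@dataclass(frozen=True)
class ConstancyFit:
    """Fitted weighted regression with everything needed for prediction.

    ``terms`` orders the columns as fitted ("intercept" first); coefficient
    dictionaries are keyed by term.  ``residual_variance`` is sigma^2 in
    Var(e_i) = sigma^2 / w_i, estimated from the weighted residuals.
    """

    terms: tuple[str, ...]
    params: dict[str, float]
    ses: dict[str, float]
    ci_lows: dict[str, float]
    ci_highs: dict[str, float]
    p_values: dict[str, float]
    adj_r2: float
    n_rows: int
    selected: tuple[str, ...]
    residual_variance: float
    df_resid: int
    median_weight: float
    cov_params: np.ndarray = field(repr=False)
    x_wmean: np.ndarray = field(repr=False)
    y_wmean: float = field(repr=False)

    @property
    def intercept(self) -> float:
        return self.params["intercept"]

    @property
    def b_smd_dl(self) -> float:
        return self.params["smd_dl"]


def regression_rows(
    splits: Sequence[RecencySplit], require_eligible: bool = True
) -> list[RegressionRow]:
    """Assemble regression rows from recency splits.

    The response is the last set's pooled SMD, the predictor the historical
    pooled SMD, and the weight the historical meta-analysis's total sample
    size.  Ineligible reviews (fewer than 4 trials, or fewer than 3 left
    after deletion) are dropped when ``require_eligible`` is set.
    """
    rows = []
    for s in splits:
        if require_eligible and not s.eligible:
            continue
        rows.append(
            RegressionRow(
                review_id=s.review_id,
                smd_lt=s.smd_lt.smd,
                smd_dl=s.smd_dl.smd,
                year_diff=float(s.year_diff),
                year_last=float(s.year_of_last),
                weight=float(s.smd_dl.n_total),
            )
        )
    return rows


def _design(
    rows: Sequence[RegressionRow], covariates: Sequence[str], center_year: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[str, ...]]:
    for c in covariates:
        if c not in CANDIDATE_COVARIATES:
            raise ValidationError(f"unknown covariate {c!r}")
    terms = ("intercept", "smd_dl") + tuple(covariates)
    y = np.array([r.smd_lt for r in rows], dtype=float)
    w = np.array([r.weight for r in rows], dtype=float)
    cols = [np.ones(len(rows)), np.array([r.smd_dl for r in rows], dtype=float)]
    for c in covariates:
        v = np.array([getattr(r, c) for r in rows], dtype=float)
        if c == "year_last" and center_year:
            v = v - v.mean()
        cols.append(v)
    return np.column_stack(cols), y, w, terms


def _check_rank(x: np.ndarray, terms: tuple[str, ...]) -> None:
    if np.linalg.matrix_rank(x) == x.shape[1]:
        return
    bad = []
    for j in range(1, x.shape[1]):
        sub = x[:, :j]
        resid = x[:, j] - sub @ np.linalg.lstsq(sub, x[:, j], rcond=None)[0]
        if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(x[:, j])):
            bad.append(terms[j])
    raise ValidationError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_wls(
    rows: Sequence[RegressionRow],
    covariates: Sequence[str] = CANDIDATE_COVARIATES,
    ci_level: float = 0.95,
    center_year: bool = False,
) -> ConstancyFit:
    """Fit the sample-size-weighted regression for a fixed covariate set.

    Coefficients solve the weighted normal equations; standard errors come
    from the weighted coefficient covariance, confidence intervals use the t
    multiplier on n - p - 1 degrees of freedom, and the adjusted R^2 is
    computed on the weighted (whitened) scale.  ``center_year`` subtracts the
    mean calendar year from ``year_last``, changing only the intercept.
    """
    covariates = tuple(covariates)
    n_params = 2 + len(covariates)
    if len(rows) < n_params:
        raise ValidationError(
            f"need at least {n_params} rows to fit {n_params} parameters, got {len(rows)}"
        )
    x, y, w, terms = _design(rows, covariates, center_year)
    _check_rank(np.sqrt(w)[:, None] * x, terms)  # rank on the weighted design
    res = sm.WLS(y, x, weights=w).fit()
    saturated = res.df_resid <= 0
    if saturated:  # exact interpolation: no residual df, no inference
        conf = np.full((x.shape[1], 2), np.nan)
    else:
        conf = res.conf_int(alpha=1.0 - ci_level)
    sw = w.sum()
    return ConstancyFit(
        terms=terms,
        params=dict(zip(terms, map(float, res.params))),
        ses=dict(zip(terms, [math.nan] * len(terms) if saturated else map(float, res.bse))),
        ci_lows=dict(zip(terms, map(float, conf[:, 0]))),
        ci_highs=dict(zip(terms, map(float, conf[:, 1]))),
        p_values=dict(
            zip(terms, [math.nan] * len(terms) if saturated else map(float, res.pvalues))
        ),
        adj_r2=math.nan if saturated else float(res.rsquared_adj),
        n_rows=len(rows),
        selected=tuple(covariates),
        residual_variance=0.0 if saturated else float(res.scale),
        df_resid=int(res.df_resid),
        median_weight=float(np.median(w)),
        cov_params=(
            np.zeros((len(terms), len(terms)))
            if saturated
            else np.asarray(res.cov_params(), dtype=float)
        ),
        x_wmean=(w[:, None] * x).sum(axis=0) / sw,
        y_wmean=float((w * y).sum() / sw),
    )


def stepwise_select(
    rows: Sequence[RegressionRow],
    candidates: Sequence[str] = CANDIDATE_COVARIATES,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    ci_level: float = 0.95,
    center_year: bool = False,
) -> ConstancyFit:
    """Deterministic stepwise covariate selection around the forced predictor.

    Forward step: among candidates not yet in the model, add the one with the
    smallest p-value if it is below ``entry_p`` (ties broken by candidate
    order).  Backward step: drop the worst in-model candidate if its p-value
    exceeds ``removal_p``.  ``smd_dl`` is never subject to removal.  Iterates
    to a fixed point and returns the final fit with ``selected`` recording
    the retained covariates.
    """
    if not 0.0 < entry_p < removal_p < 1.0:
        raise ValidationError(
            f"need 0 < entry_p < removal_p < 1, got {entry_p}, {removal_p}"
        )
    candidates = tuple(candidates)
    for c in candidates:
        if c not in CANDIDATE_COVARIATES:
            raise ValidationError(f"unknown candidate covariate {c!r}")
    selected: list[str] = []
    kwargs = dict(ci_level=ci_level, center_year=center_year)
    while True:
        changed = False
        # forward
        best, best_p = None, entry_p
        for c in candidates:
            if c in selected:
                continue
            trial_fit = fit_wls(rows, (*selected, c), **kwargs)
            pv = trial_fit.p_values[c]
            if pv < best_p:
                best, best_p = c, pv
        if best is not None:
            selected.append(best)
            changed = True
        # backward
        if selected:
            fit = fit_wls(rows, tuple(selected), **kwargs)
            worst = max(selected, key=lambda c: fit.p_values[c])
            if fit.p_values[worst] > removal_p:
                selected.remove(worst)
                changed = True
        if not changed:
            break
    return fit_wls(rows, tuple(selected), **kwargs)


def predict_future(
    fit: ConstancyFit,
    smd_dl: float,
    year_diff: Optional[float] = None,
    year_last: Optional[float] = None,
    weight: Optional[float] = None,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Point prediction and prediction interval for a future trial's SMD.

    Every covariate retained by the fit must be supplied.  The interval
    combines the coefficient-covariance term at the query point with the
    residual variance scaled by the future trial's implied weight
    (``sigma^2 / weight``); the weight defaults to the fitting corpus's
    median, since a typical future review resembles a typical historical one.
    """
    supplied = {"smd_dl": smd_dl, "year_diff": year_diff, "year_last": year_last}
    x0 = []
    for term in fit.terms:
        if term == "intercept":
            x0.append(1.0)
            continue
        v = supplied.get(term)
        if v is None:
            raise ValidationError(f"fit requires covariate {term!r} but it was not supplied")
        x0.append(float(v))
    x0 = np.array(x0)
    beta = np.array([fit.params[t] for t in fit.terms])
    pred = float(x0 @ beta)
    w0 = fit.median_weight if weight is None else float(weight)
    if w0 <= 0:
        raise ValidationError(f"future-trial weight must be positive, got {w0}")
    var_pred = float(x0 @ fit.cov_params @ x0) + fit.residual_variance / w0
    tmult = stats.t.ppf(0.5 + ci_level / 2.0, fit.df_resid) if fit.df_resid > 0 else math.inf
    half = tmult * math.sqrt(var_pred)
    return pred, (pred - half, pred + half)


def ni_discount(fit: ConstancyFit) -> float:
    """Proportional attenuation ``1 - b_smd_dl`` of a historical effect.

    A slope of 0.88 on the historical SMD means a new trial is expected to
    show an effect 12% smaller than the historical meta-analysis; a putative
    placebo effect used to set a noninferiority margin should be discounted
    by this factor.  A slope of 1 is perfect constancy (no discount).
    """
    if "smd_dl" not in fit.params:
        raise ValidationError("fit does not include the historical-SMD term")
    return 1.0 - fit.params["smd_dl"]
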