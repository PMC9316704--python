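"""Synthetic corpora of placebo-controlled trial meta-analyses with known truth.

The real corpora this pipeline targets (collections of Cochrane-style
meta-analyses) are rarely redistributable, so the generator emulates their
statistical structure with every latent quantity recorded: review-level true
effects, per-trial true effects under configurable time drift in both the
treatment effect and the placebo response, sample sizes growing weakly with
calendar year, a mix of binary and continuous outcomes, and a mix of benefit-
and harm-direction outcomes.

Two levels are generated.  :func:`simulate_corpus` emits full trial-level
records (arm summaries) that exercise the entire pipeline; binary outcomes
drift on the logit scale so the true SMD under the lnOR*sqrt(3)/pi mapping is
exact.  :func:`simulate_regression_rows` emits review-level regression rows
directly from a known linear model, with noise variance proportional to the
inverse weight so the weighted fit is correctly specified — the workhorse for
parameter-recovery checks of the constancy regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .effects import TrialRecord, ValidationError
from .regression import RegressionRow

__all__ = [
    "SimulationConfig",
    "CorpusTruth",
    "simulate_corpus",
    "simulate_regression_rows",
    "DEFAULT_COVARIATE_DISTS",
]

_SQRT3_OVER_PI = math.sqrt(3.0) / math.pi


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic corpus.

    Defaults are calibrated to the descriptives of a large corpus of
    placebo-controlled Cochrane meta-analyses: ~236 reviews of 4-51 trials
    (median 7, mean ~9.9), publication years 1931-2016, ~65.4% harm-direction
    outcomes, ~68% binary outcomes, and a median meta-analysis sample size
    around 1160 participants.

    ``effect_drift`` is the change in the true benefit-positive SMD per
    calendar year (0 = constancy holds); ``placebo_drift`` is the change in
    the placebo response per year, in outcome units for continuous outcomes
    and on the logit scale for binary ones.  ``tau`` is the between-trial SD
    of true effects within a review.  Per-arm sizes follow
    ``n_baseline * exp(n_growth * years_since_start)`` times a review-level
    and a trial-level lognormal factor.
    """

    n_reviews: int = 236
    trials_nb_r: float = 0.7
    trials_nb_mean: float = 5.9
    min_trials: int = 4
    max_trials: int = 51
    year_range: tuple[int, int] = (1931, 2016)
    max_span: int = 60
    effect_drift: float = 0.0
    placebo_drift: float = 0.0
    base_effect_mean: float = 0.4
    base_effect_sd: float = 0.25
    tau: float = 0.15
    n_baseline: float = 42.0
    n_growth: float = 0.01
    n_dispersion: float = 0.65
    review_size_sd: float = 0.6
    prop_binary: float = 0.68
    harm_fraction: float = 0.654
    placebo_base_continuous: float = 0.0
    placebo_base_binary: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_reviews < 1:
            raise ValidationError("n_reviews must be >= 1")
        y0, y1 = self.year_range
        if y1 <= y0:
            raise ValidationError(f"year_range must be non-degenerate, got {self.year_range}")
        if self.tau < 0:
            raise ValidationError("tau must be >= 0")
        for name in ("prop_binary", "harm_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.placebo_base_binary < 1.0:
            raise ValidationError(
                f"placebo_base_binary must lie in (0, 1), got {self.placebo_base_binary}"
            )
        if self.min_trials < 2 or self.max_trials < self.min_trials:
            raise ValidationError("need 2 <= min_trials <= max_trials")
        if self.trials_nb_r <= 0 or self.trials_nb_mean <= 0:
            raise ValidationError("trials_nb_r and trials_nb_mean must be positive")
        if self.n_baseline < 5:
            raise ValidationError("n_baseline must be >= 5")
        # Binary event probabilities live on the logit scale; a drift that
        # pushes the placebo logit beyond +/-12 over the year range forces
        # probabilities numerically outside (0, 1).
        span = y1 - y0
        logit0 = math.log(self.placebo_base_binary / (1 - self.placebo_base_binary))
        if abs(logit0) + abs(self.placebo_drift) * span > 12.0:
            raise ValidationError(
                "placebo_drift drives binary event probabilities outside (0, 1) "
                "over the configured year_range"
            )


@dataclass(frozen=True)
class CorpusTruth:
    """Latent ground truth behind a simulated corpus."""

    config: SimulationConfig
    reviews: pd.DataFrame = field(repr=False)  # review_id, theta, kind, direction, ...
    trials: pd.DataFrame = field(repr=False)  # review_id, trial_id, pub_year, true_effect, ...


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _draw_years(rng: np.random.Generator, k: int, cfg: SimulationConfig) -> np.ndarray:
    y0, y1 = cfg.year_range
    width = y1 - y0
    span = int(rng.integers(min(4, width), min(cfg.max_span, width) + 1))
    start = int(rng.integers(y0, y1 - span + 1))
    while True:
        years = rng.integers(start, start + span + 1, size=k)
        if np.ptp(years) > 0:
            return np.sort(years)


def simulate_corpus(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[list[list[TrialRecord]], CorpusTruth]:
    """Generate a corpus of reviews with recorded latent truth.

    Review j draws a true base effect theta_j ~ Normal(base_effect_mean,
    base_effect_sd); trial i at year t has true benefit-positive SMD
    ``theta_j + effect_drift*(t - year_range[0]) + Normal(0, tau)``.  Arm
    summaries are then sampled so the implied SMD is centred on the trial's
    true effect with the correct sampling variance: continuous arms draw
    sample means and chi-square-distributed SDs around unit-SD populations;
    binary arms draw binomial events with the active logit offset by
    ``true_effect * pi/sqrt(3)`` (sign flipped for harm-direction outcomes,
    where the raw event is bad).  Deterministic given ``config.seed``; each
    review runs on a child seed spawned from the root so corpora are stable
    under partial regeneration.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_reviews)
    y0, _ = config.year_range
    nb_p = config.trials_nb_r / (config.trials_nb_r + config.trials_nb_mean)

    reviews: list[list[TrialRecord]] = []
    review_truth = []
    trial_truth = []
    for j, child in enumerate(children):
        rng = np.random.default_rng(child)
        review_id = f"R{j:04d}"
        k = min(
            config.max_trials,
            config.min_trials + int(rng.negative_binomial(config.trials_nb_r, nb_p)),
        )
        is_binary = rng.random() < config.prop_binary
        direction = "harm" if rng.random() < config.harm_fraction else "benefit"
        if is_binary:
            # within-binary mix of declared measures (RR/OR/RD)
            measure = str(rng.choice(["RR", "OR", "RD"], p=[0.814, 0.168, 0.018]))
        else:
            measure = "MD"
        theta = float(rng.normal(config.base_effect_mean, config.base_effect_sd))
        size_factor = float(rng.lognormal(0.0, config.review_size_sd))
        years = _draw_years(rng, k, config)

        trials: list[TrialRecord] = []
        for i, year in enumerate(years):
            dt = float(year - y0)
            true_eff = theta + config.effect_drift * dt + float(rng.normal(0.0, config.tau))
            n = int(
                max(
                    5,
                    round(
                        config.n_baseline
                        * size_factor
                        * math.exp(config.n_growth * dt)
                        * rng.lognormal(0.0, config.n_dispersion)
                    ),
                )
            )
            common = dict(
                review_id=review_id,
                trial_id=f"{review_id}-T{i:03d}",
                pub_year=int(year),
                direction=direction,
                declared_measure=measure,
                active_n=n,
                placebo_n=n,
            )
            signed = true_eff if direction == "benefit" else -true_eff
            if is_binary:
                logit_p0 = (
                    math.log(config.placebo_base_binary / (1 - config.placebo_base_binary))
                    + config.placebo_drift * dt
                )
                p0 = _sigmoid(logit_p0)
                p1 = _sigmoid(logit_p0 + signed / _SQRT3_OVER_PI)
                rec = TrialRecord(
                    outcome_kind="binary",
                    active_events=int(rng.binomial(n, p1)),
                    placebo_events=int(rng.binomial(n, p0)),
                    **common,
                )
            else:
                mu_p = config.placebo_base_continuous + config.placebo_drift * dt
                mu_a = mu_p + signed  # population SD is 1, so signed is the true SMD
                rec = TrialRecord(
                    outcome_kind="continuous",
                    active_mean=float(rng.normal(mu_a, 1.0 / math.sqrt(n))),
                    active_sd=float(math.sqrt(rng.chisquare(n - 1) / (n - 1))),
                    placebo_mean=float(rng.normal(mu_p, 1.0 / math.sqrt(n))),
                    placebo_sd=float(math.sqrt(rng.chisquare(n - 1) / (n - 1))),
                    **common,
                )
            trials.append(rec)
            trial_truth.append(
                dict(
                    review_id=review_id,
                    trial_id=rec.trial_id,
                    pub_year=int(year),
                    true_effect=true_eff,
                    n_per_arm=n,
                )
            )
        reviews.append(trials)
        review_truth.append(
            dict(
                review_id=review_id,
                theta=theta,
                outcome_kind="binary" if is_binary else "continuous",
                direction=direction,
                k=k,
                size_factor=size_factor,
                first_year=int(years.min()),
                last_year=int(years.max()),
            )
        )
    truth = CorpusTruth(
        config=config,
        reviews=pd.DataFrame(review_truth),
        trials=pd.DataFrame(trial_truth),
    )
    return reviews, truth


#: Default covariate/weight distributions for regression-row simulation:
#: historical SMD ~ Normal(0.3, 0.3), historical year span ~ Uniform(1, 40),
#: year of the predicted trial ~ Uniform(1990, 2016), and weights (historical
#: total sample size) ~ LogNormal with median 1160 and log-SD 1.0, matching
#: the corpus descriptives the generator emulates.
DEFAULT_COVARIATE_DISTS: dict[str, tuple] = {
    "smd_dl": ("normal", 0.3, 0.3),
    "year_diff": ("uniform", 1.0, 40.0),
    "year_last": ("uniform", 1990.0, 2016.0),
    "weight": ("lognormal", math.log(1160.0), 1.0),
}


def _draw_dist(rng: np.random.Generator, spec: tuple, size: int) -> np.ndarray:
    if not isinstance(spec, tuple) or len(spec) != 3:
        raise ValidationError(f"distribution spec must be (family, a, b), got {spec!r}")
    family, a, b = spec
    if family == "normal":
        return rng.normal(a, b, size=size)
    if family == "uniform":
        return rng.uniform(a, b, size=size)
    if family == "lognormal":
        return rng.lognormal(a, b, size=size)
    raise ValidationError(f"unknown distribution family {family!r}")


def simulate_regression_rows(
    coefficients: Mapping[str, float],
    noise_sd: float,
    n_rows: int,
    covariate_dists: Optional[Mapping[str, tuple]] = None,
    seed: int = 0,
) -> tuple[list[RegressionRow], dict]:
    """Regression rows from a known linear model, correctly weighted.

    ``coefficients`` maps terms (``intercept``, ``smd_dl``, ``year_diff``,
    ``year_last``; missing terms contribute 0) to generating values.  The
    response is the linear combination plus Gaussian noise with variance
    ``noise_sd^2 * median(weight) / weight``, so a fit weighted by the drawn
    weights is exactly the generating model and ``noise_sd`` is the residual
    SD of a median-weight review.  Deterministic given ``seed``.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    known = {"intercept", "smd_dl", "year_diff", "year_last"}
    extra = set(coefficients) - known
    if extra:
        raise ValidationError(f"unknown coefficient terms: {sorted(extra)}")
    if n_rows <= len(coefficients) + 2:
        raise ValidationError(
            f"need n_rows > {len(coefficients) + 2} for {len(coefficients)} coefficients"
        )
    dists = dict(DEFAULT_COVARIATE_DISTS)
    if covariate_dists:
        dists.update(covariate_dists)
    rng = np.random.default_rng(seed)
    smd_dl = _draw_dist(rng, dists["smd_dl"], n_rows)
    year_diff = _draw_dist(rng, dists["year_diff"], n_rows)
    year_last = _draw_dist(rng, dists["year_last"], n_rows)
    weight = _draw_dist(rng, dists["weight"], n_rows)
    if np.any(weight <= 0):
        raise ValidationError("weight distribution produced non-positive weights")
    med_w = float(np.median(weight))
    mean = (
        coefficients.get("intercept", 0.0)
        + coefficients.get("smd_dl", 0.0) * smd_dl
        + coefficients.get("year_diff", 0.0) * year_diff
        + coefficients.get("year_last", 0.0) * year_last
    )
    y = mean + rng.normal(0.0, 1.0, size=n_rows) * noise_sd * np.sqrt(med_w / weight)
    rows = [
        RegressionRow(
            review_id=f"S{i:05d}",
            smd_lt=float(y[i]),
            smd_dl=float(smd_dl[i]),
            year_diff=float(year_diff[i]),
            year_last=float(year_last[i]),
            weight=float(weight[i]),
        )
        for i in range(n_rows)
    ]
    truth = {
        "coefficients": dict(coefficients),
        "noise_sd": float(noise_sd),
        "median_weight": med_w,
        "seed": seed,
    }
    return rows, truth
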