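import numpy as np
import pytest

from metaconstancy import TrialRecord


def continuous_trial(
    review_id="R1",
    trial_id=None,
    pub_year=2000,
    direction="benefit",
    active_mean=0.5,
    active_sd=1.0,
    placebo_mean=0.0,
    placebo_sd=1.0,
    n=100,
):
    return TrialRecord(
        review_id=review_id,
        trial_id=trial_id or f"{review_id}-{pub_year}-{np.random.default_rng(abs(hash((review_id, pub_year, active_mean))) % 2**31).integers(1e6)}",
        pub_year=pub_year,
        outcome_kind="continuous",
        direction=direction,
        declared_measure="MD",
        active_n=n,
        placebo_n=n,
        active_mean=active_mean,
        active_sd=active_sd,
        placebo_mean=placebo_mean,
        placebo_sd=placebo_sd,
    )


def binary_trial(
    review_id="R1",
    trial_id="T1",
    pub_year=2000,
    direction="benefit",
    active_events=30,
    placebo_events=20,
    n=100,
):
    return TrialRecord(
        review_id=review_id,
        trial_id=trial_id,
        pub_year=pub_year,
        outcome_kind="binary",
        direction=direction,
        declared_measure="RR",
        active_n=n,
        placebo_n=n,
        active_events=active_events,
        placebo_events=placebo_events,
    )


def review_from_smds(pairs, review_id="R1", n=400, direction="benefit"):
    """Build a continuous review whose per-trial SMDs (correction off) are exact.

    With unit arm SDs and equal arms the pooled SD is exactly 1, so the mean
    difference equals the SMD.
    """
    return [
        continuous_trial(
            review_id=review_id,
            trial_id=f"{review_id}-T{i}",
            pub_year=year,
            direction=direction,
            active_mean=smd,
            placebo_mean=0.0,
            n=n,
        )
        for i, (year, smd) in enumerate(pairs)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
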