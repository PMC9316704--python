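"""Corpus I/O, pipeline orchestration and tabular reports.

The on-disk interchange format is a flat UTF-8 CSV with one row per trial and
arm columns (the shape of a typical meta-analysis extraction sheet).  Reading
validates every row against the trial data model; offending rows are rejected
with a reason and never silently coerced.  ``run_pipeline`` chains the stages
(effects -> recency split -> trends -> constancy regression) and writes all
report tables as delimited text plus a JSON run manifest.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .effects import TrialRecord, ValidationError
from .pooling import RecencySplit, corpus_summary, recency_split
from .regression import ConstancyFit, ni_discount, regression_rows, stepwise_select
from .trends import CATEGORIES, TREND_VARIABLES, TrendSummary, aggregate_trends, review_trend

__all__ = [
    "CSV_COLUMNS",
    "PipelineConfig",
    "PipelineResult",
    "ValidationReport",
    "read_trials_csv",
    "write_corpus",
    "write_truth",
    "run_pipeline",
    "coefficient_table",
    "category_table",
]

#: Column order of the trial-level interchange CSV.
CSV_COLUMNS = (
    "review_id",
    "trial_id",
    "pub_year",
    "outcome_kind",
    "direction",
    "declared_measure",
    "active_n",
    "placebo_n",
    "active_mean",
    "active_sd",
    "placebo_mean",
    "placebo_sd",
    "active_events",
    "placebo_events",
)

_REQUIRED = CSV_COLUMNS[:8]
_FLOAT_FIELDS = ("active_mean", "active_sd", "placebo_mean", "placebo_sd")
_EVENT_FIELDS = ("active_events", "placebo_events")


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration with documented defaults.

    ``pooling_method`` picks the within-review pooling model; stepwise entry
    and removal thresholds govern covariate selection in the constancy
    regression; the eligibility rule (at least ``min_trials`` trials overall,
    ``min_historical`` after deleting the last set) gates which reviews feed
    the regression.
    """

    pooling_method: str = "random_dl"
    small_sample_correction: bool = True
    entry_p: float = 0.05
    removal_p: float = 0.10
    min_trials_corr: int = 3
    ci_level: float = 0.95
    min_trials: int = 4
    min_historical: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.entry_p < self.removal_p < 1.0:
            raise ValidationError(
                f"need 0 < entry_p < removal_p < 1, got {self.entry_p}, {self.removal_p}"
            )
        if not 0.0 < self.ci_level < 1.0:
            raise ValidationError(f"ci_level must lie in (0, 1), got {self.ci_level}")
        if self.pooling_method not in ("fixed", "random_dl"):
            raise ValidationError(f"unknown pooling method {self.pooling_method!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass
class ValidationReport:
    """Outcome of reading a corpus: accepted counts and rejected rows."""

    n_rows: int = 0
    n_accepted: int = 0
    rejected: list[dict] = field(default_factory=list)


def _cell(row: pd.Series, name: str):
    v = row.get(name)
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return v


def read_trials_csv(path: str | Path) -> tuple[dict[str, list[TrialRecord]], ValidationReport]:
    """Read and validate a trial-level corpus CSV, grouped by review.

    Rows violating the data model (events exceeding the arm size,
    non-positive SDs, unknown enums, ...) are skipped and listed in the
    validation report with the offending row number and rule; a missing
    required column aborts with an error naming it.  Review order and trial
    order within a review follow the file.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"corpus CSV is missing required columns: {missing}")
    report = ValidationReport(n_rows=len(df))
    reviews: dict[str, list[TrialRecord]] = {}
    for idx, row in df.iterrows():
        try:
            kwargs = dict(
                review_id=str(row["review_id"]),
                trial_id=str(row["trial_id"]),
                pub_year=int(row["pub_year"]),
                outcome_kind=str(row["outcome_kind"]),
                direction=str(row["direction"]),
                declared_measure=str(row["declared_measure"]),
                active_n=int(row["active_n"]),
                placebo_n=int(row["placebo_n"]),
            )
            for name in _FLOAT_FIELDS:
                v = _cell(row, name)
                kwargs[name] = None if v is None else float(v)
            for name in _EVENT_FIELDS:
                v = _cell(row, name)
                kwargs[name] = None if v is None else int(v)
            rec = TrialRecord(**kwargs)
        except (ValidationError, ValueError, TypeError, KeyError) as exc:
            report.rejected.append({"row": int(idx) + 2, "reason": str(exc)})
            continue
        reviews.setdefault(rec.review_id, []).append(rec)
        report.n_accepted += 1
    return reviews, report


def _trial_to_row(t: TrialRecord) -> dict:
    d = {c: getattr(t, c) for c in CSV_COLUMNS}
    return {k: ("" if v is None else v) for k, v in d.items()}


def write_corpus(reviews: Sequence[Sequence[TrialRecord]] | dict, path: str | Path) -> None:
    """Write a corpus to the interchange CSV (one row per trial)."""
    groups = reviews.values() if isinstance(reviews, dict) else reviews
    rows = [_trial_to_row(t) for grp in groups for t in grp]
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)


def write_truth(truth, path: str | Path) -> None:
    """Write a simulation's latent ground truth as a delimited sidecar."""
    merged = truth.trials.merge(
        truth.reviews, on="review_id", suffixes=("", "_review")
    )
    merged.to_csv(path, index=False)


def splits_table(splits: Sequence[RecencySplit]) -> pd.DataFrame:
    rows = []
    for s in splits:
        rows.append(
            dict(
                review_id=s.review_id,
                k_all=s.k_all,
                k_last=s.k_last,
                smd_all=s.smd_all.smd,
                smd_dl=s.smd_dl.smd,
                smd_lt=s.smd_lt.smd,
                se_dl=s.smd_dl.se,
                se_lt=s.smd_lt.se,
                tau2_all=s.smd_all.tau2,
                i2_all=s.smd_all.i2,
                n_historical=s.smd_dl.n_total,
                first_year=s.first_year,
                last_year=s.last_year,
                year_diff=s.year_diff,
                year_of_last=s.year_of_last,
                gap_after_deletion=s.gap_after_deletion,
                eligible=s.eligible,
            )
        )
    return pd.DataFrame(rows)


def trends_table(trends: Sequence[TrendSummary]) -> pd.DataFrame:
    rows = []
    for t in trends:
        row: dict = dict(review_id=t.review_id, k=t.k)
        for var in TREND_VARIABLES:
            vt = t.variable(var)
            row[f"r_{var}_pearson"] = vt.pearson
            row[f"r_{var}_spearman"] = vt.spearman
            row[f"category_{var}"] = vt.category or ""
        rows.append(row)
    return pd.DataFrame(rows)


def category_table(trend_report: dict) -> pd.DataFrame:
    """Six-category count table (rows: category, columns: variable)."""
    data = {}
    for var, entry in trend_report["variables"].items():
        counts = entry.get("counts", {c: 0 for c in CATEGORIES})
        data[var] = [counts[c] for c in CATEGORIES]
    return pd.DataFrame(data, index=list(CATEGORIES)).rename_axis("category")


def coefficient_table(fit: ConstancyFit) -> pd.DataFrame:
    """Coefficient report: term, B, 95% CI bounds, p-value."""
    return pd.DataFrame(
        dict(
            term=list(fit.terms),
            B=[fit.params[t] for t in fit.terms],
            ci_low=[fit.ci_lows[t] for t in fit.terms],
            ci_high=[fit.ci_highs[t] for t in fit.terms],
            p_value=[fit.p_values[t] for t in fit.terms],
        )
    )


@dataclass
class PipelineResult:
    """Bundle of everything one end-to-end run produces."""

    splits: list[RecencySplit]
    excluded: list[dict]
    trends: list[TrendSummary]
    trend_report: dict
    fit: ConstancyFit
    manifest: dict


def run_pipeline(
    reviews: dict[str, list[TrialRecord]] | Sequence[Sequence[TrialRecord]],
    config: PipelineConfig = PipelineConfig(),
    out_dir: Optional[str | Path] = None,
) -> PipelineResult:
    """Run effects -> recency split -> trends -> constancy regression.

    Reviews that cannot be split (all trials in one year) or that fail the
    eligibility rule are excluded from the regression and logged, never
    silently dropped.  With fewer than 4 eligible reviews the run aborts with
    the eligibility breakdown.  When ``out_dir`` is given, all report tables
    and the run manifest are written there as delimited text / JSON; output
    is a pure function of the corpus and the config.
    """
    if isinstance(reviews, dict):
        groups = list(reviews.values())
    else:
        groups = [list(g) for g in reviews]
    splits: list[RecencySplit] = []
    excluded: list[dict] = []
    trends: list[TrendSummary] = []
    for grp in groups:
        rid = grp[0].review_id if grp else "<empty>"
        try:
            s = recency_split(
                grp,
                method=config.pooling_method,
                small_sample_correction=config.small_sample_correction,
                min_trials=config.min_trials,
                min_historical=config.min_historical,
            )
            splits.append(s)
            if not s.eligible:
                excluded.append(
                    {"review_id": rid, "stage": "eligibility",
                     "reason": f"k_all={s.k_all}, k_dl={s.k_all - s.k_last}"}
                )
        except ValidationError as exc:
            excluded.append({"review_id": rid, "stage": "split", "reason": str(exc)})
        try:
            trends.append(
                review_trend(
                    grp,
                    small_sample_correction=config.small_sample_correction,
                    min_trials=config.min_trials_corr,
                )
            )
        except ValidationError:
            pass  # too few trials or one year; already visible in the counts
    rows = regression_rows(splits, require_eligible=True)
    if len(rows) < 4:
        raise ValidationError(
            f"only {len(rows)} eligible reviews (need >= 4); "
            f"exclusions: {excluded}"
        )
    fit = stepwise_select(
        rows,
        entry_p=config.entry_p,
        removal_p=config.removal_p,
        ci_level=config.ci_level,
    )
    trend_report = aggregate_trends(trends) if len(trends) >= 2 else {}
    manifest = {
        "package_version": __version__,
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": asdict(config),
        "n_input_reviews": len(groups),
        "n_input_trials": int(sum(len(g) for g in groups)),
        "n_splits": len(splits),
        "n_excluded": len(excluded),
        "n_eligible": len(rows),
        "n_trend_reviews": len(trends),
        "selected_covariates": list(fit.selected),
        "adj_r2": fit.adj_r2,
        "ni_discount": ni_discount(fit),
        "corpus_summary": corpus_summary(splits) if splits else {},
    }
    result = PipelineResult(
        splits=splits,
        excluded=excluded,
        trends=trends,
        trend_report=trend_report,
        fit=fit,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    splits_table(result.splits).to_csv(out_dir / "splits.csv", index=False)
    trends_table(result.trends).to_csv(out_dir / "trends.csv", index=False)
    if result.trend_report:
        category_table(result.trend_report).to_csv(out_dir / "trend_categories.csv")
    coef = coefficient_table(result.fit)
    coef.to_csv(out_dir / "coefficients.csv", index=False)
    (out_dir / "coefficients.txt").write_text(
        coef.to_string(index=False, float_format=lambda v: f"{v:.6g}") + "\n",
        encoding="utf-8",
    )
    if result.excluded:
        pd.DataFrame(result.excluded).to_csv(out_dir / "exclusions.csv", index=False)
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
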