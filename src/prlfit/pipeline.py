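"""End-to-end orchestration of the analysis.

``run_pipeline`` chains: phase scoring → per-subject model fitting and AIC
strategy classification → the three-stage exclusion funnel → the Pαβ
logistic discriminant (fitted, or the published fixed coefficients in
replication mode) → ROC cutoff selection → anomalous/typical
classification → group summary and nested-model AIC tables.  Outputs are
plain CSV/JSON files regenerated byte-identically from the same config,
seed and input.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    ExclusionReason,
    Group,
    LogisticModel,
    PAPER_FIXED_MODEL,
    REFERENCE_CUTOFF,
    ROCResult,
    SubjectRecord,
    apply_exclusions,
    classify_behavior,
    fit_palpha_beta,
    logistic_model_comparison,
    palpha_beta,
    roc_analysis,
    summarize_groups,
)
from .config import PipelineConfig
from .fitting import FitOptions, Model, classify_strategy
from .io import read_choices
from .task import phase_scores

__all__ = ["PipelineResult", "run_pipeline", "score_and_fit_subjects"]


@dataclass
class PipelineResult:
    """In-memory bundle of everything a pipeline run produced."""

    subjects: list[SubjectRecord]
    logistic_model: LogisticModel
    roc: Optional[ROCResult]
    cutoff: float
    palpha: pd.DataFrame  # subject_id, group, alpha, beta, p_alpha_beta, behavior
    model_comparison: pd.DataFrame
    group_summary: pd.DataFrame
    funnel: dict[str, int]
    warnings: list[str]

    @property
    def n_anomalous_als(self) -> int:
        mask = (self.palpha["group"] == Group.ALS.value) & (
            self.palpha["behavior"] == "anomalous"
        )
        return int(mask.sum())


def score_and_fit_subjects(
    subjects: Sequence[SubjectRecord], config: PipelineConfig
) -> list[SubjectRecord]:
    """Attach phase scores, model fits and strategy labels to raw subjects."""
    out = []
    for s in subjects:
        acq, rev, total = phase_scores(s.sequence, config.task)
        label = classify_strategy(s.sequence, config.fit)
        out.append(
            replace(
                s,
                acquisition_score=acq,
                reversal_score=rev,
                total_score=total,
                strategy=label,
            )
        )
    return out


def _fits_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        q = s.strategy.fits[Model.QLEARNING]
        w = s.strategy.fits[Model.WSLS]
        r = s.strategy.fits[Model.RANDOM]
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group.value,
                "acquisition_score": s.acquisition_score,
                "reversal_score": s.reversal_score,
                "total_score": s.total_score,
                "model": s.strategy.best_model.value,
                "alpha": q.params.alpha,
                "beta": q.params.beta,
                "p_stay_win": w.params.p_stay_win,
                "p_shift_lose": w.params.p_shift_lose,
                "loglik_q": q.loglik,
                "loglik_wsls": w.loglik,
                "loglik_random": r.loglik,
                "aic_q": q.aic,
                "aic_wsls": w.aic,
                "aic_random": r.aic,
                "n_valid_trials": q.n_valid_trials,
                "converged": q.converged,
                "at_bound": q.at_bound,
            }
        )
    return pd.DataFrame.from_records(rows)


def run_pipeline(
    config: PipelineConfig,
    choices_path: str | Path | None = None,
    subjects: Sequence[SubjectRecord] | None = None,
    out_dir: str | Path | None = None,
    write: bool = True,
) -> PipelineResult:
    """Execute the full analysis on a choice CSV (or pre-loaded subjects).

    In replication mode the published discriminant coefficients and cutoff
    are used for scoring; otherwise the discriminant is fitted on the
    included subjects and the cutoff chosen by Youden's J on the empirical
    ROC.
    """
    if subjects is None:
        if choices_path is None:
            raise ValueError("provide either choices_path or subjects")
        subjects = read_choices(choices_path, config.task)
    subjects = list(subjects)
    if not any(s.group is Group.ALS for s in subjects):
        raise ValueError("pipeline aborted before the logistic stage: no ALS subjects")
    if not any(s.group is Group.CONTROL for s in subjects):
        raise ValueError("pipeline aborted before the logistic stage: no control subjects")

    run_warnings: list[str] = []
    scored = score_and_fit_subjects(subjects, config)
    for s in scored:
        if s.strategy.fits[Model.QLEARNING].at_bound:
            run_warnings.append(f"{s.subject_id}: Q-learning fit at a parameter bound")

    excluded = apply_exclusions(scored, config.exclusion)

    funnel = {
        "input": len(excluded),
        "post_score_filter": sum(
            s.exclusion_reason
            not in (ExclusionReason.LOW_ACQUISITION, ExclusionReason.LOW_REVERSAL)
            for s in excluded
        ),
        "post_strategy_filter": sum(
            s.exclusion_reason
            not in (
                ExclusionReason.LOW_ACQUISITION,
                ExclusionReason.LOW_REVERSAL,
                ExclusionReason.NON_Q_STRATEGY,
            )
            for s in excluded
        ),
        "included": sum(s.included for s in excluded),
    }

    included = [s for s in excluded if s.included]
    if not any(s.group is Group.ALS for s in included) or not any(
        s.group is Group.CONTROL for s in included
    ):
        raise ValueError(
            "pipeline aborted before the logistic stage: a group was emptied by exclusions"
        )

    if config.replication_mode:
        model = PAPER_FIXED_MODEL
    else:
        model = fit_palpha_beta(included)
        if model.separation:
            run_warnings.append("logistic discriminant: separation flagged")

    scores = np.array([palpha_beta(model, s.alpha, s.beta) for s in included])
    labels = np.array([1 if s.group is Group.ALS else 0 for s in included])
    roc = roc_analysis(scores, labels)
    cutoff = REFERENCE_CUTOFF if config.replication_mode else roc.optimal_cutoff
    behavior = classify_behavior(scores, cutoff)

    palpha_df = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in included],
            "group": [s.group.value for s in included],
            "alpha": [s.alpha for s in included],
            "beta": [s.beta for s in included],
            "p_alpha_beta": scores,
            "behavior": behavior,
        }
    )

    comparison = logistic_model_comparison(included)
    fits_df = _fits_frame(excluded)
    summary = summarize_groups(
        fits_df[fits_df["subject_id"].isin(palpha_df["subject_id"])],
        variables=[
            "total_score",
            "acquisition_score",
            "reversal_score",
            "alpha",
            "beta",
        ],
    )

    result = PipelineResult(
        subjects=excluded,
        logistic_model=model,
        roc=roc,
        cutoff=cutoff,
        palpha=palpha_df,
        model_comparison=comparison,
        group_summary=summary,
        funnel=funnel,
        warnings=run_warnings,
    )
    if write:
        _write_outputs(result, config, fits_df, Path(out_dir or config.out_dir))
    return result


def _manifest_config(config: PipelineConfig) -> dict:
    # the output location is not part of the analysis configuration
    d = config.to_dict()
    d.pop("out_dir", None)
    return d


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(_manifest_config(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_outputs(
    result: PipelineResult,
    config: PipelineConfig,
    fits_df: pd.DataFrame,
    out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    fits_df.to_csv(out_dir / "fits.csv", index=False, float_format=fmt)
    exclusions = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in result.subjects],
            "group": [s.group.value for s in result.subjects],
            "included": [s.included for s in result.subjects],
            "exclusion_reason": [s.exclusion_reason.value for s in result.subjects],
        }
    )
    exclusions.to_csv(out_dir / "exclusions.csv", index=False)
    result.palpha.to_csv(out_dir / "palpha_beta.csv", index=False, float_format=fmt)
    roc_df = pd.DataFrame(
        {
            "threshold": result.roc.thresholds,
            "sensitivity": result.roc.sensitivity,
            "specificity": result.roc.specificity,
        }
    )
    roc_df.to_csv(out_dir / "roc_points.csv", index=False, float_format=fmt)

    m = result.logistic_model
    report = {
        "logistic_model": {
            "intercept": m.intercept,
            "coef_alpha": m.coef_alpha,
            "coef_beta": m.coef_beta,
            "source": m.source,
            "separation": m.separation,
            "printed_form": m.printed_form(),
        },
        "roc": {
            "auc": result.roc.auc,
            "optimal_cutoff": result.roc.optimal_cutoff,
            "sensitivity_at_cutoff": result.roc.sensitivity_at_cutoff,
            "specificity_at_cutoff": result.roc.specificity_at_cutoff,
        },
        "cutoff_used": result.cutoff,
        "funnel": result.funnel,
        "n_anomalous_als": result.n_anomalous_als,
        "model_comparison": json.loads(
            result.model_comparison.reset_index().to_json(orient="records")
        ),
        "group_summary": json.loads(
            result.group_summary.reset_index().to_json(orient="records")
        ),
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    manifest = {
        "package_version": __version__,
        "config": _manifest_config(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stage_counts": result.funnel,
        "warnings": result.warnings,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
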