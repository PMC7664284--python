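"""Cohort-level analysis: selection funnel, Pαβ discriminant, ROC, summaries.

The analysis mirrors a case-control behavioural study design:

1. **Score filter** — subjects whose phase reward counts fall more than
   1.5 SD below the control mean are excluded (acquisition filter on both
   groups; reversal filter on controls only, by default).
2. **Strategy filter** — only subjects whose AIC-best model is Q-learning
   are retained; WSLS and random choosers are a different strategy class.
3. **β-outlier filter** — controls with fitted inverse temperature more
   than 3 SD above the control mean are excluded.

On the retained subjects a logistic regression of group (case = 1) on the
fitted (α, β) yields the discriminant score Pαβ — the probability that a
subject's parameter pattern is case-like — followed by ROC analysis with a
Youden-J optimal cutoff and anomalous/typical classification.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .fitting import FitResult, Model, StrategyLabel
from .task import ChoiceSequence

__all__ = [
    "Group",
    "ExclusionReason",
    "ExclusionConfig",
    "SubjectRecord",
    "LogisticModel",
    "PAPER_FIXED_MODEL",
    "REFERENCE_CUTOFF",
    "ROCResult",
    "apply_exclusions",
    "fit_palpha_beta",
    "palpha_beta",
    "roc_analysis",
    "classify_behavior",
    "logistic_model_comparison",
    "summarize_groups",
]


class Group(str, Enum):
    ALS = "ALS"
    CONTROL = "control"


class ExclusionReason(str, Enum):
    NONE = "none"
    LOW_ACQUISITION = "low_acquisition"
    LOW_REVERSAL = "low_reversal"
    NON_Q_STRATEGY = "non_q_strategy"
    BETA_OUTLIER = "beta_outlier"


@dataclass(frozen=True)
class ExclusionConfig:
    """Selection-funnel thresholds and their group scope.

    SD multipliers follow the standard design (1.5 SD below the control mean
    for scores, 3 SD above for β).  Scope flags control which groups each
    filter touches; the defaults apply the acquisition filter to everyone,
    and the reversal and β filters to controls only.
    """

    score_sd: float = 1.5
    beta_sd: float = 3.0
    acquisition_filter_both_groups: bool = True
    reversal_filter_both_groups: bool = False
    beta_filter_both_groups: bool = False


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's data and derived results as they flow through the funnel."""

    subject_id: str
    group: Group
    sequence: Optional[ChoiceSequence] = None
    acquisition_score: Optional[int] = None
    reversal_score: Optional[int] = None
    total_score: Optional[int] = None
    strategy: Optional[StrategyLabel] = None
    included: bool = True
    exclusion_reason: ExclusionReason = ExclusionReason.NONE

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group(self.group))

    @property
    def q_fit(self) -> Optional[FitResult]:
        if self.strategy is None:
            return None
        return self.strategy.fits.get(Model.QLEARNING)

    @property
    def alpha(self) -> Optional[float]:
        fit = self.q_fit
        return None if fit is None else fit.params.alpha

    @property
    def beta(self) -> Optional[float]:
        fit = self.q_fit
        return None if fit is None else fit.params.beta


def _score_threshold(values: Sequence[float], sd_mult: float) -> float:
    arr = np.asarray(values, dtype=float)
    return float(arr.mean() - sd_mult * arr.std(ddof=1))


def apply_exclusions(
    subjects: Sequence[SubjectRecord], rules: ExclusionConfig = ExclusionConfig()
) -> list[SubjectRecord]:
    """Run the three-stage selection funnel; flags are set, nobody is deleted.

    Stage thresholds are computed from **all** control subjects prior to any
    exclusion (score stage) or from the controls surviving the earlier
    stages (β stage).  Each excluded subject carries the first-triggered
    reason only.  Strict inequality throughout: a subject exactly at a
    threshold is retained.
    """
    controls = [s for s in subjects if s.group is Group.CONTROL]
    if len(controls) < 2:
        raise ValueError("need at least 2 control subjects to form exclusion thresholds")

    acq_thr = _score_threshold([s.acquisition_score for s in controls], rules.score_sd)
    rev_thr = _score_threshold([s.reversal_score for s in controls], rules.score_sd)

    out: list[SubjectRecord] = []
    for s in subjects:
        reason = ExclusionReason.NONE
        is_control = s.group is Group.CONTROL
        if (rules.acquisition_filter_both_groups or is_control) and (
            s.acquisition_score < acq_thr
        ):
            reason = ExclusionReason.LOW_ACQUISITION
        elif (rules.reversal_filter_both_groups or is_control) and (
            s.reversal_score < rev_thr
        ):
            reason = ExclusionReason.LOW_REVERSAL
        elif s.strategy is not None and s.strategy.best_model is not Model.QLEARNING:
            reason = ExclusionReason.NON_Q_STRATEGY
        out.append(
            replace(s, included=reason is ExclusionReason.NONE, exclusion_reason=reason)
        )

    # β-outlier stage: threshold from controls still standing after the
    # score and strategy stages
    surviving_control_betas = [
        s.beta for s in out if s.included and s.group is Group.CONTROL and s.beta is not None
    ]
    if len(surviving_control_betas) >= 2:
        betas = np.asarray(surviving_control_betas)
        beta_thr = float(betas.mean() + rules.beta_sd * betas.std(ddof=1))
        for i, s in enumerate(out):
            if not s.included or s.beta is None:
                continue
            if (rules.beta_filter_both_groups or s.group is Group.CONTROL) and (
                s.beta > beta_thr
            ):
                out[i] = replace(
                    s, included=False, exclusion_reason=ExclusionReason.BETA_OUTLIER
                )
    return out


@dataclass(frozen=True)
class LogisticModel:
    """Two-predictor logistic discriminant, stored in standard orientation.

    Pαβ = 1 / (1 + exp(−(intercept + coef_alpha·α + coef_beta·β))) is the
    probability that a subject with Q-learning parameters (α, β) belongs to
    the case group (coded 1).
    """

    intercept: float
    coef_alpha: float
    coef_beta: float
    source: str = "fit"  # "fit" or "paper_fixed"
    fitted: bool = True
    se: Optional[tuple[float, float, float]] = None
    loglik: Optional[float] = None
    aic: Optional[float] = None
    separation: bool = False

    def printed_form(self) -> str:
        """Serialise as 1/(1+e^{a+bα+cβ}) with the exponent's signs flipped."""
        return (
            f"P_ab = 1 / (1 + exp({-self.intercept:+.3f} "
            f"{-self.coef_alpha:+.3f}*alpha {-self.coef_beta:+.3f}*beta))"
        )


#: The published discriminant: Pαβ = 1/(1 + e^{0.742 + 1.263α − 0.245β}).
PAPER_FIXED_MODEL = LogisticModel(
    intercept=-0.742,
    coef_alpha=-1.263,
    coef_beta=0.245,
    source="paper_fixed",
    fitted=True,
)

#: The published ROC-optimal Pαβ cutoff accompanying ``PAPER_FIXED_MODEL``.
REFERENCE_CUTOFF = 0.512


def palpha_beta(model: LogisticModel, alpha: float, beta: float) -> float:
    """Evaluate the discriminant probability Pαβ for parameters (α, β)."""
    if not model.fitted:
        raise ValueError("logistic model is not fitted")
    x = model.intercept + model.coef_alpha * np.asarray(alpha) + model.coef_beta * np.asarray(beta)
    x = np.clip(x, -700.0, 700.0)
    p = 1.0 / (1.0 + np.exp(-x))
    return float(p) if np.ndim(p) == 0 else p


def _logit_fit(X: np.ndarray, y: np.ndarray) -> tuple[sm.Logit, object, bool]:
    """Fit a logistic regression, flagging (quasi-)separation instead of
    silently returning diverged coefficients."""
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, Xc)
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception:  # PerfectSeparationError and numerical failures
            separation = True
            res = model.fit_regularized(alpha=1e-6, disp=0, maxiter=500)
        for w in caught:
            if "separation" in str(w.message).lower() or "convergence" in str(
                w.message
            ).lower():
                separation = True
    if np.abs(np.asarray(res.params)).max() > 1e3:
        separation = True
    return model, res, separation


def fit_palpha_beta(subjects: Sequence[SubjectRecord]) -> LogisticModel:
    """Fit the (α, β) → group logistic discriminant on included subjects."""
    rows = [
        (s.alpha, s.beta, 1.0 if s.group is Group.ALS else 0.0)
        for s in subjects
        if s.included and s.alpha is not None
    ]
    if not rows:
        raise ValueError("no included subjects with fitted parameters")
    arr = np.asarray(rows)
    X, y = arr[:, :2], arr[:, 2]
    if len(np.unique(y)) < 2:
        raise ValueError("both groups must be represented to fit the discriminant")
    _, res, separation = _logit_fit(X, y)
    params = np.asarray(res.params, dtype=float)
    try:
        se = tuple(float(v) for v in res.bse)
    except Exception:
        se = None
    return LogisticModel(
        intercept=params[0],
        coef_alpha=params[1],
        coef_beta=params[2],
        source="fit",
        fitted=True,
        se=se,
        loglik=float(res.llf),
        aic=float(res.aic),
        separation=separation,
    )


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve with trapezoid AUC and a Youden-optimal cutoff."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity_at_cutoff + self.specificity_at_cutoff - 1.0


def roc_analysis(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """Empirical ROC of a score against binary labels (positive = 1).

    A subject is called positive when its score strictly exceeds the
    threshold.  The curve runs over every distinct score value; AUC is the
    trapezoid integral over (FPR, TPR), which equals the pairwise
    concordance probability with ties counted ½.  The optimal cutoff
    maximises Youden's J = sensitivity + specificity − 1, lowest cutoff on
    ties.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC analysis needs both classes present")

    thresholds = np.unique(s)  # ascending
    # predicted positive iff score > threshold
    sens = np.array([np.mean(s[y == 1] > t) for t in thresholds])
    spec = np.array([np.mean(s[y == 0] <= t) for t in thresholds])

    # curve from (1,1) at threshold −inf down to (0,0) at the max score;
    # trapezoid over decreasing FPR, hence the sign flip
    fpr = np.concatenate(([1.0], 1.0 - spec))
    tpr = np.concatenate(([1.0], sens))
    auc = float(-np.trapezoid(tpr, fpr))

    j = sens + spec - 1.0
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])  # lowest cutoff on ties
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        optimal_cutoff=float(thresholds[best]),
        sensitivity_at_cutoff=float(sens[best]),
        specificity_at_cutoff=float(spec[best]),
    )


def classify_behavior(scores: Sequence[float], cutoff: float) -> list[str]:
    """Label each score ``anomalous`` iff it strictly exceeds the cutoff."""
    if not (0.0 < cutoff < 1.0):
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    return ["anomalous" if float(v) > cutoff else "typical" for v in np.asarray(scores, float)]


def logistic_model_comparison(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    """AIC table for the α-only, β-only and α+β logistic discriminants.

    AIC = −2·LL + 2·k with k counting the intercept plus slopes, so nested
    models are penalised consistently with the per-subject strategy AIC.
    """
    rows = [
        (s.alpha, s.beta, 1.0 if s.group is Group.ALS else 0.0)
        for s in subjects
        if s.included and s.alpha is not None
    ]
    arr = np.asarray(rows)
    if arr.size == 0 or len(np.unique(arr[:, 2])) < 2:
        raise ValueError("both groups must be represented")
    y = arr[:, 2]
    specs = {
        "alpha_only": arr[:, [0]],
        "beta_only": arr[:, [1]],
        "alpha_and_beta": arr[:, :2],
    }
    records = []
    for name, X in specs.items():
        _, res, separation = _logit_fit(X, y)
        k = X.shape[1] + 1
        ll = float(res.llf)
        records.append(
            {
                "model": name,
                "k": k,
                "loglik": ll,
                "aic": -2.0 * ll + 2.0 * k,
                "separation": separation,
            }
        )
    table = pd.DataFrame.from_records(records).set_index("model")
    table["best"] = table["aic"] == table["aic"].min()
    return table


def summarize_groups(
    data: pd.DataFrame,
    variables: Sequence[str],
    group_col: str = "group",
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-variable group means (SD) with two-sample tests.

    Numeric variables are compared with the two-sided Mann-Whitney U test,
    categorical ones with the chi-squared test of independence.  P-values
    are reported unadjusted.
    """
    groups = sorted(data[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    g0, g1 = groups
    d0, d1 = data[data[group_col] == g0], data[data[group_col] == g1]
    if len(d0) == 0 or len(d1) == 0:
        raise ValueError("both groups must be non-empty")

    rows = []
    for var in variables:
        if var in categorical:
            table = pd.crosstab(data[group_col], data[var])
            stat, p, _, _ = stats.chi2_contingency(table)
            rows.append(
                {
                    "variable": var,
                    f"{g0}_summary": "/".join(str(v) for v in table.loc[g0]),
                    f"{g1}_summary": "/".join(str(v) for v in table.loc[g1]),
                    "test": "chi2",
                    "statistic": float(stat),
                    "p_value": float(p),
                }
            )
        else:
            x0 = d0[var].dropna().astype(float)
            x1 = d1[var].dropna().astype(float)
            stat, p = stats.mannwhitneyu(x0, x1, alternative="two-sided")
            rows.append(
                {
                    "variable": var,
                    f"{g0}_summary": f"{x0.mean():.2f} ({x0.std(ddof=1):.2f})",
                    f"{g1}_summary": f"{x1.mean():.2f} ({x1.std(ddof=1):.2f})",
                    "test": "mannwhitney",
                    "statistic": float(stat),
                    "p_value": float(p),
                }
            )
    out = pd.DataFrame.from_records(rows).set_index("variable")
    out["significant"] = out["p_value"] < 0.05
    return out
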