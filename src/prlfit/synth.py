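"""Synthetic two-group cohorts with known ground truth.

No per-subject behavioural data are publicly deposited for this paradigm,
so testing the pipeline end to end requires cohorts that emulate the
*distributional* structure a real case-control PRL study reports: group
means and SDs of the Q-learning parameters, a minority of WSLS and random
strategists, and occasional missed trials.  Each subject is an agent from
:mod:`prlfit.agents` run through a fresh outcome schedule; the generating
model and parameters are returned alongside the choice data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .agents import QParams, WSLSParams, simulate_q_agent, simulate_random_agent, simulate_wsls_agent
from .cohort import LogisticModel, palpha_beta
from .task import ChoiceSequence, TaskConfig, make_outcome_schedule

__all__ = [
    "ParamDist",
    "CohortSpec",
    "sample_truncated_normal",
    "sample_cohort",
    "sequences_to_frame",
    "frame_to_sequences",
    "sample_parameter_cohort",
    "make_worked_fixture",
]

ALPHA_BOUNDS = (0.0, 1.0)
# β floor 0.1 keeps Q-subjects from being pure-noise choosers that would be
# labelled random by construction; 50 matches the fitting bound
BETA_BOUNDS = (0.1, 50.0)


@dataclass(frozen=True)
class ParamDist:
    """Mean/SD of a truncated-normal parameter distribution."""

    mean: float
    sd: float


@dataclass(frozen=True)
class CohortSpec:
    """Generating distributions for a two-group synthetic cohort.

    Defaults reproduce the reported group-level moments of a case-control
    PRL study: controls with moderate learning rates and low-to-moderate
    inverse temperatures, cases (labelled ``ALS``) with slightly lower α
    and a markedly higher, heavy-tailed β.  ``strategy_mix`` is the
    (Q-learning, WSLS, random) proportion per group; about 61% of screened
    subjects are Q-strategists, the remainder split evenly.
    """

    n_control: int = 63
    n_als: int = 62
    control_alpha: ParamDist = ParamDist(0.4, 0.3)
    control_beta: ParamDist = ParamDist(4.0, 1.7)
    als_alpha: ParamDist = ParamDist(0.3, 0.3)
    als_beta: ParamDist = ParamDist(7.0, 7.1)
    strategy_mix: tuple[float, float, float] = (0.62, 0.19, 0.19)
    wsls_param_range: tuple[float, float] = (0.55, 0.95)
    miss_probability: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.strategy_mix) - 1.0) > 1e-9:
            raise ValueError(f"strategy_mix must sum to 1, got {self.strategy_mix}")
        if any(p < 0 for p in self.strategy_mix):
            raise ValueError("strategy_mix proportions must be non-negative")
        for name, dist, (lo, hi) in (
            ("control_alpha", self.control_alpha, ALPHA_BOUNDS),
            ("als_alpha", self.als_alpha, ALPHA_BOUNDS),
            ("control_beta", self.control_beta, BETA_BOUNDS),
            ("als_beta", self.als_beta, BETA_BOUNDS),
        ):
            if dist.sd <= 0:
                raise ValueError(f"{name}: sd must be positive")
            if not (lo - 5 * dist.sd < dist.mean < hi + 5 * dist.sd):
                raise ValueError(f"{name}: mean {dist.mean} infeasibly far outside [{lo}, {hi}]")


def sample_truncated_normal(
    dist: ParamDist, bounds: tuple[float, float], size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw from Normal(mean, sd) truncated to ``bounds``."""
    lo, hi = bounds
    a, b = (lo - dist.mean) / dist.sd, (hi - dist.mean) / dist.sd
    return truncnorm.rvs(a, b, loc=dist.mean, scale=dist.sd, size=size, random_state=rng)


def sequences_to_frame(
    sequences: dict[str, tuple[str, ChoiceSequence]]
) -> pd.DataFrame:
    """Flatten ``{subject_id: (group, sequence)}`` into tidy trial rows.

    Missed trials carry NA in both ``chosen`` and ``outcome``.
    """
    rows = []
    for subject_id, (group, seq) in sequences.items():
        for rec in seq:
            rows.append(
                {
                    "subject_id": subject_id,
                    "group": group,
                    "trial": rec.trial,
                    "chosen": rec.chosen if rec.chosen is not None else pd.NA,
                    "outcome": rec.outcome if rec.outcome is not None else pd.NA,
                    "advantageous": rec.advantageous,
                }
            )
    df = pd.DataFrame.from_records(rows)
    df["chosen"] = df["chosen"].astype("Int64")
    df["outcome"] = df["outcome"].astype("Int64")
    return df


def frame_to_sequences(df: pd.DataFrame) -> dict[str, tuple[str, ChoiceSequence]]:
    """Inverse of :func:`sequences_to_frame` (no validation; see prlfit.io)."""
    from .task import TrialRecord

    out: dict[str, tuple[str, ChoiceSequence]] = {}
    for subject_id, sub in df.groupby("subject_id", sort=False):
        sub = sub.sort_values("trial")
        records = tuple(
            TrialRecord(
                trial=int(r.trial),
                chosen=None if pd.isna(r.chosen) else int(r.chosen),
                outcome=None if pd.isna(r.outcome) else int(r.outcome),
                advantageous=int(r.advantageous),
            )
            for r in sub.itertuples()
        )
        out[str(subject_id)] = (str(sub["group"].iloc[0]), ChoiceSequence(records))
    return out


def sample_cohort(
    spec: CohortSpec = CohortSpec(), task: TaskConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic cohort.

    Returns ``(choices, ground_truth)``: tidy trial rows for every subject
    and one ground-truth row per subject (generating model, parameters,
    per-subject seed).  All randomness descends from ``spec.seed`` through
    per-subject spawned seeds, so regeneration is byte-stable and
    individual subjects can be re-simulated in isolation.
    """
    base_task = task or TaskConfig()
    task_cfg = TaskConfig(
        n_trials=base_task.n_trials,
        reversal_trial=base_task.reversal_trial,
        p_reward_advantageous=base_task.p_reward_advantageous,
        p_reward_disadvantageous=base_task.p_reward_disadvantageous,
        schedule_mode=base_task.schedule_mode,
        miss_probability=spec.miss_probability,
    )
    root = np.random.SeedSequence(spec.seed)
    param_rng = np.random.default_rng(root.spawn(1)[0])

    plan = [("control", spec.n_control, spec.control_alpha, spec.control_beta), (
        "ALS", spec.n_als, spec.als_alpha, spec.als_beta)]
    n_total = spec.n_control + spec.n_als
    subject_seeds = root.spawn(n_total + 1)[1:]

    sequences: dict[str, tuple[str, ChoiceSequence]] = {}
    truth_rows = []
    idx = 0
    for group, n, alpha_dist, beta_dist in plan:
        models = param_rng.choice(
            ["qlearning", "wsls", "random"], size=n, p=list(spec.strategy_mix)
        )
        alphas = sample_truncated_normal(alpha_dist, ALPHA_BOUNDS, n, param_rng)
        betas = sample_truncated_normal(beta_dist, BETA_BOUNDS, n, param_rng)
        lo, hi = spec.wsls_param_range
        stays = param_rng.uniform(lo, hi, size=n)
        shifts = param_rng.uniform(lo, hi, size=n)
        for j in range(n):
            subject_id = f"{'C' if group == 'control' else 'A'}{j + 1:03d}"
            ss = subject_seeds[idx]
            sim_rng = np.random.default_rng(ss)
            schedule = make_outcome_schedule(task_cfg, sim_rng)
            model = str(models[j])
            row = {
                "subject_id": subject_id,
                "group": group,
                "model": model,
                "alpha": np.nan,
                "beta": np.nan,
                "p_stay_win": np.nan,
                "p_shift_lose": np.nan,
                "seed": int(ss.generate_state(1)[0]),
            }
            if model == "qlearning":
                params = QParams(alpha=float(alphas[j]), beta=float(betas[j]))
                seq = simulate_q_agent(params, schedule, task_cfg, sim_rng)
                row.update(alpha=params.alpha, beta=params.beta)
            elif model == "wsls":
                params = WSLSParams(
                    p_stay_win=float(stays[j]), p_shift_lose=float(shifts[j])
                )
                seq = simulate_wsls_agent(params, schedule, task_cfg, sim_rng)
                row.update(p_stay_win=params.p_stay_win, p_shift_lose=params.p_shift_lose)
            else:
                seq = simulate_random_agent(task_cfg, schedule, sim_rng)
            sequences[subject_id] = (group, seq)
            truth_rows.append(row)
            idx += 1
    return sequences_to_frame(sequences), pd.DataFrame.from_records(truth_rows)


def sample_parameter_cohort(
    model: LogisticModel,
    n: int,
    rng: np.random.Generator,
    alpha_range: tuple[float, float] = (0.0, 1.0),
    beta_range: tuple[float, float] = (0.0, 20.0),
) -> pd.DataFrame:
    """Draw (α, β) pairs and label each case/control from the discriminant.

    Group membership is Bernoulli with probability Pαβ under ``model``:
    the generating process matches the logistic likelihood exactly, which
    makes this the reference construction for coefficient-recovery checks.
    """
    alphas = rng.uniform(*alpha_range, size=n)
    betas = rng.uniform(*beta_range, size=n)
    p = palpha_beta(model, alphas, betas)
    labels = (rng.random(n) < p).astype(int)
    return pd.DataFrame({"alpha": alphas, "beta": betas, "is_case": labels})


# Worked fixture: six hand-picked subjects covering the pipeline's branches.
_FIXTURE_SEED = 20201025
_FIXTURE_SUBJECTS = (
    # (subject_id, group, model, params)
    ("C001", "control", "qlearning", QParams(alpha=0.45, beta=4.0)),
    ("C002", "control", "qlearning", QParams(alpha=0.2, beta=1.2)),
    ("A001", "ALS", "qlearning", QParams(alpha=0.15, beta=12.0)),
    ("A002", "ALS", "qlearning", QParams(alpha=0.20, beta=9.0)),
    ("C003", "control", "wsls", WSLSParams(p_stay_win=0.92, p_shift_lose=0.9)),
    ("A003", "ALS", "random", None),
)


def make_worked_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """A frozen six-subject miniature cohort for worked examples and goldens.

    Two typical Q-controls, two high-β/low-α Q-cases, one WSLS subject and
    one random subject, all simulated miss-free under pinned seeds; the
    same call always returns byte-identical frames.
    """
    task_cfg = TaskConfig()
    root = np.random.SeedSequence(_FIXTURE_SEED)
    seeds = root.spawn(len(_FIXTURE_SUBJECTS))
    sequences: dict[str, tuple[str, ChoiceSequence]] = {}
    truth_rows = []
    for (subject_id, group, model, params), ss in zip(_FIXTURE_SUBJECTS, seeds):
        rng = np.random.default_rng(ss)
        schedule = make_outcome_schedule(task_cfg, rng)
        if model == "qlearning":
            seq = simulate_q_agent(params, schedule, task_cfg, rng)
        elif model == "wsls":
            seq = simulate_wsls_agent(params, schedule, task_cfg, rng)
        else:
            seq = simulate_random_agent(task_cfg, schedule, rng)
        sequences[subject_id] = (group, seq)
        truth_rows.append(
            {
                "subject_id": subject_id,
                "group": group,
                "model": model,
                "alpha": getattr(params, "alpha", np.nan),
                "beta": getattr(params, "beta", np.nan),
                "p_stay_win": getattr(params, "p_stay_win", np.nan),
                "p_shift_lose": getattr(params, "p_shift_lose", np.nan),
                "seed": int(ss.generate_state(1)[0]),
            }
        )
    return sequences_to_frame(sequences), pd.DataFrame.from_records(truth_rows)
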