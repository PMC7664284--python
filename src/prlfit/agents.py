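"""Generative agents for the PRL task.

Three candidate strategies produce choice sequences: a Q-learning agent
(delta-rule value updates, softmax choice), a win-stay/lose-shift (WSLS)
heuristic conditioned only on the previous outcome, and a purely random
chooser.  These are the generative counterparts of the likelihoods in
:mod:`prlfit.fitting` and power the synthetic cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .task import ChoiceSequence, OutcomeSchedule, TaskConfig, TrialRecord, advantageous_stimulus

__all__ = [
    "QParams",
    "QState",
    "WSLSParams",
    "q_update",
    "q_choice_prob",
    "simulate_q_agent",
    "simulate_wsls_agent",
    "simulate_random_agent",
]

# exponent clamp for the softmax; |x| = 700 is still exp-representable in
# float64 and the probability is already 0/1 to machine precision there
_EXP_CLAMP = 700.0


@dataclass(frozen=True)
class QParams:
    """Q-learning parameters: learning rate α ∈ [0,1], inverse temperature β ≥ 0.

    ``q_init`` is the initial action value given to both stimuli; 0.5 is the
    neutral midpoint of the {0, 1} reward coding.
    """

    alpha: float
    beta: float
    q_init: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")


@dataclass(frozen=True)
class QState:
    """Current action-value estimates (Q1, Q2)."""

    q_values: tuple[float, float]


@dataclass(frozen=True)
class WSLSParams:
    """Win-stay/lose-shift parameters: P(stay | win) and P(shift | lose)."""

    p_stay_win: float
    p_shift_lose: float

    def __post_init__(self) -> None:
        for name in ("p_stay_win", "p_shift_lose"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")


def q_update(state: QState, chosen: int, reward: float, alpha: float) -> QState:
    """Delta-rule update of the chosen stimulus's value: Q ← Q + α(R − Q)."""
    q1, q2 = state.q_values
    if chosen == 1:
        q1 = q1 + alpha * (reward - q1)
    elif chosen == 2:
        q2 = q2 + alpha * (reward - q2)
    else:
        raise ValueError(f"chosen must be 1 or 2, got {chosen}")
    return QState((q1, q2))


def q_choice_prob(state: QState, beta: float) -> float:
    """Softmax probability of choosing stimulus 1: 1 / (1 + e^{−β(Q1−Q2)})."""
    q1, q2 = state.q_values
    x = beta * (q1 - q2)
    x = max(-_EXP_CLAMP, min(_EXP_CLAMP, x))
    return 1.0 / (1.0 + math.exp(-x))


def _make_record(trial: int, chosen: int | None, outcome: int | None, config: TaskConfig) -> TrialRecord:
    return TrialRecord(
        trial=trial,
        chosen=chosen,
        outcome=outcome,
        advantageous=advantageous_stimulus(trial, config),
    )


def simulate_q_agent(
    params: QParams,
    schedule: OutcomeSchedule,
    config: TaskConfig,
    seed: int | np.random.Generator | None = None,
) -> ChoiceSequence:
    """Run a Q-learning agent through the task.

    Each trial the agent chooses via the softmax, reads the pre-drawn outcome
    for its choice, and updates the chosen value.  With probability
    ``config.miss_probability`` a trial is missed: no choice is made and no
    update occurs.
    """
    rng = np.random.default_rng(seed)
    state = QState((params.q_init, params.q_init))
    records = []
    for t in range(1, config.n_trials + 1):
        if config.miss_probability > 0 and rng.random() < config.miss_probability:
            records.append(_make_record(t, None, None, config))
            continue
        p1 = q_choice_prob(state, params.beta)
        chosen = 1 if rng.random() < p1 else 2
        outcome = schedule.outcome(t, chosen)
        records.append(_make_record(t, chosen, outcome, config))
        state = q_update(state, chosen, outcome, params.alpha)
    return ChoiceSequence(tuple(records))


def simulate_wsls_agent(
    params: WSLSParams,
    schedule: OutcomeSchedule,
    config: TaskConfig,
    seed: int | np.random.Generator | None = None,
) -> ChoiceSequence:
    """Run a WSLS agent: stay after wins with P(stay|win), shift after losses
    with P(shift|lose); a trial with no valid predecessor is chosen uniformly."""
    rng = np.random.default_rng(seed)
    prev: tuple[int, int] | None = None  # (chosen, outcome) of the previous valid trial
    records = []
    for t in range(1, config.n_trials + 1):
        if config.miss_probability > 0 and rng.random() < config.miss_probability:
            records.append(_make_record(t, None, None, config))
            prev = None  # a miss erases the one-trial memory
            continue
        if prev is None:
            chosen = int(rng.integers(1, 3))
        else:
            last_choice, last_outcome = prev
            if last_outcome == 1:
                stay = rng.random() < params.p_stay_win
            else:
                stay = not (rng.random() < params.p_shift_lose)
            chosen = last_choice if stay else 3 - last_choice
        outcome = schedule.outcome(t, chosen)
        records.append(_make_record(t, chosen, outcome, config))
        prev = (chosen, outcome)
    return ChoiceSequence(tuple(records))


def simulate_random_agent(
    config: TaskConfig,
    schedule: OutcomeSchedule,
    seed: int | np.random.Generator | None = None,
) -> ChoiceSequence:
    """Run an agent choosing uniformly at random on every valid trial."""
    rng = np.random.default_rng(seed)
    records = []
    for t in range(1, config.n_trials + 1):
        if config.miss_probability > 0 and rng.random() < config.miss_probability:
            records.append(_make_record(t, None, None, config))
            continue
        chosen = int(rng.integers(1, 3))
        outcome = schedule.outcome(t, chosen)
        records.append(_make_record(t, chosen, outcome, config))
    return ChoiceSequence(tuple(records))
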