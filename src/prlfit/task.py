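"""Probabilistic reversal learning (PRL) task structure and phase scoring.

The task is a two-alternative bandit: on each of ``n_trials`` trials the
subject picks one of two stimuli and receives a binary reward.  One stimulus
is *advantageous* (high reward probability, default 0.8) and the other
*disadvantageous* (default 0.2); after ``reversal_trial`` trials the roles
swap with no signal to the subject.  Trials before and including the swap
form the *acquisition phase*, the remainder the *reversal phase*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "ScheduleMode",
    "TaskConfig",
    "OutcomeSchedule",
    "TrialRecord",
    "ChoiceSequence",
    "make_outcome_schedule",
    "advantageous_stimulus",
    "phase_scores",
]


class ScheduleMode(str, Enum):
    """How per-trial reward indicators are generated.

    ``EXACT_RATIO`` pre-draws each phase so every stimulus receives exactly
    ``round(p * phase_length)`` rewards in a random order (a fixed-ratio
    schedule); ``BERNOULLI`` draws every trial independently.
    """

    EXACT_RATIO = "exact_ratio"
    BERNOULLI = "bernoulli"


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the PRL task.

    Defaults give the canonical 120-trial task with an 80:20 reward
    contingency reversing after trial 60.  The two stimuli's reward
    probabilities are independent and need not sum to 1.
    """

    n_trials: int = 120
    reversal_trial: int = 60
    p_reward_advantageous: float = 0.8
    p_reward_disadvantageous: float = 0.2
    schedule_mode: ScheduleMode = ScheduleMode.EXACT_RATIO
    miss_probability: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.reversal_trial < self.n_trials):
            raise ValueError(
                f"reversal_trial must satisfy 0 < reversal_trial < n_trials, "
                f"got {self.reversal_trial} with n_trials={self.n_trials}"
            )
        for name in ("p_reward_advantageous", "p_reward_disadvantageous", "miss_probability"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        # accept plain strings for the mode (YAML round-trip convenience)
        object.__setattr__(self, "schedule_mode", ScheduleMode(self.schedule_mode))

    @property
    def acquisition_trials(self) -> range:
        """1-based trial indices of the acquisition phase."""
        return range(1, self.reversal_trial + 1)

    @property
    def reversal_trials(self) -> range:
        """1-based trial indices of the reversal phase."""
        return range(self.reversal_trial + 1, self.n_trials + 1)


def advantageous_stimulus(trial: int, config: TaskConfig) -> int:
    """Return which stimulus (1 or 2) is advantageous on a 1-based trial."""
    if not (1 <= trial <= config.n_trials):
        raise IndexError(f"trial {trial} outside 1..{config.n_trials}")
    return 1 if trial <= config.reversal_trial else 2


@dataclass(frozen=True)
class OutcomeSchedule:
    """Pre-drawn reward indicators, shape (n_trials, 2).

    ``rewards[t-1, s-1] == 1`` means stimulus ``s`` yields a reward if chosen
    on trial ``t``.  The schedule encodes no reversal signal beyond the
    change in reward rates.
    """

    rewards: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rewards, dtype=np.int8)
        if r.ndim != 2 or r.shape[1] != 2:
            raise ValueError(f"schedule must have shape (n_trials, 2), got {r.shape}")
        if not np.isin(r, (0, 1)).all():
            raise ValueError("reward indicators must be 0 or 1")
        r.setflags(write=False)
        object.__setattr__(self, "rewards", r)

    @property
    def n_trials(self) -> int:
        return self.rewards.shape[0]

    def outcome(self, trial: int, stimulus: int) -> int:
        """Reward (1) or loss (0) for choosing ``stimulus`` on 1-based ``trial``."""
        return int(self.rewards[trial - 1, stimulus - 1])


def _phase_reward_counts(p: float, phase_length: int) -> int:
    expected = p * phase_length
    count = round(expected)
    if abs(expected - count) > 1e-9:
        raise ValueError(
            f"exact_ratio schedule needs an integer reward count per phase; "
            f"p={p} over {phase_length} trials gives {expected}"
        )
    return count


def make_outcome_schedule(
    config: TaskConfig, seed: int | np.random.Generator | None = None
) -> OutcomeSchedule:
    """Draw the per-trial reward indicators for both stimuli.

    In ``exact_ratio`` mode each (phase, stimulus) cell carries exactly
    ``round(p * phase_length)`` rewards, placed by a seeded permutation; in
    ``bernoulli`` mode each cell is an independent draw.  The same seed
    always yields the same schedule.
    """
    rng = np.random.default_rng(seed)
    n, rev = config.n_trials, config.reversal_trial
    rewards = np.zeros((n, 2), dtype=np.int8)
    phases = [(slice(0, rev), 1), (slice(rev, n), 2)]  # (trial slice, advantageous stimulus)
    for phase_slice, adv in phases:
        phase_len = phase_slice.stop - phase_slice.start
        for stim in (1, 2):
            p = (
                config.p_reward_advantageous
                if stim == adv
                else config.p_reward_disadvantageous
            )
            if config.schedule_mode is ScheduleMode.EXACT_RATIO:
                k = _phase_reward_counts(p, phase_len)
                cell = np.zeros(phase_len, dtype=np.int8)
                cell[:k] = 1
                rng.shuffle(cell)
            else:
                cell = (rng.random(phase_len) < p).astype(np.int8)
            rewards[phase_slice, stim - 1] = cell
    return OutcomeSchedule(rewards)


@dataclass(frozen=True)
class TrialRecord:
    """One trial's observed choice and outcome.

    ``chosen`` is the stimulus id (1 or 2) or ``None`` for a missed
    ("Time-up") trial; ``outcome`` is the binary reward R(t) and is ``None``
    exactly when the trial was missed.
    """

    trial: int
    chosen: Optional[int]
    outcome: Optional[int]
    advantageous: int

    def __post_init__(self) -> None:
        if (self.chosen is None) != (self.outcome is None):
            raise ValueError(
                f"trial {self.trial}: outcome must be absent iff the trial was missed"
            )
        if self.chosen is not None and self.chosen not in (1, 2):
            raise ValueError(f"trial {self.trial}: chosen must be 1 or 2, got {self.chosen}")
        if self.outcome is not None and self.outcome not in (0, 1):
            raise ValueError(f"trial {self.trial}: outcome must be 0 or 1, got {self.outcome}")
        if self.advantageous not in (1, 2):
            raise ValueError(f"trial {self.trial}: advantageous must be 1 or 2")

    @property
    def missed(self) -> bool:
        return self.chosen is None


@dataclass(frozen=True)
class ChoiceSequence:
    """A subject's ordered trials, indices 1..n with no gaps."""

    records: tuple[TrialRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        for i, rec in enumerate(self.records, start=1):
            if rec.trial != i:
                raise ValueError(
                    f"trial indices must be contiguous from 1; position {i} holds trial {rec.trial}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TrialRecord]:
        return iter(self.records)

    def __getitem__(self, idx: int) -> TrialRecord:
        return self.records[idx]

    @property
    def n_valid_trials(self) -> int:
        return sum(not r.missed for r in self.records)

    def valid_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Chosen stimuli and outcomes of non-missed trials, in trial order."""
        chosen = np.array([r.chosen for r in self.records if not r.missed], dtype=np.int64)
        outcome = np.array([r.outcome for r in self.records if not r.missed], dtype=np.float64)
        return chosen, outcome


def phase_scores(seq: ChoiceSequence, config: TaskConfig) -> tuple[int, int, int]:
    """Count rewards received in the acquisition phase, reversal phase, and overall.

    Missed trials contribute nothing.  Reward counts are the task's "score";
    the acquisition score under the default task maxes out at 60.
    """
    acq = sum(
        1 for r in seq if not r.missed and r.outcome == 1 and r.trial <= config.reversal_trial
    )
    rev = sum(
        1 for r in seq if not r.missed and r.outcome == 1 and r.trial > config.reversal_trial
    )
    return acq, rev, acq + rev
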