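"""Reading and writing the tidy choice-data CSV dialect.

One row per trial: ``subject_id, group, trial, chosen, outcome,
advantageous``.  ``chosen``/``outcome`` are 1/2 and 1/0, with ``NA`` in
both columns encoding a missed ("Time-up") trial.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .cohort import Group, SubjectRecord
from .task import ChoiceSequence, TaskConfig, TrialRecord

__all__ = ["read_choices", "write_choices", "CSV_FLOAT_FORMAT"]

CSV_FLOAT_FORMAT = "%.10g"

_REQUIRED_COLUMNS = ("subject_id", "group", "trial", "chosen", "outcome", "advantageous")


def read_choices(path: str | Path, config: TaskConfig | None = None) -> list[SubjectRecord]:
    """Load and validate a choice CSV into per-subject records.

    Validates column presence, group labels, trial-index range and
    uniqueness, the NA pairing of ``chosen``/``outcome``, and (when a task
    config is given) the per-subject trial count.
    """
    df = pd.read_csv(path, dtype={"subject_id": str}, na_values=["NA"], keep_default_na=True)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    bad_groups = set(df["group"].unique()) - {g.value for g in Group}
    if bad_groups:
        raise ValueError(f"{path}: unknown group labels {sorted(bad_groups)}")

    dup = df.duplicated(subset=["subject_id", "trial"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate (subject, trial) pair ({row.subject_id}, {int(row.trial)})"
        )

    n_trials = config.n_trials if config is not None else None
    subjects: list[SubjectRecord] = []
    for subject_id, sub in df.groupby("subject_id", sort=False):
        sub = sub.sort_values("trial")
        if n_trials is not None:
            out_of_range = sub[(sub["trial"] < 1) | (sub["trial"] > n_trials)]
            if len(out_of_range):
                raise ValueError(
                    f"{path}: subject {subject_id} has trial "
                    f"{int(out_of_range['trial'].iloc[0])} outside 1..{n_trials}"
                )
            if len(sub) != n_trials:
                raise ValueError(
                    f"{path}: subject {subject_id} has {len(sub)} trials, expected {n_trials}"
                )
        records = []
        for r in sub.itertuples():
            chosen_na, outcome_na = pd.isna(r.chosen), pd.isna(r.outcome)
            if chosen_na != outcome_na:
                raise ValueError(
                    f"{path}: subject {subject_id} trial {int(r.trial)}: chosen and outcome "
                    f"must be NA together (missed trial) or both present"
                )
            records.append(
                TrialRecord(
                    trial=int(r.trial),
                    chosen=None if chosen_na else int(r.chosen),
                    outcome=None if outcome_na else int(r.outcome),
                    advantageous=int(r.advantageous),
                )
            )
        subjects.append(
            SubjectRecord(
                subject_id=str(subject_id),
                group=Group(sub["group"].iloc[0]),
                sequence=ChoiceSequence(tuple(records)),
            )
        )
    return subjects


def write_choices(df: pd.DataFrame, path: str | Path) -> None:
    """Write tidy choice rows with the canonical NA spelling."""
    df.to_csv(path, index=False, na_rep="NA")
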