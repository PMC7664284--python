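"""Pipeline configuration with lossless YAML round-trip.

Unknown keys are rejected rather than ignored so that config typos fail
loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import ExclusionConfig
from .fitting import FitOptions
from .task import TaskConfig

__all__ = ["PipelineConfig"]


def _from_mapping(cls, data: dict, context: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"{context}: unknown keys {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full pipeline run depends on, in one serialisable object.

    ``replication_mode`` scores subjects with the published discriminant
    coefficients and cutoff instead of refitting them on the cohort at hand.
    """

    task: TaskConfig = field(default_factory=TaskConfig)
    fit: FitOptions = field(default_factory=FitOptions)
    exclusion: ExclusionConfig = field(default_factory=ExclusionConfig)
    replication_mode: bool = False
    seed: int = 0
    out_dir: str = "prlfit_results"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"pipeline config: unknown keys {sorted(unknown)}")
        kwargs = dict(data)
        if "task" in kwargs:
            kwargs["task"] = _from_mapping(TaskConfig, kwargs["task"], "task config")
        if "fit" in kwargs:
            kwargs["fit"] = _from_mapping(FitOptions, kwargs["fit"], "fit options")
        if "exclusion" in kwargs:
            kwargs["exclusion"] = _from_mapping(
                ExclusionConfig, kwargs["exclusion"], "exclusion config"
            )
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["task"]["schedule_mode"] = self.task.schedule_mode.value
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
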