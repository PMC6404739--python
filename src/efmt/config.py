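"""Trial configuration: one dataclass tree, YAML round-trippable.

Defaults encode the study conditions of the pilot protocol this package
simulates: 51 enrollees, permuted blocks of six, 18 sessions over 6 weeks
(three per week), weekly clinician ratings at weeks 0..6, and the generator
anchors described in :mod:`efmt.participants`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .participants import CohortConfig
from .task_engine import AdaptivePolicy, BlockSpec

__all__ = ["TaskConfig", "LikertConfig", "TrialConfig"]


@dataclass
class TaskConfig:
    """Task-engine parameters shared by both arms (stimuli differ only)."""

    n_scored_items: int = 15
    target_rate: float = 1.0 / 3.0
    lure_rate: float = 0.2
    up_threshold: float = 0.85
    down_threshold: float = 0.60
    n_min: int = 1
    n_max: int = 15
    carryover_rule: str = "last"

    def block_spec(self, n_level: int = 1) -> BlockSpec:
        return BlockSpec(n_level=n_level, n_scored_items=self.n_scored_items,
                         target_rate=self.target_rate, lure_rate=self.lure_rate)

    def policy(self) -> AdaptivePolicy:
        return AdaptivePolicy(up_threshold=self.up_threshold,
                              down_threshold=self.down_threshold,
                              n_min=self.n_min, n_max=self.n_max,
                              carryover_rule=self.carryover_rule)


@dataclass
class LikertConfig:
    """Means/SDs of the 1-5 acceptability and helpfulness ratings, per arm.

    These exist to exercise the between-group t-test pathway, nothing more.
    """

    accept_baseline: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"EFMT": (3.79, 0.98), "CT": (3.81, 1.22)})
    accept_outcome: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"EFMT": (3.94, 1.24), "CT": (3.71, 0.91)})
    help_attention: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"EFMT": (2.75, 1.13), "CT": (3.14, 1.10)})
    help_thoughts: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"EFMT": (2.81, 1.17), "CT": (3.14, 1.41)})
    help_mood: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"EFMT": (2.69, 1.01), "CT": (2.86, 1.23)})
    help_memory: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"EFMT": (2.56, 1.21), "CT": (3.79, 1.05)})


@dataclass
class TrialConfig:
    n_participants: int = 51
    n_weeks: int = 6
    sessions_per_week: int = 3
    attendance_prob: float = 0.88
    residual_sd: float = 4.9
    residual_rho: float = 0.5
    dose_effect: float = -0.7
    wais_gain_mean: float = 1.0
    wais_gain_sd: float = 0.5
    simulate_sessions: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    task: TaskConfig = field(default_factory=TaskConfig)
    likert: LikertConfig = field(default_factory=LikertConfig)

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_weeks != 6:
            raise ValueError("the visit schedule covers weeks 0..6; n_weeks must be 6")
        if not (0.0 <= self.attendance_prob <= 1.0):
            raise ValueError("attendance_prob must lie in [0, 1]")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if not (-1.0 < self.residual_rho < 1.0):
            raise ValueError("residual_rho must lie in (-1, 1)")

    # -- YAML round-trip ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TrialConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig(**d["cohort"])
        if "task" in d and isinstance(d["task"], dict):
            d["task"] = TaskConfig(**d["task"])
        if "likert" in d and isinstance(d["likert"], dict):
            lk = {k: {a: tuple(v) for a, v in vv.items()} for k, vv in d["likert"].items()}
            d["likert"] = LikertConfig(**lk)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrialConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
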