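"""Simulated task performers (psychometric observers) for the N-back engine.

A responder's probability of a correct match/nonmatch judgment falls with the
memory load N along a logistic curve: ``capacity`` is the N at which accuracy
crosses 75% (midway between chance and lapse-free ceiling), ``slope`` sets how
fast it falls, ``lapse`` lowers the ceiling, and ``bias_negative`` adds
emotion-specific error on face stimuli only (zero for shapes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .task_engine import TrialItem

__all__ = ["ResponderModel", "perfect_responder", "chance_responder"]

_ACC_FLOOR = 0.05


@dataclass(frozen=True)
class ResponderModel:
    """Logistic-in-load observer; callable as a ``run_session`` responder."""

    capacity: float = 3.0
    slope: float = 1.0
    lapse: float = 0.0
    bias_negative: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if not (0.0 <= self.lapse < 0.5):
            raise ValueError("lapse must lie in [0, 0.5)")

    def accuracy(self, n_level: int, modality: str = "face") -> float:
        """P(correct) at load ``n_level``: 0.5 + (0.5 − lapse)·σ(−(n−κ)/s),
        minus the emotion penalty for faces; clipped to [0.05, 1]."""
        p = 0.5 + (0.5 - self.lapse) * expit(-(n_level - self.capacity) / self.slope)
        if modality == "face":
            p -= self.bias_negative
        return float(np.clip(p, _ACC_FLOOR, 1.0))

    def __call__(self, item: TrialItem, n_level: int, rng: np.random.Generator) -> str:
        correct = "match" if item.is_target else "nonmatch"
        wrong = "nonmatch" if item.is_target else "match"
        p = self.accuracy(n_level, item.stimulus.modality)
        return correct if rng.random() < p else wrong


def perfect_responder(item: TrialItem, n_level: int, rng: np.random.Generator) -> str:
    """Always-correct responder (staircase goes straight up)."""
    return "match" if item.is_target else "nonmatch"


def chance_responder() -> ResponderModel:
    """Coin-flip observer: accuracy 0.5 at every load."""
    return ResponderModel(capacity=-50.0, slope=1.0)
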