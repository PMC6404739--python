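"""Adaptive emotional-faces / shapes N-back task engine.

The training exercise is a continuous-performance N-back: stimuli (facial
expressions of emotion, or neutral geometric shapes in the control variant)
appear one at a time — 1 s of stimulus, 1 s of fixation cross — and for every
scored item the participant judges whether the current category label matches
the label N positions earlier.  Difficulty (the N level) moves up or down
between blocks according to block accuracy, so the task tracks each
participant's capacity.  A session is 15 blocks; the very first session starts
at N = 1 and later sessions start where the previous one left off.

Only stimulus *metadata* is handled here (category labels, identities); no
images are rendered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "FACE_LABELS",
    "SHAPE_LABELS",
    "Stimulus",
    "BlockSpec",
    "TrialItem",
    "BlockResult",
    "AdaptivePolicy",
    "SessionResult",
    "SequenceError",
    "ScoringError",
    "generate_block_sequence",
    "score_block",
    "update_difficulty",
    "run_session",
    "next_session_start",
]

#: Default emotion categories for the emotional-faces task variant.
FACE_LABELS: tuple[str, ...] = ("happy", "sad", "angry", "fearful", "surprised", "neutral")
#: Default shape categories for the working-memory control variant.
SHAPE_LABELS: tuple[str, ...] = ("circle", "square", "triangle", "star", "diamond", "hexagon")

#: Stimulus on-screen duration and fixation-cross duration, seconds.
STIM_DUR_S = 1.0
FIXATION_DUR_S = 1.0


class SequenceError(ValueError):
    """Raised when a block sequence cannot be generated from the given spec."""


class ScoringError(ValueError):
    """Raised when a block cannot be scored (e.g. missing responses)."""


@dataclass(frozen=True)
class Stimulus:
    """One presentable stimulus: a category label plus optional identity.

    ``actor_id`` distinguishes face identities so the same emotion can appear
    on different faces; it is cosmetic for shapes.
    """

    id: str
    modality: str  # "face" | "shape"
    label: str
    actor_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.modality not in ("face", "shape"):
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass(frozen=True)
class BlockSpec:
    """Design parameters of a single N-back block.

    ``n_scored_items`` scored judgments are collected; the first ``n_level``
    items only provide memory context and are unscored, so
    ``n_scored_items + n_level`` items are presented in total.
    """

    n_level: int
    n_scored_items: int = 15
    target_rate: float = 1.0 / 3.0
    lure_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.n_level < 1:
            raise ValueError("n_level must be >= 1")
        if self.n_scored_items <= 0:
            raise ValueError("n_scored_items must be > 0")
        if not (0.0 < self.target_rate < 1.0):
            raise ValueError("target_rate must lie in (0, 1) (use a single-label "
                             "category set to force an all-target block)")
        if not (0.0 <= self.lure_rate < 1.0):
            raise ValueError("lure_rate must lie in [0, 1)")
        if not (0.0 < self.target_rate + self.lure_rate < 1.0):
            raise ValueError("target_rate + lure_rate must lie in (0, 1)")

    @property
    def n_items(self) -> int:
        """Total items presented (scored + leading context)."""
        return self.n_scored_items + self.n_level

    @property
    def n_targets(self) -> int:
        return int(round(self.target_rate * self.n_scored_items))

    @property
    def n_lures(self) -> int:
        return int(round(self.lure_rate * self.n_scored_items))


@dataclass
class TrialItem:
    """One presented item with its scoring flags and (optionally) a response.

    ``is_target`` means the label repeats the label ``n_level`` back;
    ``is_lure`` means it repeats the label at lag ``n_level ± 1`` but not at
    lag ``n_level`` (lures force lag-specific memory).  ``response`` is
    ``"match"``, ``"nonmatch"``, ``"none"`` (omitted), or ``None`` if not yet
    collected.
    """

    position: int
    stimulus: Stimulus
    is_target: bool
    is_lure: bool
    response: Optional[str] = None
    correct: Optional[bool] = None
    onset_s: float = 0.0
    stim_dur_s: float = STIM_DUR_S
    fixation_dur_s: float = FIXATION_DUR_S


@dataclass(frozen=True)
class BlockResult:
    """Scored outcome of one block."""

    n_level: int
    accuracy: float
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    @property
    def n_scored(self) -> int:
        return self.hits + self.misses + self.false_alarms + self.correct_rejections


@dataclass(frozen=True)
class AdaptivePolicy:
    """Between-block staircase rule.

    N goes up one level when block accuracy reaches ``up_threshold``, down one
    when it falls to ``down_threshold`` or below, otherwise stays; always
    clamped to ``[n_min, n_max]``.
    """

    up_threshold: float = 0.85
    down_threshold: float = 0.60
    n_min: int = 1
    n_max: int = 15
    carryover_rule: str = "last"  # "last" | "modal" | "rounded_mean"

    def __post_init__(self) -> None:
        if not (0.0 <= self.down_threshold < self.up_threshold <= 1.0):
            raise ValueError("need 0 <= down_threshold < up_threshold <= 1")
        if self.n_min < 1 or self.n_max < self.n_min:
            raise ValueError("need 1 <= n_min <= n_max")
        if self.carryover_rule not in ("last", "modal", "rounded_mean"):
            raise ValueError(f"unknown carryover_rule {self.carryover_rule!r}")


@dataclass
class SessionResult:
    """One 15-block training session.

    ``end_n`` is the difficulty a hypothetical next block would use (the
    staircase update applied to the final block), which the default "last"
    carryover rule hands to the next session.
    """

    session_index: int
    start_n: int
    blocks: list[BlockResult]
    mean_n: float
    end_n: int
    modality: str
    complete: bool = True
    items: list[list[TrialItem]] = field(default_factory=list, repr=False)
    seed: Optional[int] = None

    @property
    def n_levels(self) -> list[int]:
        return [b.n_level for b in self.blocks]


BLOCKS_PER_SESSION = 15
_MAX_RESAMPLES = 1000


def _draw_label(rng: np.random.Generator, categories: Sequence[str],
                exclude: set[str]) -> Optional[str]:
    allowed = [c for c in categories if c not in exclude]
    if not allowed:
        return None
    return allowed[int(rng.integers(len(allowed)))]


def generate_block_sequence(
    spec: BlockSpec,
    category_set: Sequence[str],
    rng: np.random.Generator,
    modality: str = "face",
) -> list[TrialItem]:
    """Generate the item sequence for one block.

    Target and lure counts are exact (``round(rate * n_scored_items)``);
    scored items that are neither targets nor lures get labels that differ
    from the labels at lags N and N±1, so a correct "nonmatch" there cannot be
    produced by accident of the construction.  Reproducible from ``rng``.

    A single-label ``category_set`` is accepted only as the degenerate
    all-target design (every scored item necessarily matches at every lag).
    """
    categories = list(dict.fromkeys(category_set))
    n = spec.n_level
    if len(categories) == 1:
        return _degenerate_single_label(spec, categories[0], rng, modality)
    if len(categories) < 3:
        raise SequenceError(
            f"need at least 3 category labels to place non-target items whose labels "
            f"differ from the lag-N and lag-N±1 labels; got {len(categories)}"
        )
    n_targets, n_lures = spec.n_targets, spec.n_lures
    if n_targets + n_lures > spec.n_scored_items:
        raise SequenceError(
            f"target_rate {spec.target_rate} and lure_rate {spec.lure_rate} are infeasible "
            f"for {spec.n_scored_items} scored items "
            f"({n_targets} targets + {n_lures} lures)"
        )

    scored_positions = list(range(n, spec.n_items))
    for _ in range(_MAX_RESAMPLES):
        perm = rng.permutation(len(scored_positions))
        target_pos = {scored_positions[i] for i in perm[:n_targets]}
        lure_pos = {scored_positions[i] for i in perm[n_targets:n_targets + n_lures]}
        labels: list[Optional[str]] = [None] * spec.n_items
        ok = True
        for p in range(spec.n_items):
            if p < n:
                labels[p] = categories[int(rng.integers(len(categories)))]
                continue
            lag_n_label = labels[p - n]
            if p in target_pos:
                labels[p] = lag_n_label
            elif p in lure_pos:
                # lure = match at lag N±1 that is NOT a match at lag N;
                # lag N-1 is undefined for N = 1 (it would be the item itself)
                lags = [lag for lag in (n - 1, n + 1) if lag >= 1 and p - lag >= 0]
                cand = [labels[p - lag] for lag in lags if labels[p - lag] != lag_n_label]
                if not cand:
                    ok = False
                    break
                labels[p] = cand[int(rng.integers(len(cand)))]
            else:
                exclude = {lag_n_label}
                for lag in (n - 1, n + 1):
                    if lag >= 1 and p - lag >= 0:
                        exclude.add(labels[p - lag])
                lab = _draw_label(rng, categories, exclude)
                if lab is None:
                    ok = False
                    break
                labels[p] = lab
        if ok:
            return _build_items(spec, labels, target_pos, lure_pos, rng, modality)
    raise SequenceError("could not place lures/non-targets after "
                        f"{_MAX_RESAMPLES} resamples; category set too small?")


def _degenerate_single_label(spec: BlockSpec, label: str, rng: np.random.Generator,
                             modality: str) -> list[TrialItem]:
    items = []
    for p in range(spec.n_items):
        stim = Stimulus(id=f"s{p:03d}", modality=modality, label=label,
                        actor_id=_actor(rng, modality))
        items.append(TrialItem(position=p, stimulus=stim,
                               is_target=p >= spec.n_level, is_lure=False,
                               onset_s=p * (STIM_DUR_S + FIXATION_DUR_S)))
    return items


def _actor(rng: np.random.Generator, modality: str) -> Optional[str]:
    # draw unconditionally so face and shape sessions consume identical
    # random streams (identical dynamics for identical seeds/responses)
    k = int(rng.integers(40))
    return f"actor{k:02d}" if modality == "face" else None


def _build_items(spec, labels, target_pos, lure_pos, rng, modality):
    items = []
    for p, lab in enumerate(labels):
        stim = Stimulus(id=f"s{p:03d}", modality=modality, label=lab,
                        actor_id=_actor(rng, modality))
        items.append(TrialItem(
            position=p, stimulus=stim,
            is_target=p in target_pos, is_lure=p in lure_pos,
            onset_s=p * (STIM_DUR_S + FIXATION_DUR_S),
        ))
    return items


def score_block(items: Sequence[TrialItem], spec: BlockSpec) -> BlockResult:
    """Score one block: accuracy = (hits + correct rejections) / scored items.

    Omitted responses (``"none"``) are counted as errors — tabulated with the
    error cell of their item type (miss on a target, false alarm otherwise) so
    the four counts always sum to ``n_scored_items``.
    """
    scored = [it for it in items if it.position >= spec.n_level]
    if len(scored) != spec.n_scored_items:
        raise ScoringError(
            f"expected {spec.n_scored_items} scored items, got {len(scored)}")
    missing = [it.position for it in scored if it.response is None]
    if missing:
        raise ScoringError(f"scored items without responses at positions {missing}")
    hits = misses = fas = crs = 0
    for it in scored:
        if it.response not in ("match", "nonmatch", "none"):
            raise ScoringError(f"invalid response {it.response!r} at position {it.position}")
        if it.is_target:
            if it.response == "match":
                hits += 1
                it.correct = True
            else:
                misses += 1
                it.correct = False
        else:
            if it.response == "nonmatch":
                crs += 1
                it.correct = True
            else:
                fas += 1
                it.correct = False
    acc = (hits + crs) / spec.n_scored_items
    return BlockResult(n_level=spec.n_level, accuracy=acc, hits=hits,
                       misses=misses, false_alarms=fas, correct_rejections=crs)


def update_difficulty(policy: AdaptivePolicy, result: BlockResult) -> int:
    """Next block's N: up at ``accuracy >= up_threshold``, down at
    ``accuracy <= down_threshold``, clamped to ``[n_min, n_max]``."""
    n = result.n_level
    if result.accuracy >= policy.up_threshold:
        n += 1
    elif result.accuracy <= policy.down_threshold:
        n -= 1
    return int(np.clip(n, policy.n_min, policy.n_max))


Responder = Callable[[TrialItem, int, np.random.Generator], str]


def run_session(
    session_index: int,
    start_n: int,
    responder: Responder,
    policy: AdaptivePolicy,
    rng: np.random.Generator,
    spec_template: BlockSpec | None = None,
    category_set: Sequence[str] | None = None,
    modality: str = "face",
    keep_items: bool = False,
    seed: Optional[int] = None,
) -> SessionResult:
    """Run one 15-block session, adapting N between blocks.

    ``responder`` is called once per scored item with (item, n_level, rng) and
    must return "match", "nonmatch" or "none".  Session 1 must start at N = 1.
    A responder exception yields a partial session flagged incomplete.
    """
    if session_index == 1 and start_n != 1:
        raise ValueError("the first session must begin at N = 1")
    if spec_template is None:
        spec_template = BlockSpec(n_level=1)
    if category_set is None:
        category_set = FACE_LABELS if modality == "face" else SHAPE_LABELS
    n = int(np.clip(start_n, policy.n_min, policy.n_max))
    blocks: list[BlockResult] = []
    all_items: list[list[TrialItem]] = []
    complete = True
    for _ in range(BLOCKS_PER_SESSION):
        spec = replace(spec_template, n_level=n)
        items = generate_block_sequence(spec, category_set, rng, modality=modality)
        try:
            for it in items:
                if it.position >= spec.n_level:
                    it.response = responder(it, n, rng)
        except Exception:
            complete = False
            break
        blocks.append(score_block(items, spec))
        if keep_items:
            all_items.append(items)
        n = update_difficulty(policy, blocks[-1])
    mean_n = float(np.mean([b.n_level for b in blocks])) if blocks else float(policy.n_min)
    return SessionResult(session_index=session_index, start_n=start_n, blocks=blocks,
                         mean_n=mean_n, end_n=n, modality=modality, complete=complete,
                         items=all_items, seed=seed)


def next_session_start(prev: SessionResult, policy: AdaptivePolicy) -> int:
    """Starting N for the session after ``prev`` under the policy's carryover
    rule; an incomplete previous session falls back to ``n_min``."""
    if not prev.complete or not prev.blocks:
        return policy.n_min
    rule = policy.carryover_rule
    if rule == "last":
        n = prev.end_n
    elif rule == "modal":
        levels = prev.n_levels
        n = int(max(set(levels), key=lambda v: (levels.count(v), -v)))
    else:  # rounded_mean
        n = int(round(prev.mean_n))
    return int(np.clip(n, policy.n_min, policy.n_max))
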