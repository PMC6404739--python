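"""Permuted-block treatment allocation (blocks of six, 1:1 target ratio).

Every complete block of six enrollees contains exactly three active (EFMT) and
three control (CT) assignments in random order; a final partial block is the
leading part of one more randomly permuted balanced block.  The whole sequence
is a deterministic function of the seeded generator, i.e. a pre-determined
allocation list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["Assignment", "BLOCK_SIZE", "permuted_block_sequence"]

BLOCK_SIZE = 6
ARMS = ("EFMT", "CT")


@dataclass(frozen=True)
class Assignment:
    participant_id: str
    arm: str
    block_index: int
    position_in_block: int

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        if not (0 <= self.position_in_block < BLOCK_SIZE):
            raise ValueError("position_in_block must be in 0..5")


def permuted_block_sequence(n: int, rng: np.random.Generator,
                            participant_ids: Optional[Sequence[str]] = None,
                            ) -> list[Assignment]:
    """Allocation list for ``n`` enrollees in enrollment order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if participant_ids is None:
        participant_ids = [f"P{i + 1:03d}" for i in range(n)]
    elif len(participant_ids) != n:
        raise ValueError("participant_ids length must equal n")
    out: list[Assignment] = []
    n_blocks = -(-n // BLOCK_SIZE)
    base = np.array([0, 0, 0, 1, 1, 1])
    for b in range(n_blocks):
        perm = rng.permutation(base)
        for pos, arm_idx in enumerate(perm):
            i = b * BLOCK_SIZE + pos
            if i >= n:
                break
            out.append(Assignment(participant_id=participant_ids[i],
                                  arm=ARMS[arm_idx], block_index=b,
                                  position_in_block=pos))
    return out
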