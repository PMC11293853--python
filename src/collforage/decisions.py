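"""Individual memory, patch-quality estimation and collective choice.

Each individual carries a private sliding window of its own recent foraging
outcomes.  At every timestep it estimates the quality of each accessible
patch from the number of *rewarded* visits it remembers there, through a
logistic function

    q(r) = 1 / (1 + exp(-(r - sensitivity)))

so a patch with no remembered reward has low but non-zero quality and each
extra remembered reward multiplies the odds of preferring it by ``e``.
Preferences are sampled with probability linearly proportional to quality,
which makes uninformed individuals choose uniformly.  Groups aggregate the
sampled preferences by plurality (ties broken uniformly at random) and
occasionally override the outcome with a uniformly random accessible patch
(exploration).

Memory is strictly private: nothing here ever reads another individual's
window, which is what makes the competition in the simulator *indirect*.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MemoryWindow",
    "QualityVector",
    "reward_count",
    "patch_quality",
    "sample_preference",
    "majority_choice",
    "apply_exploration",
]

DEFAULT_SENSITIVITY = 3.0


class MemoryWindow:
    """Sliding window over an individual's last ``capacity`` foraging events.

    Entries are ``(patch, rewarded)`` pairs, newest last.  Appending beyond
    capacity evicts the oldest entry.  A capacity of 0 keeps the window
    permanently empty (an uninformed individual).  Rewarded-visit counts per
    patch are cached so quality evaluation is O(1) per patch.
    """

    __slots__ = ("capacity", "_entries", "_counts")

    def __init__(
        self, capacity: int, entries: Iterable[tuple[int, bool]] = ()
    ) -> None:
        if capacity < 0:
            raise ValueError(f"capacity must be >= 0, got {capacity}")
        self.capacity = capacity
        self._entries: deque[tuple[int, bool]] = deque(maxlen=capacity)
        self._counts: dict[int, int] = {}
        for patch, rewarded in entries:
            self.append(patch, bool(rewarded))

    def append(self, patch: int, rewarded: bool) -> None:
        if self.capacity == 0:
            return
        if len(self._entries) == self.capacity:
            old_patch, old_rewarded = self._entries[0]
            if old_rewarded:
                self._counts[old_patch] -= 1
        self._entries.append((patch, rewarded))
        if rewarded:
            self._counts[patch] = self._counts.get(patch, 0) + 1

    def reward_count(self, patch: int) -> int:
        """Remembered rewarded visits to ``patch`` (unrewarded visits count 0)."""
        return self._counts.get(patch, 0)

    @property
    def entries(self) -> tuple[tuple[int, bool], ...]:
        return tuple(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __repr__(self) -> str:
        return f"MemoryWindow(capacity={self.capacity}, entries={list(self._entries)})"


def reward_count(memory: MemoryWindow, patch: int) -> int:
    """Number of remembered rewarded visits to ``patch`` in ``memory``."""
    return memory.reward_count(patch)


def patch_quality(rewards: int, sensitivity: float = DEFAULT_SENSITIVITY) -> float:
    """Logistic quality estimate ``1 / (1 + exp(-rewards + sensitivity))``.

    Strictly increasing in ``rewards`` and strictly inside (0, 1), so every
    accessible patch always has a positive selection probability.  The value
    is clamped to [1e-12, 1 - 1e-12] because the raw logistic saturates to
    exactly 0 or 1 in floating point once |rewards - sensitivity| is large.
    """
    x = sensitivity - rewards
    if x >= 0:
        q = 1.0 / (1.0 + math.exp(min(x, 700.0)))
    else:
        z = math.exp(max(x, -700.0))  # = e^x, small
        q = 1.0 / (1.0 + z)
    return min(max(q, 1e-12), 1.0 - 1e-12)


@dataclass(frozen=True)
class QualityVector:
    """Per-patch quality estimates for one individual over its access list."""

    patches: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.patches) != len(self.values):
            raise ValueError("patches and values must have equal length")
        if not self.patches:
            raise ValueError("at least one accessible patch is required")
        if any(not 0.0 < v < 1.0 for v in self.values):
            raise ValueError("qualities must lie strictly in (0, 1)")

    @classmethod
    def from_memory(
        cls,
        memory: MemoryWindow,
        access: Sequence[int],
        sensitivity: float = DEFAULT_SENSITIVITY,
    ) -> "QualityVector":
        return cls(
            tuple(access),
            tuple(patch_quality(memory.reward_count(p), sensitivity) for p in access),
        )


def sample_preference(qualities: QualityVector, rng: np.random.Generator) -> int:
    """Draw one patch with probability proportional to its quality.

    With an empty memory all qualities are equal and the draw is uniform.
    Returns the patch index (not the position in the access list).
    """
    values = qualities.values
    total = 0.0
    cumulative = []
    for v in values:
        total += v
        cumulative.append(total)
    u = rng.random() * total
    for patch, c in zip(qualities.patches, cumulative):
        if u < c:
            return patch
    return qualities.patches[-1]  # u == total edge case


def majority_choice(
    preferences: Sequence[int], rng: np.random.Generator
) -> tuple[int, float]:
    """Plurality vote over member preferences.

    Returns ``(patch, agreement_share)`` where the patch attains the maximal
    preference count (uniform random among ties, including the all-distinct
    case) and ``agreement_share`` is that maximal count divided by group
    size, computed before tie-breaking.
    """
    if not len(preferences):
        raise ValueError("majority_choice requires at least one preference")
    counts: dict[int, int] = {}
    for p in preferences:
        counts[p] = counts.get(p, 0) + 1
    best = max(counts.values())
    winners = [p for p, c in counts.items() if c == best]
    if len(winners) == 1:
        patch = winners[0]
    else:
        winners.sort()  # stable order so the tie-break depends only on the rng
        patch = winners[int(rng.integers(len(winners)))]
    return patch, best / len(preferences)


def apply_exploration(
    choice: int,
    access: Sequence[int],
    exploration: float,
    rng: np.random.Generator,
) -> tuple[int, bool]:
    """Group-level exploration: with probability ``exploration`` replace the
    majority choice with a uniformly random accessible patch.

    Returns ``(patch, explorative)``.  One Bernoulli draw is consumed on
    every call so the random stream stays aligned across exploration rates;
    the uniform patch draw is consumed only when exploring.
    """
    if not 0.0 <= exploration <= 1.0:
        raise ValueError(f"exploration must be in [0, 1], got {exploration}")
    if rng.random() < exploration:
        return access[int(rng.integers(len(access)))], True
    return choice, False
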