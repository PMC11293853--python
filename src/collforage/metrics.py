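"""Outcome metrics: patch preference, resource partitioning, foraging
success, within-group agreement, and the 'tendency' summary.

Preference and partitioning are both one-complement / normalized Shannon
entropies of patch-use distributions, but over different axes:

* **patch preference** (within-group): ``1 - H(p) / log(N'_P)`` where ``p``
  is the distribution of one group's visits over patches across the
  recording window.  1 means the group used a single patch throughout;
  0 means it spread its visits uniformly.
* **resource partitioning** (between-group): ``H(p) / log(N_P)`` where ``p``
  is the distribution of groups over patches within one timestep, averaged
  over the window.  0 means all groups piled onto one patch; 1 means every
  patch held exactly one group.

Foraging success is the mean per-individual probability of acquiring a
resource per timestep; agreement is the mean share of group members whose
sampled preference matched their group's modal preference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .engine import SimConfig, TimestepLog
    from .environment import AccessNetwork

__all__ = [
    "MetricsSummary",
    "shannon_entropy",
    "patch_preference",
    "resource_partitioning",
    "foraging_success",
    "agreement",
    "tendency",
    "summarize_run",
    "trajectory_metrics",
]

PREFERENCE_THRESHOLD = 0.5
PARTITIONING_THRESHOLD = 0.9


def shannon_entropy(proportions: Sequence[float]) -> float:
    """Shannon entropy ``sum(-p * log(p))`` in nats, with ``0 log 0 = 0``.

    Proportions must be non-negative and sum to 1 (tolerance 1e-9).
    """
    p = np.asarray(proportions, dtype=float)
    if p.size == 0 or (p < 0).any():
        raise ValueError("proportions must be a non-empty, non-negative vector")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {p.sum()!r}")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _normalized_entropy(counts: np.ndarray, n_categories: int) -> float:
    """Entropy of a count vector divided by its maximum ``log(n_categories)``."""
    if n_categories <= 1:
        return 0.0
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum() / math.log(n_categories))


def patch_preference(final_patches: Sequence[int], n_accessible: int) -> float:
    """Consistency of one group's patch use over the recording window.

    ``1 - H(visit proportions) / log(n_accessible)``: 1 when one patch is
    used at every recorded timestep, 0 when all accessible patches are used
    equally often.  A group with a single accessible patch trivially always
    uses one patch, so the degenerate ``n_accessible == 1`` case returns 1.
    """
    patches = np.asarray(final_patches)
    if patches.size == 0:
        raise ValueError("at least one recorded timestep is required")
    if n_accessible < 1:
        raise ValueError(f"n_accessible must be >= 1, got {n_accessible}")
    if n_accessible == 1:
        return 1.0
    _, counts = np.unique(patches, return_counts=True)
    return 1.0 - _normalized_entropy(counts, n_accessible)


def resource_partitioning(
    final_patches_all_groups: Sequence[Sequence[int]], n_patches: int
) -> float:
    """Evenness of the spread of groups over patches, per timestep, averaged
    over the window.

    Each row of ``final_patches_all_groups`` is one timestep's vector of
    group choices.  Returns the window mean of
    ``H(group proportions over patches) / log(n_patches)``: 0 when all
    groups share one patch, 1 when groups cover the patches one-to-one.
    """
    rows = np.atleast_2d(np.asarray(final_patches_all_groups))
    if rows.size == 0:
        raise ValueError("at least one timestep and one group are required")
    per_step = [
        _normalized_entropy(np.unique(row, return_counts=True)[1], n_patches)
        for row in rows
    ]
    return float(np.mean(per_step))


def foraging_success(rewards: np.ndarray) -> float:
    """Mean proportion of recorded timesteps in which individuals acquired a
    resource.

    ``rewards`` is a boolean array whose first axis is the timestep and
    whose remaining axes index individuals.
    """
    rewards = np.asarray(rewards)
    if rewards.size == 0:
        raise ValueError("at least one individual-timestep is required")
    return float(rewards.mean())


def agreement(
    preferences: Sequence[Sequence[Sequence[int]]] | Sequence[Sequence[int]],
    group_size: int,
) -> float:
    """Mean share of members whose sampled preference matches the group mode.

    ``preferences`` is either ``[timestep][group][member]`` or a flat
    ``[group-timestep][member]`` collection of preference vectors.  Ranges
    from ``1 / N'_P`` (members always perfectly spread) to 1 (unanimity).
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    flat: list[Sequence[int]] = []
    for item in preferences:
        if item and isinstance(item[0], (list, tuple, np.ndarray)):
            flat.extend(item)
        else:
            flat.append(item)
    if not flat:
        raise ValueError("at least one preference vector is required")
    shares = [
        np.unique(np.asarray(vec), return_counts=True)[1].max() / group_size
        for vec in flat
    ]
    return float(np.mean(shares))


def tendency(values: Iterable[float], threshold: float) -> float:
    """Proportion of values at or above ``threshold`` (inclusive)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("at least one value is required")
    return float((arr >= threshold).mean())


@dataclass(frozen=True)
class MetricsSummary:
    """The four outcome metrics of one run, over its recording window."""

    patch_preference_by_group: tuple[float, ...]
    patch_preference_mean: float
    resource_partitioning: float
    foraging_success: float
    agreement: float
    window: int

    def to_dict(self) -> dict:
        return {
            "patch_preference_mean": self.patch_preference_mean,
            "resource_partitioning": self.resource_partitioning,
            "foraging_success": self.foraging_success,
            "agreement": self.agreement,
            "window": self.window,
        }


def summarize_run(
    logs: Sequence["TimestepLog"], config: "SimConfig", network: "AccessNetwork"
) -> MetricsSummary:
    """Compute all four metrics from the final ``record_window`` timesteps.

    Preference normalization uses each group's own number of accessible
    patches (its degree in the access network); partitioning normalization
    uses the environment-wide patch count.
    """
    window = logs[-config.record_window :]
    final = np.array([log.final_patch for log in window])  # (W, n_groups)
    prefs_by_group = tuple(
        patch_preference(final[:, g], len(network.access[g]))
        for g in range(config.n_groups)
    )
    rewards = np.array([log.rewards for log in window])  # (W, n_groups, n)
    agreements = [share for log in window for share in log.agreement]
    return MetricsSummary(
        patch_preference_by_group=prefs_by_group,
        patch_preference_mean=float(np.mean(prefs_by_group)),
        resource_partitioning=resource_partitioning(final, config.n_patches),
        foraging_success=foraging_success(rewards),
        agreement=float(np.mean(agreements)),
        window=len(window),
    )


def trajectory_metrics(
    trajectory: pd.DataFrame,
    n_accessible: int,
    n_patches: int,
    record_window: int | None = None,
) -> pd.DataFrame:
    """Recompute preference, partitioning and mean agreement from a
    group-level trajectory table (columns ``replicate, timestep, group,
    final_patch, agreement``), one output row per replicate.

    Foraging success requires individual-level reward logs and is not
    recoverable from the group-level table.
    """
    out = []
    for replicate, df in trajectory.groupby("replicate"):
        steps = np.sort(df["timestep"].unique())
        if record_window is not None:
            steps = steps[-record_window:]
        df = df[df["timestep"].isin(steps)]
        wide = df.pivot(index="timestep", columns="group", values="final_patch")
        prefs = [
            patch_preference(wide[g].to_numpy(), n_accessible) for g in wide.columns
        ]
        out.append(
            {
                "replicate": replicate,
                "patch_preference_mean": float(np.mean(prefs)),
                "resource_partitioning": resource_partitioning(
                    wide.to_numpy(), n_patches
                ),
                "agreement": float(df["agreement"].mean()),
            }
        )
    return pd.DataFrame(out)
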