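"""Group-patch access topologies.

Which patches a group may forage at is described by a bipartite access
network mapping each group to an ordered list of patch indices.  Three
constructions are provided:

* **full** -- every group can reach every patch (no spatial restriction);
* **ring** -- each group is restricted to a contiguous window of patches
  centred on "its" patch, so neighbouring groups overlap in access
  (a stylised restricted home range);
* **random** -- a degree-preserving rewiring of a ring network, which keeps
  the number of options per group fixed while destroying the spatial
  arrangement of overlaps.

Indices are 0-based throughout, including serialized edge lists.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidConfigurationError

__all__ = [
    "AccessNetwork",
    "build_full_network",
    "build_ring_network",
    "build_random_network",
    "read_edge_list",
    "write_edge_list",
]


@dataclass(frozen=True)
class AccessNetwork:
    """Bipartite mapping from groups to the patches they can forage at.

    Parameters
    ----------
    n_groups, n_patches
        Number of groups and number of patches in the environment.
    access
        ``access[g]`` is the ordered tuple of distinct patch indices that
        group ``g`` may choose from.
    """

    n_groups: int
    n_patches: int
    access: tuple[tuple[int, ...], ...] = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.n_patches < 1:
            raise InvalidConfigurationError(
                "n_groups and n_patches must be positive, got "
                f"{self.n_groups} and {self.n_patches}"
            )
        if len(self.access) != self.n_groups:
            raise InvalidConfigurationError(
                f"access lists for {len(self.access)} groups but n_groups={self.n_groups}"
            )
        for g, patches in enumerate(self.access):
            if len(set(patches)) != len(patches):
                raise InvalidConfigurationError(f"group {g} lists a patch twice")
            if not patches:
                raise InvalidConfigurationError(f"group {g} has no accessible patch")
            for p in patches:
                if not 0 <= p < self.n_patches:
                    raise InvalidConfigurationError(
                        f"group {g} lists patch {p} outside [0, {self.n_patches})"
                    )

    @property
    def degrees(self) -> tuple[int, ...]:
        """Number of accessible patches per group."""
        return tuple(len(a) for a in self.access)

    @property
    def n_edges(self) -> int:
        return sum(self.degrees)

    def patch_degree(self, patch: int) -> int:
        """Number of groups that can access ``patch``."""
        return sum(patch in a for a in self.access)

    def edges(self) -> list[tuple[int, int]]:
        """All (group, patch) edges in group order then list order."""
        return [(g, p) for g, a in enumerate(self.access) for p in a]


def build_full_network(n_groups: int, n_patches: int) -> AccessNetwork:
    """Complete bipartite access: every group can reach every patch."""
    if n_groups < 1 or n_patches < 1:
        raise InvalidConfigurationError(
            f"counts must be positive, got n_groups={n_groups}, n_patches={n_patches}"
        )
    full = tuple(range(n_patches))
    return AccessNetwork(n_groups, n_patches, tuple(full for _ in range(n_groups)))


def build_ring_network(n_groups: int, n_patches: int, n_accessible: int) -> AccessNetwork:
    """Ring access: group ``g`` reaches ``n_accessible`` contiguous patches
    centred on patch ``g`` (modulo ``n_patches``).

    Requires ``n_groups == n_patches`` and an odd ``n_accessible`` so the
    window is symmetric.  With ``n_accessible == n_patches`` the ring
    degenerates to a full network.  Each patch ends up accessible to exactly
    ``n_accessible`` groups.
    """
    if n_groups != n_patches:
        raise InvalidConfigurationError(
            f"ring networks require n_groups == n_patches, got {n_groups} != {n_patches}"
        )
    if n_accessible < 1 or n_accessible > n_patches:
        raise InvalidConfigurationError(
            f"n_accessible must be in [1, n_patches], got {n_accessible}"
        )
    if n_accessible % 2 == 0:
        raise InvalidConfigurationError(
            f"n_accessible must be odd for a symmetric window, got {n_accessible}"
        )
    half = n_accessible // 2
    access = tuple(
        tuple((g + d) % n_patches for d in range(-half, half + 1))
        for g in range(n_groups)
    )
    return AccessNetwork(n_groups, n_patches, access)


def build_random_network(
    seed_ring: AccessNetwork, rng: np.random.Generator
) -> AccessNetwork:
    """Degree-preserving random rewiring of a ring network.

    Performs ``floor(E / 2)`` sequential edge swaps, where ``E`` is the total
    edge count.  Each swap picks one existing (group, patch) edge uniformly
    from the *current* edge set and moves it to a patch the group cannot yet
    access, chosen uniformly.  Group degrees are conserved; patch degrees are
    not, so some patches may end up reachable by no group and others by many.
    """
    degrees = set(seed_ring.degrees)
    if degrees == {seed_ring.n_patches}:
        raise InvalidConfigurationError(
            "cannot rewire a saturated network: every patch is already accessible"
        )
    access = [list(a) for a in seed_ring.access]
    n_patches = seed_ring.n_patches
    all_patches = set(range(n_patches))
    n_swaps = seed_ring.n_edges // 2
    # Cumulative degree offsets are constant because swaps preserve degrees.
    offsets = np.concatenate([[0], np.cumsum(seed_ring.degrees)])
    for _ in range(n_swaps):
        e = int(rng.integers(offsets[-1]))
        g = int(np.searchsorted(offsets, e, side="right")) - 1
        slot = e - offsets[g]
        candidates = sorted(all_patches - set(access[g]))
        new_patch = candidates[int(rng.integers(len(candidates)))]
        access[g][slot] = new_patch
    return AccessNetwork(
        seed_ring.n_groups, n_patches, tuple(tuple(a) for a in access)
    )


def write_edge_list(network: AccessNetwork, path: str | Path) -> None:
    """Write the access network as a ``group,patch`` edge-list CSV (0-based)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group", "patch"])
        writer.writerows(network.edges())


def read_edge_list(
    path: str | Path, n_groups: int | None = None, n_patches: int | None = None
) -> AccessNetwork:
    """Read an access network from a ``group,patch`` edge-list CSV.

    Counts default to one more than the largest index seen, so isolated
    trailing patches must be declared explicitly via ``n_patches``.
    """
    edges: dict[int, list[int]] = {}
    max_patch = -1
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != ["group", "patch"]:
            raise InvalidConfigurationError(
                f"expected header 'group,patch', got {reader.fieldnames}"
            )
        for row in reader:
            g, p = int(row["group"]), int(row["patch"])
            edges.setdefault(g, []).append(p)
            max_patch = max(max_patch, p)
    n_groups = n_groups if n_groups is not None else max(edges) + 1
    n_patches = n_patches if n_patches is not None else max_patch + 1
    access = tuple(tuple(edges.get(g, ())) for g in range(n_groups))
    return AccessNetwork(n_groups, n_patches, access)
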