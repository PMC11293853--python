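"""Simulation engine: configuration, state, timestep loop and full runs.

A population consists of ``n_groups`` cohesive groups of ``group_size``
individuals foraging over ``n_patches`` patches, each holding
``patch_resources`` resources that are fully replenished every timestep.
Each timestep proceeds simultaneously for all groups:

1. every individual samples a patch preference from its private memory;
2. every group aggregates preferences by majority rule, then may override
   the outcome with a random accessible patch (exploration);
3. resources at each chosen patch are split as evenly as possible among the
   groups present and allocated to random members within each group;
4. every individual appends (group's final patch, own reward) to its memory.

The whole trajectory is reproducible from ``(config, seed)``: one
``numpy.random.Generator`` drives a run, with draws consumed in group-index
order and member-index order within each group.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .decisions import MemoryWindow, QualityVector, apply_exploration, majority_choice, sample_preference
from .environment import (
    AccessNetwork,
    build_full_network,
    build_random_network,
    build_ring_network,
)
from .errors import InitializationInfeasibleError, InvalidConfigurationError

__all__ = [
    "SimConfig",
    "PopulationState",
    "TimestepLog",
    "SimResult",
    "allocate_resources",
    "build_network",
    "initialize_state",
    "initialize_partitioned",
    "step",
    "run_simulation",
    "state_to_dict",
    "state_from_dict",
]

NETWORK_TYPES = ("full", "ring", "random")


@dataclass(frozen=True)
class SimConfig:
    """Full parameter set of one simulation run.

    Parameters
    ----------
    n_groups
        Number of groups in the population.
    group_size
        Individuals per group; 1 (solitary) or an odd integer >= 3 so
        majorities are more often clear.
    network_type
        One of ``full``, ``ring``, ``random``.
    n_patches
        Patches in the environment; defaults to ``n_groups``.
    n_accessible
        Patches each group can reach on ring/random networks (odd); ignored
        for full networks, where every group reaches every patch.
    history
        Memory capacity in timesteps; 0 gives uninformed (uniform) choices.
    exploration
        Per-group, per-timestep probability of a random patch override.
    sensitivity
        Offset of the logistic quality function; larger values make a
        remembered reward count for more relative to an unrewarded patch.
    timesteps, record_window
        Run length and the number of final timesteps used for metrics.
    patch_resources
        Resources per patch per timestep; defaults to ``group_size`` so a
        lone group on a patch can feed every member.
    seed
        Seed for the single run-level random generator.
    """

    n_groups: int
    group_size: int
    network_type: str = "ring"
    n_patches: int | None = None
    n_accessible: int = 3
    history: int = 3
    exploration: float = 0.01
    sensitivity: float = 3.0
    timesteps: int = 300
    record_window: int = 30
    patch_resources: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patches is None:
            object.__setattr__(self, "n_patches", self.n_groups)
        if self.patch_resources is None:
            object.__setattr__(self, "patch_resources", self.group_size)
        if self.network_type not in NETWORK_TYPES:
            raise InvalidConfigurationError(
                f"network_type must be one of {NETWORK_TYPES}, got {self.network_type!r}"
            )
        if self.n_groups < 1 or self.n_patches < 1:
            raise InvalidConfigurationError("n_groups and n_patches must be >= 1")
        if self.group_size < 1 or (self.group_size > 1 and self.group_size % 2 == 0):
            raise InvalidConfigurationError(
                f"group_size must be 1 or an odd integer >= 3, got {self.group_size}"
            )
        if self.history < 0:
            raise InvalidConfigurationError("history must be >= 0")
        if not 0.0 <= self.exploration <= 1.0:
            raise InvalidConfigurationError("exploration must be in [0, 1]")
        if self.timesteps < 1 or not 1 <= self.record_window <= self.timesteps:
            raise InvalidConfigurationError(
                "need timesteps >= 1 and 1 <= record_window <= timesteps"
            )
        if self.patch_resources < 1:
            raise InvalidConfigurationError("patch_resources must be >= 1")
        if self.network_type != "full" and not 1 <= self.n_accessible <= self.n_patches:
            raise InvalidConfigurationError(
                f"n_accessible must be in [1, n_patches], got {self.n_accessible}"
            )

    @property
    def accessible_per_group(self) -> int:
        """Patches each group can choose from (N_P on a full network)."""
        return self.n_patches if self.network_type == "full" else self.n_accessible

    @property
    def n_individuals(self) -> int:
        return self.n_groups * self.group_size

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class PopulationState:
    """Mutable simulation state: the access network plus every individual's
    memory window, indexed ``memories[group][member]``."""

    network: AccessNetwork
    memories: list[list[MemoryWindow]]
    timestep: int = 0

    def validate_against(self, config: SimConfig) -> None:
        if (
            len(self.memories) != config.n_groups
            or any(len(g) != config.group_size for g in self.memories)
            or self.network.n_groups != config.n_groups
            or self.network.n_patches != config.n_patches
        ):
            raise InvalidConfigurationError("population state inconsistent with config")


@dataclass(frozen=True)
class TimestepLog:
    """Record of one timestep: sampled preferences, collective choices and
    individual rewards."""

    timestep: int
    preferences: tuple[tuple[int, ...], ...]  # [group][member] -> patch
    majority_patch: tuple[int, ...]
    final_patch: tuple[int, ...]
    explorative: tuple[bool, ...]
    agreement: tuple[float, ...]
    rewards: np.ndarray = field(repr=False)  # bool, (n_groups, group_size)


def build_network(config: SimConfig, rng: np.random.Generator) -> AccessNetwork:
    """Construct the access network named by ``config.network_type``.

    Random networks consume draws from ``rng``; full and ring do not.
    """
    if config.network_type == "full":
        return build_full_network(config.n_groups, config.n_patches)
    ring = build_ring_network(config.n_groups, config.n_patches, config.n_accessible)
    if config.network_type == "ring":
        return ring
    return build_random_network(ring, rng)


def initialize_state(config: SimConfig, network: AccessNetwork) -> PopulationState:
    """Fresh population: empty memories, timestep 0."""
    memories = [
        [MemoryWindow(config.history) for _ in range(config.group_size)]
        for _ in range(config.n_groups)
    ]
    return PopulationState(network, memories)


def initialize_partitioned(
    config: SimConfig, network: AccessNetwork | None = None
) -> PopulationState:
    """Population pre-committed to maximal partitioning.

    Finds an assignment of groups to distinct accessible patches (a perfect
    matching on the access network) and pre-fills every member's memory with
    ``history`` rewarded visits to the group's assigned patch, so the first
    informed decision strongly favours distinct patches.
    """
    import networkx as nx

    if network is None:
        network = build_network(config, np.random.default_rng(config.seed))
    graph = nx.Graph()
    group_nodes = [("g", g) for g in range(network.n_groups)]
    graph.add_nodes_from(group_nodes, bipartite=0)
    graph.add_nodes_from((("p", p) for p in range(network.n_patches)), bipartite=1)
    graph.add_edges_from(
        (("g", g), ("p", p)) for g, p in network.edges()
    )
    matching = nx.bipartite.maximum_matching(graph, top_nodes=group_nodes)
    if any(node not in matching for node in group_nodes):
        raise InitializationInfeasibleError(
            "no assignment of groups to distinct accessible patches exists"
        )
    state = initialize_state(config, network)
    for g in range(network.n_groups):
        patch = matching[("g", g)][1]
        for mem in state.memories[g]:
            for _ in range(config.history):
                mem.append(patch, True)
    return state


def allocate_resources(
    final_choices: Sequence[int],
    group_sizes: Sequence[int] | int,
    patch_resources: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Split each chosen patch's resources among the groups present and hand
    them to random members.

    A patch chosen by ``G`` groups yields ``floor(R / G)`` resources per
    group; the remainder ``R mod G`` goes one unit each to groups drawn
    uniformly without replacement.  Within a group with share ``s``,
    ``min(s, group_size)`` distinct members drawn uniformly each receive one
    resource; any excess share is discarded with a warning (possible only
    when R exceeds the mouths available).

    Returns a boolean array of shape ``(n_groups, max_group_size)``.
    """
    n_groups = len(final_choices)
    if isinstance(group_sizes, int):
        group_sizes = [group_sizes] * n_groups
    n_max = max(group_sizes)
    rewards = np.zeros((n_groups, n_max), dtype=bool)
    by_patch: dict[int, list[int]] = {}
    for g, patch in enumerate(final_choices):
        by_patch.setdefault(patch, []).append(g)
    for patch in sorted(by_patch):
        groups = by_patch[patch]  # ascending group index
        n_present = len(groups)
        base, remainder = divmod(patch_resources, n_present)
        shares = [base] * n_present
        if remainder:
            for i in rng.choice(n_present, size=remainder, replace=False):
                shares[i] += 1
        for g, share in zip(groups, shares):
            size = group_sizes[g]
            if share > size:
                warnings.warn(
                    f"group {g} received share {share} > group size {size}; "
                    "excess resources discarded",
                    stacklevel=2,
                )
                share = size
            if share == size:
                rewards[g, :size] = True
            elif share > 0:
                rewards[g, rng.choice(size, size=share, replace=False)] = True
    return rewards


def step(
    state: PopulationState, config: SimConfig, rng: np.random.Generator
) -> tuple[PopulationState, TimestepLog]:
    """Advance the population by one timestep (in place) and log it.

    Draw order: for each group in index order, member preference draws in
    member order, then the majority tie-break (if needed), then the
    exploration Bernoulli (and patch draw if exploring); finally the
    allocation draws in ascending patch order.
    """
    network = state.network
    preferences: list[tuple[int, ...]] = []
    majority: list[int] = []
    final: list[int] = []
    explorative: list[bool] = []
    agreement: list[float] = []
    for g in range(config.n_groups):
        access = network.access[g]
        member_prefs = tuple(
            sample_preference(
                QualityVector.from_memory(mem, access, config.sensitivity), rng
            )
            for mem in state.memories[g]
        )
        patch, share = majority_choice(member_prefs, rng)
        final_patch, explored = apply_exploration(
            patch, access, config.exploration, rng
        )
        preferences.append(member_prefs)
        majority.append(patch)
        final.append(final_patch)
        explorative.append(explored)
        agreement.append(share)
    rewards = allocate_resources(final, config.group_size, config.patch_resources, rng)
    for g in range(config.n_groups):
        patch = final[g]
        for m, mem in enumerate(state.memories[g]):
            mem.append(patch, bool(rewards[g, m]))
    state.timestep += 1
    return state, TimestepLog(
        timestep=state.timestep,
        preferences=tuple(preferences),
        majority_patch=tuple(majority),
        final_patch=tuple(final),
        explorative=tuple(explorative),
        agreement=tuple(agreement),
        rewards=rewards,
    )


def state_to_dict(state: PopulationState) -> dict:
    """JSON-ready checkpoint of the full population state."""
    return {
        "timestep": state.timestep,
        "network": {
            "n_groups": state.network.n_groups,
            "n_patches": state.network.n_patches,
            "access": [list(a) for a in state.network.access],
        },
        "memories": [
            [
                {"capacity": mem.capacity,
                 "entries": [[p, bool(r)] for p, r in mem.entries]}
                for mem in group
            ]
            for group in state.memories
        ],
    }


def state_from_dict(payload: dict) -> PopulationState:
    """Rebuild a population state from :func:`state_to_dict` output."""
    net = payload["network"]
    network = AccessNetwork(
        net["n_groups"], net["n_patches"], tuple(tuple(a) for a in net["access"])
    )
    memories = [
        [
            MemoryWindow(mem["capacity"], [(p, bool(r)) for p, r in mem["entries"]])
            for mem in group
        ]
        for group in payload["memories"]
    ]
    return PopulationState(network, memories, timestep=payload["timestep"])


@dataclass(frozen=True)
class SimResult:
    """Complete trajectory of one run plus summary metrics over the final
    recording window."""

    config: SimConfig
    network: AccessNetwork
    logs: tuple[TimestepLog, ...]
    metrics: "MetricsSummary"  # noqa: F821 - defined in collforage.metrics

    def window_logs(self) -> tuple[TimestepLog, ...]:
        return self.logs[-self.config.record_window :]

    def trajectory_frame(self, replicate: int = 0) -> pd.DataFrame:
        """Long-format group-level trajectory, one row per group-timestep."""
        rows = [
            (replicate, log.timestep, g, log.majority_patch[g], log.final_patch[g],
             log.explorative[g], log.agreement[g])
            for log in self.logs
            for g in range(self.config.n_groups)
        ]
        return pd.DataFrame(
            rows,
            columns=["replicate", "timestep", "group", "majority_patch",
                     "final_patch", "explorative", "agreement"],
        )

    def individuals_frame(self, replicate: int = 0) -> pd.DataFrame:
        """Long-format individual-level trajectory, one row per member-timestep."""
        rows = [
            (replicate, log.timestep, g, m, log.preferences[g][m],
             bool(log.rewards[g, m]))
            for log in self.logs
            for g in range(self.config.n_groups)
            for m in range(self.config.group_size)
        ]
        return pd.DataFrame(
            rows,
            columns=["replicate", "timestep", "group", "member", "preference",
                     "rewarded"],
        )

    def manifest(self) -> dict:
        """Run manifest: config, seed and network edge list, JSON-ready."""
        from . import __version__

        return {
            "config": self.config.to_dict(),
            "package_version": __version__,
            "network_edges": self.network.edges(),
        }

    def write_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=2))


def run_simulation(
    config: SimConfig, initial_state: PopulationState | None = None
) -> SimResult:
    """Run a full simulation: build the network, advance ``timesteps`` steps
    and compute metrics on the final ``record_window`` steps.

    Fully reproducible from ``(config, config.seed)``.  Passing an
    ``initial_state`` (e.g. from :func:`initialize_partitioned`) reuses its
    network and memories instead of a fresh start.
    """
    from .metrics import summarize_run

    rng = np.random.default_rng(config.seed)
    if initial_state is None:
        network = build_network(config, rng)
        state = initialize_state(config, network)
    else:
        initial_state.validate_against(config)
        state = initial_state
    logs: list[TimestepLog] = []
    for _ in range(config.timesteps):
        state, log = step(state, config, rng)
        logs.append(log)
    logs_t = tuple(logs)
    summary = summarize_run(logs_t, config, state.network)
    return SimResult(config=config, network=state.network, logs=logs_t, metrics=summary)
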