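"""Timestep loop, resource allocation, reproducibility and state handling."""

import json

import numpy as np
import pytest

from collforage.engine import (
    SimConfig,
    allocate_resources,
    build_network,
    initialize_partitioned,
    initialize_state,
    run_simulation,
    state_from_dict,
    state_to_dict,
    step,
)
from collforage.environment import AccessNetwork, build_ring_network
from collforage.errors import (
    InitializationInfeasibleError,
    InvalidConfigurationError,
)


class TestSimConfig:
    def test_defaults_mirror_study_conditions(self):
        config = SimConfig(n_groups=7, group_size=3)
        assert config.n_patches == 7
        assert config.patch_resources == 3
        assert (config.n_accessible, config.history, config.exploration) == (3, 3, 0.01)
        assert (config.timesteps, config.record_window, config.sensitivity) == (300, 30, 3.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"group_size": 2},
            {"group_size": 4},
            {"group_size": 0},
            {"network_type": "grid"},
            {"history": -1},
            {"exploration": 1.5},
            {"record_window": 400},
            {"patch_resources": 0},
            {"n_accessible": 9},
        ],
    )
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(InvalidConfigurationError):
            SimConfig(n_groups=7, group_size=kwargs.pop("group_size", 3), **kwargs)

    def test_full_network_accessible_count_is_all_patches(self):
        config = SimConfig(n_groups=7, group_size=3, network_type="full")
        assert config.accessible_per_group == 7


class TestAllocateResources:
    def test_two_groups_split_three_resources_two_one(self, rng):
        # two groups on the same patch with three resources: shares 2 and 1
        rewards = allocate_resources([0, 0], 3, 3, rng)
        assert sorted(rewards.sum(axis=1)) == [1, 2]

    def test_which_group_gets_the_extra_unit_is_uniform(self):
        extras = [
            int(np.argmax(allocate_resources([0, 0], 3, 3, np.random.default_rng(s)).sum(axis=1)))
            for s in range(2000)
        ]
        assert 0.45 < np.mean(extras) < 0.55

    def test_lone_group_with_matching_resources_feeds_everyone(self, rng):
        rewards = allocate_resources([4], 5, 5, rng)
        assert rewards.all()

    def test_exact_division_one_reward_per_group(self, rng):
        rewards = allocate_resources([2, 2, 2], 3, 3, rng)
        assert list(rewards.sum(axis=1)) == [1, 1, 1]

    def test_distinct_patches_do_not_interact(self, rng):
        rewards = allocate_resources([0, 1, 2], 3, 3, rng)
        assert rewards.all()

    def test_excess_share_discarded_with_warning(self, rng):
        with pytest.warns(UserWarning, match="excess"):
            rewards = allocate_resources([0], 3, 10, rng)
        assert rewards.sum() == 3


class TestStep:
    def test_uninformed_choices_are_uniform(self):
        # history 0: a single solitary group over 4 patches chooses uniformly
        config = SimConfig(
            n_groups=1, group_size=1, network_type="full", n_patches=4,
            history=0, exploration=0.0, timesteps=1, record_window=1,
        )
        rng = np.random.default_rng(0)
        network = build_network(config, rng)
        state = initialize_state(config, network)
        choices = []
        for _ in range(20_000):
            state, log = step(state, config, rng)
            choices.append(log.final_patch[0])
        freqs = np.bincount(choices, minlength=4) / len(choices)
        se = np.sqrt(0.25 * 0.75 / len(choices))
        assert np.all(np.abs(freqs - 0.25) < 3 * se)

    def test_memory_records_group_final_patch_for_every_member(self, rng):
        config = SimConfig(n_groups=2, group_size=3, network_type="full",
                           timesteps=1, record_window=1, seed=0)
        network = build_network(config, rng)
        state = initialize_state(config, network)
        state, log = step(state, config, rng)
        for g in range(2):
            for mem in state.memories[g]:
                assert mem.entries[-1][0] == log.final_patch[g]

    def test_state_config_mismatch_rejected(self, rng):
        config = SimConfig(n_groups=3, group_size=3)
        other = SimConfig(n_groups=5, group_size=3)
        state = initialize_state(config, build_network(config, rng))
        with pytest.raises(InvalidConfigurationError):
            state.validate_against(other)


class TestRunSimulation:
    def test_same_seed_gives_identical_trajectories(self):
        config = SimConfig(n_groups=5, group_size=3, network_type="random", seed=42,
                           timesteps=50, record_window=10)
        a, b = run_simulation(config), run_simulation(config)
        assert a.network.access == b.network.access
        for la, lb in zip(a.logs, b.logs):
            assert la.final_patch == lb.final_patch
            assert la.preferences == lb.preferences
            assert np.array_equal(la.rewards, lb.rewards)
        assert a.metrics == b.metrics

    def test_final_patches_stay_within_access(self):
        result = run_simulation(SimConfig(n_groups=7, group_size=3, seed=9))
        for log in result.logs:
            for g in range(7):
                assert log.final_patch[g] in result.network.access[g]
                assert log.majority_patch[g] in result.network.access[g]

    def test_reward_conservation_every_step(self):
        # R = n, so total rewards each step = n x (distinct chosen patches)
        result = run_simulation(SimConfig(n_groups=7, group_size=3, seed=11))
        for log in result.logs:
            distinct = len(set(log.final_patch))
            assert log.rewards.sum() == 3 * distinct

    def test_memory_never_exceeds_history(self):
        config = SimConfig(n_groups=5, group_size=3, history=3, seed=2,
                           timesteps=40, record_window=10)
        rng = np.random.default_rng(config.seed)
        network = build_network(config, rng)
        state = initialize_state(config, network)
        for _ in range(config.timesteps):
            state, _ = step(state, config, rng)
            assert all(len(m) <= 3 for group in state.memories for m in group)

    def test_degenerate_single_individual_environment(self):
        result = run_simulation(
            SimConfig(n_groups=1, group_size=1, network_type="full",
                      timesteps=40, record_window=10, seed=5)
        )
        assert result.metrics.patch_preference_mean == 1.0
        assert result.metrics.agreement == 1.0
        assert result.metrics.foraging_success == 1.0

    def test_trajectory_frames_have_documented_schema(self):
        result = run_simulation(SimConfig(n_groups=3, group_size=3, seed=1,
                                          timesteps=10, record_window=5))
        traj = result.trajectory_frame(replicate=4)
        assert list(traj.columns) == [
            "replicate", "timestep", "group", "majority_patch", "final_patch",
            "explorative", "agreement",
        ]
        assert len(traj) == 10 * 3
        assert (traj["replicate"] == 4).all()
        ind = result.individuals_frame()
        assert list(ind.columns) == [
            "replicate", "timestep", "group", "member", "preference", "rewarded",
        ]
        assert len(ind) == 10 * 3 * 3

    def test_manifest_round_trips_through_json(self, tmp_path):
        result = run_simulation(SimConfig(n_groups=3, group_size=3, seed=1,
                                          timesteps=5, record_window=5))
        path = tmp_path / "manifest.json"
        result.write_manifest(path)
        manifest = json.loads(path.read_text())
        assert manifest["config"]["n_groups"] == 3
        assert len(manifest["network_edges"]) == result.network.n_edges


class TestPartitionedStart:
    def test_ring_identity_assignment(self):
        config = SimConfig(n_groups=7, group_size=3, seed=0)
        state = initialize_partitioned(config)
        patches = [state.memories[g][0].entries[0][0] for g in range(7)]
        assert sorted(patches) == list(range(7))  # distinct patches
        for g in range(7):
            for mem in state.memories[g]:
                assert len(mem) == 3
                assert all(p == patches[g] and r for p, r in mem.entries)

    def test_full_network_assignment_is_a_permutation(self):
        config = SimConfig(n_groups=5, group_size=3, network_type="full", seed=0)
        state = initialize_partitioned(config)
        patches = [state.memories[g][0].entries[0][0] for g in range(5)]
        assert sorted(patches) == list(range(5))

    def test_infeasible_network_raises(self):
        config = SimConfig(n_groups=2, group_size=3, network_type="full",
                           n_patches=2, timesteps=5, record_window=5)
        bottleneck = AccessNetwork(2, 2, ((0,), (0,)))
        with pytest.raises(InitializationInfeasibleError):
            initialize_partitioned(config, network=bottleneck)


def test_state_checkpoint_round_trip(rng):
    config = SimConfig(n_groups=3, group_size=3, seed=8, timesteps=10, record_window=5)
    network = build_network(config, rng)
    state = initialize_state(config, network)
    for _ in range(6):
        state, _ = step(state, config, rng)
    payload = json.loads(json.dumps(state_to_dict(state)))
    restored = state_from_dict(payload)
    assert restored.timestep == state.timestep
    assert restored.network.access == state.network.access
    for g in range(3):
        for a, b in zip(restored.memories[g], state.memories[g]):
            assert a.entries == b.entries and a.capacity == b.capacity
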