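# Methods

## Model

The simulator advances a population of `N_G` cohesive groups, each of `n`
individuals, over `N_P` discrete resource patches in synchronous timesteps.
All groups act simultaneously within a timestep — there are no
arrival-order effects — and patches are fully replenished every timestep,
so the only coupling between groups is indirect: sharing a patch halves (or
worse) each group's share of its `R` resources, which individuals can sense
only through their own foraging outcomes.

Within a timestep the order of operations is fixed: (1) every individual
samples a patch preference from its memory; (2) every group aggregates
preferences by plurality and possibly overrides the result with a random
accessible patch (exploration); (3) resources are allocated; (4) every
individual appends the group's final patch and its own reward to its memory.

### Memory and quality estimation

Each individual keeps a private sliding window of its last `history`
foraging events (patch, rewarded-or-not). Only *rewarded* visits carry
weight: unrewarded visits and unvisited patches are equivalent (preference
without avoidance). The estimated quality of a patch with `r` remembered
rewards is the logistic

```
q(r) = 1 / (1 + exp(−r + sensitivity))
```

and the preference draw is linearly proportional to quality across the
group's accessible patches. Qualities are clamped to
`[1e−12, 1 − 1e−12]`: the raw logistic saturates to exactly 0 or 1 in
float64 once `|r − sensitivity|` exceeds ≈ 37, which would otherwise zero
out selection probabilities that the model requires to stay positive.
Preferences are ephemeral — regenerated each timestep, never observed by
others, never stored.

### Collective choice

Groups choose the patch preferred by the largest number of members. Any tie
among maximal-count patches — including the all-distinct case — is broken
uniformly at random. Exploration is a *group-level* event applied once per
group per timestep after aggregation (the model describes groups, not
individuals, as making occasional random choices); the agreement statistic
is computed from the sampled preferences before tie-breaking and before any
explorative override.

### Allocation

A patch chosen by `G` groups yields `floor(R/G)` resources per group, with
the remainder `R mod G` assigned one unit each to groups drawn uniformly
without replacement. Within a group with share `s`, `min(s, n)` distinct
members drawn uniformly each receive one resource; members of a sharing
group that go unrewarded still record the (unrewarded) visit, which is how
information about competition enters the population. A share exceeding the
group size (possible only when `R > n` and few groups share) is discarded
with a warning.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `n_groups` (`N_G`) | — | groups in the population |
| `n_patches` (`N_P`) | `n_groups` | patches in the environment |
| `group_size` (`n`) | — | 1 or odd ≥ 3, so plurality votes rarely tie |
| `patch_resources` (`R`) | `group_size` | resources per patch per timestep |
| `network_type` | `ring` | `full`, `ring` or `random` access topology |
| `n_accessible` (`N'_P`) | 3 | patches per group on ring/random networks |
| `history` | 3 | memory window in timesteps; 0 = uninformed |
| `exploration` | 0.01 | per-group random-override probability |
| `sensitivity` | 3 | logistic offset; higher = remembered rewards dominate more |
| `timesteps` (`T`) | 300 | run length |
| `record_window` (`W`) | 30 | final timesteps used for metrics (10% of `T`) |

The defaults are the study conditions of the resource-matched environment:
`N_P = N_G`, `R = n`, so perfect partitioning feeds everyone. Resource-poor
variants are plain configuration (`n_patches < n_groups`, or
`patch_resources < group_size`), not separate code paths.

### Access networks

The ring network anchors group `g` to patch `g` (a bijection between groups
and patches) and grants it the `N'_P` contiguous patches centred there,
modulo `N_P`; `N'_P` must be odd so the window is symmetric. The choice of
centring is a convention the model leaves open; the bijective one matches
the one-group-per-patch layout the environment defaults imply. The random
network performs `floor(E/2)` sequential swaps (`E` = total edges): each
swap picks a uniformly random existing group–patch edge from the *current*
network and moves it to a uniformly random patch that group cannot yet
reach. Group degrees are conserved exactly; patch degrees are not, and
patches may become unreachable — intentionally, since that is what
distinguishes random from ring access. In sweeps, each replicate draws its
own random network; a fixed network can be reused by passing a pre-built
initial state to `run_simulation`.

## Metrics

Patch preference and resource partitioning are normalized Shannon
entropies (natural log; the base cancels after normalization, which a test
verifies). Preference is `1 − H/log N'_P` of one group's visit proportions
over the recording window, normalized by that group's own access-list size
(on full networks, `N_P`); the degenerate single-option group (`N'_P = 1`)
is defined as preference 1. Partitioning is `H/log N_P` of the
groups-over-patches distribution computed within each timestep and then
averaged over the window — the per-timestep-then-mean order matters and the
pooled-window alternative is deliberately not used, since pooling would hide
timesteps in which groups pile onto one patch. Foraging success is the mean
over individuals of the proportion of recorded timesteps with a reward;
with `R = n` it equals `R × mean distinct chosen patches / (N_G · n)`,
an identity used as an engine cross-check. Agreement is the mean modal
preference share. The *tendency* summary is the proportion of replicates
with preference ≥ 0.5 or partitioning ≥ 0.9 (inclusive).

## Reference (null) model

Every condition is paired with the identical configuration run at
`history = 0`, which makes every preference draw uniform (behaviourally
equivalent to exploring on every decision, so the exploration rate is left
untouched). Paired runs share the replicate seed, hence the same network
realization, so informed-vs-reference contrasts isolate the decision rule.

## Reproducibility

One `numpy.random.Generator`, seeded with the config seed, drives an entire
run. Draws are consumed in a fixed documented order (network construction
first for random networks; then per timestep: groups in index order with
member preference draws in member order, tie-break, exploration; then
allocation in ascending patch order). Sweep replicate seeds are
`crc32(combination_key | replicate) XOR base_seed`, masked below `2^31`, so
results are independent of worker count and execution order. Exploration
consumes its Bernoulli draw even at rate 0, keeping streams aligned across
exploration rates.

## Design choices in open territory

- **Group-size grid.** The published design used 37 group sizes from 1 to
  93; the exact interior values are not printed. The default grid is
  `[1] + odd 3…55 + 61, 65, …, 93` — dense where the behavioural
  transitions occur, sparser above — and is overridable per sweep.
- **Partitioned start.** "Start from maximal partitioning" is implemented
  as memory pre-fill: a perfect group-to-patch matching is found on the
  access network (Hopcroft–Karp via networkx; an error if none exists) and
  every member's memory is filled with `history` rewarded visits to the
  assigned patch. Forcing first choices instead of pre-filling memory would
  be an alternative reading; pre-fill was chosen because it uses only the
  model's own state, not a special-cased first timestep.
- **Walkthrough fixture.** The deterministic two-group demonstration
  searches seeds in ascending order for a run realizing a canonical
  narrative (both groups collide, one later explores away and preferences
  diverge), rather than hard-coding generator internals.

## What the simulations do and do not show

All inputs are synthetic by construction — the model *is* the study system.
The simulator emulates scramble competition sensed purely through own
foraging outcomes; it contains no contest competition, dominance, social
learning, movement costs, patch depletion across timesteps, or unequal
group members. Passing tests therefore demonstrate properties of this
idealized process, not of any field system: they show that memory plus
majority aggregation *can* generate stable partitioning, and under which
parameter regimes, but say nothing about whether real populations achieve
the assumed information privacy or group cohesion.

## Problem sizes used in the test suite

Unit tests run micro-configurations (≤ 9 groups, ≤ 50 timesteps).
The behavioural checks use a 7-group ring with 25 paired replicates at group
sizes 1 and 11 (sign tests at α = 0.01), 10 replicates for the
partitioned-start stability check, 10⁴ timesteps for the two-group
uninformed closed form (expected success 0.75), and 10⁵ draws for
tie-break/exploration frequency oracles. The acceptance script measures the
realized exploration rate over 100 replicates of the default 7×3 ring batch
(210,000 group decisions). These sizes give the sign tests and 3-standard-
error bands comfortable resolving power for the contrasts they check.
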