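"""Factorial parameter sweeps, the uninformed reference model, and summaries.

A sweep enumerates the cross-product of parameter axes (network type,
population size, group size, memory, exploration, ...), runs a configurable
number of seeded replicates per combination, and for every replicate also
runs a *reference model*: the identical configuration with ``history = 0``,
so every choice is uninformed and uniform.  The paired reference run shares
the replicate's seed, so the informed-vs-reference contrast isolates the
effect of memory-based decision-making from the realized network and
allocation randomness.

Replicate seeds are derived from ``base_seed`` and a stable hash of the
combination and replicate index, so results are reproducible and
independent of worker count or execution order.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .engine import SimConfig, run_simulation
from .errors import InvalidConfigurationError
from .metrics import (
    PARTITIONING_THRESHOLD,
    PREFERENCE_THRESHOLD,
    tendency,
)

__all__ = [
    "SweepSpec",
    "reference_config",
    "replicate_seed",
    "default_group_sizes",
    "run_replicate",
    "run_sweep",
    "summarize",
]

_COMBO_COLUMNS = [
    "network",
    "n_groups",
    "n_patches",
    "group_size",
    "n_accessible",
    "history",
    "exploration",
    "patch_resources",
]
_METRIC_COLUMNS = [
    "patch_preference_mean",
    "resource_partitioning",
    "foraging_success",
    "agreement",
]
MANIFEST_NAME = "sweep_manifest.json"
RESULTS_NAME = "results.csv"


def reference_config(config: SimConfig) -> SimConfig:
    """The uninformed null model paired with ``config``: ``history = 0``
    (equivalent to exploring on every decision), all else unchanged."""
    return replace(config, history=0)


def default_group_sizes() -> list[int]:
    """The default 37-value group-size grid: 1 plus odd sizes from 3 to 93,
    dense at small sizes (every odd value up to 55) and sparser beyond
    (every fourth value from 61).  The grid endpoints and length match the
    study design; the interior spacing is this package's reconstruction and
    can be overridden in a :class:`SweepSpec`."""
    return [1] + list(range(3, 56, 2)) + list(range(61, 94, 4))


def replicate_seed(base_seed: int, combo_key: str, replicate: int) -> int:
    """Stable per-replicate seed below 2**31, derived from the base seed and
    a hash of the combination key and replicate index."""
    digest = zlib.crc32(f"{combo_key}|r={replicate}".encode())
    return (digest ^ (base_seed & 0xFFFFFFFF)) & 0x7FFFFFFF


@dataclass(frozen=True)
class SweepSpec:
    """Axes of a factorial sweep over :class:`SimConfig` parameters.

    Every combination of the listed axis values is run for ``replicates``
    seeded replicates, each paired with a reference-model run.  ``n_patches``
    and ``patch_resources`` axes of ``None`` take the model defaults
    (``n_patches = n_groups``, ``patch_resources = group_size``).
    """

    network_types: tuple[str, ...] = ("full", "ring", "random")
    n_groups: tuple[int, ...] = (7,)
    group_sizes: tuple[int, ...] = field(default_factory=lambda: tuple(default_group_sizes()))
    n_accessible: tuple[int, ...] = (3,)
    history: tuple[int, ...] = (3,)
    exploration: tuple[float, ...] = (0.01,)
    n_patches: tuple[int | None, ...] = (None,)
    patch_resources: tuple[int | None, ...] = (None,)
    timesteps: int = 300
    record_window: int = 30
    sensitivity: float = 3.0
    replicates: int = 100
    base_seed: int = 0

    def combinations(self) -> Iterator[dict]:
        """Enumerate axis combinations deterministically (row-major over the
        field order above)."""
        for network in self.network_types:
            for n_g in self.n_groups:
                for n_p in self.n_patches:
                    for size in self.group_sizes:
                        for n_acc in self.n_accessible:
                            for hist in self.history:
                                for explo in self.exploration:
                                    for res in self.patch_resources:
                                        yield {
                                            "network": network,
                                            "n_groups": n_g,
                                            "n_patches": n_p if n_p is not None else n_g,
                                            "group_size": size,
                                            "n_accessible": n_acc,
                                            "history": hist,
                                            "exploration": explo,
                                            "patch_resources": res if res is not None else size,
                                        }

    def config_for(self, combo: dict, seed: int) -> SimConfig:
        return SimConfig(
            n_groups=combo["n_groups"],
            group_size=combo["group_size"],
            network_type=combo["network"],
            n_patches=combo["n_patches"],
            n_accessible=combo["n_accessible"],
            history=combo["history"],
            exploration=combo["exploration"],
            patch_resources=combo["patch_resources"],
            timesteps=self.timesteps,
            record_window=self.record_window,
            sensitivity=self.sensitivity,
            seed=seed,
        )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _combo_key(combo: dict) -> str:
    return "|".join(f"{k}={combo[k]}" for k in _COMBO_COLUMNS)


def run_replicate(spec: SweepSpec, combo: dict, replicate: int) -> list[dict]:
    """Run one informed replicate and its paired reference run; return the
    two metric rows."""
    seed = replicate_seed(spec.base_seed, _combo_key(combo), replicate)
    rows = []
    for model, config in (
        ("informed", spec.config_for(combo, seed)),
        ("reference", reference_config(spec.config_for(combo, seed))),
    ):
        result = run_simulation(config)
        rows.append(
            {
                **combo,
                "model": model,
                "replicate": replicate,
                "seed": seed,
                **result.metrics.to_dict(),
            }
        )
    return rows


def _row_key(row: dict) -> tuple:
    return (_combo_key(row), row["model"], row["replicate"])


def run_sweep(
    spec: SweepSpec,
    workers: int = 1,
    out_dir: str | Path | None = None,
    resume: bool = False,
    overwrite: bool = False,
) -> pd.DataFrame:
    """Run every combination x replicate of ``spec`` (informed + paired
    reference) and return one metrics row per run.

    Output is sorted and byte-stable for a given ``base_seed`` regardless of
    ``workers``.  With ``out_dir`` set, writes ``results.csv`` plus a
    manifest recording the spec; ``resume=True`` skips rows already present
    in a manifest-backed output, while a results file without a manifest is
    refused unless ``overwrite=True``.
    """
    tasks = [
        (combo, r)
        for combo in spec.combinations()
        for r in range(spec.replicates)
    ]
    done: set[tuple] = set()
    previous = pd.DataFrame()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        results_path = out_dir / RESULTS_NAME
        manifest_path = out_dir / MANIFEST_NAME
        if results_path.exists():
            if not manifest_path.exists() and not overwrite:
                raise InvalidConfigurationError(
                    f"{results_path} exists without a manifest; refusing to "
                    "resume (pass overwrite=True to start over)"
                )
            if resume and manifest_path.exists():
                previous = pd.read_csv(results_path)
                done = {_row_key(row) for row in previous.to_dict("records")}
    pending = [
        (combo, r) for combo, r in tasks
        if (_combo_key(combo), "informed", r) not in done
        or (_combo_key(combo), "reference", r) not in done
    ]
    if workers > 1:
        chunks = Parallel(n_jobs=workers)(
            delayed(run_replicate)(spec, combo, r) for combo, r in pending
        )
    else:
        chunks = [run_replicate(spec, combo, r) for combo, r in pending]
    rows = [row for chunk in chunks for row in chunk]
    new = pd.DataFrame(rows)
    frames = [df for df in (previous, new) if not df.empty]
    results = pd.concat(frames, ignore_index=True) if frames else new
    if not results.empty:
        results = results.sort_values(
            _COMBO_COLUMNS + ["model", "replicate"], ignore_index=True
        )
        # drop rows duplicated by a resume of a partially-written file
        results = results.drop_duplicates(
            subset=_COMBO_COLUMNS + ["model", "replicate"], ignore_index=True
        )
    if out_dir is not None:
        results.to_csv(out_dir / RESULTS_NAME, index=False)
        (Path(out_dir) / MANIFEST_NAME).write_text(
            json.dumps({"spec": spec.to_dict()}, indent=2)
        )
    return results


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Per-combination summary: metric means and SDs across informed
    replicates, preference/partitioning tendencies, and the paired
    reference-model means.

    SD is left missing for single-replicate combinations.
    """
    if results.empty:
        raise ValueError("results table is empty")
    out = []
    for key, df in results.groupby(_COMBO_COLUMNS, sort=True):
        informed = df[df["model"] == "informed"]
        ref = df[df["model"] == "reference"]
        row = dict(zip(_COMBO_COLUMNS, key))
        row["replicates"] = len(informed)
        for col in _METRIC_COLUMNS:
            row[f"{col}_mean"] = informed[col].mean()
            row[f"{col}_sd"] = informed[col].std(ddof=1)
            row[f"{col}_ref_mean"] = ref[col].mean() if len(ref) else np.nan
        row["tendency_preference"] = tendency(
            informed["patch_preference_mean"], PREFERENCE_THRESHOLD
        )
        row["tendency_partitioning"] = tendency(
            informed["resource_partitioning"], PARTITIONING_THRESHOLD
        )
        out.append(row)
    return pd.DataFrame(out)


def plot_group_size_trend(summary: pd.DataFrame, metric: str = "patch_preference_mean", ax=None):
    """Quickstart plot: mean metric vs group size, one line per network type,
    dashed lines for the paired reference model.  Requires matplotlib."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for network, df in summary.groupby("network"):
        df = df.sort_values("group_size")
        line, = ax.plot(df["group_size"], df[f"{metric}_mean"], label=network)
        ax.plot(
            df["group_size"], df[f"{metric}_ref_mean"],
            linestyle="--", color=line.get_color(), alpha=0.6,
        )
    ax.set_xlabel("group size")
    ax.set_ylabel(metric.replace("_", " "))
    ax.legend(title="network (dashed: uninformed)")
    return ax
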