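"""Random forests of perfect trees.

A forest repeatedly draws a feature subset of fixed size, grows one tree on
ALL observations (no bootstrap — resampling would weight observations), and
keeps drawing until every feature has been selected into at least
``min_instances_per_feature`` trees (default 100). Only trees that reach an
error-free classification contribute to the per-feature event counters;
imperfect trees still count toward the selection quota.

Three drawing modes exist. STANDARD draws each tree's features uniformly
without replacement from the whole pool; ADJUSTED is the same drawing used
as a confirmation design with more features per neuron (2, 3 or 15);
STRATIFIED builds each tree from exactly one feature of a previously
selected set plus ``n - 1`` features from the unselected pool.

Randomness: one master seed; tree number ``i`` gets the generator seeded by
``(seed, i)``, so the subset drawn for a given tree never depends on worker
scheduling and parallel runs reproduce the serial tally bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator, Optional, Sequence
import warnings

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .dataset import Dataset
from .tree import (
    SignProfile,
    SolutionClass,
    TreeConfig,
    TreeResult,
    grow_tree,
)

#: Column order of the per-feature tally table; the ten event counters are
#: the numerators of the NIC ratios.
TALLY_COLUMNS = (
    "times_selected",
    "perfect_trees",
    "all_zero",
    "all_positive",
    "all_negative",
    "non_monotone",
    "two_neuron_perfect",
    "one_neuron_perfect",
    "enumerable_solutions",
    "unique_solution",
)


class ForestMode(Enum):
    STANDARD = "standard"
    ADJUSTED = "adjusted"
    STRATIFIED = "stratified"


@dataclass(frozen=True)
class ForestConfig:
    """Forest-level parameters.

    ``max_trees`` defaults to ``10 * quota * n_features`` as a runaway guard
    when the quota cannot be reached. ``selected_features`` is required in
    STRATIFIED mode and must be disjoint from the rest of the pool.
    """

    n_features_per_neuron: int = 1
    min_instances_per_feature: int = 100
    tree_config: TreeConfig = None
    seed: int = 0
    mode: ForestMode = ForestMode.STANDARD
    selected_features: Optional[tuple] = None
    max_trees: Optional[int] = None

    def __post_init__(self):
        if self.min_instances_per_feature < 1:
            raise ValueError("min_instances_per_feature must be >= 1")
        if self.tree_config is None:
            object.__setattr__(
                self,
                "tree_config",
                TreeConfig(n_features_per_neuron=self.n_features_per_neuron),
            )
        elif self.tree_config.n_features_per_neuron != self.n_features_per_neuron:
            raise ValueError("tree_config feature count disagrees with forest config")
        if self.mode is ForestMode.STRATIFIED:
            if not self.selected_features:
                raise ValueError("STRATIFIED mode needs a nonempty selected feature set")
            object.__setattr__(
                self, "selected_features", tuple(int(f) for f in self.selected_features)
            )

    def effective_max_trees(self, n_features_total: int) -> int:
        if self.max_trees is not None:
            return self.max_trees
        return 10 * self.min_instances_per_feature * n_features_total


def _tree_rng(seed: int, tree_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, tree_index]))


def _draw_subset(config: ForestConfig, n_features_total: int, tree_index: int) -> np.ndarray:
    rng = _tree_rng(config.seed, tree_index)
    n = config.n_features_per_neuron
    if config.mode is ForestMode.STRATIFIED:
        sel = np.asarray(config.selected_features, dtype=np.intp)
        pool = np.setdiff1d(np.arange(n_features_total, dtype=np.intp), sel)
        if n - 1 > pool.size:
            raise ValueError("unselected pool smaller than n_features_per_neuron - 1")
        one = rng.choice(sel, size=1)
        rest = rng.choice(pool, size=n - 1, replace=False)
        return np.concatenate([one, rest])
    return rng.choice(n_features_total, size=n, replace=False)


def plan_forest(
    n_features_total: int, config: ForestConfig
) -> Iterator[np.ndarray]:
    """Stream of per-tree feature subsets, stopping once every feature has
    met the selection quota (or at ``max_trees``, with a warning)."""
    if config.n_features_per_neuron > n_features_total:
        raise ValueError("more features per neuron than features in the pool")
    counts = np.zeros(n_features_total, dtype=np.int64)
    quota = config.min_instances_per_feature
    cap = config.effective_max_trees(n_features_total)
    i = 0
    while (counts < quota).any():
        if i >= cap:
            warnings.warn(
                f"selection quota unreachable within max_trees={cap}; "
                f"{int((counts < quota).sum())} features below quota",
                stacklevel=2,
            )
            return
        subset = _draw_subset(config, n_features_total, i)
        counts[subset] += 1
        i += 1
        yield subset


def expected_selections_per_feature(
    n_trees: int, n_features_per_neuron: int, n_features_total: int
) -> float:
    """Mean number of times a feature is drawn into a tree, by slot counting:
    ``n_trees * n_features_per_neuron / n_features_total``."""
    if n_features_total <= 0:
        raise ValueError("feature pool must be nonempty")
    return n_trees * n_features_per_neuron / n_features_total


def minimum_tree_count(
    n_features_total: int, n_features_per_neuron: int, quota: int
) -> int:
    """Smallest conceivable tree count meeting the quota (slot counting)."""
    return math.ceil(quota * n_features_total / n_features_per_neuron)


def _tally_tree(result: TreeResult, tally: np.ndarray) -> None:
    """Add one tree's events to the counter matrix (features x columns)."""
    feats = np.asarray(result.feature_indices, dtype=np.intp)
    tally[feats, 0] += 1
    if not result.is_perfect:
        return
    tally[feats, 1] += 1
    profile = result.sign_profile
    col = {
        SignProfile.ALL_ZERO: 2,
        SignProfile.ALL_POSITIVE: 3,
        SignProfile.ALL_NEGATIVE: 4,
        SignProfile.NON_MONOTONE: 5,
    }.get(profile)
    if col is not None:  # MIXED_WITH_ZERO enters no sign counter
        tally[feats, col] += 1
    if result.neurons_used <= 2:
        tally[feats, 6] += 1
    if result.neurons_used == 1:
        tally[feats, 7] += 1
    sol = result.solution_class
    if sol in (SolutionClass.UNIQUE, SolutionClass.FINITE):
        tally[feats, 8] += 1
    if sol is SolutionClass.UNIQUE:
        tally[feats, 9] += 1


def _grow_chunk(data, config, subsets, start_index, collect_log):
    tally = np.zeros((data.n_features, len(TALLY_COLUMNS)), dtype=np.int64)
    records = [] if collect_log else None
    for offset, subset in enumerate(subsets):
        rng = _tree_rng(config.seed, start_index + offset)
        result = grow_tree(data, subset, config.tree_config, rng=rng)
        _tally_tree(result, tally)
        if collect_log:
            records.append(result.to_record())
    return tally, records


def build_forest(
    data: Dataset,
    config: ForestConfig,
    n_jobs: int = 1,
    collect_log: bool = False,
    progress_every: int = 100_000,
    logger=None,
):
    """Grow the whole forest and return ``(tally, tree_log)``.

    ``tally`` is a DataFrame indexed by feature name with the columns of
    :data:`TALLY_COLUMNS`; ``tree_log`` is a list of JSON-serializable tree
    records (``None`` unless ``collect_log``). The result is identical for
    any ``n_jobs`` because each tree's randomness is keyed by its index and
    integer tallies are summed in tree order.
    """
    data.require_both_classes()
    subsets = list(plan_forest(data.n_features, config))
    if logger is not None:
        logger.info("forest plan: %d trees over %d features", len(subsets), data.n_features)
    chunk = max(1, min(len(subsets), progress_every if n_jobs == 1 else math.ceil(len(subsets) / (4 * n_jobs))))
    chunks = [
        (subsets[i : i + chunk], i) for i in range(0, len(subsets), chunk)
    ]
    if n_jobs == 1:
        parts = []
        done = 0
        for sub, start in chunks:
            parts.append(_grow_chunk(data, config, sub, start, collect_log))
            done += len(sub)
            if logger is not None and done % progress_every < chunk:
                logger.info("grew %d / %d trees", done, len(subsets))
    else:
        parts = Parallel(n_jobs=n_jobs)(
            delayed(_grow_chunk)(data, config, sub, start, collect_log)
            for sub, start in chunks
        )
    tally = np.zeros((data.n_features, len(TALLY_COLUMNS)), dtype=np.int64)
    records = [] if collect_log else None
    for part_tally, part_records in parts:
        tally += part_tally
        if collect_log:
            records.extend(part_records)
    frame = pd.DataFrame(tally, index=list(data.feature_names), columns=list(TALLY_COLUMNS))
    frame.index.name = "feature"
    return frame, records


def check_tally_invariants(tally: pd.DataFrame) -> None:
    """Raise AssertionError if any counter relation is violated."""
    t = tally
    assert (t["perfect_trees"] <= t["times_selected"]).all()
    for col in TALLY_COLUMNS[2:]:
        assert (t[col] <= t["perfect_trees"]).all(), col
    assert (
        t["all_zero"] + t["all_positive"] + t["all_negative"] + t["non_monotone"]
        <= t["perfect_trees"]
    ).all()
    assert (t["one_neuron_perfect"] <= t["two_neuron_perfect"]).all()
    assert (t["unique_solution"] <= t["enumerable_solutions"]).all()
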