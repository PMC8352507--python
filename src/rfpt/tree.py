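"""Growth of a single perfect tree with neuron nodes.

The tree has a "half Christmas tree" architecture: at each node one side of
the neuron's dichotomy is *finalized* (those samples leave the tree with
their predicted label, which must be error-free) while the other side is
reinjected into the trunk and handed to the next neuron. Steps alternate
polarity — finalize the predicted negatives, then the predicted positives —
and one negative + one positive step form a cycle; the default budget of
three cycles caps the tree at six neurons, with no pruning. Whenever some
admissible neuron classifies the whole surviving set without error, it is
applied as a terminal both-sides node and the tree is *perfect*: 100%
sensitivity and specificity on the training observations.

Each step searches every coefficient vector in the configured range and
every achievable dichotomy of the active samples (thresholds at midpoints
between consecutive distinct projection scores, plus one below the minimum
and one above the maximum). The step keeps the candidate that finalizes the
most samples without a single false finalization, and records how many
distinct coefficient vectors attain that optimum — the raw material of the
solution-multiplicity criteria. A tree whose every node admits every vector
(or that contains a node finalizing nothing) has an unconstrained solution
set; otherwise the tree's multiplicity is the product of per-node optima
counts, and a product of one is a unique solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .dataset import Dataset
from .neuron import (
    DEFAULT_COEFFICIENT_RANGE,
    NeuronSpec,
    StepPolicy,
    enumerate_coefficient_vectors,
)

#: Marker for a step where every enumerated coefficient vector is optimal —
#: the solution set is not constrained by the data ("infinite" solutions).
UNCONSTRAINED = math.inf


class SearchMode(Enum):
    EXHAUSTIVE_GREEDY = "exhaustive_greedy"
    FULL_ENUMERATION = "full_enumeration"
    SAMPLED_HEURISTIC = "sampled_heuristic"


class SignProfile(Enum):
    ALL_ZERO = "all_zero"
    ALL_POSITIVE = "all_positive"
    ALL_NEGATIVE = "all_negative"
    NON_MONOTONE = "non_monotone"
    MIXED_WITH_ZERO = "mixed_with_zero"


class SolutionClass(Enum):
    UNIQUE = "unique"
    FINITE = "finite"
    UNCONSTRAINED = "unconstrained"


class InvalidStateError(RuntimeError):
    pass


@dataclass(frozen=True)
class TreeConfig:
    """Growth parameters of a single tree.

    ``max_cycles * steps_per_cycle`` bounds the neuron count (default 3 x 2
    = 6). ``SAMPLED_HEURISTIC`` replaces the exhaustive per-node vector
    enumeration with ``n_sampled_vectors`` distinct random vectors; it is
    NOT exhaustive and its solution counts are lower bounds relative to the
    sampled pool only — intended for neurons with many features where
    |range|^n is out of reach.
    """

    n_features_per_neuron: int = 1
    max_cycles: int = 3
    steps_per_cycle: int = 2
    coefficient_range: tuple = DEFAULT_COEFFICIENT_RANGE
    search_mode: SearchMode = SearchMode.EXHAUSTIVE_GREEDY
    n_sampled_vectors: int = 2048

    @property
    def max_steps(self) -> int:
        return self.max_cycles * self.steps_per_cycle


@dataclass
class StepFit:
    """Outcome of fitting one neuron on the current active set."""

    neuron: NeuronSpec
    finalized_indices: np.ndarray  # global sample indices
    assigned_labels: np.ndarray    # labels given to the finalized samples
    n_optimal_vectors: float       # int count, or UNCONSTRAINED


@dataclass
class TreeResult:
    """A grown tree: fitted neurons, finalized sets and summary flags."""

    feature_indices: tuple
    neurons: list
    finalized: list                # list of (indices ndarray, labels ndarray)
    per_neuron_solution_count: list
    is_perfect: bool
    n_samples: int

    @property
    def neurons_used(self) -> int:
        return len(self.neurons)

    @property
    def sign_profile(self) -> SignProfile:
        return sign_profile(self)

    @property
    def solution_class(self) -> Optional[SolutionClass]:
        if not self.is_perfect:
            return None
        return count_solutions(self)

    @property
    def solution_multiplicity(self) -> float:
        """Product of per-neuron optimum counts (inf when unconstrained)."""
        out = 1.0
        for c in self.per_neuron_solution_count:
            out *= c
        return out

    def to_record(self) -> dict:
        """JSON-serializable one-line log record for this tree."""
        return {
            "features": [int(f) for f in self.feature_indices],
            "neurons": [
                {
                    "coefficients": list(n.coefficients),
                    "threshold": float(n.threshold),
                    "policy": n.policy.value,
                }
                for n in self.neurons
            ],
            "finalized_counts": [int(len(idx)) for idx, _ in self.finalized],
            "is_perfect": bool(self.is_perfect),
            "neurons_used": self.neurons_used,
            "sign_profile": self.sign_profile.value,
            "solution_class": self.solution_class.value if self.is_perfect else None,
            "solution_counts": [
                None if math.isinf(c) else int(c)
                for c in self.per_neuron_solution_count
            ],
        }


# ---------------------------------------------------------------------------
# per-vector dichotomy search


def _boundary_threshold(ss: np.ndarray, b: int) -> float:
    """Threshold realizing the split 'first b sorted samples negative'."""
    m = ss.shape[0]
    if b == 0:
        return float(ss[0] - 1.0)
    if b == m:
        return float(ss[-1] + 1.0)
    return float((ss[b - 1] + ss[b]) / 2.0)


def _max_pure_negative_prefix(ss: np.ndarray, ys: np.ndarray) -> int:
    """Largest group-aligned boundary p with ys[:p] all 0."""
    m = ys.shape[0]
    ones = np.flatnonzero(ys == 1)
    p = int(ones[0]) if ones.size else m
    # pull back to a boundary between distinct scores
    while 0 < p < m and ss[p - 1] == ss[p]:
        p -= 1
    return p


def _max_pure_positive_suffix(ss: np.ndarray, ys: np.ndarray) -> int:
    """Smallest group-aligned boundary b with ys[b:] all 1."""
    m = ys.shape[0]
    zeros = np.flatnonzero(ys == 0)
    b = int(zeros[-1]) + 1 if zeros.size else 0
    while 0 < b < m and ss[b - 1] == ss[b]:
        b += 1
    return b


def _perfect_split_boundary(ss: np.ndarray, ys: np.ndarray) -> Optional[int]:
    """Boundary separating all true 0s below from all true 1s above, if the
    vector's score ordering admits one."""
    m = ys.shape[0]
    n0 = int(np.count_nonzero(ys == 0))
    ones = np.flatnonzero(ys == 1)
    lead0 = int(ones[0]) if ones.size else m
    if lead0 != n0:  # a 0 sits above a 1 in score order
        return None
    if 0 < n0 < m and ss[n0 - 1] == ss[n0]:  # boundary inside a tie group
        return None
    return n0


def _candidate_vectors(config: TreeConfig, rng: Optional[np.random.Generator]) -> np.ndarray:
    n = config.n_features_per_neuron
    k = len(np.unique(np.asarray(config.coefficient_range, dtype=float)))
    total = k**n
    if config.search_mode is SearchMode.SAMPLED_HEURISTIC and total > config.n_sampled_vectors:
        if rng is None:
            rng = np.random.default_rng(0)
        vals = np.unique(np.asarray(config.coefficient_range, dtype=float))
        # rejection sampling of distinct vector indices; avoids materializing
        # the k^n permutation for large n
        chosen: set = set()
        while len(chosen) < config.n_sampled_vectors:
            need = config.n_sampled_vectors - len(chosen)
            chosen.update(rng.integers(0, total, size=2 * need).tolist())
        idx = np.sort(np.fromiter(chosen, dtype=np.int64)[: config.n_sampled_vectors])
        digits = np.empty((idx.size, n), dtype=np.int64)
        rem = idx.copy()
        for j in range(n - 1, -1, -1):
            digits[:, j] = rem % k
            rem //= k
        return vals[digits]
    return enumerate_coefficient_vectors(n, config.coefficient_range)


def _fit_step_arrays(
    Xa: np.ndarray,
    ya: np.ndarray,
    active: np.ndarray,
    policy: StepPolicy,
    vectors: np.ndarray,
) -> StepFit:
    """Best admissible neuron for one step on the active rows ``Xa``/``ya``.

    ``active`` holds the global indices of the rows, used to report the
    finalized set in the caller's coordinates.
    """
    m = ya.shape[0]
    scores = Xa @ vectors.T  # (m, n_vectors)
    best_count = -1
    best = None  # (vec_idx, order, boundary)
    n_best = 0
    for j in range(vectors.shape[0]):
        s = scores[:, j]
        order = np.argsort(s, kind="stable")
        ss = s[order]
        ys = ya[order]
        if policy is StepPolicy.FINALIZE_NEGATIVE:
            p = _max_pure_negative_prefix(ss, ys)
            count = p
        elif policy is StepPolicy.FINALIZE_POSITIVE:
            b = _max_pure_positive_suffix(ss, ys)
            count = m - b
            p = b
        else:  # FINALIZE_BOTH: only an error-free full split is admissible
            b = _perfect_split_boundary(ss, ys)
            if b is None:
                continue
            count = m
            p = b
        if count > best_count:
            best_count = count
            best = (j, order, p)
            n_best = 1
        elif count == best_count:
            n_best += 1
    if best is None:
        raise InvalidStateError("no admissible neuron for FINALIZE_BOTH step")
    j, order, p = best
    s = scores[:, j]
    ss = s[order]
    threshold = _boundary_threshold(ss, p)
    if policy is StepPolicy.FINALIZE_NEGATIVE:
        local = order[:p]
        labels = np.zeros(local.size, dtype=np.int8)
    elif policy is StepPolicy.FINALIZE_POSITIVE:
        local = order[p:]
        labels = np.ones(local.size, dtype=np.int8)
    else:
        local = order
        labels = np.concatenate(
            [np.zeros(p, dtype=np.int8), np.ones(m - p, dtype=np.int8)]
        )
    n_opt = UNCONSTRAINED if n_best == vectors.shape[0] else float(n_best)
    neuron = NeuronSpec(tuple(vectors[j]), threshold, policy)
    return StepFit(neuron, np.asarray(active)[local], labels, n_opt)


def _has_perfect_split(Xa, ya, vectors) -> bool:
    scores = Xa @ vectors.T
    for j in range(vectors.shape[0]):
        s = scores[:, j]
        order = np.argsort(s, kind="stable")
        if _perfect_split_boundary(s[order], ya[order]) is not None:
            return True
    return False


# ---------------------------------------------------------------------------
# public operations


def fit_neuron_step(
    data: Dataset,
    features: Sequence[int],
    active: Sequence[int],
    policy: StepPolicy,
    config: TreeConfig,
    rng: Optional[np.random.Generator] = None,
) -> StepFit:
    """Fit the single best admissible neuron for one finalization step.

    Under ``FINALIZE_NEGATIVE`` the predicted-negative samples are finalized
    with label 0 and the candidate is admissible only if they are all truly
    class 0 (symmetrically for ``FINALIZE_POSITIVE``); among admissible
    candidates the one finalizing the most samples wins, ties broken to the
    lexicographically smallest coefficient vector. An empty finalization is
    a legal outcome. ``n_optimal_vectors`` reports how many distinct vectors
    attain the optimum, or :data:`UNCONSTRAINED` when all of them do.
    """
    active = np.asarray(active, dtype=np.intp)
    if active.size == 0:
        raise ValueError("active sample set must be nonempty")
    feats = np.asarray(features, dtype=np.intp)
    vectors = _candidate_vectors(config, rng)
    Xa = data.X[np.ix_(active, feats)]
    ya = data.y[active]
    return _fit_step_arrays(Xa, ya, active, policy, vectors)


def grow_tree(
    data: Dataset,
    features: Sequence[int],
    config: TreeConfig,
    rng: Optional[np.random.Generator] = None,
) -> TreeResult:
    """Grow one tree over a fixed feature subset.

    Steps alternate FINALIZE_NEGATIVE / FINALIZE_POSITIVE on the shrinking
    active set; before each step, if some admissible neuron classifies the
    whole active set without error it is applied as a terminal
    FINALIZE_BOTH node. Neurons that finalize nothing still consume one of
    the ``max_steps`` slots. ``is_perfect`` is true iff the active set
    empties within the budget.

    With ``search_mode=FULL_ENUMERATION`` the greedy result is returned when
    perfect; otherwise an exhaustive search over all admissible
    (vector, dichotomy) sequences is attempted and any witness found is
    replayed into a :class:`TreeResult`.
    """
    feats = tuple(int(f) for f in features)
    if len(feats) == 0:
        raise ValueError("feature subset must be nonempty")
    if len(feats) != config.n_features_per_neuron:
        raise ValueError(
            f"{len(feats)} features given but config expects "
            f"{config.n_features_per_neuron} per neuron"
        )
    result = _grow_greedy(data, feats, config, rng)
    if config.search_mode is SearchMode.FULL_ENUMERATION and not result.is_perfect:
        witness = _search_exhaustive(data, feats, config)
        if witness is not None:
            return witness
    return result


def _grow_greedy(data, feats, config, rng) -> TreeResult:
    vectors = _candidate_vectors(config, rng)
    X = data.X[:, feats]
    y = data.y
    active = np.arange(data.n_samples, dtype=np.intp)
    neurons, finalized, counts = [], [], []
    for step in range(config.max_steps):
        Xa = X[active]
        ya = y[active]
        if _has_perfect_split(Xa, ya, vectors):
            fit = _fit_step_arrays(Xa, ya, active, StepPolicy.FINALIZE_BOTH, vectors)
            neurons.append(fit.neuron)
            finalized.append((fit.finalized_indices, fit.assigned_labels))
            counts.append(fit.n_optimal_vectors)
            active = np.empty(0, dtype=np.intp)
            break
        policy = (
            StepPolicy.FINALIZE_NEGATIVE if step % 2 == 0 else StepPolicy.FINALIZE_POSITIVE
        )
        fit = _fit_step_arrays(Xa, ya, active, policy, vectors)
        neurons.append(fit.neuron)
        finalized.append((fit.finalized_indices, fit.assigned_labels))
        counts.append(fit.n_optimal_vectors)
        if fit.finalized_indices.size:
            mask = np.ones(active.size, dtype=bool)
            # map global finalized back to positions in `active`
            pos = np.searchsorted(active, fit.finalized_indices)
            mask[pos] = False
            active = active[mask]
        if active.size == 0:
            break
    return TreeResult(
        feature_indices=feats,
        neurons=neurons,
        finalized=finalized,
        per_neuron_solution_count=counts,
        is_perfect=active.size == 0,
        n_samples=data.n_samples,
    )


def verify_perfect(result: TreeResult, truth: Sequence[int]) -> bool:
    """Independent re-check that a tree is perfect.

    Rebuilds the assignment from the finalized sets alone and requires full
    disjoint coverage with sensitivity and specificity both 1 against
    ``truth``. Does not consult the growth code path.
    """
    truth = np.asarray(truth)
    assigned = np.full(truth.shape[0], -1, dtype=np.int8)
    for idx, labels in result.finalized:
        idx = np.asarray(idx, dtype=np.intp)
        if idx.size == 0:
            continue
        if (assigned[idx] != -1).any():
            return False
        assigned[idx] = labels
    if (assigned == -1).any():
        return False
    tp = int(np.count_nonzero((assigned == 1) & (truth == 1)))
    tn = int(np.count_nonzero((assigned == 0) & (truth == 0)))
    fp = int(np.count_nonzero((assigned == 1) & (truth == 0)))
    fn = int(np.count_nonzero((assigned == 0) & (truth == 1)))
    sens = tp / (tp + fn) if (tp + fn) else 1.0
    spec = tn / (tn + fp) if (tn + fp) else 1.0
    return sens == 1.0 and spec == 1.0


def sign_profile(result: TreeResult) -> SignProfile:
    """Categorize the coefficient signs across all used neurons."""
    coefs = np.concatenate([np.asarray(n.coefficients) for n in result.neurons])
    has_pos = bool((coefs > 0).any())
    has_neg = bool((coefs < 0).any())
    has_zero = bool((coefs == 0).any())
    if not has_pos and not has_neg:
        return SignProfile.ALL_ZERO
    if has_pos and has_neg:
        return SignProfile.NON_MONOTONE
    if has_zero:
        return SignProfile.MIXED_WITH_ZERO
    return SignProfile.ALL_POSITIVE if has_pos else SignProfile.ALL_NEGATIVE


def count_solutions(result: TreeResult) -> SolutionClass:
    """Classify a perfect tree's solution multiplicity.

    The multiplicity is the product over used neurons of the number of
    coefficient vectors attaining that neuron's optimum (thresholds form
    continuous intervals and are never counted). Any unconstrained neuron
    makes the whole tree UNCONSTRAINED.
    """
    if not result.is_perfect:
        raise InvalidStateError("solution counting is defined for perfect trees only")
    if any(math.isinf(c) for c in result.per_neuron_solution_count):
        return SolutionClass.UNCONSTRAINED
    return (
        SolutionClass.UNIQUE
        if result.solution_multiplicity == 1
        else SolutionClass.FINITE
    )


# ---------------------------------------------------------------------------
# exhaustive search (test oracle)


def perfect_tree_exists(
    data: Dataset, features: Sequence[int], config: TreeConfig
) -> bool:
    """Exact existence check by depth-first search over every admissible
    (coefficient vector, dichotomy) sequence under the alternating policy
    schedule. Exponential; intended for small feature counts and sample
    sizes, as an oracle against the greedy grower."""
    return _search_exhaustive(data, tuple(int(f) for f in features), config) is not None


def _admissible_finalizations(ss, ys, order, policy):
    """All group-aligned error-free finalizations (local index arrays)."""
    m = ys.shape[0]
    out = []
    if policy is StepPolicy.FINALIZE_NEGATIVE:
        pmax = _max_pure_negative_prefix(ss, ys)
        for p in range(pmax + 1):
            if p == 0 or p == m or ss[p - 1] < ss[p]:
                out.append((order[:p], p))
    else:
        bmin = _max_pure_positive_suffix(ss, ys)
        for b in range(bmin, m + 1):
            if b == 0 or b == m or ss[b - 1] < ss[b]:
                out.append((order[b:], b))
    return out


def _search_exhaustive(data, feats, config) -> Optional[TreeResult]:
    vectors = enumerate_coefficient_vectors(
        config.n_features_per_neuron, config.coefficient_range
    )
    X = data.X[:, feats]
    y = data.y
    n = data.n_samples
    failed = set()

    def dfs(active: np.ndarray, step: int):
        key = (active.tobytes(), step)
        if key in failed:
            return None
        Xa = X[active]
        ya = y[active]
        # terminal both-sides node, checked before consuming the step
        if step < config.max_steps:
            fit_both = None
            scores = Xa @ vectors.T
            for j in range(vectors.shape[0]):
                s = scores[:, j]
                order = np.argsort(s, kind="stable")
                if _perfect_split_boundary(s[order], ya[order]) is not None:
                    fit_both = _fit_step_arrays(
                        Xa, ya, active, StepPolicy.FINALIZE_BOTH, vectors
                    )
                    break
            if fit_both is not None:
                return [fit_both]
            policy = (
                StepPolicy.FINALIZE_NEGATIVE
                if step % 2 == 0
                else StepPolicy.FINALIZE_POSITIVE
            )
            # children ordered largest finalization first
            seen_children = set()
            for j in range(vectors.shape[0]):
                s = scores[:, j]
                order = np.argsort(s, kind="stable")
                ss = s[order]
                ys = ya[order]
                for local, b in _admissible_finalizations(ss, ys, order, policy):
                    child = np.delete(active, np.sort(local)) if local.size else active
                    ckey = child.tobytes()
                    if ckey in seen_children:
                        continue
                    seen_children.add(ckey)
                    if child.size == 0 or (tail := dfs(child, step + 1)) is not None:
                        tail = tail if child.size else []
                        if policy is StepPolicy.FINALIZE_NEGATIVE:
                            labels = np.zeros(local.size, dtype=np.int8)
                        else:
                            labels = np.ones(local.size, dtype=np.int8)
                        threshold = _boundary_threshold(ss, b)
                        n_opt = _count_attaining(Xa, ya, vectors, policy, local.size)
                        fit = StepFit(
                            NeuronSpec(tuple(vectors[j]), threshold, policy),
                            active[np.sort(local)] if local.size else np.empty(0, dtype=np.intp),
                            labels,
                            n_opt,
                        )
                        return [fit] + tail
        failed.add(key)
        return None

    path = dfs(np.arange(n, dtype=np.intp), 0)
    if path is None:
        return None
    return TreeResult(
        feature_indices=feats,
        neurons=[f.neuron for f in path],
        finalized=[(f.finalized_indices, f.assigned_labels) for f in path],
        per_neuron_solution_count=[f.n_optimal_vectors for f in path],
        is_perfect=True,
        n_samples=n,
    )


def _count_attaining(Xa, ya, vectors, policy, count) -> float:
    """How many vectors admit an error-free finalization of ``count`` samples."""
    m = ya.shape[0]
    scores = Xa @ vectors.T
    n_att = 0
    for j in range(vectors.shape[0]):
        s = scores[:, j]
        order = np.argsort(s, kind="stable")
        ss = s[order]
        ys = ya[order]
        if policy is StepPolicy.FINALIZE_NEGATIVE:
            ok = _max_pure_negative_prefix(ss, ys) >= count
        else:
            ok = m - _max_pure_positive_suffix(ss, ys) >= count
        n_att += bool(ok)
    return UNCONSTRAINED if n_att == vectors.shape[0] else float(n_att)
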