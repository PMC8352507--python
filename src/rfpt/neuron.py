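"""Ternary-weight neuron arithmetic.

A node of a perfect tree is a linear threshold unit whose coefficients are
restricted to a small finite range, {-1, 0, +1} by default: each of the
node's n features contributes positively, negatively or not at all, and a
sample is called positive when its projection score exceeds the node's
threshold. Restricting the weights keeps the per-node search finite
(|range|^n candidate vectors) and the fitted effects directly readable as
risk-increasing / risk-decreasing / inert.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum

import numpy as np

#: Default simulation range for node coefficients.
DEFAULT_COEFFICIENT_RANGE = (-1.0, 0.0, 1.0)


class StepPolicy(Enum):
    """Which side of a node's dichotomy is finalized (removed from the
    trunk) at this step of tree growth."""

    FINALIZE_NEGATIVE = "finalize_negative"
    FINALIZE_POSITIVE = "finalize_positive"
    FINALIZE_BOTH = "finalize_both"


@dataclass(frozen=True)
class NeuronSpec:
    """A fitted node: coefficient vector, threshold and step policy.

    ``coefficients`` has one entry per tree feature, each drawn from the
    configured coefficient range; a sample with projection score
    ``sum_j c_j x_ij`` strictly above ``threshold`` is predicted positive.
    """

    coefficients: tuple
    threshold: float
    policy: StepPolicy = StepPolicy.FINALIZE_BOTH

    def __post_init__(self):
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))


def enumerate_coefficient_vectors(n, values=DEFAULT_COEFFICIENT_RANGE) -> np.ndarray:
    """All |values|^n coefficient vectors over ``n`` features.

    Returns an ``(|values|^n, n)`` array in lexicographic order with
    ``values`` sorted ascending, so with the default range the first row is
    all ``-1`` and the last all ``+1``. ``n = 0`` yields the single empty
    vector.
    """
    if n < 0:
        raise ValueError(f"feature count must be non-negative, got {n}")
    vals = np.unique(np.asarray(values, dtype=float))
    if vals.size == 0:
        raise ValueError("coefficient range must be nonempty")
    if n == 0:
        return np.empty((1, 0), dtype=float)
    return np.array(list(itertools.product(vals, repeat=n)), dtype=float)


def projection_scores(coefficients, X: np.ndarray) -> np.ndarray:
    """Per-sample projection score ``s_i = sum_j c_j x_ij``."""
    return np.asarray(X, dtype=float) @ np.asarray(coefficients, dtype=float)


def neuron_predict(neuron: NeuronSpec, X: np.ndarray) -> np.ndarray:
    """Thresholded binary prediction for each row of ``X``.

    ``X`` is the data restricted to the tree's features (columns in the same
    order as the neuron's coefficients). Ties go negative: a score exactly
    equal to the threshold predicts 0.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(neuron.coefficients):
        raise ValueError(
            f"neuron has {len(neuron.coefficients)} coefficients but data has "
            f"{X.shape[1] if X.ndim == 2 else '?'} features"
        )
    if not np.isfinite(X).all():
        raise ValueError("missing value encountered in neuron input")
    s = projection_scores(neuron.coefficients, X)
    return (s > neuron.threshold).astype(np.int8)
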