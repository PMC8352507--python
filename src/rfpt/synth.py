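"""Reproducible synthetic datasets with planted feature archetypes.

The generator emulates the statistical shape of the method's target inputs
— a continuous (expression-array-like) feature table with a binary outcome
— while planting features whose forest behaviour is known in advance:

* ``SEPARABLE`` — class-conditional Gaussian shifted by ``delta`` with noise
  ``sigma``; at the default ``delta/sigma = 20`` the class ranges are
  disjoint with overwhelming probability at realistic sample sizes, so a
  single-feature neuron separates the classes in one node.
* ``MONOTONE_WEAK`` — the same construction with a small shift
  (``delta_weak``), informative but rarely perfectly separating.
* ``PARADOXICAL`` — the class shift's sign flips with a Rademacher context
  variable shared across paradoxical features (exposed in the table as a
  ``CONTEXT`` feature), so the feature's effect direction depends on
  context; targets the non-monotone / paradoxical criteria.
* ``INTERMEDIATE_NULL`` — a deterministic average of two planted features,
  carrying only information already present upstream; targets the all-zero
  coefficient discussion.
* ``NOISE`` — label-independent Gaussian (optionally heavy-tailed,
  Student-t with 3 df).

Labels are i.i.d. Bernoulli(prevalence). Everything is driven by one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import Dataset

ARCHETYPES = (
    "SEPARABLE",
    "MONOTONE_WEAK",
    "PARADOXICAL",
    "CONTEXT",
    "INTERMEDIATE_NULL",
    "NOISE",
)


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic dataset.

    Archetype counts (plus one CONTEXT feature when ``n_paradoxical > 0``)
    must not exceed ``n_features``; the remainder is NOISE.
    """

    n_samples: int = 40
    n_features: int = 50
    prevalence: float = 0.5
    n_separable: int = 1
    n_monotone_weak: int = 0
    n_paradoxical: int = 0
    n_intermediate_null: int = 0
    delta: float = 20.0
    delta_weak: float = 0.5
    sigma: float = 1.0
    heavy_tailed: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie strictly between 0 and 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if min(
            self.n_samples,
            self.n_features,
            self.n_separable,
            self.n_monotone_weak,
            self.n_paradoxical,
            self.n_intermediate_null,
        ) < 0 or self.n_samples == 0:
            raise ValueError("counts must be non-negative and n_samples positive")
        if self.n_planted + self.n_context > self.n_features:
            raise ValueError("archetype counts exceed n_features")
        if self.n_intermediate_null > 0 and self.n_separable + self.n_monotone_weak < 2:
            raise ValueError(
                "INTERMEDIATE_NULL needs at least two planted parent features"
            )

    @property
    def n_context(self) -> int:
        return 1 if self.n_paradoxical > 0 else 0

    @property
    def n_planted(self) -> int:
        return (
            self.n_separable
            + self.n_monotone_weak
            + self.n_paradoxical
            + self.n_intermediate_null
        )


def _noise(rng: np.random.Generator, size, sigma: float, heavy: bool) -> np.ndarray:
    if heavy:
        return rng.standard_t(df=3, size=size) * sigma
    return rng.normal(0.0, sigma, size=size)


def generate_dataset(spec: SynthSpec):
    """Build the dataset and its ground-truth archetype map.

    Returns ``(Dataset, archetype_map)`` where the map assigns every feature
    name a dict with at least an ``"archetype"`` entry (parents recorded for
    INTERMEDIATE_NULL, the context feature for PARADOXICAL).
    """
    rng = np.random.default_rng(spec.seed)
    m, p = spec.n_samples, spec.n_features
    y = rng.binomial(1, spec.prevalence, size=m).astype(np.int8)
    X = np.empty((m, p), dtype=float)
    names = [f"f{j}" for j in range(p)]
    amap: dict = {}
    j = 0
    parents: list = []

    for _ in range(spec.n_separable):
        X[:, j] = spec.delta * y + _noise(rng, m, spec.sigma, spec.heavy_tailed)
        amap[names[j]] = {"archetype": "SEPARABLE"}
        parents.append(j)
        j += 1
    for _ in range(spec.n_monotone_weak):
        X[:, j] = spec.delta_weak * y + _noise(rng, m, spec.sigma, spec.heavy_tailed)
        amap[names[j]] = {"archetype": "MONOTONE_WEAK"}
        parents.append(j)
        j += 1
    if spec.n_paradoxical > 0:
        z = rng.choice([-1.0, 1.0], size=m)
        ctx = j
        X[:, j] = z + _noise(rng, m, 0.1 * spec.sigma, False)
        amap[names[j]] = {"archetype": "CONTEXT"}
        j += 1
        for _ in range(spec.n_paradoxical):
            X[:, j] = spec.delta * y * z + _noise(rng, m, spec.sigma, spec.heavy_tailed)
            amap[names[j]] = {"archetype": "PARADOXICAL", "context": names[ctx]}
            j += 1
    for _ in range(spec.n_intermediate_null):
        a, b = parents[0], parents[1]
        X[:, j] = (X[:, a] + X[:, b]) / 2.0
        amap[names[j]] = {
            "archetype": "INTERMEDIATE_NULL",
            "parents": [names[a], names[b]],
        }
        j += 1
    while j < p:
        X[:, j] = _noise(rng, m, spec.sigma, spec.heavy_tailed)
        amap[names[j]] = {"archetype": "NOISE"}
        j += 1

    data = Dataset(X, y, feature_names=names)
    return data, amap
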