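"""Validated container for a feature matrix with a binary outcome.

The forest machinery operates on complete real-valued tables (samples in
rows, features in columns) with one {0,1} label per sample — the shape of a
transposed expression matrix with a dichotomized phenotype. Missing values
are rejected outright: the combinatorial search has no sensible imputation
semantics, so incomplete tables are a hard error at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class DataError(ValueError):
    """Raised for structurally invalid input data (missing values, label
    mismatches, non-numeric cells)."""


@dataclass(frozen=True)
class Dataset:
    """A complete numeric feature table plus binary outcome.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_features)
        Real-valued measurements, samples in rows.
    y : ndarray of shape (n_samples,)
        Binary outcome, entries in {0, 1}.
    feature_names : sequence of str, optional
        Defaults to ``f0 .. f{n-1}``.
    sample_names : sequence of str, optional
        Defaults to ``s0 .. s{m-1}``.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple = field(default=None)
    sample_names: tuple = field(default=None)

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise DataError(f"feature matrix must be 2-D, got shape {X.shape}")
        y = np.asarray(self.y)
        if y.ndim != 1:
            raise DataError("labels must be a 1-D vector")
        if y.shape[0] != X.shape[0]:
            raise DataError(
                f"{y.shape[0]} labels for {X.shape[0]} samples; "
                "check the table orientation"
            )
        if not np.isfinite(X).all():
            i, j = np.argwhere(~np.isfinite(X))[0]
            raise DataError(
                f"missing or non-finite value at sample {i}, feature {j}: "
                "the model does not support missing data"
            )
        uniq = np.unique(y)
        if not np.isin(uniq, [0, 1]).all():
            raise DataError(f"labels must be 0/1, found values {uniq!r}")
        y = y.astype(np.int8)
        fnames = self.feature_names
        if fnames is None:
            fnames = tuple(f"f{j}" for j in range(X.shape[1]))
        else:
            fnames = tuple(str(n) for n in fnames)
            if len(fnames) != X.shape[1]:
                raise DataError("feature_names length does not match matrix")
        snames = self.sample_names
        if snames is None:
            snames = tuple(f"s{i}" for i in range(X.shape[0]))
        else:
            snames = tuple(str(n) for n in snames)
            if len(snames) != X.shape[0]:
                raise DataError("sample_names length does not match matrix")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "feature_names", fnames)
        object.__setattr__(self, "sample_names", snames)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def require_both_classes(self) -> None:
        """Forest building needs positive and negative observations."""
        if len(np.unique(self.y)) < 2:
            raise ValueError("both outcome classes must be present")

    def rename_features(self, names: Sequence[str]) -> "Dataset":
        return Dataset(self.X, self.y, tuple(names), self.sample_names)
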