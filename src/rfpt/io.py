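"""Delimited-table readers and writers, feature blinding, run manifests.

The matrix convention follows expression arrays: features in rows, samples
in columns, first column holding feature identifiers and the header row the
sample identifiers. The transposed (samples-in-rows) layout is accepted
behind an explicit flag. Labels arrive in a separate two-column table
(sample, label in {0,1}). Missing values anywhere are a hard error with the
offending cell named.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .dataset import DataError, Dataset


class Orientation(Enum):
    FEATURES_IN_ROWS = "features_in_rows"
    SAMPLES_IN_ROWS = "samples_in_rows"


@dataclass(frozen=True)
class TableLayout:
    orientation: Orientation = Orientation.FEATURES_IN_ROWS
    delimiter: str = "\t"


def _numeric_or_die(frame: pd.DataFrame, path) -> pd.DataFrame:
    out = frame.apply(pd.to_numeric, errors="coerce")
    bad = out.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"{path}: non-numeric or missing value at row {frame.index[i]!r}, "
            f"column {frame.columns[j]!r}"
        )
    return out


def read_dataset(
    matrix_path, labels_path, layout: TableLayout = TableLayout()
) -> Dataset:
    """Read a delimited feature matrix plus a labels table into a Dataset.

    Sample order follows the matrix; the labels table is aligned by sample
    name when the names match, otherwise a label-count mismatch (e.g. a
    transposed file read with the wrong orientation) is a descriptive error.
    """
    frame = pd.read_csv(matrix_path, sep=layout.delimiter, index_col=0)
    frame = _numeric_or_die(frame, matrix_path)
    if layout.orientation is Orientation.FEATURES_IN_ROWS:
        frame = frame.T  # now samples in rows
    labels = pd.read_csv(labels_path, sep=layout.delimiter)
    if labels.shape[1] != 2:
        raise DataError(f"{labels_path}: expected two columns (sample, label)")
    labels.columns = ["sample", "label"]
    labels["sample"] = labels["sample"].astype(str)
    if labels.shape[0] != frame.shape[0]:
        raise DataError(
            f"{labels_path}: {labels.shape[0]} labels for {frame.shape[0]} samples "
            f"under orientation {layout.orientation.value}; check the orientation flag"
        )
    frame.index = frame.index.astype(str)
    if set(labels["sample"]) == set(frame.index):
        labels = labels.set_index("sample").loc[frame.index]
    return Dataset(
        frame.to_numpy(dtype=float),
        labels["label"].to_numpy(),
        feature_names=list(frame.columns),
        sample_names=list(frame.index),
    )


def write_dataset(data: Dataset, matrix_path, labels_path, layout: TableLayout = TableLayout()) -> None:
    frame = pd.DataFrame(
        data.X, index=list(data.sample_names), columns=list(data.feature_names)
    )
    if layout.orientation is Orientation.FEATURES_IN_ROWS:
        frame = frame.T
        frame.index.name = "feature"
    else:
        frame.index.name = "sample"
    frame.to_csv(matrix_path, sep=layout.delimiter)
    pd.DataFrame({"sample": list(data.sample_names), "label": data.y}).to_csv(
        labels_path, sep=layout.delimiter, index=False
    )


def anonymize_features(data: Dataset):
    """Blind feature identities as a1..aN, preserving order.

    Returns ``(blinded_dataset, mapping)`` where the mapping DataFrame
    (columns ``anonymized``, ``original``) inverts the renaming.
    """
    new_names = [f"a{j + 1}" for j in range(data.n_features)]
    mapping = pd.DataFrame(
        {"anonymized": new_names, "original": list(data.feature_names)}
    )
    return data.rename_features(new_names), mapping


def deanonymize_features(data: Dataset, mapping: pd.DataFrame) -> Dataset:
    back = dict(zip(mapping["anonymized"], mapping["original"]))
    return data.rename_features([back[n] for n in data.feature_names])


def write_nic_table(nic_table: pd.DataFrame, tally: pd.DataFrame, path) -> None:
    """Write the per-feature report: selection/event counts, NIC ratios and
    the score (printed to two decimals), ordered by score rank."""
    merged = tally.join(nic_table, how="inner")
    merged = merged.sort_values("score_rank")
    merged = merged.copy()
    merged["nic_score"] = merged["nic_score"].round(2)
    merged.to_csv(path, sep="\t")


def read_nic_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tree_log(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def write_manifest(path, seed: int, config: dict, extra: Optional[dict] = None) -> None:
    """Persist everything needed to reproduce a run bitwise: seed, full
    configuration and the versions of the numerical stack."""
    import sklearn
    import statsmodels

    from . import __version__

    manifest = {
        "seed": seed,
        "config": config,
        "versions": {
            "rfpt": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
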