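"""Nguyen information criteria (NICs), the NIC score, rankings and gap
selection.

Each feature's forest tally is converted to ten proportions:

====  =========================================================  ===========
NIC   numerator (over the forest)                                denominator
====  =========================================================  ===========
NIC1  trees reaching an error-free classification                selections
NIC2  perfect trees with every coefficient zero                  perfect trees
NIC3  perfect trees with every coefficient positive              perfect trees
NIC4  perfect trees with every coefficient negative              perfect trees
NIC5  NIC3 x NIC4 (between-tree paradoxical effect)              —
NIC6  perfect trees with both signs in one tree (non-monotone)   perfect trees
NIC7  perfect trees needing at most two neurons                  perfect trees
NIC8  perfect trees needing a single neuron                      perfect trees
NIC9  perfect trees with an enumerable solution set              perfect trees
NIC10 perfect trees with a unique solution                       perfect trees
====  =========================================================  ===========

NIC1–NIC6 describe predictive quality, NIC7–NIC8 proximity of the feature
to the outcome, NIC9–NIC10 the complexity of the relationship. The
composite score

    NICscore = NIC1 - NIC2 - NIC6 + NIC8 + NIC9 + NIC10

ranges from -2 to 4; 4 is attained only by features whose every selection
yields a single-neuron, unique-solution perfect tree with no zero-weight or
sign-flipping solutions. NIC5 and NIC7 are reported but excluded from the
score (NIC5 lacks a defined normalization; NIC7 is nested in NIC8).

A feature never seen in a perfect tree carries no NIC evidence: its ratios
are zero and it is flagged ``no_pt`` and ranked last — never dropped, since
such features may still be essential intermediates.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

NIC_COLUMNS = tuple(f"nic{i}" for i in range(1, 11))

#: tally column providing each NIC's numerator
_NUMERATORS = {
    "nic1": "perfect_trees",
    "nic2": "all_zero",
    "nic3": "all_positive",
    "nic4": "all_negative",
    "nic6": "non_monotone",
    "nic7": "two_neuron_perfect",
    "nic8": "one_neuron_perfect",
    "nic9": "enumerable_solutions",
    "nic10": "unique_solution",
}

#: default hierarchical ranking keys, most important first
DEFAULT_HIERARCHY = ("one_minus_nic2", "nic1", "nic10", "nic8")

_VALID_KEYS = frozenset(NIC_COLUMNS) | {"one_minus_nic2", "nic_score"}


def compute_nics(tally: pd.DataFrame) -> pd.DataFrame:
    """Per-feature NIC ratios, score and ranks from a forest tally.

    Expects the column schema of :data:`rfpt.forest.TALLY_COLUMNS`. Features
    with zero perfect trees get all ratios 0 and ``no_pt=True``. Raises if
    any feature was never selected (its NIC1 denominator is undefined).
    """
    if (tally["times_selected"] == 0).any():
        bad = tally.index[tally["times_selected"] == 0][0]
        raise ValueError(f"feature {bad!r} was never selected; NIC1 is undefined")
    pt = tally["perfect_trees"].to_numpy(dtype=float)
    out = pd.DataFrame(index=tally.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["nic1"] = pt / tally["times_selected"].to_numpy(dtype=float)
        for nic, col in _NUMERATORS.items():
            if nic == "nic1":
                continue
            ratio = np.where(pt > 0, tally[col].to_numpy(dtype=float) / np.where(pt > 0, pt, 1.0), 0.0)
            out[nic] = ratio
    out["nic5"] = out["nic3"] * out["nic4"]
    out = out[list(NIC_COLUMNS)]
    out["no_pt"] = pt == 0
    out["nic_score"] = nic_score(out)
    out["hierarchical_rank"] = _rank(out, DEFAULT_HIERARCHY)
    out["score_rank"] = _rank(out, ("nic_score",))
    return out


def nic_score(row) -> "pd.Series | float":
    """NIC1 - NIC2 - NIC6 + NIC8 + NIC9 + NIC10 (full precision; rounding to
    two decimals happens only at presentation)."""
    return (
        row["nic1"] - row["nic2"] - row["nic6"]
        + row["nic8"] + row["nic9"] + row["nic10"]
    )


def _sort_order(table: pd.DataFrame, keys: Sequence[str]) -> np.ndarray:
    """Positions of features in ranked order: descending lexicographic on
    the keys, no-perfect-tree features last, ties by input order."""
    for k in keys:
        if k not in _VALID_KEYS:
            raise ValueError(f"unknown ranking key {k!r}")
    cols = {}
    for k in keys:
        if k == "one_minus_nic2":
            cols[k] = 1.0 - table["nic2"]
        else:
            cols[k] = table[k]
    aux = pd.DataFrame(cols, index=table.index)
    if "no_pt" in table:
        aux.insert(0, "_no_pt", table["no_pt"].astype(int))
    order = np.lexsort(
        [np.arange(len(aux))]
        + [-aux[c].to_numpy() for c in reversed([c for c in aux.columns if c != "_no_pt"])]
        + ([aux["_no_pt"].to_numpy()] if "_no_pt" in aux else [])
    )
    return order


def _rank(table: pd.DataFrame, keys: Sequence[str]) -> np.ndarray:
    order = _sort_order(table, keys)
    ranks = np.empty(len(order), dtype=np.int64)
    ranks[order] = np.arange(1, len(order) + 1)
    return ranks


def hierarchical_rank(
    table: pd.DataFrame, key_order: Sequence[str] = DEFAULT_HIERARCHY
) -> list:
    """Feature names in rank order under a lexicographic key hierarchy.

    The default (1-NIC2)/NIC1/NIC10/NIC8 gives the first key overriding
    weight and the later keys tie-breaking roles only. The sort is stable:
    fully tied features keep their input order.
    """
    order = _sort_order(table, key_order)
    return [table.index[i] for i in order]


def select_by_gap(scores: Mapping[str, float], min_gap: float = 1.0):
    """Cut a descending score list at the first gap of at least ``min_gap``.

    Returns ``(selected_names, no_gap_flag)``; when no adjacent pair of
    sorted scores differs by ``min_gap`` the full list is returned with the
    flag set.
    """
    if min_gap <= 0:
        raise ValueError("min_gap must be positive")
    s = pd.Series(scores)
    if s.empty:
        return [], False
    s = s.iloc[np.argsort(-s.to_numpy(), kind="stable")]
    vals = s.to_numpy()
    diffs = vals[:-1] - vals[1:]
    hit = np.flatnonzero(diffs >= min_gap)
    if hit.size == 0:
        return list(s.index), True
    return list(s.index[: hit[0] + 1]), False
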