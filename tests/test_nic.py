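import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rfpt import compute_nics, hierarchical_rank, nic_score, select_by_gap
from rfpt.forest import TALLY_COLUMNS


def tally_frame(rows: dict) -> pd.DataFrame:
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(TALLY_COLUMNS))
    frame.index.name = "feature"
    return frame


# Reference per-probe tally counts from the published GSE22513 single-probe
# forest analysis (selections, perfect trees, then the eight event counters).
REFERENCE_ROWS = {
    "205363_at/BBOX1": (160, 160, 0, 160, 0, 0, 160, 160, 160, 160),
    "227462_at/ERAP2": (140, 140, 0, 0, 140, 0, 140, 140, 140, 140),
    "207781_s_at/ZNF711": (170, 170, 0, 168, 0, 0, 170, 170, 170, 170),
    "1553875_s_at/ZSCAN10": (155, 155, 0, 0, 0, 155, 0, 0, 155, 155),
    "200618_at/LASP1": (177, 177, 0, 0, 0, 177, 0, 0, 177, 177),
}


class TestComputeNics:
    def test_consistently_perfect_single_neuron_probe(self):
        table = compute_nics(tally_frame(REFERENCE_ROWS))
        bbox1 = table.loc["205363_at/BBOX1"]
        assert bbox1[["nic1", "nic3", "nic7", "nic8", "nic9", "nic10"]].tolist() == [1.0] * 6
        assert bbox1[["nic2", "nic4", "nic5", "nic6"]].tolist() == [0.0] * 4
        assert round(bbox1["nic_score"], 2) == 4.00

    def test_all_negative_probe_has_zero_paradox(self):
        table = compute_nics(tally_frame(REFERENCE_ROWS))
        erap2 = table.loc["227462_at/ERAP2"]
        assert erap2["nic4"] == 1.0 and erap2["nic3"] == 0.0 and erap2["nic5"] == 0.0
        assert round(erap2["nic_score"], 2) == 4.00

    def test_non_monotone_probe_scores_two(self):
        table = compute_nics(tally_frame(REFERENCE_ROWS))
        zscan10 = table.loc["1553875_s_at/ZSCAN10"]
        assert zscan10["nic6"] == 1.0 and zscan10["nic8"] == 0.0
        # 1 - 0 - 1 + 0 + 1 + 1
        assert round(zscan10["nic_score"], 2) == 2.00

    def test_no_perfect_trees_flagged_and_zeroed(self):
        rows = {"dead": (50, 0, 0, 0, 0, 0, 0, 0, 0, 0)}
        table = compute_nics(tally_frame(rows))
        assert bool(table.loc["dead", "no_pt"])
        assert (table.loc["dead", [f"nic{i}" for i in range(1, 11)]] == 0).all()

    def test_never_selected_feature_rejected(self):
        rows = {"ghost": (0, 0, 0, 0, 0, 0, 0, 0, 0, 0)}
        with pytest.raises(ValueError):
            compute_nics(tally_frame(rows))

    def test_score_of_pure_nic1_row(self):
        rows = {"x": (100, 100, 0, 0, 0, 0, 0, 0, 0, 0)}
        table = compute_nics(tally_frame(rows))
        assert table.loc["x", "nic_score"] == pytest.approx(1.0)

    @given(
        selected=st.integers(1, 500),
        perfect=st.integers(0, 500),
        parts=st.lists(st.integers(0, 500), min_size=6, max_size=6),
    )
    @settings(derandomize=True, deadline=None)
    def test_ratio_ranges_and_identities(self, selected, perfect, parts):
        """NICs live in [0,1], NIC5 = NIC3*NIC4, nestings hold, score in [-2,4]."""
        perfect = min(perfect, selected)
        zero, pos, neg, nonmono, cyc, uniq = parts
        # force the containment structure of a real tally
        total = zero + pos + neg + nonmono
        if total > perfect and total:
            scale = perfect / total
            zero, pos, neg, nonmono = (int(v * scale) for v in (zero, pos, neg, nonmono))
        one = min(cyc, perfect)
        cyc = min(max(cyc, one), perfect)
        enum = min(uniq + 1, perfect)
        uniq = min(uniq, enum)
        rows = {"f": (selected, perfect, zero, pos, neg, nonmono, cyc, one, enum, uniq)}
        table = compute_nics(tally_frame(rows))
        nics = table.loc["f", [f"nic{i}" for i in range(1, 11)]].astype(float)
        assert ((0 <= nics) & (nics <= 1)).all()
        assert table.loc["f", "nic5"] == pytest.approx(
            table.loc["f", "nic3"] * table.loc["f", "nic4"]
        )
        assert table.loc["f", "nic8"] <= table.loc["f", "nic7"] + 1e-12
        assert table.loc["f", "nic10"] <= table.loc["f", "nic9"] + 1e-12
        assert -2 <= table.loc["f", "nic_score"] <= 4


class TestRanking:
    def test_single_neuron_probe_outranks_non_monotone_probe(self):
        table = compute_nics(tally_frame(REFERENCE_ROWS))
        order = hierarchical_rank(table)
        assert order.index("205363_at/BBOX1") < order.index("1553875_s_at/ZSCAN10")
        assert order.index("227462_at/ERAP2") < order.index("200618_at/LASP1")

    def test_stable_on_identical_rows(self):
        rows = {
            "a": (100, 100, 0, 100, 0, 0, 100, 100, 100, 100),
            "b": (100, 100, 0, 100, 0, 0, 100, 100, 100, 100),
        }
        table = compute_nics(tally_frame(rows))
        assert hierarchical_rank(table) == ["a", "b"]

    def test_single_row_ranks_first(self):
        rows = {"only": (10, 10, 0, 10, 0, 0, 10, 10, 10, 10)}
        table = compute_nics(tally_frame(rows))
        assert table.loc["only", "hierarchical_rank"] == 1

    def test_no_pt_features_rank_last(self):
        rows = {
            "dead": (50, 0, 0, 0, 0, 0, 0, 0, 0, 0),
            "alive": (50, 10, 0, 0, 0, 10, 0, 0, 0, 0),
        }
        table = compute_nics(tally_frame(rows))
        assert hierarchical_rank(table) == ["alive", "dead"]
        assert table.loc["dead", "score_rank"] == 2

    def test_unknown_key_rejected(self):
        table = compute_nics(tally_frame({"x": (10, 10, 0, 10, 0, 0, 10, 10, 10, 10)}))
        with pytest.raises(ValueError):
            hierarchical_rank(table, ("nic99",))

    def test_custom_key_order_changes_priorities(self):
        rows = {
            # high NIC1, no single-neuron trees
            "deep": (100, 100, 0, 0, 0, 0, 0, 0, 100, 100),
            # low NIC1, always single-neuron
            "shallow": (100, 10, 0, 10, 0, 0, 10, 10, 10, 10),
        }
        table = compute_nics(tally_frame(rows))
        assert hierarchical_rank(table, ("nic1",))[0] == "deep"
        assert hierarchical_rank(table, ("nic8",))[0] == "shallow"


class TestGapSelection:
    def test_published_gap_structure_selects_sixteen(self):
        scores = {f"top{i}": 4.00 for i in range(12)}
        scores.update({f"near{i}": 3.99 for i in range(4)})
        scores.update({f"rest{i}": 2.00 - 0.1 * i for i in range(20)})
        selected, no_gap = select_by_gap(scores, min_gap=1.0)
        assert len(selected) == 16 and not no_gap
        assert all(name.startswith(("top", "near")) for name in selected)

    def test_all_equal_scores_is_no_gap(self):
        selected, no_gap = select_by_gap({"a": 1.0, "b": 1.0}, min_gap=1.0)
        assert selected == ["a", "b"] and no_gap

    def test_single_gap(self):
        selected, no_gap = select_by_gap({"a": 4.0, "b": 2.0}, min_gap=1.0)
        assert selected == ["a"] and not no_gap

    def test_empty_input(self):
        assert select_by_gap({}, min_gap=1.0) == ([], False)

    def test_nonpositive_gap_rejected(self):
        with pytest.raises(ValueError):
            select_by_gap({"a": 1.0}, min_gap=0.0)
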