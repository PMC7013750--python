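"""Classifier truth tables, concordance counting, Venn regions and the
overlap ledger, checked against published counts and brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gravicomp import datasets
from gravicomp.classify import (
    CROSS_UG_LABELS,
    TEMPORAL_LABELS,
    build_overlap_ledger,
    classify_counts,
    classify_cross_microgravity,
    classify_temporal,
    count_direction_concordance,
    double_sensitive,
    round_percent,
    venn_counts,
)
from gravicomp.diffexp import ComparisonResult, ComparisonSpec
from gravicomp.io import Group, Platform, TranscriptSet


class TestClassifyTemporal:
    @pytest.mark.parametrize(
        "early, late, expected",
        [
            ("up", "up", "continuous"),
            ("down", "down", "continuous"),
            ("up", "none", "adaptation"),
            ("up", "down", "adaptation"),
            ("down", "up", "adaptation"),
            ("none", "down", "late"),
            ("none", "up", "late"),
            ("none", "none", "non_responsive"),
        ],
    )
    def test_truth_table(self, early, late, expected):
        assert classify_temporal(early, late) == expected

    def test_eliminated_dominates(self):
        assert classify_temporal("up", "up", eliminated=True) == "eliminated"

    def test_partitions_universe(self):
        """Every (early, late, eliminated) combination maps to exactly one
        of the five labels."""
        for early, late in itertools.product(("up", "down", "none"), repeat=2):
            for elim in (False, True):
                assert classify_temporal(early, late, elim) in TEMPORAL_LABELS

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValueError):
            classify_temporal("sideways", "up")


class TestClassifyCrossMicrogravity:
    @pytest.mark.parametrize(
        "flight, vag, expected",
        [
            ("up", "up", "same_response"),
            ("down", "down", "same_response"),
            ("down", "none", "no_or_reverse"),
            ("up", "down", "no_or_reverse"),
            ("none", "up", "vag_only"),
            ("none", "none", "non_responsive"),
        ],
    )
    def test_truth_table(self, flight, vag, expected):
        assert classify_cross_microgravity(flight, vag) == expected

    def test_labels_partition(self):
        for flight, vag in itertools.product(("up", "down", "none"), repeat=2):
            assert classify_cross_microgravity(flight, vag) in CROSS_UG_LABELS


class TestPublishedClassificationArithmetic:
    def test_temporal_class_totals(self):
        """Aggregating the classifier over the published 75 s x 300 s
        cross-tabulation reproduces the printed class totals
        (33 continuous, 267 adaptation, 1459 late, 40909 non-responsive)."""
        data = datasets.temporal_crosstab()
        totals = classify_counts(
            data["cells"], classify_temporal, eliminated=data["eliminated"]
        )
        assert totals["continuous"] == 33
        assert totals["adaptation"] == 267
        assert totals["late"] == 1459
        assert totals["non_responsive"] == 40909
        assert totals["eliminated"] == 727
        assert sum(totals.values()) == data["universe"]

    def test_cross_microgravity_class_totals(self):
        data = datasets.cross_microgravity_crosstab()
        totals = classify_counts(
            data["cells"], classify_cross_microgravity,
            eliminated=data["eliminated"],
        )
        assert totals["same_response"] == 9
        assert totals["no_or_reverse"] == 358
        assert totals["vag_only"] == 215
        assert totals["non_responsive"] == 42086
        assert sum(totals.values()) == data["universe"]


def _result(spec_name, calls: dict[str, str], fcs: dict[str, float],
            universe: list[str]) -> ComparisonResult:
    spec = ComparisonSpec(
        spec_name, Group.CLINOSTAT_2D, Group.CONTROL_1G, Platform.GBF
    )
    table = pd.DataFrame(
        {
            "fc": [fcs.get(tc, 1.0) for tc in universe],
            "p": [0.01 if tc in calls else 0.9 for tc in universe],
            "call": [calls.get(tc, "none") for tc in universe],
        },
        index=pd.Index(universe, name="tc_id"),
    )
    return ComparisonResult(spec, table, pd.Series("", index=table.index))


class TestDoubleSensitive:
    def test_identical_results_all_same_direction(self):
        universe = ["a", "b", "c", "d"]
        res = _result("x", {"a": "up", "b": "down"}, {"a": 2.0, "b": -1.5}, universe)
        inter, same, reverse = double_sensitive(res, res)
        assert inter.tc_ids() == {"a", "b"}
        assert (same, reverse) == (2, 0)

    def test_negated_fc_all_reverse(self):
        universe = ["a", "b", "c"]
        a = _result("x", {"a": "up", "b": "down"}, {"a": 2.0, "b": -1.5}, universe)
        b = _result("y", {"a": "down", "b": "up"}, {"a": -2.0, "b": 1.5}, universe)
        _, same, reverse = double_sensitive(a, b)
        assert (same, reverse) == (0, 2)

    def test_concordance_symmetric(self):
        universe = [f"t{i}" for i in range(6)]
        a = _result("x", {"t0": "up", "t1": "down", "t2": "up"},
                    {"t0": 1.6, "t1": -1.4, "t2": 2.0}, universe)
        b = _result("y", {"t0": "up", "t1": "up", "t2": "up"},
                    {"t0": 1.5, "t1": 1.4, "t2": 1.9}, universe)
        _, same_ab, rev_ab = double_sensitive(a, b)
        _, same_ba, rev_ba = double_sensitive(b, a)
        assert (same_ab, rev_ab) == (same_ba, rev_ba) == (2, 1)

    def test_universe_mismatch_rejected(self):
        a = _result("x", {}, {}, ["a", "b"])
        b = _result("y", {}, {}, ["a", "c"])
        with pytest.raises(ValueError, match="universe"):
            double_sensitive(a, b)

    def test_published_hypergravity_concordance(self):
        """The 28 published cross-platform hypergravity FC pairs split into
        22 same-direction and 6 reverse-direction transcript clusters."""
        table = datasets.hypergravity_cross_platform_fc()
        same, reverse = count_direction_concordance(
            table["fc_centrifuge_9g"], table["fc_tx_hyp_g"]
        )
        assert (same, reverse) == (22, 6)


class TestVennCounts:
    def test_disjoint_sets(self):
        a = TranscriptSet({"a": "up"}, "A")
        b = TranscriptSet({"b": "down"}, "B")
        regions = venn_counts([a, b])
        assert regions["10"]["all"] == 1
        assert regions["01"]["all"] == 1
        assert regions["11"]["all"] == 0

    def test_subset_relation(self):
        a = TranscriptSet({"x": "up", "y": "up"}, "A")
        b = TranscriptSet({"x": "up", "y": "down", "z": "up"}, "B")
        regions = venn_counts([a, b])
        assert regions["11"]["all"] == len(a)
        assert regions["10"]["all"] == 0

    def test_three_sets_match_brute_force(self):
        rng = np.random.default_rng(17)
        universe = [f"t{i}" for i in range(60)]
        sets = []
        for name in "ABC":
            members = {
                tc: ("up" if rng.random() < 0.5 else "down")
                for tc in universe
                if rng.random() < 0.4
            }
            sets.append(TranscriptSet(members, name))
        annotated = {tc for tc in universe if rng.random() < 0.5}
        regions = venn_counts(sets, annotated)
        # brute-force oracle: enumerate every tc and its membership pattern
        expected: dict[str, list[int]] = {}
        for tc in universe:
            pattern = "".join("1" if tc in s else "0" for s in sets)
            if pattern == "000":
                continue
            expected.setdefault(pattern, [0, 0])
            expected[pattern][0] += 1
            expected[pattern][1] += tc in annotated
        for pattern, counts in regions.items():
            exp_all, exp_ann = expected.get(pattern, [0, 0])
            assert counts["all"] == exp_all
            assert counts["annotated"] == exp_ann


class TestOverlapLedger:
    def test_published_percentage_cell(self):
        """171 of 181 clinostat-upregulated TCs also upregulated in the
        centrifuge comparison gives 94.5%."""
        row = datasets.clinostat_up_overlap_row()
        assert round_percent(row["centrifuge_9g"]["up"], row["total"]) == 94.5

    def test_secondary_identical_to_primary_diagonal(self):
        universe = [f"t{i}" for i in range(10)]
        res = _result("p", {"t0": "up", "t1": "up", "t2": "down"},
                      {"t0": 1.5, "t1": 1.6, "t2": -1.5}, universe)
        ledger = build_overlap_ledger(res, [res])
        rows = ledger.rows
        assert rows["up"]["secondaries"]["p"]["up"]["pct_all"] == 100.0
        assert rows["down"]["secondaries"]["p"]["down"]["pct_all"] == 100.0
        assert rows["non_responsive"]["secondaries"]["p"]["non_responsive"][
            "pct_all"] == 100.0

    def test_rows_sum_to_total(self):
        rng = np.random.default_rng(23)
        universe = [f"t{i}" for i in range(40)]
        def random_result(name):
            calls = {}
            fcs = {}
            for tc in universe:
                u = rng.random()
                if u < 0.2:
                    calls[tc], fcs[tc] = "up", 1.5
                elif u < 0.4:
                    calls[tc], fcs[tc] = "down", -1.5
            return _result(name, calls, fcs, universe)
        primary = random_result("p")
        secondary = random_result("s")
        ledger = build_overlap_ledger(primary, [secondary])
        for label, row in ledger.rows.items():
            sec = row["secondaries"]["s"]
            assert sum(cell["all"] for cell in sec.values()) == row["total"]["all"]

    def test_empty_row_flagged(self):
        universe = ["a", "b"]
        res = _result("p", {"a": "up", "b": "up"}, {"a": 1.5, "b": 1.5}, universe)
        ledger = build_overlap_ledger(res, [res])
        down_row = ledger.rows["down"]
        assert down_row["empty_row"] is True
        assert down_row["secondaries"]["p"]["down"]["pct_all"] == 0.0


class TestRoundPercent:
    @pytest.mark.parametrize(
        "count, total, expected",
        [(171, 181, 94.5), (1520, 5778, 26.3), (9, 43395, 0.0),
         (1, 8, 12.5), (1, 16, 6.3)],  # 6.25 rounds half-up to 6.3
    )
    def test_half_up_rounding(self, count, total, expected):
        assert round_percent(count, total) == expected
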