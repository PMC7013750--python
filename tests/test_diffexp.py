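"""Quantile normalization and DE-calling checks against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gravicomp.diffexp import (
    ComparisonSpec,
    anova_p,
    quantile_normalize,
    run_comparison,
    signed_fold_change,
)
from gravicomp.io import ExpressionMatrix, Group, Platform


def _matrix_from_log2(cols: dict[str, list[float]]) -> ExpressionMatrix:
    values = pd.DataFrame({k: np.exp2(v) for k, v in cols.items()})
    values.index = pd.Index([f"tc{i}" for i in range(len(values))], name="tc_id")
    return ExpressionMatrix(values, pd.Series("", index=values.index))


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        m = _matrix_from_log2({"a": [1.0, 5.0, 3.0], "b": [1.0, 5.0, 3.0]})
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values, rtol=1e-12)

    def test_hand_computed_two_columns(self):
        # log2 columns (1,2) and (3,4): mean order statistics are (2,3)
        m = _matrix_from_log2({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        out = np.log2(quantile_normalize(m).values.to_numpy())
        np.testing.assert_allclose(out, [[2.0, 2.0], [3.0, 3.0]], atol=1e-12)

    def test_all_columns_share_sorted_multiset(self):
        rng = np.random.default_rng(11)
        values = pd.DataFrame(
            rng.lognormal(3, 1.2, (50, 5)),
            index=pd.Index([f"tc{i}" for i in range(50)], name="tc_id"),
            columns=list("abcde"),
        )
        out = quantile_normalize(
            ExpressionMatrix(values, pd.Series("", index=values.index))
        ).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, rtol=1e-12)

    def test_ranks_preserved_within_columns(self):
        rng = np.random.default_rng(12)
        values = pd.DataFrame(
            rng.lognormal(3, 1.0, (30, 4)),
            index=pd.Index([f"tc{i}" for i in range(30)], name="tc_id"),
            columns=list("abcd"),
        )
        m = ExpressionMatrix(values, pd.Series("", index=values.index))
        out = quantile_normalize(m).values.to_numpy()
        for j in range(4):
            orig_rank = stats.rankdata(values.to_numpy()[:, j])
            new_rank = stats.rankdata(out[:, j])
            assert (orig_rank == new_rank).all()

    def test_ties_get_mean_of_tied_reference_values(self):
        # column b has a tie spanning reference positions 0 and 1
        m = _matrix_from_log2({"a": [1.0, 3.0, 5.0], "b": [2.0, 2.0, 6.0]})
        out = np.log2(quantile_normalize(m).values.to_numpy())
        ref = np.array([1.5, 2.5, 5.5])
        np.testing.assert_allclose(out[:, 0], ref, atol=1e-12)
        np.testing.assert_allclose(out[:, 1], [2.0, 2.0, 5.5], atol=1e-12)

    def test_single_sample_rejected(self):
        m = _matrix_from_log2({"a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="2 samples"):
            quantile_normalize(m)


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "mean_a, mean_b, expected",
        [(2.0, 1.0, 2.0), (1.0, 2.0, -2.0), (3.7, 3.7, 1.0), (3.0, 2.0, 1.5)],
    )
    def test_examples(self, mean_a, mean_b, expected):
        assert signed_fold_change(mean_a, mean_b) == pytest.approx(expected)

    def test_antisymmetry_and_magnitude(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = rng.lognormal(0, 1, 2)
            fc = signed_fold_change(a, b)
            assert abs(fc) >= 1.0
            if a != b:
                assert signed_fold_change(b, a) == pytest.approx(-fc)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            signed_fold_change(0.0, 1.0)


class TestAnovaP:
    def test_identical_groups_give_p_one(self):
        assert anova_p([1.0, 2.0, 3.0], [3.0, 1.0, 2.0]) == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**20))
    def test_equals_pooled_t_test(self, seed):
        """F = t^2: the one-way two-group ANOVA p must match the two-sided
        equal-variance t-test p to 1e-12."""
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.5, 1, 6)
        expected = stats.ttest_ind(a, b, equal_var=True).pvalue
        assert anova_p(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 8)
        assert anova_p(a, b) == anova_p(b, a)

    def test_degenerate_zero_variance(self):
        assert anova_p([2.0, 2.0], [2.0, 2.0]) == 1.0
        assert anova_p([2.0, 2.0], [3.0, 3.0]) == 0.0


class TestRunComparison:
    @pytest.fixture
    def planted(self, gbf_sheet):
        """Noise-free GBF matrix: tc0 planted at FC +1.5 in the clinostat,
        tc1 below the gate at 1.2, the rest null."""
        rng = np.random.default_rng(3)
        n_tc = 40
        base = rng.lognormal(5, 0.8, n_tc)
        cols = {}
        for _, row in gbf_sheet.table.iterrows():
            vals = base.copy()
            if row["group"] == "CLINOSTAT_2D":
                vals[0] *= 1.5
                vals[1] *= 1.2
            cols[row["sample_id"]] = vals
        values = pd.DataFrame(
            cols, index=pd.Index([f"tc{i}" for i in range(n_tc)], name="tc_id")
        )
        return ExpressionMatrix(values, pd.Series("", index=values.index))

    def test_planted_fc_called_up(self, planted, gbf_sheet):
        spec = ComparisonSpec(
            "clino vs ctrl", Group.CLINOSTAT_2D, Group.CONTROL_1G, Platform.GBF
        )
        res = run_comparison(planted, gbf_sheet, spec)
        assert res.table.loc["tc0", "call"] == "up"
        assert res.table.loc["tc0", "fc"] == pytest.approx(1.5)
        # below the inclusive 1.3 gate despite p = 0
        assert res.table.loc["tc1", "call"] == "none"
        assert (res.table.drop(["tc0", "tc1"])["call"] == "none").all()

    def test_swapping_groups_swaps_calls(self, planted, gbf_sheet):
        fwd = run_comparison(
            planted, gbf_sheet,
            ComparisonSpec("f", Group.CLINOSTAT_2D, Group.CONTROL_1G, Platform.GBF),
        )
        rev = run_comparison(
            planted, gbf_sheet,
            ComparisonSpec("r", Group.CONTROL_1G, Group.CLINOSTAT_2D, Platform.GBF),
        )
        assert fwd.up_set().tc_ids() == rev.down_set().tc_ids()
        assert fwd.down_set().tc_ids() == rev.up_set().tc_ids()

    def test_call_set_monotone_in_thresholds(self, small_study):
        from gravicomp.diffexp import quantile_normalize
        from gravicomp.io import Platform

        m = quantile_normalize(small_study.matrices[Platform.GBF])
        sheet = small_study.sheets[Platform.GBF]
        spec = ComparisonSpec(
            "clino vs ctrl", Group.CLINOSTAT_2D, Group.CONTROL_1G, Platform.GBF
        )
        sizes = []
        for fc, alpha in [(1.3, 0.05), (1.5, 0.05), (1.5, 0.01), (2.0, 0.001)]:
            res = run_comparison(m, sheet, spec, fc_threshold=fc, alpha=alpha)
            up, down = res.up_set().tc_ids(), res.down_set().tc_ids()
            assert not up & down
            sizes.append(len(up) + len(down))
        assert sizes == sorted(sizes, reverse=True)

    def test_missing_group_named_in_error(self, planted, gbf_sheet):
        spec = ComparisonSpec(
            "bad", Group.TX_UG, Group.IF_1G, Platform.TEXUS
        )
        with pytest.raises(ValueError, match="TX_UG"):
            run_comparison(planted, gbf_sheet, spec)

    def test_large_fc_fails_p_gate(self, gbf_sheet):
        """High fold change with high within-group spread is not called."""
        n_tc = 20
        rng = np.random.default_rng(9)
        base = rng.lognormal(5, 0.5, n_tc)
        cols = {}
        for i, (_, row) in enumerate(gbf_sheet.table.iterrows()):
            vals = base.copy()
            if row["group"] == "CLINOSTAT_2D":
                # one extreme sample drives the mean up but ruins the ANOVA
                vals[0] *= 16.0 if row["sample_id"].endswith("_1") else 1.0
            cols[row["sample_id"]] = vals
        values = pd.DataFrame(
            cols, index=pd.Index([f"tc{i}" for i in range(n_tc)], name="tc_id")
        )
        m = ExpressionMatrix(values, pd.Series("", index=values.index))
        spec = ComparisonSpec(
            "clino vs ctrl", Group.CLINOSTAT_2D, Group.CONTROL_1G, Platform.GBF
        )
        res = run_comparison(m, gbf_sheet, spec)
        assert res.table.loc["tc0", "fc"] > 1.3
        assert res.table.loc["tc0", "p"] >= 0.05
        assert res.table.loc["tc0", "call"] == "none"

    def test_null_data_p_uniformity(self):
        """On a study with no planted effects the p-value distribution is
        near-uniform: the fraction below 0.05 stays within binomial 3-sigma
        of 0.05."""
        from gravicomp.diffexp import quantile_normalize
        from gravicomp.simulate import SimulationConfig, generate_study

        study = generate_study(
            SimulationConfig(n_tc=3000, class_proportions={}, seed=3)
        )
        m = quantile_normalize(study.matrices[Platform.GBF])
        spec = ComparisonSpec(
            "clino vs ctrl", Group.CLINOSTAT_2D, Group.CONTROL_1G, Platform.GBF
        )
        res = run_comparison(m, study.sheets[Platform.GBF], spec)
        frac = (res.table["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 3000) + 0.005
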