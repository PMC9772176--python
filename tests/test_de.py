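import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from coopdeg.de import (
    P_FLOOR,
    bh_adjust,
    call_degs,
    call_developmental_degs,
    compute_rpkm,
    signed_fold_change,
    t_test_two_tailed,
)
from conftest import brute_force_bh


def t_density_p(t_stat: float, df: float) -> float:
    """Independent oracle: two-tailed p by numerical integration of the t
    density (written from the gamma-function formula, not a CDF call)."""
    def pdf(u):
        return (math.gamma((df + 1) / 2)
                / (math.sqrt(df * math.pi) * math.gamma(df / 2))
                * (1 + u * u / df) ** (-(df + 1) / 2))
    tail, _ = quad(pdf, abs(t_stat), math.inf)
    return 2 * tail


class TestRpkm:
    @pytest.mark.parametrize(
        "counts,length,total,expected",
        [
            (0.0, 1000, 10**6, 0.0),
            (1000.0, 1000, 10**6, 1000.0),
            (10.0, 2000, 2 * 10**7, 0.25),
        ],
    )
    def test_formula(self, counts, length, total, expected):
        assert compute_rpkm(np.array([counts]), length, total)[0] == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            compute_rpkm(np.array([1.0]), 1000, 0)


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "mb,ma,expected_fc,expected_l2",
        [
            (5.0, 5.0, 1.0, 0.0),
            (1.0, 40.0, -40.0, math.log2(1 / 40)),
            (8.0, 2.0, 4.0, 2.0),
        ],
    )
    def test_reciprocal_convention(self, mb, ma, expected_fc, expected_l2):
        fc, l2 = signed_fold_change(mb, ma, pseudocount=0.0)
        assert fc == pytest.approx(expected_fc)
        assert l2 == pytest.approx(expected_l2)

    def test_both_zero_gives_nan_sentinel_not_exception(self):
        fc, l2 = signed_fold_change(0.0, 0.0, pseudocount=0.0)
        assert math.isnan(fc) and math.isnan(l2)

    @settings(max_examples=200, deadline=None)
    @given(a=st.floats(1e-6, 1e6), b=st.floats(1e-6, 1e6))
    def test_antisymmetry(self, a, b):
        # the convention maps a ratio of exactly 1 to +1 in both directions,
        # so antisymmetry applies to genuinely changed genes
        from hypothesis import assume

        assume(abs(math.log2(b / a)) > 1e-9)
        fwd, _ = signed_fold_change(b, a)
        rev, _ = signed_fold_change(a, b)
        assert fwd == pytest.approx(-rev, rel=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(a=st.floats(1e-6, 1e6), b=st.floats(1e-6, 1e6))
    def test_sign_convention_links_fc_and_log2fc(self, a, b):
        fc, l2 = signed_fold_change(b, a)
        assert abs(fc) >= 1.0
        assert (fc >= 1) == (l2 >= 0)


class TestTTest:
    def test_identical_groups_p_one(self):
        p, flagged = t_test_two_tailed([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert p == pytest.approx(1.0)
        assert not flagged

    def test_zero_variance_equal_means(self):
        p, flagged = t_test_two_tailed([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0 and flagged

    def test_zero_variance_unequal_means_floored_and_flagged(self):
        p, flagged = t_test_two_tailed([2.0, 2.0], [5.0, 5.0])
        assert p == P_FLOOR and flagged

    def test_pooled_p_matches_integrated_t_density(self):
        # a=(1,2,3) vs b=(10,11,12): pooled variance 1, t = −9/sqrt(2/3), df 4
        p, _ = t_test_two_tailed([1.0, 2.0, 3.0], [10.0, 11.0, 12.0], mode="pooled")
        assert p == pytest.approx(3.8506771136653903e-04, rel=1e-6)
        assert p == pytest.approx(t_density_p(-9 / math.sqrt(2 / 3), 4), rel=1e-6)

    def test_welch_differs_from_pooled_under_unequal_variance(self):
        a = [1.0, 1.1, 0.9, 1.0]
        b = [5.0, 9.0, 1.0, 7.0]
        p_pooled, _ = t_test_two_tailed(a, b, mode="pooled")
        p_welch, _ = t_test_two_tailed(a, b, mode="welch")
        assert p_pooled != p_welch


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_equal_ps_fixed_point(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_hand_stepped_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan]):
            with pytest.raises(ValueError):
                bh_adjust(bad)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(1e-12, 1.0, exclude_min=False), min_size=1,
                    max_size=40))
    def test_matches_brute_force_step_up(self, ps):
        np.testing.assert_allclose(bh_adjust(ps), brute_force_bh(ps),
                                   rtol=1e-12, atol=1e-12)


class TestCallDegs:
    def test_low_expression_filtered_regardless_of_p(self, tiny_matrix):
        # gD sits at RPKM << 1 in both conditions once scaled; force it by
        # direct rpkm unit
        rpkm = tiny_matrix.values.copy()
        rpkm.loc["gD"] = [0.5, 0.5, 0.5, 0.1, 0.1, 0.1]
        from coopdeg.io import ExpressionMatrix

        m = ExpressionMatrix(values=rpkm, design=tiny_matrix.design, unit="rpkm")
        res = call_degs(m, "control", "mutant")
        assert res.table.loc["gD", "status"] == "filtered"

    def test_counts_need_gene_lengths(self, tiny_matrix):
        with pytest.raises(ValueError, match="gene_lengths"):
            call_degs(tiny_matrix, "control", "mutant")

    def test_planted_fourfold_up_called(self, tiny_matrix):
        # explicit library sizes: with only 4 genes the DE gene would
        # otherwise dominate the column totals and cancel its own change
        lengths = pd.Series(1000.0, index=tiny_matrix.values.index)
        totals = pd.Series(1e6, index=tiny_matrix.values.columns)
        res = call_degs(tiny_matrix, "control", "mutant", gene_lengths=lengths,
                        total_mapped=totals)
        assert res.table.loc["gA", "status"] == "up"
        assert res.table.loc["gB", "status"] == "ns"
        assert res.table.loc["gC", "status"] == "up"  # 0 → 50: extreme up

    def test_invariant_to_gene_and_sample_order(self, tiny_matrix):
        from coopdeg.io import ExpressionMatrix

        lengths = pd.Series(1000.0, index=tiny_matrix.values.index)
        base = call_degs(tiny_matrix, "control", "mutant", gene_lengths=lengths)
        shuffled = tiny_matrix.values.iloc[::-1][
            ["control_2", "control_1", "control_3",
             "mutant_3", "mutant_1", "mutant_2"]]
        m2 = ExpressionMatrix(values=shuffled,
                              design=tiny_matrix.design[shuffled.columns])
        res2 = call_degs(m2, "control", "mutant", gene_lengths=lengths)
        pd.testing.assert_frame_equal(
            res2.table.sort_index(), base.table.sort_index())

    def test_requires_two_replicates(self, tiny_matrix):
        from coopdeg.io import ExpressionMatrix

        one_rep = tiny_matrix.values[["control_1", "mutant_1", "mutant_2"]]
        m = ExpressionMatrix(values=one_rep,
                             design=tiny_matrix.design[one_rep.columns],
                             unit="rpkm")
        with pytest.raises(ValueError, match="replicates"):
            call_degs(m, "control", "mutant")


class TestDevelopmentalCall:
    @pytest.mark.parametrize("fc,label", [(2.5, "dev_up"), (-2.5, "dev_down"),
                                          (1.5, "dev_ns"), (-2.0, "dev_ns")])
    def test_threshold_only_labels(self, fc, label):
        assert call_developmental_degs(np.array([fc]))[0] == label
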