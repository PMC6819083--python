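"""Summary-based t tests, correlation, KS, and FDR procedures."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from photoflux import stats as gst


def summary(label, mean, sem, n):
    return gst.GroupSummary(label, mean, sem, n)


class TestPooledTFromSummary:
    def test_identical_groups_zero(self):
        a = summary("a", 5.0, 0.5, 10)
        res = gst.pooled_t_from_summary(a, summary("b", 5.0, 0.5, 10))
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_published_rheobase_summaries_reconstruct_printed_t(self):
        # 124.1 +/- 8.65 pA (n=21) vs 171.7 +/- 7.779 pA (n=29) -> |t(48)| = 4.05
        res = gst.pooled_t_from_summary(
            summary("wt", 124.1, 8.65, 21), summary("het", 171.7, 7.779, 29)
        )
        assert abs(res.statistic) == pytest.approx(4.05, abs=0.02)
        assert res.df == 48
        assert res.p < 0.001

    def test_published_firing_rate_summaries_reconstruct_printed_t(self):
        # 2.633 +/- 0.2464 Hz (n=12) vs 1.703 +/- 0.244 Hz (n=18) -> |t(28)| = 2.58
        res = gst.pooled_t_from_summary(
            summary("wt", 2.633, 0.2464, 12), summary("het", 1.703, 0.244, 18)
        )
        assert abs(res.statistic) == pytest.approx(2.58, abs=0.02)
        assert res.df == 28

    def test_raw_route_equals_summary_route(self, rng):
        x = rng.normal(10, 2, 5)
        y = rng.normal(12, 2, 5)
        raw = gst.pooled_t(x, y)
        via_summary = gst.pooled_t_from_summary(
            summary("x", x.mean(), x.std(ddof=1) / np.sqrt(5), 5),
            summary("y", y.mean(), y.std(ddof=1) / np.sqrt(5), 5),
        )
        assert raw.statistic == pytest.approx(via_summary.statistic, rel=1e-12)

    def test_cross_check_against_scipy(self, rng):
        from scipy import stats as sps

        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 11)
        ours = gst.pooled_t(x, y)
        ref = sps.ttest_ind(x, y)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_antisymmetry_and_shift_invariance(self):
        a = summary("a", 3.0, 0.4, 8)
        b = summary("b", 4.5, 0.6, 12)
        ab = gst.pooled_t_from_summary(a, b).statistic
        ba = gst.pooled_t_from_summary(b, a).statistic
        assert ab == pytest.approx(-ba)
        shifted = gst.pooled_t_from_summary(
            summary("a", 13.0, 0.4, 8), summary("b", 14.5, 0.6, 12)
        ).statistic
        assert shifted == pytest.approx(ab, rel=1e-12)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n must be"):
            summary("a", 1.0, 0.1, 1)


class TestWelchAndPaired:
    def test_welch_close_to_pooled_for_equal_variance(self):
        a = summary("a", 3.0, 0.5, 20)
        b = summary("b", 4.0, 0.5, 20)
        assert gst.welch_t_from_summary(a, b).statistic == pytest.approx(
            gst.pooled_t_from_summary(a, b).statistic, rel=1e-9
        )

    def test_welch_cross_check_against_scipy(self, rng):
        from scipy import stats as sps

        x = rng.normal(0, 1, 9)
        y = rng.normal(0, 3, 14)
        ours = gst.welch_t_from_summary(
            summary("x", x.mean(), x.std(ddof=1) / 3, 9),
            summary("y", y.mean(), y.std(ddof=1) / np.sqrt(14), 14),
        )
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.df == pytest.approx(ref.df, rel=1e-9)

    def test_paired_identical_zero(self):
        res = gst.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0

    def test_paired_three_pair_closed_form(self):
        x = np.array([4.0, 5.0, 6.0])
        y = np.array([3.0, 3.5, 4.0])
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        res = gst.paired_t(x, y)
        assert res.statistic == pytest.approx(t_hand, rel=1e-12)
        assert res.df == 2


class TestPearson:
    def test_perfect_positive_and_negative(self):
        x = np.array([1.0, 2, 3, 4])
        assert gst.pearson(x, x)[0] == pytest.approx(1.0)
        assert gst.pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_four_point_hand_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        r, r2, _ = gst.pearson(x, y)
        assert r == pytest.approx(num / den, rel=1e-12)
        assert r2 == pytest.approx((num / den) ** 2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            gst.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def ks_oracle(x, y):
    pooled = np.concatenate([x, y])
    ecdf_x = np.searchsorted(np.sort(x), pooled, side="right") / x.size
    ecdf_y = np.searchsorted(np.sort(y), pooled, side="right") / y.size
    return np.max(np.abs(ecdf_x - ecdf_y))


class TestKsTwoSample:
    def test_identical_samples_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert gst.ks_two_sample(x, x)[0] == 0.0

    def test_disjoint_supports_one(self):
        d, p = gst.ks_two_sample([1.0, 2, 3], [4.0, 5, 6])
        assert d == 1.0
        assert p < 0.2

    def test_equals_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = rng.normal(0, 1, int(rng.integers(5, 100)))
            y = rng.normal(0.3, 1.5, int(rng.integers(5, 100)))
            assert gst.ks_two_sample(x, y)[0] == pytest.approx(
                ks_oracle(x, y), abs=1e-12
            )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            gst.ks_two_sample([], [1.0])


class TestAdjustP:
    def test_all_ones_no_rejections(self):
        for method in ("bonferroni", "bky_two_stage"):
            assert gst.adjust_p([1.0] * 5, method=method).n_rejected == 0

    def test_bonferroni_arithmetic(self):
        res = gst.adjust_p([0.01, 0.4], method="bonferroni")
        np.testing.assert_allclose(res.adjusted, [0.02, 0.8])
        assert res.rejected.tolist() == [True, False]

    def test_bky_hand_worked_example_rejects_three(self):
        # stage 1 at q' = 0.047619 rejects 3; stage 2 at 0.119048 confirms 3
        res = gst.adjust_p([0.001, 0.01, 0.02, 0.3, 0.9], method="bky_two_stage", q=0.05)
        assert res.rejected.tolist() == [True, True, True, False, False]

    def test_bky_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.uniform(0, 1, int(rng.integers(3, 25)))
            p[: rng.integers(0, 4)] *= 1e-3  # some signal
            ours = gst.adjust_p(p, method="bky_two_stage", q=0.05).rejected
            ref = multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
            np.testing.assert_array_equal(ours, ref)

    def test_bky_dominates_stage_one_bh(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            p = rng.uniform(0, 1, 15)
            p[:3] *= 0.01
            q = 0.05
            bky = gst.adjust_p(p, method="bky_two_stage", q=q).n_rejected
            bh1 = int(gst._bh_stepup(np.asarray(p), q / (1 + q)).sum())
            assert bky >= bh1

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_rejection_flags_shape_and_bounds(self, pvals):
        res = gst.adjust_p(pvals, method="bky_two_stage")
        assert res.rejected.size == len(pvals)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            gst.adjust_p([0.5, 1.5])
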