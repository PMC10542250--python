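import numpy as np
import pytest
from hypothesis import given, strategies as st

from ergfda import (
    BootstrapSpec,
    boxplot_series,
    location_curve,
    scale_curve,
    summary_bundle,
)
from ergfda.summaries import MAD_CONSISTENCY, _mad


class TestLocationCurve:
    def test_mean_of_constant_curves(self):
        m = np.vstack([np.ones(5), 3 * np.ones(5)])
        c = location_curve(m, estimator="mean")
        assert np.allclose(c.estimate, 2.0)
        assert np.all(c.n == 2)

    def test_two_point_t_interval_closed_form(self):
        # {1,3}: mean 2, s=sqrt(2), SE=1, t_{0.975,1}=12.706
        m = np.array([[1.0], [3.0]])
        c = location_curve(m, estimator="mean", alpha=0.05)
        assert np.isclose(c.estimate[0], 2.0)
        assert np.isclose(c.ci_low[0], -10.7062, atol=1e-3)
        assert np.isclose(c.ci_high[0], 14.7062, atol=1e-3)

    def test_median_resists_outlier(self):
        m = np.vstack([np.ones(4), 2 * np.ones(4), 10 * np.ones(4)])
        c = location_curve(m, estimator="median", boot=BootstrapSpec(200, 1))
        assert np.allclose(c.estimate, 2.0)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            location_curve(np.ones((1, 4)))

    def test_zero_bootstrap_replicates_rejected(self):
        with pytest.raises(ValueError, match="at least 1 replicate"):
            BootstrapSpec(n_boot=0)

    def test_missing_cells_rejected(self):
        m = np.ones((3, 4))
        m[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            location_curve(m)


class TestScaleCurve:
    def test_identical_rows_have_zero_dispersion(self):
        m = np.vstack([np.arange(6.0)] * 4)
        for est in ("sd", "mad"):
            c = scale_curve(m, estimator=est, boot=BootstrapSpec(100, 2))
            assert np.allclose(c.estimate, 0.0)

    def test_two_point_sample_sd(self):
        m = np.array([[1.0], [3.0]])
        c = scale_curve(m, estimator="sd", boot=BootstrapSpec(100, 3))
        assert np.isclose(c.estimate[0], np.sqrt(2.0), atol=1e-5)

    def test_hand_computed_mad(self):
        # column {1,2,10}: median 2, |dev| {1,0,8}, median -> 1
        m = np.array([[1.0], [2.0], [10.0]])
        c = scale_curve(m, estimator="mad", boot=BootstrapSpec(100, 4))
        assert c.estimate[0] == 1.0

    def test_mad_variants_and_consistency_scaling(self):
        col = np.array([[1.0], [2.0], [10.0]])
        assert _mad(col, "median_about_median", 1.0)[0] == 1.0
        # mean 13/3; |dev| {10/3, 7/3, 17/3}; mean = 34/9
        assert np.isclose(_mad(col, "mean_about_mean", 1.0)[0], 34 / 9)
        # about median 2: |dev| {1,0,8} -> mean 3
        assert np.isclose(_mad(col, "mean_about_median", 1.0)[0], 3.0)
        assert np.isclose(
            _mad(col, "median_about_median", MAD_CONSISTENCY)[0], MAD_CONSISTENCY
        )


class TestBoxplotSeries:
    def test_hand_computed_tukey_boxplot(self):
        m = np.array([[1.0], [2.0], [3.0], [4.0], [100.0]])
        bx = boxplot_series(m, ids=list("abcde"))
        assert bx.median[0] == 3.0
        assert bx.q1[0] == 2.0 and bx.q3[0] == 4.0
        assert bx.whisker_low[0] == 1.0 and bx.whisker_high[0] == 4.0
        assert bx.outliers[0] == (("e", 100.0),)

    def test_identical_column_collapses_to_point(self):
        m = np.full((6, 3), 2.5)
        bx = boxplot_series(m)
        for arr in (bx.median, bx.q1, bx.q3, bx.whisker_low, bx.whisker_high):
            assert np.allclose(arr, 2.5)
        assert all(o == () for o in bx.outliers)

    def test_no_outliers_when_all_within_fences(self, rng):
        m = rng.uniform(0, 1, size=(10, 4))  # uniform data: fences rarely exceeded
        bx = boxplot_series(m)
        for j, pts in enumerate(bx.outliers):
            col = m[:, j]
            q1, q3 = np.percentile(col, [25, 75])
            fence_lo, fence_hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
            for _, v in pts:
                assert v < fence_lo or v > fence_hi

    def test_whisker_order_invariant(self, rng):
        m = rng.normal(size=(20, 7))
        bx = boxplot_series(m)
        assert np.all(bx.whisker_low <= bx.q1)
        assert np.all(bx.q1 <= bx.median)
        assert np.all(bx.median <= bx.q3)
        assert np.all(bx.q3 <= bx.whisker_high)


class TestSummaryBundle:
    def test_equals_naive_per_column_oracle(self, rng):
        m = rng.normal(size=(12, 9))
        b = summary_bundle(m, boot=BootstrapSpec(50, 7))
        for j in range(9):
            col = m[:, j]
            assert np.isclose(b.mean.estimate[j], sum(col) / 12, atol=1e-12)
            assert np.isclose(
                b.sd.estimate[j],
                np.sqrt(sum((col - col.mean()) ** 2) / 11),
                atol=1e-12,
            )
            assert np.isclose(b.median.estimate[j], sorted(col)[5] / 2 + sorted(col)[6] / 2, atol=1e-12)
            med = np.median(col)
            assert np.isclose(
                b.mad.estimate[j], np.median([abs(v - med) for v in col]), atol=1e-12
            )

    def test_single_column_matrix(self):
        m = np.array([[1.0], [2.0], [5.0]])
        b = summary_bundle(m, boot=BootstrapSpec(50, 8))
        assert b.mean.estimate.shape == (1,)
        assert b.boxplots.median.shape == (1,)

    def test_mean_median_coincide_for_symmetric_rows(self, rng):
        base = rng.normal(size=(5, 8))
        m = np.vstack([base, 2.0 - base])  # symmetric about 1
        b = summary_bundle(m, boot=BootstrapSpec(50, 9))
        assert np.allclose(b.mean.estimate, b.median.estimate, atol=1e-12)
        assert np.allclose(b.mean.estimate, 1.0, atol=1e-12)


class TestInvariances:
    def test_shift_equivariance(self, rng):
        m = rng.normal(size=(10, 6))
        shift = 3.7
        b0 = summary_bundle(m, boot=BootstrapSpec(80, 10))
        b1 = summary_bundle(m + shift, boot=BootstrapSpec(80, 10))
        assert np.allclose(b1.mean.estimate, b0.mean.estimate + shift, atol=1e-12)
        assert np.allclose(b1.median.estimate, b0.median.estimate + shift, atol=1e-12)
        assert np.allclose(b1.sd.estimate, b0.sd.estimate, atol=1e-12)
        assert np.allclose(b1.mad.estimate, b0.mad.estimate, atol=1e-12)

    def test_scale_equivariance(self, rng):
        m = rng.normal(size=(10, 6))
        gamma = 2.5
        b0 = summary_bundle(m, boot=BootstrapSpec(80, 11))
        b1 = summary_bundle(gamma * m, boot=BootstrapSpec(80, 11))
        for est in ("mean", "median", "sd", "mad"):
            assert np.allclose(
                b1[est].estimate, gamma * b0[est].estimate, atol=1e-10
            )

    def test_bootstrap_same_seed_bit_identical(self, rng):
        m = rng.normal(size=(15, 5))
        c1 = scale_curve(m, estimator="sd", boot=BootstrapSpec(300, 42))
        c2 = scale_curve(m, estimator="sd", boot=BootstrapSpec(300, 42))
        assert np.array_equal(c1.ci_low, c2.ci_low)
        assert np.array_equal(c1.ci_high, c2.ci_high)
        c3 = scale_curve(m, estimator="sd", boot=BootstrapSpec(300, 43))
        assert not np.array_equal(c1.ci_low, c3.ci_low)

    def test_cluster_bootstrap_runs_and_differs_from_row_bootstrap(self, rng):
        m = rng.normal(size=(12, 4)) + np.repeat(rng.normal(size=(6, 1)), 2, axis=0)
        clusters = tuple(np.repeat([f"p{i}" for i in range(6)], 2))
        row = scale_curve(m, estimator="sd", boot=BootstrapSpec(200, 1))
        clu = scale_curve(
            m, estimator="sd", boot=BootstrapSpec(200, 1, cluster_ids=clusters)
        )
        assert np.all(clu.ci_high >= clu.ci_low)
        assert not np.array_equal(row.ci_low, clu.ci_low)

    def test_band_always_contains_estimate(self, rng):
        for _ in range(5):
            m = rng.standard_exponential(size=(4, 6))
            for est, fn in (("median", location_curve), ("mad", scale_curve)):
                c = fn(m, estimator=est, boot=BootstrapSpec(100, 5))
                assert np.all(c.ci_low <= c.estimate)
                assert np.all(c.estimate <= c.ci_high)


@given(st.integers(0, 2**31 - 1))
def test_mean_band_is_symmetric_about_estimate(seed):
    m = np.random.default_rng(seed).normal(size=(8, 3))
    c = location_curve(m, estimator="mean")
    assert np.allclose(c.estimate - c.ci_low, c.ci_high - c.estimate, atol=1e-9)
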