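import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ctdose as cd
from ctdose.metrics import ROIStats, SSIM_OFFSET, SSIM_DATA_RANGE


def _uniform_image(value=100.0, n=64, spacing=1.0):
    return cd.ImageGrid(np.full((n, n), value), spacing)


class TestRoiStats:
    def test_uniform_image(self):
        stats = cd.roi_stats(_uniform_image(), cd.ROI.circle((0, 0), 10))
        assert stats.mean_hu == 100.0 and stats.sd_hu == 0.0

    def test_circle_pixel_count_near_analytic_area(self):
        img = _uniform_image(n=128, spacing=1.0)
        stats = cd.roi_stats(img, cd.ROI.circle((0, 0), 10))
        assert abs(stats.n_pixels - np.pi * 100) / (np.pi * 100) < 0.05

    def test_roi_outside_image_raises(self):
        with pytest.raises(ValueError):
            cd.roi_stats(_uniform_image(n=32), cd.ROI.circle((500, 500), 5))

    def test_polygon_roi(self):
        img = _uniform_image(n=64)
        poly = cd.ROI.polygon([(-10, -10), (10, -10), (10, 10), (-10, 10)])
        stats = cd.roi_stats(img, poly)
        assert abs(stats.n_pixels - 400) / 400 < 0.1


class TestCNR:
    def test_equal_means_give_zero(self):
        assert cd.cnr(ROIStats(100, 5, 50), ROIStats(100, 9, 50)) == 0.0

    def test_direct_evaluation(self):
        assert cd.cnr(ROIStats(500, 30, 50), ROIStats(100, 20, 50)) == pytest.approx(
            16.0
        )

    def test_zero_sds_raise(self):
        with pytest.raises(ValueError):
            cd.cnr(ROIStats(500, 0, 50), ROIStats(100, 0, 50))

    @settings(max_examples=30, deadline=None)
    @given(
        mx=st.floats(-500, 500),
        my=st.floats(-500, 500),
        shift=st.floats(-200, 200),
        sx=st.floats(1, 50),
        sy=st.floats(1, 50),
    )
    def test_symmetry_and_shift_invariance(self, mx, my, shift, sx, sy):
        x, y = ROIStats(mx, sx, 20), ROIStats(my, sy, 20)
        xs = ROIStats(mx + shift, sx, 20)
        ys = ROIStats(my + shift, sy, 20)
        assert cd.cnr(x, y) == pytest.approx(cd.cnr(y, x))
        assert cd.cnr(xs, ys) == pytest.approx(cd.cnr(x, y), abs=1e-9)


def _reference_ssim_map(a, b, data_range):
    """Independent sliding-window SSIM with explicit 11x11 Gaussian weights
    (sigma 1.5), valid region only."""
    r = 5
    ax = np.arange(-r, r + 1)
    g1 = np.exp(-(ax**2) / (2 * 1.5**2))
    w = np.outer(g1, g1)
    w /= w.sum()
    k1, k2 = 0.01, 0.03
    c1, c2 = (k1 * data_range) ** 2, (k2 * data_range) ** 2
    h, width = a.shape
    out = np.full(a.shape, np.nan)
    for i in range(r, h - r):
        for j in range(r, width - r):
            pa = a[i - r : i + r + 1, j - r : j + r + 1]
            pb = b[i - r : i + r + 1, j - r : j + r + 1]
            mu_a = (w * pa).sum()
            mu_b = (w * pb).sum()
            va = (w * pa * pa).sum() - mu_a**2
            vb = (w * pb * pb).sum() - mu_b**2
            cov = (w * pa * pb).sum() - mu_a * mu_b
            out[i, j] = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
                (mu_a**2 + mu_b**2 + c1) * (va + vb + c2)
            )
    return out


class TestMaskedSSIM:
    def test_identity_is_one(self, chest_slice_128, rois):
        res = cd.masked_ssim(chest_slice_128, chest_slice_128, rois["heart_mask"])
        assert res.mean_ssim == pytest.approx(1.0)

    def test_more_noise_lower_ssim(self, chest_slice_128, rois):
        rng = np.random.default_rng(0)
        small = cd.ImageGrid(
            chest_slice_128.pixels + rng.normal(0, 20, chest_slice_128.pixels.shape),
            chest_slice_128.spacing_mm,
        )
        large = cd.ImageGrid(
            chest_slice_128.pixels + rng.normal(0, 200, chest_slice_128.pixels.shape),
            chest_slice_128.spacing_mm,
        )
        mask = rois["heart_mask"]
        s_small = cd.masked_ssim(chest_slice_128, small, mask).mean_ssim
        s_large = cd.masked_ssim(chest_slice_128, large, mask).mean_ssim
        assert s_large < s_small

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        a = cd.ImageGrid(rng.uniform(-500, 1500, (24, 24)), 1.0)
        b = cd.ImageGrid(a.pixels + rng.normal(0, 50, (24, 24)), 1.0)
        mask = cd.ROI.polygon([(-12, -12), (12, -12), (12, 12), (-12, 12)])
        result = cd.masked_ssim(a, b, mask)
        au = np.clip(a.pixels + SSIM_OFFSET, 0, SSIM_DATA_RANGE)
        bu = np.clip(b.pixels + SSIM_OFFSET, 0, SSIM_DATA_RANGE)
        ref = _reference_ssim_map(au, bu, SSIM_DATA_RANGE)
        assert result.mean_ssim == pytest.approx(
            np.nanmean(ref), abs=1e-10
        )

    def test_shape_mismatch_raises(self, chest_slice_128, rois):
        other = _uniform_image(n=64)
        with pytest.raises(ValueError):
            cd.masked_ssim(chest_slice_128, other, rois["heart_mask"])


class TestAucSSIM:
    def test_constant_and_triangle(self):
        assert cd.auc_ssim([1.0, 1.0], [0.0, 1.0]) == pytest.approx(1.0)
        assert cd.auc_ssim([0.0, 1.0], [0.0, 1.0]) == pytest.approx(0.5)

    def test_matches_trapezoid_oracle(self):
        rng = np.random.default_rng(1)
        d = np.sort(rng.uniform(0.02, 1.0, 13))
        s = rng.uniform(0.8, 1.0, 13)
        manual = sum(
            (s[i] + s[i + 1]) / 2 * (d[i + 1] - d[i]) for i in range(12)
        )
        assert cd.auc_ssim(s, d) == pytest.approx(manual, abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            cd.auc_ssim([1.0, 1.0, 1.0], [0.0, 1.0])

    @settings(max_examples=20, deadline=None)
    @given(scale=st.floats(0.1, 5.0), n=st.integers(3, 10))
    def test_linearity_property(self, scale, n):
        rng = np.random.default_rng(n)
        d = np.linspace(0.1, 1.0, n)
        s = rng.uniform(0, 1, n)
        assert cd.auc_ssim(scale * s, d) == pytest.approx(
            scale * cd.auc_ssim(s, d), rel=1e-12
        )


class TestCnrRegression:
    def test_perfect_and_doubled(self):
        x = [1.0, 2.0, 3.0, 4.0]
        fit = cd.cnr_regression(x, x)
        assert fit.slope == pytest.approx(1.0) and fit.r2 == pytest.approx(1.0)
        fit2 = cd.cnr_regression(x, [2 * v for v in x])
        assert fit2.slope == pytest.approx(2.0) and fit2.r2 == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(1, 15, 13)
        y = rng.uniform(1, 15, 13)
        fit = cd.cnr_regression(x, y)
        xm, ym = x.mean(), y.mean()
        slope = ((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum()
        intercept = ym - slope * xm
        ss_res = ((y - slope * x - intercept) ** 2).sum()
        r2 = 1 - ss_res / ((y - ym) ** 2).sum()
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.r2 == pytest.approx(r2, abs=1e-10)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            cd.cnr_regression([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


def _metrics(slope, r2, auc):
    return cd.ParameterMetrics(
        params={},
        cnr_fit=cd.RegressionFit(slope=slope, intercept=0.0, r2=r2),
        auc_ssim=auc,
    )


class TestNormalizeAndDeviation:
    def test_per_metric_maximum_has_zero_deviation(self):
        out = cd.normalize_and_deviation(
            [_metrics(1.0, 1.0, 1.0), _metrics(0.2, 0.5, 0.5)]
        )
        assert out[0].deviation == pytest.approx(0.0)
        assert out[1].deviation == pytest.approx(np.sqrt(3.0))

    def test_mid_grid_deviation(self):
        out = cd.normalize_and_deviation(
            [_metrics(0.0, 0.0, 0.0), _metrics(0.5, 0.5, 0.5), _metrics(1.0, 1.0, 1.0)]
        )
        assert out[1].slope_norm == pytest.approx(0.5)
        assert out[1].deviation == pytest.approx(np.sqrt(0.75), abs=1e-12)

    def test_degenerate_metric_normalizes_to_one(self):
        out = cd.normalize_and_deviation(
            [_metrics(1.0, 0.9, 0.7), _metrics(1.0, 0.5, 0.9)]
        )
        assert out[0].slope_norm == 1.0 and out[1].slope_norm == 1.0

    def test_distance_to_ideal_mode_prefers_unit_slope(self):
        out = cd.normalize_and_deviation(
            [_metrics(1.0, 0.9, 0.9), _metrics(2.0, 0.9, 0.9)],
            slope_mode="distance_to_ideal",
        )
        assert out[0].slope_norm == 1.0 and out[1].slope_norm == 0.0

    def test_deviation_nonnegative_property(self):
        rng = np.random.default_rng(3)
        ms = [
            _metrics(rng.uniform(-2, 3), rng.uniform(0, 1), rng.uniform(0.5, 1))
            for _ in range(10)
        ]
        out = cd.normalize_and_deviation(ms)
        assert all(m.deviation >= 0 for m in out)
        assert all(
            0 <= v <= 1 for m in out for v in (m.slope_norm, m.r2_norm, m.auc_norm)
        )
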