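"""Similarity metrics, Bland-Altman, and region agreement tables."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity

from pvcbrain import VolumeImage
from pvcbrain.metrics import (
    bland_altman,
    joint_histogram,
    metric_report,
    psnr,
    region_suv_table,
    rmse,
    ssim,
)

from conftest import random_volume


class TestRmse:
    def test_identical_is_zero(self):
        img = random_volume(seed=0)
        assert rmse(img, img) == 0.0

    def test_hand_arithmetic(self):
        a = np.zeros((8, 8, 8))
        b = np.zeros((8, 8, 8))
        a[0, 0, :2] = [0, 0]
        b[0, 0, :2] = [3, 4]
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[0, 0, :2] = True
        assert rmse(VolumeImage(a), VolumeImage(b), mask) == pytest.approx(
            np.sqrt(12.5)
        )

    def test_matches_loop(self):
        a, b = random_volume(seed=1), random_volume(seed=2)
        total = 0.0
        for idx in np.ndindex(a.shape):
            total += (a.values[idx] - b.values[idx]) ** 2
        assert rmse(a, b) == pytest.approx(np.sqrt(total / a.values.size), rel=1e-12)

    def test_empty_mask_rejected(self):
        img = random_volume(seed=3)
        with pytest.raises(ValueError):
            rmse(img, img, np.zeros(img.shape, dtype=bool))


class TestPsnr:
    def test_closed_forms(self):
        a = np.zeros((8, 8, 8))
        b = np.full((8, 8, 8), 0.1)  # MSE = 0.01
        assert psnr(VolumeImage(a), VolumeImage(b), data_range=1.0) == pytest.approx(20.0)
        b255 = np.full((8, 8, 8), 255.0)
        assert psnr(VolumeImage(a), VolumeImage(b255), data_range=255.0) == pytest.approx(0.0)

    def test_identical_flagged_infinite(self):
        img = random_volume(seed=4)
        assert psnr(img, img) == float("inf")


class TestSsim:
    def test_self_similarity_is_one(self):
        img = random_volume(shape=(32, 32, 32), seed=5)
        assert ssim(img, img, data_range=10.0) == pytest.approx(1.0)

    def test_luminance_shift_reduces(self):
        img = random_volume(shape=(32, 32, 32), seed=6)
        shifted = img.with_values(img.values + 50.0)
        assert ssim(img, shifted, data_range=10.0) < 1.0

    def test_symmetry(self):
        a = random_volume(shape=(24, 24, 24), seed=7)
        b = random_volume(shape=(24, 24, 24), seed=8)
        assert abs(ssim(a, b, data_range=10.0) - ssim(b, a, data_range=10.0)) < 1e-9

    def test_matches_reference_implementation(self):
        a = random_volume(shape=(32, 32, 32), seed=9)
        b = random_volume(shape=(32, 32, 32), seed=10)
        ours = ssim(a, b, data_range=10.0)
        ref = structural_similarity(
            a.values, b.values, data_range=10.0, gaussian_weights=True,
            sigma=1.5, use_sample_covariance=True,
        )
        assert ours == pytest.approx(ref, abs=1e-6)

    def test_window_larger_than_grid_rejected(self):
        a = random_volume(shape=(8, 8, 8), seed=11)
        with pytest.raises(ValueError):
            ssim(a, a, data_range=1.0)


class TestJointHistogram:
    def test_identical_on_diagonal(self):
        img = random_volume(seed=12)
        counts, _ = joint_histogram(img, img, bins=16)
        off_diag = counts - np.diag(np.diag(counts))
        assert off_diag.sum() == 0

    def test_counts_conserved(self):
        a, b = random_volume(seed=13), random_volume(seed=14)
        mask = a.values > 5.0
        counts, _ = joint_histogram(a, b, bins=8, mask=mask)
        assert counts.sum() == mask.sum()

    def test_constant_shift_lands_off_diagonal(self):
        gen = np.random.default_rng(15)
        vals = gen.uniform(0.0, 8.0, size=(8, 8, 8))
        a = VolumeImage(vals)
        bins, rng_hi = 8, 8.0
        shift = rng_hi / bins
        b = VolumeImage(np.clip(vals + shift, 0, rng_hi - 1e-9))
        counts, _ = joint_histogram(a, b, bins=bins, value_range=(0.0, rng_hi))
        first_off = np.diag(counts, k=1).sum() + counts[-1, -1]
        assert first_off == counts.sum()

    def test_too_few_bins(self):
        img = random_volume(seed=16)
        with pytest.raises(ValueError):
            joint_histogram(img, img, bins=1)


class TestBlandAltman:
    def test_hand_arithmetic(self):
        res = bland_altman([1, 2, 3], [1.1, 1.9, 3.0])
        assert res.mean_bias == pytest.approx(0.0)
        assert res.sd_diff == pytest.approx(0.1)
        assert res.loa_low == pytest.approx(-0.196)
        assert res.loa_high == pytest.approx(0.196)

    def test_identical_gives_zero_limits(self):
        res = bland_altman([1.0, 2.0, 4.0], [1.0, 2.0, 4.0])
        assert res.mean_bias == 0.0 and res.loa_low == 0.0 and res.loa_high == 0.0

    def test_pure_offset(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0])
        res = bland_altman(ref, ref + 0.02)
        assert res.mean_bias == pytest.approx(0.02)
        assert res.sd_diff == pytest.approx(0.0, abs=1e-15)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0])

    def test_recovers_injected_bias_and_limits(self):
        """Monte-Carlo recovery: bias 0.02 SUV, SD 0.15, n = 83 regions."""
        gen = np.random.default_rng(2024)
        n, reps, bias, sd = 83, 200, 0.02, 0.15
        biases, widths = [], []
        for _ in range(reps):
            ref = gen.uniform(1.0, 8.0, size=n)
            pred = ref + bias + sd * gen.standard_normal(n)
            res = bland_altman(ref, pred)
            biases.append(res.mean_bias)
            widths.append(res.loa_high - res.loa_low)
        se = sd / np.sqrt(n) / np.sqrt(reps)
        assert abs(np.mean(biases) - bias) < 3 * se
        assert abs(np.mean(widths) - 2 * 1.96 * sd) / (2 * 1.96 * sd) < 0.15


class TestRegionTable:
    def test_perfect_agreement(self, paired_dataset):
        s = paired_dataset[0]
        table, fit = region_suv_table(s.truth, s.truth, s.atlas)
        assert fit["r_squared"] == pytest.approx(1.0)
        assert fit["slope"] == pytest.approx(1.0)
        np.testing.assert_allclose(table["suv_mean_ref"], table["suv_mean_pred"])

    def test_doubling_gives_slope_two(self, paired_dataset):
        s = paired_dataset[0]
        doubled = s.truth.with_values(2 * s.truth.values)
        _, fit = region_suv_table(s.truth, doubled, s.atlas)
        assert fit["slope"] == pytest.approx(2.0)
        assert fit["r_squared"] == pytest.approx(1.0)

    def test_matches_per_label_loop(self, paired_dataset):
        s = paired_dataset[0]
        table, _ = region_suv_table(s.nonpvc, s.reference_pvc, s.atlas)
        for _, row in table.iterrows():
            m = s.atlas.labels == row["region_id"]
            assert row["suv_mean_ref"] == pytest.approx(
                float(s.nonpvc.values[m].mean()), rel=1e-12
            )


class TestMetricReport:
    def test_aggregates(self, paired_dataset):
        pairs = [(s.reference_pvc, s.nonpvc) for s in paired_dataset]
        report = metric_report(pairs)
        summary = report.summary()
        assert len(report.ssim_values) == 3
        assert all(-1 <= v <= 1 for v in report.ssim_values)
        assert all(v >= 0 for v in report.rmse_values)
        assert summary["rmse_mean"] > 0
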