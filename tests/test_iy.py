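"""Iterative Yang correction: region means, artificial image, updates."""

import numpy as np
import pytest

from pvcbrain import (
    IYConfig,
    LabelAtlas,
    ProbabilityMaps,
    PSFModel,
    RegionMeans,
    VolumeImage,
    artificial_image,
    gaussian_blur,
    iy_correct,
    iy_step,
    make_probability_maps,
    region_means,
)

from oracles import dense_gaussian_blur


def _binary_maps(labels: np.ndarray, n: int) -> ProbabilityMaps:
    maps = np.stack([(labels == j) * 1.0 for j in range(1, n + 1)])
    return ProbabilityMaps(maps, tuple(f"r{j}" for j in range(1, n + 1)))


def _rmse(a, b):
    return float(np.sqrt(np.mean((a.values - b.values) ** 2)))


class TestRegionMeans:
    def test_constant_image(self):
        labels = np.zeros((8, 8, 8), dtype=int)
        labels[:4] = 1
        labels[4:] = 2
        img = VolumeImage(np.full((8, 8, 8), 5.0))
        means = region_means(img, _binary_maps(labels, 2))
        np.testing.assert_allclose(means.values, [5.0, 5.0])

    def test_two_halfspaces(self):
        labels = np.zeros((8, 8, 8), dtype=int)
        labels[:4] = 1
        labels[4:] = 2
        vals = np.where(labels == 1, 1.0, 3.0)
        means = region_means(VolumeImage(vals), _binary_maps(labels, 2))
        np.testing.assert_allclose(means.values, [1.0, 3.0])

    def test_matches_per_label_loop(self):
        gen = np.random.default_rng(4)
        labels = gen.integers(0, 4, size=(8, 8, 8))
        vals = gen.uniform(0, 10, size=(8, 8, 8))
        means = region_means(VolumeImage(vals), _binary_maps(labels, 3))
        for j in range(1, 4):
            expected = np.mean([vals[i] for i in zip(*np.nonzero(labels == j))])
            assert means.values[j - 1] == pytest.approx(expected, rel=1e-12)

    def test_soft_maps_weighted_mean(self):
        gen = np.random.default_rng(5)
        vals = gen.uniform(0, 10, size=(8, 8, 8))
        w = gen.uniform(0, 0.5, size=(2, 8, 8, 8))
        pm = ProbabilityMaps(w, ("a", "b"))
        means = region_means(VolumeImage(vals), pm)
        for j in range(2):
            assert means.values[j] == pytest.approx(
                (vals * w[j]).sum() / w[j].sum(), rel=1e-12
            )

    def test_zero_weight_region_named(self):
        maps = np.zeros((2, 8, 8, 8))
        maps[0, :4] = 1.0
        pm = ProbabilityMaps(maps, ("full", "empty"))
        with pytest.raises(ValueError, match="empty"):
            region_means(VolumeImage(np.ones((8, 8, 8))), pm)


class TestArtificialImage:
    def test_binary_maps_piecewise_constant(self):
        labels = np.zeros((8, 8, 8), dtype=int)
        labels[:3] = 1
        labels[3:] = 2
        pm = _binary_maps(labels, 2)
        f_a = artificial_image(RegionMeans([2.0, 7.0]), pm)
        assert np.all(f_a[labels == 1] == 2.0)
        assert np.all(f_a[labels == 2] == 7.0)

    def test_equal_means_give_constant_inside(self):
        labels = np.ones((8, 8, 8), dtype=int)
        labels[4:] = 2
        f_a = artificial_image(RegionMeans([3.0, 3.0]), _binary_maps(labels, 2))
        assert np.all(f_a == 3.0)

    def test_soft_maps_match_dense_sum(self):
        gen = np.random.default_rng(6)
        w = gen.uniform(0, 0.33, size=(3, 8, 8, 8))
        pm = ProbabilityMaps(w, ("a", "b", "c"))
        means = RegionMeans([1.0, 2.0, 5.0])
        f_a = artificial_image(means, pm)
        expected = 1.0 * w[0] + 2.0 * w[1] + 5.0 * w[2]
        np.testing.assert_allclose(f_a, expected, atol=1e-12)

    def test_length_mismatch(self):
        labels = np.ones((8, 8, 8), dtype=int)
        with pytest.raises(ValueError):
            artificial_image(RegionMeans([1.0, 2.0]), _binary_maps(labels, 1))


class TestIYStep:
    def test_delta_psf_returns_input(self):
        gen = np.random.default_rng(7)
        labels = np.ones((8, 8, 8), dtype=int)
        labels[4:] = 2
        f = VolumeImage(gen.uniform(1, 5, size=(8, 8, 8)))
        cfg = IYConfig(psf=PSFModel.delta())
        out = iy_step(f, f, _binary_maps(labels, 2), cfg)
        np.testing.assert_array_equal(out.values, f.values)

    def test_single_region_constant_fixed(self):
        labels = np.ones((8, 8, 8), dtype=int)
        f = VolumeImage(np.full((8, 8, 8), 4.0))
        cfg = IYConfig(psf=PSFModel.isotropic(3.0))
        out = iy_step(f, f, _binary_maps(labels, 1), cfg)
        np.testing.assert_allclose(out.values, f.values, rtol=1e-12)

    def test_matches_scalar_reimplementation(self):
        """One update on an 8^3 two-region instance vs straight-line loops."""
        gen = np.random.default_rng(8)
        labels = np.ones((8, 8, 8), dtype=int)
        labels[:, :4, :] = 2
        f_vals = gen.uniform(1, 6, size=(8, 8, 8))
        prev_vals = gen.uniform(1, 6, size=(8, 8, 8))
        pm = _binary_maps(labels, 2)
        cfg = IYConfig(psf=PSFModel.isotropic(3.0))

        out = iy_step(VolumeImage(f_vals), VolumeImage(prev_vals), pm, cfg)

        # straight-line scalar oracle -------------------------------------
        sums = [0.0, 0.0]
        counts = [0, 0]
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    r = labels[i, j, k] - 1
                    sums[r] += prev_vals[i, j, k]
                    counts[r] += 1
        means = [sums[r] / counts[r] for r in range(2)]
        f_a = np.empty((8, 8, 8))
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    f_a[i, j, k] = means[labels[i, j, k] - 1]
        sigma = (3.0 / (2 * np.sqrt(2 * np.log(2)))) / 1.0
        denom = dense_gaussian_blur(f_a, (sigma, sigma, sigma),
                                    truncate=cfg.psf.truncation_radius)
        guard = cfg.ratio_epsilon * f_a.max()
        expected = np.empty((8, 8, 8))
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    ratio = 1.0 if denom[i, j, k] < guard else f_a[i, j, k] / denom[i, j, k]
                    expected[i, j, k] = f_vals[i, j, k] * max(ratio, 0.0)
        assert np.max(np.abs(out.values - expected)) < 1e-10


class TestIYCorrect:
    def test_defaults_match_reference_protocol(self):
        cfg = IYConfig()
        assert cfg.iterations == 10
        assert cfg.psf.fwhm_mm == (3.0, 3.0, 3.0)

    def test_delta_psf_identity_any_iterations(self, paired_dataset):
        s = paired_dataset[0]
        cfg = IYConfig(iterations=7, psf=PSFModel.delta())
        out = iy_correct(s.nonpvc, s.probmaps, cfg)
        np.testing.assert_array_equal(out.values, s.nonpvc.values)

    def test_recovery_halves_rmse(self, small_spec, small_atlas, small_probmaps):
        from pvcbrain import assign_activities, simulate_pet

        rng = np.random.default_rng(0)
        truth = assign_activities(small_atlas, small_spec, rng)
        psf = PSFModel.isotropic(3.0)
        blurred = simulate_pet(truth, psf, 0.0, rng)
        out = iy_correct(blurred, small_probmaps, IYConfig(psf=psf))
        assert _rmse(out, truth) < 0.5 * _rmse(blurred, truth)

    def test_rmse_strictly_decreases(self, small_spec, small_atlas, small_probmaps):
        from pvcbrain import assign_activities, simulate_pet

        rng = np.random.default_rng(1)
        truth = assign_activities(small_atlas, small_spec, rng)
        psf = PSFModel.isotropic(3.0)
        blurred = simulate_pet(truth, psf, 0.0, rng)
        _, traj = iy_correct(blurred, small_probmaps,
                             IYConfig(psf=psf, record_trajectory=True))
        errs = [_rmse(t, truth) for t in traj]
        assert all(b < a for a, b in zip(errs[:-1], errs[1:]))

    def test_non_negative_output(self, paired_dataset):
        s = paired_dataset[0]
        out = iy_correct(s.nonpvc, s.probmaps, IYConfig())
        assert out.values.min() >= 0

    def test_whole_brain_region_mean_preserved(self):
        gen = np.random.default_rng(9)
        labels = np.ones((16, 16, 16), dtype=int)
        f = VolumeImage(gen.uniform(2, 4, size=(16, 16, 16)))
        pm = _binary_maps(labels, 1)
        out = iy_correct(f, pm, IYConfig(psf=PSFModel.isotropic(3.0)))
        assert out.values.mean() == pytest.approx(f.values.mean(), rel=5e-3)

    def test_negative_input_rejected(self):
        labels = np.ones((8, 8, 8), dtype=int)
        with pytest.raises(ValueError):
            iy_correct(VolumeImage(np.full((8, 8, 8), -1.0) + 0.5),
                       _binary_maps(labels, 1), IYConfig())
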