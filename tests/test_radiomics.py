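"""Radiomic features against brute-force enumeration oracles."""

import numpy as np
import pytest

from pvcbrain import VolumeImage
from pvcbrain.radiomics import (
    FEATURE_NAMES,
    RadiomicsSettings,
    discretize,
    radiomics_features,
    radiomics_table,
    relative_error_heatmap,
)

import oracles

TEXTURE_FEATURES = [
    "HISTO_kurtosis", "HISTO_entropy_log10", "HISTO_entropy_log2",
    "HISTO_uniformity",
    "GLCM_homogeneity", "GLCM_energy", "GLCM_dissimilarity",
    "GLRLM_run_percentage", "NGLDM_contrast",
    "GLZLM_SZE", "GLZLM_LGZE", "GLZLM_HGZE",
]


def _random_region(seed: int):
    """A random 3^3 or 4^3 region (possibly ragged) inside an 8^3 grid."""
    gen = np.random.default_rng(seed)
    side = int(gen.integers(3, 5))
    mask = np.zeros((8, 8, 8), dtype=bool)
    block = gen.random((side, side, side)) < 0.8
    while block.sum() < 8:
        block = gen.random((side, side, side)) < 0.8
    o = int(gen.integers(0, 8 - side))
    mask[o : o + side, o : o + side, o : o + side] = block
    vals = np.zeros((8, 8, 8))
    vals[mask] = gen.uniform(0.5, 10.0, size=int(mask.sum()))
    n_bins = int(gen.integers(3, 9))
    return VolumeImage(vals), mask, n_bins


class TestDiscretize:
    def test_identity_mapping(self):
        levels, degenerate = discretize(np.arange(64, dtype=float), 64)
        np.testing.assert_array_equal(levels, np.arange(1, 65))
        assert not degenerate

    def test_constant_region_flagged(self):
        levels, degenerate = discretize(np.full(10, 3.0), 64)
        assert degenerate
        assert np.all(levels == 1)

    def test_counts_conserved(self):
        gen = np.random.default_rng(0)
        vals = gen.uniform(0, 5, size=200)
        levels, _ = discretize(vals, 16)
        assert levels.min() >= 1 and levels.max() <= 16
        assert np.bincount(levels)[1:].sum() == 200


class TestOracleBattery:
    """All texture/histogram features vs explicit pair/run/zone counting."""

    @pytest.mark.parametrize("seed", range(50))
    def test_features_match_brute_force(self, seed):
        img, mask, n_bins = _random_region(seed)
        settings = RadiomicsSettings(n_bins=n_bins)
        feats = radiomics_features(img, mask, settings)

        vals = img.values[mask]
        levels_region, _ = discretize(vals, n_bins)
        lv = np.zeros(img.shape, dtype=np.int64)
        lv[mask] = levels_region

        expected = {}
        expected.update(oracles.histogram_features(vals, levels_region))
        expected.update(oracles.glcm_features(lv, mask, n_bins))
        expected["GLRLM_run_percentage"] = oracles.glrlm_run_percentage(lv, mask)
        expected["NGLDM_contrast"] = oracles.ngldm_contrast(lv, mask)
        expected.update(oracles.glzlm_features(lv, mask))

        for name in TEXTURE_FEATURES:
            assert feats[name] == pytest.approx(expected[name], rel=1e-10, abs=1e-12), name


class TestClosedForms:
    def test_constant_region(self):
        vals = np.zeros((12, 12, 12))
        vals[1:11, 1:11, 1:11] = 2.0  # 1000 voxels of 1 mm^3
        img = VolumeImage(vals, spacing=(1.0, 1.0, 1.0))
        feats = radiomics_features(img, vals > 0)
        assert feats["degenerate"]
        assert feats["SUV_mean"] == 2.0
        assert feats["SUV_max"] == 2.0
        assert feats["SUV_std"] == 0.0
        assert feats["TLG_mL"] == pytest.approx(2.0)
        assert feats["HISTO_uniformity"] == 1.0
        assert feats["HISTO_entropy_log2"] == 0.0
        assert feats["HISTO_entropy_log10"] == 0.0
        assert feats["GLCM_homogeneity"] == 1.0
        assert feats["GLCM_energy"] == 1.0
        assert feats["GLCM_dissimilarity"] == 0.0
        assert feats["NGLDM_contrast"] == 0.0
        assert feats["AUC_CSH"] == 1.0

    def test_two_value_histogram(self):
        vals = np.zeros((8, 8, 8))
        vals[0, 0, :8] = [1, 1, 1, 1, 2, 2, 2, 2]
        img = VolumeImage(vals)
        feats = radiomics_features(img, np.isin(vals, [1, 2]) & (vals > 0))
        assert feats["SUV_Q2"] == pytest.approx(1.5)
        assert feats["HISTO_uniformity"] == pytest.approx(0.5)

    def test_quartiles_interpolate(self):
        vals = np.zeros((8, 8, 8))
        vals[0, 0] = np.arange(1, 9, dtype=float)
        feats = radiomics_features(VolumeImage(vals), vals > 0)
        assert feats["SUV_Q1"] == pytest.approx(np.percentile(np.arange(1, 9), 25))

    def test_small_region_rejected(self):
        vals = np.zeros((8, 8, 8))
        vals[0, 0, 0] = 1.0
        with pytest.raises(ValueError):
            radiomics_features(VolumeImage(vals), vals > 0)


class TestAxisPermutationInvariance:
    @pytest.mark.parametrize("perm", [(1, 0, 2), (2, 1, 0), (1, 2, 0)])
    def test_texture_invariant_to_axis_permutation(self, perm):
        img, mask, n_bins = _random_region(123)
        settings = RadiomicsSettings(n_bins=n_bins)
        feats = radiomics_features(img, mask, settings)
        img_p = VolumeImage(np.transpose(img.values, perm))
        feats_p = radiomics_features(img_p, np.transpose(mask, perm), settings)
        for name in TEXTURE_FEATURES:
            assert feats[name] == pytest.approx(feats_p[name], rel=1e-10), name


class TestTableAndHeatmap:
    def test_table_has_all_features(self, paired_dataset):
        s = paired_dataset[0]
        table = radiomics_table(s.reference_pvc, s.atlas)
        assert list(table.index) == list(s.atlas.region_names)
        for f in FEATURE_NAMES:
            assert f in table.columns

    def test_identity_heatmap_zero(self, paired_dataset):
        s = paired_dataset[0]
        table = radiomics_table(s.truth, s.atlas)
        err = relative_error_heatmap(table, table)
        assert np.nanmax(np.abs(err.to_numpy(dtype=float))) == pytest.approx(0.0)

    def test_scaled_prediction_ten_percent(self, paired_dataset):
        s = paired_dataset[0]
        ref = radiomics_table(s.truth, s.atlas)
        pred = ref.copy()
        pred[list(FEATURE_NAMES)] = pred[list(FEATURE_NAMES)].astype(float) * 1.1
        err = relative_error_heatmap(ref, pred)
        vals = err.to_numpy(dtype=float)
        np.testing.assert_allclose(vals[np.isfinite(vals)], 10.0, rtol=1e-9)

    def test_zero_reference_flagged_not_infinite(self, paired_dataset):
        s = paired_dataset[0]
        ref = radiomics_table(s.truth, s.atlas)
        pred = ref.copy()
        ref.loc[ref.index[0], "SUV_mean"] = 0.0
        err = relative_error_heatmap(ref, pred)
        assert np.isnan(err.iloc[0, err.columns.get_loc("SUV_mean")])
        assert not np.isinf(err.to_numpy(dtype=float)).any()

    def test_left_right_averaging_merges_homologues(self, paired_dataset):
        s = paired_dataset[0]
        table = radiomics_table(s.truth, s.atlas)
        err = relative_error_heatmap(table, table, lr_average=True)
        assert "deep_grey" in err.index
        assert "deep_grey_left" not in err.index

    def test_mismatched_tables_rejected(self, paired_dataset):
        s = paired_dataset[0]
        table = radiomics_table(s.truth, s.atlas)
        with pytest.raises(ValueError):
            relative_error_heatmap(table, table.iloc[:-1])
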