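"""Discretization, conventional parameters, first-order features and the
41-feature extraction contract."""

import numpy as np
import pytest

from petscore import (
    PhantomSpec,
    SUVVolume,
    build_texture_matrices,
    conventional_params,
    discretize,
    extract_all,
    first_order_features,
    generate_phantom,
    higher_order_features,
)
from petscore.radiomics import (
    CONVENTIONAL_NAMES,
    FEATURE_NAMES,
    FIRST_ORDER_NAMES,
    HIGHER_ORDER_NAMES,
    DiscretizedVOI,
)
from conftest import ball_mask


def _cube_volume(values, spacing=(1, 1, 1)):
    data = np.asarray(values, dtype=float)
    return SUVVolume(data=data, spacing=spacing), np.ones(data.shape, dtype=bool)


class TestDiscretize:
    def test_constant_tumor_maps_to_top_level(self):
        volume, mask = _cube_volume(np.full((4, 4, 4), 7.3))
        disc = discretize(volume, mask, levels=64)
        assert np.all(disc.masked_levels == 64)

    def test_dense_ramp_occupies_all_64_levels(self):
        values = np.linspace(1e-6, 5.0, 10_000).reshape(10, 10, 100)
        volume, mask = _cube_volume(values)
        disc = discretize(volume, mask, levels=64)
        assert len(np.unique(disc.masked_levels)) == 64

    def test_bin_edge_arithmetic_at_half_maximum(self):
        eps = 1e-6
        data = np.zeros((2, 1, 1))
        data[:, 0, 0] = [0.5 - eps, 0.5 + eps]
        volume = SUVVolume(data * 2.0, (1, 1, 1))  # max 1.0 + 2eps scaled
        # construct directly: values {max/2 - e, max/2 + e} with max = 1.0
        data = np.zeros((3, 1, 1))
        data[:, 0, 0] = [0.5 - eps, 0.5 + eps, 1.0]
        volume = SUVVolume(data, (1, 1, 1))
        mask = np.ones((3, 1, 1), dtype=bool)
        disc = discretize(volume, mask, levels=64)
        assert disc.levels[0, 0, 0] == 32
        assert disc.levels[1, 0, 0] == 33

    def test_zero_maps_to_level_one_and_max_to_top(self):
        data = np.zeros((2, 1, 1))
        data[1, 0, 0] = 3.0
        volume = SUVVolume(data, (1, 1, 1))
        disc = discretize(volume, np.ones((2, 1, 1), dtype=bool), levels=64)
        assert disc.levels[0, 0, 0] == 1
        assert disc.levels[1, 0, 0] == 64

    def test_degenerate_inputs_rejected(self):
        volume, mask = _cube_volume(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="zero uptake"):
            discretize(volume, mask)
        volume, mask = _cube_volume(np.ones((3, 3, 3)))
        with pytest.raises(ValueError, match="levels"):
            discretize(volume, mask, levels=1)


class TestConventionalParams:
    def test_tlg_is_mtv_times_mean_suv(self):
        # uniform SUV 5 over 10 cm^3 -> TLG 50 g
        volume, mask = _cube_volume(np.full((10, 10, 100), 5.0))  # 10000 mm^3
        params = conventional_params(volume, mask)
        assert params["mtv_cm3"] == pytest.approx(10.0)
        assert params["tlg_g"] == pytest.approx(50.0)

    def test_mtv_scales_with_voxel_volume(self):
        data = np.zeros((10, 10, 10))
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask.flat[:100] = True
        data[mask] = 1.0
        volume = SUVVolume(data, spacing=(4, 4, 4))
        params = conventional_params(volume, mask)
        assert params["mtv_cm3"] == pytest.approx(100 * 0.064)

    def test_uniform_tumor_peak_equals_max_equals_mean(self):
        data = np.full((20, 20, 20), 4.0)
        volume = SUVVolume(data, (2, 2, 2))
        mask = ball_mask((20, 20, 20), (10, 10, 10), 6)
        params = conventional_params(volume, mask)
        assert params["suv_peak"] == pytest.approx(4.0)
        assert params["suv_max"] == pytest.approx(4.0)

    def test_tlg_identity_on_random_tumors(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            data = rng.uniform(0, 12, (12, 12, 12))
            mask = rng.random((12, 12, 12)) < 0.4
            mask[5, 5, 5] = True
            volume = SUVVolume(data, tuple(rng.uniform(1, 4, 3)))
            p = conventional_params(volume, mask)
            expected = p["mtv_cm3"] * data[mask].mean()
            assert p["tlg_g"] == pytest.approx(expected, rel=1e-9)


class TestFirstOrderFeatures:
    def _disc_from_levels(self, levels_1d, n_levels=64):
        arr = np.asarray(levels_1d, dtype=np.int32).reshape(-1, 1, 1)
        mask = np.ones(arr.shape, dtype=bool)
        return DiscretizedVOI(arr, mask, n_levels, 0.0, 1.0)

    def test_uniform_histogram_entropy_six_bits_energy_one_64th(self):
        disc = self._disc_from_levels(np.repeat(np.arange(1, 65), 8))
        feats = first_order_features(disc, (1, 1, 1))
        assert feats["firstorder_entropy"] == pytest.approx(6.0)
        assert feats["firstorder_energy"] == pytest.approx(1.0 / 64.0)

    def test_single_level_entropy_zero_energy_one(self):
        disc = self._disc_from_levels([5] * 100)
        feats = first_order_features(disc, (1, 1, 1))
        assert feats["firstorder_entropy"] == 0.0
        assert feats["firstorder_energy"] == 1.0

    def test_single_voxel_moments_flagged_missing(self):
        disc = self._disc_from_levels([7])
        feats = first_order_features(disc, (1, 1, 1))
        assert np.isnan(feats["firstorder_skewness"])
        assert np.isnan(feats["firstorder_kurtosis"])

    def test_digitized_ball_sphericity_near_one(self):
        mask = ball_mask((24, 24, 24), (12, 12, 12), 10)
        disc = DiscretizedVOI(mask.astype(np.int32), mask, 64, 0.0, 1.0)
        feats = first_order_features(disc, (1, 1, 1))
        assert 0.95 <= feats["shape_sphericity"] <= 1.0
        assert feats["shape_compacity"] == pytest.approx(
            1.0 / feats["shape_sphericity"]
        )


class TestExtractAll:
    def test_feature_inventory_41_partitioned(self, default_phantom):
        volume, truth = default_phantom
        fv = extract_all(volume, truth.tumor_mask)
        assert tuple(fv.keys()) == FEATURE_NAMES
        assert len(fv) == 41
        assert len(CONVENTIONAL_NAMES) == 4
        assert len(FIRST_ORDER_NAMES) == 6
        assert len(HIGHER_ORDER_NAMES) == 31
        assert all(np.isfinite(v) for v in fv.values())

    def test_small_lesion_rejected_at_64_voxel_floor(self):
        data = np.ones((8, 8, 8))
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask.flat[:63] = True
        with pytest.raises(ValueError, match="64"):
            extract_all(SUVVolume(data, (1, 1, 1)), mask)

    def test_extraction_is_deterministic(self, default_phantom):
        volume, truth = default_phantom
        fv1 = extract_all(volume, truth.tumor_mask)
        fv2 = extract_all(volume, truth.tumor_mask)
        assert fv1 == fv2

    def test_intensity_rescaling_leaves_texture_invariant(self, default_phantom):
        """Relative binning makes histogram/matrix features invariant under
        SUV rescaling, while max/peak/TLG scale linearly and MTV is fixed."""
        volume, truth = default_phantom
        k = 3.7
        fv = extract_all(volume, truth.tumor_mask)
        fv_k = extract_all(SUVVolume(volume.data * k, volume.spacing), truth.tumor_mask)
        for name in ("suv_max", "suv_peak", "tlg_g"):
            assert fv_k[name] == pytest.approx(k * fv[name], rel=1e-9)
        assert fv_k["mtv_cm3"] == pytest.approx(fv["mtv_cm3"], rel=1e-12)
        for name in FIRST_ORDER_NAMES + HIGHER_ORDER_NAMES:
            assert fv_k[name] == pytest.approx(fv[name], rel=1e-9), name


class TestHigherOrderDegenerate:
    def test_constant_lesion_glcm_entropy_zero_energy_one(self):
        levels = np.full((4, 4, 4), 10, dtype=np.int32)
        mask = np.ones((4, 4, 4), dtype=bool)
        disc = DiscretizedVOI(levels, mask, 64, 0.0, 1.0)
        feats = higher_order_features(build_texture_matrices(disc))
        assert feats["glcm_entropy"] == 0.0
        assert feats["glcm_energy"] == 1.0
        assert np.isnan(feats["glcm_correlation"])  # flagged missing

    def test_checker_pattern_has_contrast_and_reduced_homogeneity(self):
        idx = np.indices((4, 4, 4)).sum(axis=0)
        levels = np.where(idx % 2 == 0, 1, 2).astype(np.int32)
        mask = np.ones((4, 4, 4), dtype=bool)
        disc = DiscretizedVOI(levels, mask, 2, 0.0, 1.0)
        feats = higher_order_features(build_texture_matrices(disc))
        assert feats["glcm_contrast"] > 0
        assert feats["glcm_homogeneity"] < 1

    def test_entropy_families_track_each_other_across_heterogeneity(self):
        """First-order and GLCM entropy rank-correlate strongly (> 0.8)
        across a 50-phantom battery spanning heterogeneity levels."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(0)
        first, glcm = [], []
        for i in range(50):
            h = float(rng.uniform(0.05, 1.2))
            volume, truth = generate_phantom(PhantomSpec(heterogeneity=h, seed=500 + i))
            fv = extract_all(volume, truth.tumor_mask)
            first.append(fv["firstorder_entropy"])
            glcm.append(fv["glcm_entropy"])
        rho = spearmanr(first, glcm).statistic
        assert rho > 0.8
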