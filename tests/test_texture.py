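"""Texture features against brute-force oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest

from pdmci.exceptions import DegenerateDesignError, ValidationError
from pdmci.texture import (GLCMConfig, MaskedVolume, OFFSETS_26,
                           first_order_features, glcm_26, haralick_features,
                           quantize, select_features, texture_features)


def glcm_bruteforce(levels, mask, n_levels):
    """Enumerate every ordered in-mask voxel pair at Chebyshev distance 1."""
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                for dx, dy, dz in OFFSETS_26:
                    u, v, w = x + dx, y + dy, z + dz
                    if not (0 <= u < shape[0] and 0 <= v < shape[1]
                            and 0 <= w < shape[2]):
                        continue
                    if not mask[u, v, w]:
                        continue
                    counts[levels[x, y, z] - 1, levels[u, v, w] - 1] += 1
    return counts


def random_masked_volume(rng, n=6):
    vol = rng.normal(size=(n, n, n))
    mask = rng.random((n, n, n)) < 0.7
    if mask.sum() < 8:
        mask[:2, :2, :2] = True
    return MaskedVolume(vol, mask)


class TestGlcm:
    def test_matches_bruteforce_on_random_volumes(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            mv = random_masked_volume(rng)
            levels = quantize(mv, 4)
            P = glcm_26(levels, mv.mask, GLCMConfig(n_levels=4))
            ref = glcm_bruteforce(levels, mv.mask, 4)
            assert ref.sum() > 0
            assert np.array_equal(np.round(P * ref.sum()).astype(np.int64),
                                  ref)

    def test_toy_2x2x1_pair_enumeration(self):
        """Levels [[1,2],[2,1]] in a 2x2x1 slab: 12 ordered pairs, 8 of
        them discordant, giving contrast 2/3."""
        levels = np.array([[[1], [2]], [[2], [1]]])
        mask = np.ones_like(levels, dtype=bool)
        P = glcm_26(levels, mask, GLCMConfig(n_levels=2))
        assert P[0, 1] + P[1, 0] == pytest.approx(8 / 12)
        assert P[0, 0] + P[1, 1] == pytest.approx(4 / 12)
        feats = haralick_features(P)
        assert feats["contrast"] == pytest.approx(8 / 12)

    def test_constant_volume_is_pure_diagonal(self):
        levels = np.ones((3, 3, 3), dtype=int)
        P = glcm_26(levels, np.ones((3, 3, 3), bool), GLCMConfig(n_levels=2))
        assert P[0, 0] == pytest.approx(1.0)
        assert np.sum((np.arange(2)[:, None] - np.arange(2)) ** 2 * P) == 0

    def test_isolated_voxel_raises_empty_glcm(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        levels = np.where(mask, 1, 0)
        with pytest.raises(DegenerateDesignError):
            glcm_26(levels, mask, GLCMConfig(n_levels=2))

    def test_rotation_invariance_of_features(self):
        """The 26-offset neighbourhood is symmetric under 90-degree
        rotations, so all features must be too."""
        rng = np.random.default_rng(1)
        mv = random_masked_volume(rng, n=7)
        base = texture_features(mv, n_levels=8)
        rot = MaskedVolume(np.rot90(mv.intensities, axes=(0, 1)).copy(),
                           np.rot90(mv.mask, axes=(0, 1)).copy())
        for k, v in texture_features(rot, n_levels=8).items():
            assert v == pytest.approx(base[k]), k


class TestFirstOrder:
    def test_symmetric_two_point_distribution(self):
        """Equal counts of -1/+1: mean 0, skewness 0, kurtosis
        E[x^4]/E[x^2]^2 = 1."""
        vals = np.tile([-1.0, 1.0], 32).reshape(4, 4, 4)
        mv = MaskedVolume(vals, np.ones_like(vals, bool))
        f = first_order_features(mv)
        assert f["mean"] == pytest.approx(0.0)
        assert f["skewness"] == pytest.approx(0.0)
        assert f["kurtosis"] == pytest.approx(1.0)

    def test_normal_sample_kurtosis_near_three(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(30, 30, 30))
        f = first_order_features(MaskedVolume(vals, np.ones_like(vals, bool)))
        assert f["kurtosis"] == pytest.approx(3.0, abs=0.15)
        assert f["skewness"] == pytest.approx(0.0, abs=0.1)

    def test_constant_intensities_rejected(self):
        vals = np.full((4, 4, 4), 7.0)
        with pytest.raises(DegenerateDesignError):
            first_order_features(MaskedVolume(vals, np.ones_like(vals, bool)))


class TestQuantize:
    def test_integer_ramp_is_identity_labeling(self):
        vals = np.arange(32.0).reshape(2, 4, 4)
        mv = MaskedVolume(vals, np.ones_like(vals, bool))
        levels = quantize(mv, 32)
        assert np.array_equal(np.sort(levels.ravel()),
                              np.arange(1, 33))

    def test_min_max_map_to_extreme_levels(self):
        rng = np.random.default_rng(3)
        mv = random_masked_volume(rng)
        levels = quantize(mv, 16)
        inmask = levels[mv.mask]
        assert inmask[np.argmin(mv.values)] == 1
        assert inmask[np.argmax(mv.values)] == 16
        assert inmask.min() >= 1 and inmask.max() <= 16

    def test_constant_volume_single_level(self):
        vals = np.full((3, 3, 3), 5.0)
        mv = MaskedVolume(vals, np.ones_like(vals, bool))
        levels = quantize(mv, 8)
        assert set(levels[mv.mask]) == {1}


class TestHaralick:
    def test_uniform_2x2_entropy_is_two_bits(self):
        P = np.full((2, 2), 0.25)
        assert haralick_features(P)["entropy"] == pytest.approx(2.0)

    def test_uniform_diagonal_has_zero_contrast_unit_idm(self):
        P = np.eye(4) / 4
        f = haralick_features(P)
        assert f["contrast"] == 0.0
        assert f["inverse_difference_moment"] == pytest.approx(1.0)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValidationError):
            haralick_features(np.full((2, 2), 0.3))

    def test_degenerate_marginal_rejected(self):
        P = np.zeros((3, 3))
        P[1, 1] = 1.0
        with pytest.raises(DegenerateDesignError):
            haralick_features(P)


class TestSelectFeatures:
    def make_table(self, values, feature="f", structure="s"):
        return pd.DataFrame({
            "subject_id": [f"sub-{i}" for i in range(len(values))],
            "structure_id": structure, "feature": feature, "value": values,
        })

    def test_monotone_feature_selected(self):
        codes = pd.Series(np.repeat([0, 1, 2, 3], 10),
                          index=[f"sub-{i}" for i in range(40)])
        table = self.make_table(np.arange(40.0) + 0.1)
        out = select_features(table, codes)
        assert out.loc[0, "selected"]

    def test_constant_feature_skipped_with_warning(self):
        codes = pd.Series(np.repeat([0, 1, 2, 3], 5),
                          index=[f"sub-{i}" for i in range(20)])
        table = self.make_table(np.ones(20))
        with pytest.warns(UserWarning, match="constant"):
            out = select_features(table, codes)
        assert out.empty

    def test_null_features_selected_at_about_alpha_rate(self):
        rng = np.random.default_rng(4)
        codes = pd.Series(np.repeat([0, 1, 2, 3], 25),
                          index=[f"sub-{i}" for i in range(100)])
        frames = [self.make_table(rng.normal(size=100), feature=f"f{j}")
                  for j in range(400)]
        out = select_features(pd.concat(frames, ignore_index=True), codes)
        rate = out["selected"].mean()
        assert 0.01 <= rate <= 0.10   # binomial band around the 5% rate
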