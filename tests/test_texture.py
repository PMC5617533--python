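"""NGLCM/NGTDM texture tests, including brute-force oracle equivalence."""

import numpy as np
import pytest

from ohscc.texture import (
    NGTDM_EPS,
    LabelVolume,
    Nglcm,
    compute_nglcm,
    compute_ngtdm,
    nglcm_features,
    nglcm_features_per_direction,
    ngtdm_features,
    resample_intensities,
    texture_features_all,
)
from oracles import nglcm_brute, ngtdm_brute, ngtdm_features_brute

from conftest import random_label_volume


class TestResampling:
    def test_integer_ramp_maps_bijectively_onto_bins(self):
        vals = np.arange(32, dtype=float).reshape(2, 4, 4)
        lv = resample_intensities(vals, np.ones(vals.shape, bool), bins=32)
        assert sorted(lv.data.ravel()) == list(range(1, 33))

    def test_extremes_map_to_first_and_last_bin(self, rng):
        vals = rng.uniform(2, 9, size=(4, 4, 4))
        mask = np.ones(vals.shape, bool)
        for bins in (32, 64):
            lv = resample_intensities(vals, mask, bins=bins)
            assert lv.data[np.unravel_index(vals.argmin(), vals.shape)] == 1
            assert lv.data[np.unravel_index(vals.argmax(), vals.shape)] == bins
            assert lv.data[mask].min() >= 1 and lv.data[mask].max() <= bins

    def test_constant_region_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            resample_intensities(np.ones((3, 3, 3)), np.ones((3, 3, 3), bool), bins=32)


class TestNglcm:
    def test_constant_labels_give_single_entry(self):
        lv = LabelVolume(np.ones((3, 3, 3), int), 2, np.ones((3, 3, 3), bool))
        m = compute_nglcm(lv)
        assert m.matrix[0, 0] == pytest.approx(1.0)
        assert m.matrix.sum() == pytest.approx(1.0)

    def test_alternating_line_matrix(self):
        # 1x1x4 line [1,2,1,2]: only the in-line direction has pairs
        lv = LabelVolume(np.array([[[1, 2, 1, 2]]]), 2, np.ones((1, 1, 4), bool))
        m = compute_nglcm(lv)
        np.testing.assert_allclose(m.matrix, [[0, 0.5], [0.5, 0]])

    def test_normalization_on_random_masks(self, rng):
        for _ in range(10):
            labels, mask = random_label_volume(rng)
            try:
                m = compute_nglcm(LabelVolume(labels, 4, mask))
            except ValueError:
                continue
            assert m.matrix.sum() == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(m.matrix, m.matrix.T)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(30):
            labels, mask = random_label_volume(rng)
            try:
                ours = compute_nglcm(LabelVolume(labels, 4, mask)).matrix
            except ValueError:
                continue
            np.testing.assert_allclose(ours, nglcm_brute(labels, mask, 4), atol=1e-12)


class TestNglcmFeatures:
    def test_one_hot_matrix_limits(self):
        m = np.zeros((4, 4))
        m[2, 2] = 1.0
        f = nglcm_features(Nglcm(m, 4))
        assert f.uniformity == pytest.approx(1.0)
        assert f.entropy == pytest.approx(0.0)
        assert f.contrast == pytest.approx(0.0)
        assert f.homogeneity == pytest.approx(1.0)
        assert f.correlation == 0.0  # sigma = 0 convention

    def test_two_level_alternating_matrix_hand_values(self):
        f = nglcm_features(Nglcm(np.array([[0, 0.5], [0.5, 0]]), 2))
        assert f.uniformity == pytest.approx(0.5)
        assert f.contrast == pytest.approx(1.0)
        assert f.dissimilarity == pytest.approx(1.0)
        assert f.entropy == pytest.approx(1.0)  # log base 2

    @pytest.mark.parametrize("bins", [4, 32])
    def test_uniform_matrix_closed_forms(self, bins):
        m = np.full((bins, bins), 1.0 / bins**2)
        f = nglcm_features(Nglcm(m, bins))
        assert f.entropy == pytest.approx(2 * np.log2(bins))
        assert f.uniformity == pytest.approx(1.0 / bins**2)
        assert f.correlation == pytest.approx(0.0, abs=1e-12)


class TestNgtdm:
    def test_constant_labels_zero_differences(self):
        lv = LabelVolume(np.full((3, 3, 3), 2, dtype=int), 4, np.ones((3, 3, 3), bool))
        p, s, n = compute_ngtdm(lv)
        assert n == 27
        np.testing.assert_allclose(s, 0.0)
        assert p.sum() == pytest.approx(1.0)

    def test_1x1x3_line_hand_enumeration(self):
        lv = LabelVolume(np.array([[[1, 2, 1]]]), 2, np.ones((1, 1, 3), bool))
        p, s, n = compute_ngtdm(lv)
        assert n == 3
        np.testing.assert_allclose(s, [2.0, 1.0])
        np.testing.assert_allclose(p, [2 / 3, 1 / 3])

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(30):
            labels, mask = random_label_volume(rng)
            lv = LabelVolume(labels, 4, mask)
            p, s, n = compute_ngtdm(lv)
            pb, sb, nb = ngtdm_brute(labels, mask, 4)
            assert n == nb
            np.testing.assert_allclose(p, pb, atol=1e-12)
            np.testing.assert_allclose(s, sb, atol=1e-10)

    def test_single_level_conventions(self):
        p = np.array([1.0, 0.0])
        s = np.zeros(2)
        f = ngtdm_features(p, s, 8, 2)
        assert f.coarseness == pytest.approx(1.0 / NGTDM_EPS)
        assert f.contrast == 0.0 and f.busyness == 0.0

    def test_features_match_brute_force_formulas(self, rng):
        for _ in range(20):
            labels, mask = random_label_volume(rng)
            lv = LabelVolume(labels, 4, mask)
            p, s, n = compute_ngtdm(lv)
            if n == 0:
                continue
            ours = ngtdm_features(p, s, n, 4)
            ref = ngtdm_features_brute(p, s, n, 4)
            assert ours.coarseness == pytest.approx(ref["coarseness"], rel=1e-10)
            assert ours.contrast == pytest.approx(ref["contrast"], rel=1e-10, abs=1e-14)
            assert ours.busyness == pytest.approx(ref["busyness"], rel=1e-10, abs=1e-14)
            assert ours.complexity == pytest.approx(ref["complexity"], rel=1e-10, abs=1e-14)
            assert ours.strength == pytest.approx(ref["strength"], rel=1e-10, abs=1e-14)


class TestPipelineLevel:
    def test_checkerboard_separation_monotonicity(self):
        """Widening the two-level separation cannot raise uniformity or
        lower NGLCM contrast (heterogeneity sanity check)."""
        from ohscc.synthetic import LesionSpec, generate_pet_phantom

        uniformities, contrasts = [], []
        for delta in (0.5, 1.0, 2.0):
            spec = LesionSpec(center=(12, 12, 12), radius_mm=10.0, lesion_suv_mean=8.0,
                              heterogeneity_texture="two-level-checker",
                              checker_delta=delta, seed=5)
            ph = generate_pet_phantom(spec, shape=(25, 25, 25), spacing_mm=(2, 2, 2))
            feats = texture_features_all(ph.volume, ph.lesion_mask, bins=(32,))
            uniformities.append(feats["uniformity_32"])
            contrasts.append(feats["contrast_32"])
        assert uniformities[0] >= uniformities[1] >= uniformities[2]
        assert contrasts[0] <= contrasts[1] <= contrasts[2]

    def test_both_bin_counts_reported_with_suffixed_keys(self, constant_phantom):
        ph = constant_phantom
        # add a gradient so the tumor is not constant
        vol = ph.volume
        vol.data[ph.lesion_mask.data] += np.linspace(
            0, 2, ph.lesion_mask.n_voxels)
        feats = texture_features_all(vol, ph.lesion_mask, bins=(32, 64))
        for b in (32, 64):
            for name in ("uniformity", "entropy", "coarseness", "busyness"):
                assert f"{name}_{b}" in feats
                assert np.isfinite(feats[f"{name}_{b}"])

    def test_feature_averaging_route_close_but_distinct_api(self, rng):
        labels, mask = random_label_volume(rng, max_side=6)
        lv = LabelVolume(labels, 4, mask)
        f = nglcm_features_per_direction(lv)
        assert np.isfinite(f.uniformity) and 0 < f.uniformity <= 1
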