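import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glcmrad as gr
from glcmrad.features import (
    FEATURE_NAMES,
    FIRST_ORDER_NAMES,
    GLCM_DIRECTIONS,
    SECOND_ORDER_NAMES,
    GLCMatrix,
)
from glcmrad.imaging import ValidationError

from _oracles import (
    first_order_bruteforce,
    glcm_bruteforce,
    second_order_bruteforce,
)


class TestQuantize:
    def test_linear_binning_with_top_edge_rule(self):
        v = np.array([0.0, 50.0, 100.0])
        assert gr.quantize_intensities(v, 8).tolist() == [1, 5, 8]

    def test_constant_volume_maps_to_level_one(self):
        assert (gr.quantize_intensities(np.full((3, 4, 4), 7.0), 16) == 1).all()

    def test_rejects_fewer_than_two_levels(self):
        with pytest.raises(ValidationError):
            gr.quantize_intensities(np.arange(10.0), 1)

    @given(st.integers(0, 2**31 - 1), st.sampled_from([2, 8, 64, 512]))
    @settings(max_examples=30, deadline=None)
    def test_levels_bounded_and_count_conserved(self, seed, n):
        x = np.random.default_rng(seed).normal(size=40)
        q = gr.quantize_intensities(x, n)
        assert q.min() >= 1 and q.max() <= n
        assert np.bincount(q).sum() == x.size

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_mapping_monotone_in_intensity(self, seed):
        x = np.sort(np.random.default_rng(seed).normal(size=30))
        q = gr.quantize_intensities(x, 16)
        assert (np.diff(q) >= 0).all()


class TestComputeGLCM:
    def test_hand_enumerated_pairs(self):
        img = np.array([[1, 1, 2], [1, 2, 2]])
        g = gr.compute_glcm(img, np.ones((2, 3), bool), 2, 0)
        assert g.values.tolist() == [[2.0, 2.0], [2.0, 2.0]]

    def test_constant_region_concentrates_at_diagonal(self):
        img = np.full((4, 4), 3)
        g = gr.compute_glcm(img, np.ones((4, 4), bool), 4, 90)
        assert g.values[2, 2] == g.values.sum() > 0

    def test_single_pixel_mask_is_degenerate(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        g = gr.compute_glcm(np.ones((3, 3), int), mask, 2, 0)
        assert g.degenerate and g.values.sum() == 0

    @pytest.mark.parametrize("direction", [0, 45, 90, 135])
    def test_matches_bruteforce_and_conserves_pairs(self, direction):
        rng = np.random.default_rng(direction)
        for _ in range(25):
            n = int(rng.integers(2, 17))
            shape = (int(rng.integers(2, 17)), int(rng.integers(2, 17)))
            img = rng.integers(1, n + 1, size=shape)
            mask = rng.random(shape) < 0.7
            if not mask.any():
                continue
            g = gr.compute_glcm(img, mask, n, direction)
            ref = glcm_bruteforce(img, mask, n, direction)
            np.testing.assert_allclose(g.values, ref, atol=1e-9)
            assert np.allclose(g.values, g.values.T)  # symmetric by construction


    @pytest.mark.parametrize("direction,angle", [(0, 0.0), (45, 3 * np.pi / 4),
                                                 (90, np.pi / 2), (135, np.pi / 4)])
    def test_agrees_with_skimage_on_full_masks(self, direction, angle):
        """On unmasked images the pair counts must match an established
        co-occurrence implementation.

        Angle conventions differ: here 45 deg steps up-right (as in the
        common image-processing convention with the row axis pointing
        down), while skimage's angles sweep the other way, so 45 and 135
        swap."""
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(42)
        img = rng.integers(1, 9, size=(12, 14))
        ours = gr.compute_glcm(img, np.ones(img.shape, bool), 8, direction)
        ref = graycomatrix(
            (img - 1).astype(np.uint8), [1], [angle], levels=8, symmetric=True
        )[:, :, 0, 0]
        np.testing.assert_array_equal(ours.values, ref)


class TestAggregate:
    def _random_glcms(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(1, 5, size=(8, 8))
        mask = np.ones((8, 8), bool)
        return [gr.compute_glcm(img, mask, 4, d) for d in GLCM_DIRECTIONS]

    def test_average_of_identical_matrices_is_idempotent(self):
        m = np.full((2, 2), 0.25)
        out = gr.aggregate_glcm([GLCMatrix(m * 4, 2, directions=(d,))
                                 for d in (0, 45, 90, 135)])
        np.testing.assert_allclose(out.values, m)

    def test_output_normalized(self):
        out = gr.aggregate_glcm(self._random_glcms(1))
        assert out.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert out.normalized and out.offsets_averaged

    def test_all_degenerate_propagates(self):
        z = GLCMatrix(np.zeros((3, 3)), 3, degenerate=True)
        assert gr.aggregate_glcm([z, z, z, z]).degenerate

    def test_whole_tumor_mean_matches_bruteforce(self):
        glcms = [gr.aggregate_glcm(self._random_glcms(s)) for s in range(5)]
        out = gr.whole_tumor_glcm(glcms)
        ref = np.mean([g.values for g in glcms], axis=0)
        np.testing.assert_allclose(out.values, ref, atol=1e-12)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rotation_by_90_degrees_preserves_aggregate(self):
        rng = np.random.default_rng(9)
        img = rng.integers(1, 7, size=(9, 12))
        mask = rng.random((9, 12)) < 0.8
        a = gr.aggregate_glcm([gr.compute_glcm(img, mask, 6, d)
                               for d in GLCM_DIRECTIONS])
        img_r, mask_r = np.rot90(img), np.rot90(mask)
        b = gr.aggregate_glcm([gr.compute_glcm(img_r, mask_r, 6, d)
                               for d in GLCM_DIRECTIONS])
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)


class TestFirstOrder:
    def test_symmetric_sample(self):
        f = gr.first_order_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert f["mean_intensity"] == pytest.approx(2.5)
        assert f["median_intensity"] == pytest.approx(2.5)
        assert f["intensity_skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_right_tailed_sample_has_positive_skew(self):
        f = gr.first_order_features(np.array([0.0, 0.0, 0.0, 10.0]))
        assert f["intensity_skewness"] > 0

    def test_constant_sample_flags_moments_undefined(self):
        f = gr.first_order_features(np.full(10, 3.0))
        assert np.isnan(f["intensity_skewness"]) and np.isnan(f["intensity_kurtosis"])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_definition_formulas(self, seed):
        x = np.random.default_rng(seed).normal(50, 10, size=200)
        ours = gr.first_order_features(x)
        ref = first_order_bruteforce(x)
        for name in FIRST_ORDER_NAMES:
            assert ours[name] == pytest.approx(ref[name], rel=1e-9), name


class TestSecondOrder:
    def test_uniform_two_level_glcm(self):
        g = GLCMatrix(np.full((2, 2), 0.25), 2, normalized=True)
        f = gr.second_order_features(g)
        assert f["contrast"] == pytest.approx(0.5)
        assert f["joint_energy"] == pytest.approx(0.25)
        assert f["joint_entropy"] == pytest.approx(2.0)  # bits
        assert f["maximum_probability"] == pytest.approx(0.25)

    def test_single_cell_glcm(self):
        m = np.zeros((4, 4))
        m[2, 2] = 1.0  # level 3
        f = gr.second_order_features(GLCMatrix(m, 4, normalized=True))
        assert f["contrast"] == 0.0
        assert f["joint_energy"] == pytest.approx(1.0)
        assert f["autocorrelation"] == pytest.approx(9.0)
        assert np.isnan(f["correlation"])  # zero variance -> undefined

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 17))
        m = rng.random((n, n))
        m = m + m.T
        m /= m.sum()
        ours = gr.second_order_features(GLCMatrix(m, n, normalized=True))
        ref = second_order_bruteforce(m)
        for name in SECOND_ORDER_NAMES:
            assert ours[name] == pytest.approx(ref[name], abs=1e-9), name


class TestExtractFeatureVector:
    def test_emits_all_registry_features_finite(self, small_phantom):
        volume, mask = small_phantom
        fv = gr.extract_feature_vector(volume, mask, "whole", 512)
        assert len(fv) == len(FEATURE_NAMES) == 33
        assert np.isfinite(fv.to_series().to_numpy()).all()

    def test_deterministic(self, small_phantom):
        volume, mask = small_phantom
        a = gr.extract_feature_vector(volume, mask, "central", 64)
        b = gr.extract_feature_vector(volume, mask, "central", 64)
        assert a.features == b.features

    def test_correlation_length_separates_cluster_prominence(self):
        """Texture classes with very different correlation lengths must be
        separable by cluster prominence well beyond sampling noise."""
        fine = gr.PhantomClassSpec("fine", 0.6, 500, 100, 0.0, 1, 0.1, 0.1, 0.01)
        coarse = gr.PhantomClassSpec("coarse", 4.0, 500, 100, 0.0, 1, 0.1, 0.1, 0.01)
        vals = {}
        for spec in (fine, coarse):
            v = []
            for seed in range(8):
                # a large tumor keeps the fourth-moment estimate stable
                vol, m = gr.generate_phantom_volume(spec, 120.0, (32, 160, 160), seed)
                fv = gr.extract_feature_vector(vol, m, "whole", 32)
                v.append(fv.features["cluster_prominence"])
            vals[spec.class_label] = np.asarray(v)
        gap = abs(vals["fine"].mean() - vals["coarse"].mean())
        pooled_sd = np.sqrt((vals["fine"].var() + vals["coarse"].var()) / 2)
        assert gap > 3 * pooled_sd

    def test_absent_region_rejected(self):
        vox = np.zeros((3, 6, 6), bool)
        vox[1, :3, :3] = True
        mask = gr.ROIMask(vox)
        volume = gr.ImageVolume(np.random.default_rng(0).normal(size=(3, 6, 6)))
        with pytest.raises(ValidationError):
            gr.extract_feature_vector(volume, mask, "edge", 8)

    def test_size_dependent_features_move_monotonically_with_n(self, small_phantom):
        """Index-scaling features must grow with the number of gray levels
        while a constant region's joint energy stays pinned at 1."""
        volume, mask = small_phantom
        sizes = (8, 32, 128, 512)
        tracked = {"autocorrelation": [], "cluster_prominence": [],
                   "sum_of_squares": [], "sum_variance": []}
        for n in sizes:
            fv = gr.extract_feature_vector(volume, mask, "whole", n)
            for k in tracked:
                tracked[k].append(fv.features[k])
        for k, vals in tracked.items():
            assert (np.diff(vals) > 0).all(), k
        flat = gr.ImageVolume(np.zeros((2, 6, 6)))
        # constant image: every in-mask pair sits at level (1, 1) at any N
        for n in sizes:
            g = gr.compute_glcm(gr.quantize_intensities(flat.voxels, n)[0],
                                np.ones((6, 6), bool), n, 0)
            f = gr.second_order_features(gr.aggregate_glcm([g]))
            assert f["joint_energy"] == pytest.approx(1.0)
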