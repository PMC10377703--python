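import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fluoseries as fs
from fluoseries.image import MultispectralImage
from fluoseries.roi import RoiMask


def toy_image(X, H, W):
    """Fold an (H*W)×C data table back into an image with a full mask."""
    C = X.shape[1]
    pad = np.zeros((H * W, 11))
    pad[:, :C] = X
    return MultispectralImage(pad.reshape(H, W, 11)), RoiMask(np.ones((H, W), bool))


def single_pixel_image(x):
    img = MultispectralImage(np.asarray(x, float).reshape(1, 1, -1).repeat(1, axis=0))
    return img, RoiMask(np.ones((1, 1), bool))


class TestLocalStats:
    def test_two_pixel_hand_oracle(self):
        # pixels (1,2) and (3,4): s=(4,6), V = X'X = [[10,14],[14,20]]
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        img, roi = toy_image(X, 1, 2)
        st_ = fs.accumulate_local_stats(img, roi)
        assert st_.n == 2
        np.testing.assert_array_equal(st_.s[:2], [4, 6])
        np.testing.assert_array_equal(st_.V[:2, :2], [[10, 14], [14, 20]])

    def test_single_pixel_outer_product(self, rng):
        x = rng.uniform(0, 100, 11)
        img, roi = single_pixel_image(x)
        st_ = fs.accumulate_local_stats(img, roi)
        assert st_.n == 1
        np.testing.assert_allclose(st_.s, x)
        np.testing.assert_allclose(st_.V, np.outer(x, x))

    def test_all_zero_pixels(self):
        img = MultispectralImage(np.zeros((2, 2, 11)))
        st_ = fs.accumulate_local_stats(img, RoiMask(np.ones((2, 2), bool)))
        assert (st_.s == 0).all() and (st_.V == 0).all()

    def test_empty_roi_rejected(self):
        img = MultispectralImage(np.ones((2, 2, 11)))
        with pytest.raises(ValueError, match="empty"):
            fs.accumulate_local_stats(img, RoiMask(np.zeros((2, 2), bool)))


class TestFitLargePca:
    def test_two_one_pixel_images_hand_covariance(self):
        i1, r1 = single_pixel_image(np.array([1.0] + [0.0] * 10))
        i2, r2 = single_pixel_image(np.array([3.0] + [0.0] * 10))
        stats = [fs.accumulate_local_stats(i1, r1), fs.accumulate_local_stats(i2, r2)]
        model = fs.fit_large_pca(stats)
        assert model.n == 2
        assert model.mean[0] == 2.0
        assert model.cov[0, 0] == 1.0          # divide-by-n convention
        assert model.eigenvalues[0] == 1.0
        assert abs(model.eigenvalues[1]) <= 1e-12
        np.testing.assert_allclose(model.loadings[:, 0], [1.0] + [0.0] * 10, atol=1e-12)

    def test_constant_pixels_all_eigenvalues_zero(self):
        img = MultispectralImage(np.full((3, 3, 11), 4.0))
        roi = RoiMask(np.ones((3, 3), bool))
        with pytest.warns(RuntimeWarning, match="zero total variance"):
            model = fs.fit_large_pca([fs.accumulate_local_stats(img, roi)])
        assert model.degenerate
        np.testing.assert_allclose(model.eigenvalues, 0.0, atol=1e-9)

    def test_matches_in_memory_eigendecomposition(self, small_series, fitted_model):
        images, masks, _ = small_series
        pooled = np.vstack([img.unfold(m.mask) for img, m in zip(images, masks)])
        cov = np.cov(pooled, rowvar=False, ddof=0)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        np.testing.assert_allclose(
            fitted_model.eigenvalues, np.maximum(evals[order], 0), rtol=1e-8, atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(fitted_model.loadings), np.abs(evecs[:, order]), atol=1e-6
        )

    def test_loading_sign_convention(self, fitted_model):
        L = fitted_model.loadings
        peaks = L[np.argmax(np.abs(L), axis=0), np.arange(L.shape[1])]
        assert (peaks > 0).all()

    def test_model_invariants(self, fitted_model):
        m = fitted_model
        np.testing.assert_allclose(m.loadings.T @ m.loadings, np.eye(m.n_components), atol=1e-10)
        assert (np.diff(m.eigenvalues) <= 1e-12).all()
        assert (m.eigenvalues >= -1e-10).all()
        np.testing.assert_allclose(m.eigenvalues.sum(), np.trace(m.cov), rtol=1e-8)
        np.testing.assert_allclose(m.variance_pct.sum(), 100.0, rtol=1e-10)

    def test_streaming_order_invariance(self, small_series):
        images, masks, _ = small_series
        stats = [fs.accumulate_local_stats(i, m) for i, m in zip(images, masks)]
        m1 = fs.fit_large_pca(stats)
        m2 = fs.fit_large_pca(stats[::-1])
        np.testing.assert_allclose(m1.eigenvalues, m2.eigenvalues, rtol=1e-10)
        np.testing.assert_allclose(m1.loadings, m2.loadings, atol=1e-8)

    def test_ddof_choice_leaves_loadings_unchanged(self, small_series):
        images, masks, _ = small_series
        stats = [fs.accumulate_local_stats(i, m) for i, m in zip(images, masks)]
        m0 = fs.fit_large_pca(stats, ddof=0)
        m1 = fs.fit_large_pca(stats, ddof=1)
        np.testing.assert_allclose(m0.loadings, m1.loadings, atol=1e-9)
        n = m0.n
        np.testing.assert_allclose(m1.cov * (n - 1) / n, m0.cov, rtol=1e-12)

    def test_json_round_trip(self, fitted_model, tmp_path):
        path = tmp_path / "model.json"
        fitted_model.to_json(path)
        back = fs.PcaModel.from_json(path)
        np.testing.assert_array_equal(back.loadings, fitted_model.loadings)
        np.testing.assert_array_equal(back.eigenvalues, fitted_model.eigenvalues)
        assert back.n == fitted_model.n


class TestPartitionInvariance:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=9), st.integers(min_value=0, max_value=10_000))
    def test_chunked_accumulation_matches_whole(self, n_chunks, seed):
        rng = np.random.default_rng(seed)
        n = 40
        X = rng.uniform(0, 1000, (n, 11))
        img, roi = MultispectralImage(X.reshape(n, 1, 11)), RoiMask(np.ones((n, 1), bool))
        whole = fs.accumulate_local_stats(img, roi)
        bounds = np.sort(rng.choice(np.arange(1, n), size=min(n_chunks - 1, n - 1), replace=False))
        parts = []
        prev = 0
        for b in list(bounds) + [n]:
            sub = MultispectralImage(X[prev:b].reshape(b - prev, 1, 11))
            parts.append(fs.accumulate_local_stats(sub, RoiMask(np.ones((b - prev, 1), bool))))
            prev = b
        merged = parts[0]
        for p in parts[1:]:
            merged = merged.merge(p)
        assert merged.n == whole.n
        np.testing.assert_allclose(merged.s, whole.s, rtol=1e-12)
        np.testing.assert_allclose(merged.V, whole.V, rtol=1e-12)
        c_whole = fs.fit_large_pca([whole]).cov
        c_merged = fs.fit_large_pca(parts).cov
        # relative to the covariance scale (off-diagonals may be near zero)
        assert np.abs(c_merged - c_whole).max() <= 1e-12 * np.abs(c_whole).max()


class TestProjectScores:
    def test_global_mean_pixel_scores_zero(self, small_series, fitted_model):
        images, masks, _ = small_series
        x = fitted_model.mean
        img, roi = single_pixel_image(x)
        simg = fs.project_scores(img, roi, fitted_model)
        np.testing.assert_allclose(simg.scores[0, 0], 0.0, atol=1e-4)

    def test_unit_loading_displacement_recovers_amplitude(self, fitted_model):
        a = 123.0
        k = 1
        x = fitted_model.mean + a * fitted_model.loadings[:, k]
        img, roi = single_pixel_image(x)
        simg = fs.project_scores(img, roi, fitted_model)
        expected = np.zeros(fitted_model.n_components)
        expected[k] = a
        np.testing.assert_allclose(simg.scores[0, 0], expected, atol=1e-3)

    def test_matches_brute_force_projection(self, fitted_model, rng):
        X = rng.uniform(0, 2000, (3, 11))
        img, roi = MultispectralImage(X.reshape(3, 1, 11)), RoiMask(np.ones((3, 1), bool))
        simg = fs.project_scores(img, roi, fitted_model)
        expected = (X - fitted_model.mean) @ fitted_model.loadings
        np.testing.assert_allclose(simg.scores[:, 0, :], expected, rtol=1e-5)

    def test_non_roi_pixels_are_nan(self, fitted_model):
        img = MultispectralImage(np.ones((2, 2, 11)))
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = True
        simg = fs.project_scores(img, RoiMask(mask), fitted_model)
        assert np.isnan(simg.scores[1, 1]).all()
        assert np.isfinite(simg.scores[0, 0]).all()
        assert simg.scores.dtype == np.float32

    def test_pooled_scores_centred_with_variance_lambda(self, small_series, fitted_model):
        images, masks, _ = small_series
        pooled = np.vstack(
            [
                fs.project_scores(i, m, fitted_model).scores[m.mask]
                for i, m in zip(images, masks)
            ]
        ).astype(np.float64)
        sd = np.sqrt(fitted_model.eigenvalues[0])
        assert abs(pooled[:, 0].mean()) <= 1e-6 * sd * 10
        np.testing.assert_allclose(
            pooled.var(axis=0)[:4], fitted_model.eigenvalues[:4], rtol=1e-4
        )

    def test_channel_mismatch_rejected(self):
        # a model fitted on data with a different channel count must refuse
        five_channel_model = fs.PcaModel(
            n=2, mean=np.zeros(5), cov=np.eye(5), eigenvalues=np.ones(5),
            loadings=np.eye(5), variance_pct=np.full(5, 20.0),
        )
        img = MultispectralImage(np.ones((1, 1, 11)))
        with pytest.raises(ValueError, match="channels"):
            fs.project_scores(img, RoiMask(np.ones((1, 1), bool)), five_channel_model)


class TestEncodeScoreImage:
    def make_score_image(self, values, eigenvalue=4.0):
        vals = np.asarray(values, np.float32).reshape(1, -1, 1)
        mask = RoiMask(np.ones(vals.shape[:2], bool))
        return fs.ScoreImage(scores=vals, mask=mask, eigenvalues=np.array([eigenvalue]))

    def test_endpoints_midpoint_and_clipping(self):
        sigma = 2.0  # sqrt of eigenvalue 4
        simg = self.make_score_image([-5 * sigma, 0.0, 5 * sigma, 6 * sigma])
        out = fs.encode_score_image(simg, 0, factor=5)
        np.testing.assert_array_equal(out[0], [0, 128, 255, 255])

    def test_literal_eigenvalue_statistic(self):
        simg = self.make_score_image([-20.0, 20.0], eigenvalue=4.0)
        out = fs.encode_score_image(simg, 0, scale_stat="eigenvalue", factor=5)
        np.testing.assert_array_equal(out[0], [0, 255])

    def test_non_roi_pixels_are_zero(self):
        vals = np.full((1, 2, 1), 3.0, np.float32)
        mask = np.array([[True, False]])
        simg = fs.ScoreImage(vals, RoiMask(mask), np.array([4.0]))
        out = fs.encode_score_image(simg, 0)
        assert out[0, 1] == 0

    def test_zero_eigenvalue_rejected(self):
        simg = self.make_score_image([0.0], eigenvalue=0.0)
        with pytest.raises(ValueError):
            fs.encode_score_image(simg, 0)
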