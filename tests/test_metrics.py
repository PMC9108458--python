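"""Tests of DSC, balanced average Hausdorff distance, Fréchet distance and
SSIM against hand evaluations and brute-force oracles."""

import numpy as np
import pytest

from dpvesselsynth.metrics import (
    FeatureStats,
    SSIMParams,
    bahd,
    dsc,
    extract_features,
    frechet_distance,
    handcrafted_features,
    mean_pairwise_ssim,
    ssim,
)


def brute_force_bahd(gt, pred):
    """All-pairs distance-matrix evaluation of the printed formula."""
    G = np.argwhere(np.asarray(gt, bool))
    S = np.argwhere(np.asarray(pred, bool))
    n_g = len(G)
    d = np.sqrt(((G[:, None, :] - S[None, :, :]) ** 2).sum(-1))
    return (d.min(axis=1).sum() / n_g + d.min(axis=0).sum() / n_g) / 2.0


class TestDSC:
    def test_identical_masks(self):
        m = np.zeros((5, 5), np.uint8)
        m[1:3, 1:3] = 1
        assert dsc(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), np.uint8)
        b = np.zeros((4, 4), np.uint8)
        a[0, 0] = 1
        b[3, 3] = 1
        assert dsc(a, b) == 0.0

    def test_hand_counted_value(self):
        # TP=2, FP=1, FN=1 -> 4/6
        pred = np.array([[1, 1, 1, 0]], np.uint8)
        gt = np.array([[1, 1, 0, 1]], np.uint8)
        assert dsc(pred, gt) == pytest.approx(2 / 3)

    def test_empty_conventions(self):
        z = np.zeros((3, 3), np.uint8)
        o = np.eye(3, dtype=np.uint8)
        assert dsc(z, z) == 1.0
        assert dsc(o, z) == 0.0
        assert dsc(z, o) == 0.0

    def test_symmetry(self, rng):
        for _ in range(20):
            a = (rng.random((6, 6)) < 0.4).astype(np.uint8)
            b = (rng.random((6, 6)) < 0.4).astype(np.uint8)
            assert dsc(a, b) == pytest.approx(dsc(b, a))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dsc(np.zeros((2, 2), np.uint8), np.zeros((3, 3), np.uint8))


class TestBAHD:
    def test_identical_sets_zero(self):
        m = np.zeros((6, 6), np.uint8)
        m[2:4, 2:4] = 1
        assert bahd(m, m) == 0.0

    def test_three_four_five_triangle(self):
        g = np.zeros((6, 6), np.uint8)
        s = np.zeros((6, 6), np.uint8)
        g[0, 0] = 1
        s[3, 4] = 1
        assert bahd(g, s) == pytest.approx(5.0)

    def test_hand_evaluated_both_sums(self):
        # G = {(0,0), (0,1)}, S = {(0,0)}:
        # ((0 + 1)/2 + 0/2) / 2 = 0.25
        g = np.zeros((2, 2), np.uint8)
        s = np.zeros((2, 2), np.uint8)
        g[0, 0] = g[0, 1] = 1
        s[0, 0] = 1
        assert bahd(g, s) == pytest.approx(0.25)

    def test_asymmetric_when_sizes_differ(self):
        """Both directed sums are normalised by N_G, so swapping the roles of
        an unequal-sized pair changes the value — this pins the formula as
        printed, against the conventional variant normalising by |S|."""
        g = np.zeros((4, 4), np.uint8)
        s = np.zeros((4, 4), np.uint8)
        g[0, 0] = 1
        s[0, 2] = s[0, 3] = s[3, 3] = 1
        assert bahd(g, s) != pytest.approx(bahd(s, g))
        assert bahd(g, s) == pytest.approx(brute_force_bahd(g, s))
        assert bahd(s, g) == pytest.approx(brute_force_bahd(s, g))

    def test_false_positive_heavy_prediction_is_punished(self):
        """A prediction covering the ground truth plus many distant false
        positives scores far worse than a tight prediction."""
        g = np.zeros((20, 20), np.uint8)
        g[10, 10] = 1
        tight = g.copy()
        sprawling = np.ones((20, 20), np.uint8)
        assert bahd(g, sprawling) > 50 * bahd(g, tight + 0)

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(200):
            g = (rng.random((6, 6)) < 0.3).astype(np.uint8)
            s = (rng.random((6, 6)) < 0.3).astype(np.uint8)
            if g.sum() == 0 or s.sum() == 0:
                continue
            assert bahd(g, s) == pytest.approx(brute_force_bahd(g, s), rel=1e-12)

    def test_spacing_scales_distances(self):
        g = np.zeros((3, 3, 3), np.uint8)
        s = np.zeros((3, 3, 3), np.uint8)
        g[0, 0, 0] = 1
        s[0, 0, 1] = 1
        assert bahd(g, s) == pytest.approx(1.0)
        assert bahd(g, s, spacing=(0.5, 0.5, 0.7)) == pytest.approx(0.7)

    def test_empty_mask_rejected(self):
        g = np.zeros((3, 3), np.uint8)
        s = np.zeros((3, 3), np.uint8)
        g[0, 0] = 1
        with pytest.raises(ValueError):
            bahd(g, s)


class TestFrechet:
    def test_identical_stats_zero(self, rng):
        x = rng.normal(size=(50, 4))
        st = FeatureStats(x.mean(0), np.cov(x, rowvar=False), 50)
        assert frechet_distance(st, st) == pytest.approx(0.0, abs=1e-8)

    def test_scalar_closed_form(self):
        a = FeatureStats(np.array([0.0]), np.array([[1.0]]), 10)
        b = FeatureStats(np.array([3.0]), np.array([[4.0]]), 10)
        # 9 + (1 + 4 - 2 sqrt(4)) = 10
        assert frechet_distance(a, b) == pytest.approx(10.0, abs=1e-8)

    def test_diagonal_closed_form(self, rng):
        v1 = rng.uniform(0.5, 2.0, size=5)
        v2 = rng.uniform(0.5, 2.0, size=5)
        m1 = rng.normal(size=5)
        m2 = rng.normal(size=5)
        a = FeatureStats(m1, np.diag(v1), 10)
        b = FeatureStats(m2, np.diag(v2), 10)
        expected = ((m1 - m2) ** 2).sum() + ((np.sqrt(v1) - np.sqrt(v2)) ** 2).sum()
        assert frechet_distance(a, b) == pytest.approx(expected, abs=1e-8)

    def test_rotation_invariance(self, rng):
        x = rng.normal(size=(200, 3))
        y = rng.normal(size=(200, 3)) + 1.0
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        stats = lambda z: FeatureStats(z.mean(0), np.cov(z, rowvar=False), len(z))
        d0 = frechet_distance(stats(x), stats(y))
        d1 = frechet_distance(stats(x @ q.T), stats(y @ q.T))
        assert d1 == pytest.approx(d0, rel=1e-8)

    def test_nonnegative(self, rng):
        for _ in range(10):
            x = rng.normal(size=(30, 4))
            y = rng.normal(size=(30, 4))
            d = frechet_distance(
                FeatureStats(x.mean(0), np.cov(x, rowvar=False), 30),
                FeatureStats(y.mean(0), np.cov(y, rowvar=False), 30),
            )
            assert d >= 0.0


class TestExtractFeatures:
    def test_identical_images_zero_covariance(self):
        img = np.full((8, 8), 0.5)
        st = extract_features([img] * 5, handcrafted_features)
        np.testing.assert_allclose(st.cov, 0.0, atol=1e-12)

    def test_permutation_invariance(self, rng):
        imgs = [rng.random((8, 8)) for _ in range(6)]
        a = extract_features(imgs, handcrafted_features)
        b = extract_features(imgs[::-1], handcrafted_features)
        np.testing.assert_allclose(a.mu, b.mu)
        np.testing.assert_allclose(a.cov, b.cov)

    def test_hand_computed_moments(self):
        """Two-feature extractor (mean intensity, label-like bright fraction)
        on three constant images with hand-computable moments."""
        ex = lambda im: np.array([im.mean(), (im > 0.5).mean()])
        imgs = [np.full((4, 4), v) for v in (0.0, 0.6, 0.9)]
        st = extract_features(imgs, ex)
        feats = np.array([[0.0, 0.0], [0.6, 1.0], [0.9, 1.0]])
        np.testing.assert_allclose(st.mu, feats.mean(0))
        np.testing.assert_allclose(st.cov, np.cov(feats, rowvar=False))

    def test_single_image_rejected(self):
        with pytest.raises(ValueError):
            extract_features([np.zeros((4, 4))], handcrafted_features)


def naive_sliding_ssim(x, y, w, k1=0.01, k2=0.03, L=1.0):
    """Independent double-loop evaluation of the sliding-window mode."""
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    h = w // 2
    vals = []
    for i in range(h, x.shape[0] - h):
        for j in range(h, x.shape[1] - h):
            xs = x[i - h : i - h + w, j - h : j - h + w]
            ys = y[i - h : i - h + w, j - h : j - h + w]
            mx, my = xs.mean(), ys.mean()
            vx, vy = xs.var(), ys.var()
            cxy = ((xs - mx) * (ys - my)).mean()
            vals.append(
                ((2 * mx * my + c1) * (2 * cxy + c2))
                / ((mx**2 + my**2 + c1) * (vx + vy + c2))
            )
    return float(np.mean(vals))


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        x = rng.random((16, 16))
        assert ssim(x, x) == pytest.approx(1.0)
        assert ssim(x, x, SSIMParams(window=7)) == pytest.approx(1.0)

    def test_constant_images_luminance_only(self):
        a, b = 0.3, 0.7
        c1 = (0.01 * 1.0) ** 2
        expected = (2 * a * b + c1) / (a**2 + b**2 + c1)
        x = np.full((8, 8), a)
        y = np.full((8, 8), b)
        assert ssim(x, y) == pytest.approx(expected)

    def test_anticorrelated_images_negative(self):
        x = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert ssim(x, -x, SSIMParams(L=2.0)) < 0.0

    def test_approaches_one_as_noise_shrinks(self, rng):
        x = rng.random((16, 16))
        noise = rng.normal(size=(16, 16))
        scores = [ssim(x, x + eps * noise) for eps in (0.3, 0.1, 0.03, 0.01, 0.0)]
        assert all(a <= b + 1e-12 for a, b in zip(scores, scores[1:]))
        assert scores[-1] == pytest.approx(1.0)

    def test_sliding_window_matches_naive_loop(self, rng):
        x = rng.random((12, 12))
        y = np.clip(x + 0.1 * rng.normal(size=(12, 12)), 0, 1)
        ours = ssim(x, y, SSIMParams(window=5))
        naive = naive_sliding_ssim(x, y, 5)
        assert ours == pytest.approx(naive, rel=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((4, 4)), np.zeros((5, 5)))


class TestMeanPairwiseSSIM:
    def test_identical_collection_is_one(self):
        imgs = [np.full((8, 8), 0.4)] * 4
        assert mean_pairwise_ssim(imgs) == pytest.approx(1.0)

    def test_matches_exhaustive_triple_loop(self, rng):
        imgs = [rng.random((8, 8)) for _ in range(3)]
        expected = np.mean(
            [ssim(imgs[0], imgs[1]), ssim(imgs[0], imgs[2]), ssim(imgs[1], imgs[2])]
        )
        assert mean_pairwise_ssim(imgs) == pytest.approx(expected)

    def test_too_few_images_rejected(self):
        with pytest.raises(ValueError):
            mean_pairwise_ssim([np.zeros((4, 4))])
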