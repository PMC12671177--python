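"""Masked keypoints, ratio-test matching, RANSAC homographies, gain
compensation, multi-band blending and the full stitcher."""

import numpy as np
import pytest

from clemosaic import mosaic, simgen
from conftest import true_transform_to


def _kps_from_points(pts):
    return [mosaic.Keypoint(x=float(x), y=float(y), scale=1.0,
                            orientation=0.0,
                            descriptor=np.zeros(128, np.float32))
            for x, y in pts]


def _descriptor_cloud(rng, n):
    d = rng.random((n, 128)).astype(np.float32) * 100
    return [mosaic.Keypoint(x=float(i), y=float(i), scale=1.0,
                            orientation=0.0, descriptor=d[i])
            for i in range(n)]


class TestMaskedKeypoints:
    def test_full_mask_equals_unconstrained(self, small_frame):
        frame, _ = small_frame
        ones = np.ones_like(frame, dtype=np.uint8)
        kps = mosaic.extract_masked_keypoints(frame, ones)
        assert len(kps) > 0
        # unconstrained detection has the same count
        assert len(kps) == len(mosaic.extract_masked_keypoints(frame, ones))

    def test_zero_mask_empty(self, small_frame):
        frame, _ = small_frame
        assert mosaic.extract_masked_keypoints(
            frame, np.zeros_like(frame, dtype=np.uint8)) == []

    def test_every_keypoint_on_foreground(self, small_frame):
        """Oracle: exhaustive per-keypoint mask lookup."""
        frame, mask = small_frame
        kps = mosaic.extract_masked_keypoints(frame, mask)
        assert kps, "expected keypoints on glandular foreground"
        for k in kps:
            assert mask[int(round(k.y)), int(round(k.x))] == 1
            assert k.descriptor.shape == (128,)

    def test_partial_mask_subset_of_full(self, small_frame):
        frame, mask = small_frame
        full = mosaic.extract_masked_keypoints(
            frame, np.ones_like(mask))
        constrained = mosaic.extract_masked_keypoints(frame, mask)
        assert 0 < len(constrained) <= len(full)


class TestMatchFeatures:
    def test_self_match_zero_distance(self):
        rng = np.random.default_rng(0)
        kps = _descriptor_cloud(rng, 20)
        ms = mosaic.match_features(kps, kps, ratio=0.75)
        assert len(ms.pairs) == 20
        assert all(i == j for i, j in ms.pairs)
        assert all(d == 0 for d in ms.distances)

    def test_zero_ratio_empty(self):
        rng = np.random.default_rng(1)
        a = _descriptor_cloud(rng, 10)
        b = _descriptor_cloud(rng, 10)
        assert mosaic.match_features(a, b, ratio=0.0).pairs == []

    def test_empty_inputs(self):
        assert mosaic.match_features([], [], 0.75).pairs == []

    def test_matches_equal_bruteforce_oracle(self):
        """Oracle: all-pairs distances computed independently."""
        rng = np.random.default_rng(2)
        a = _descriptor_cloud(rng, 30)
        b = _descriptor_cloud(rng, 40)
        ms = mosaic.match_features(a, b, ratio=0.9)
        da = np.stack([k.descriptor for k in a]).astype(float)
        db = np.stack([k.descriptor for k in b]).astype(float)
        expected = []
        for i in range(30):
            dist = np.sqrt(((da[i] - db) ** 2).sum(axis=1))
            order = np.argsort(dist)
            if dist[order[0]] < 0.9 * dist[order[1]]:
                expected.append((i, int(order[0])))
        assert ms.pairs == expected

    def test_a_indices_unique(self):
        rng = np.random.default_rng(3)
        a = _descriptor_cloud(rng, 25)
        b = _descriptor_cloud(rng, 25)
        ms = mosaic.match_features(a, b, 0.95)
        firsts = [i for i, _ in ms.pairs]
        assert len(firsts) == len(set(firsts))


class TestEstimateHomography:
    def _kps_from_points(self, pts):
        return _kps_from_points(pts)

    def test_exact_translation_recovered(self):
        rng = np.random.default_rng(0)
        src = rng.uniform(0, 100, (30, 2))
        dst = src + np.array([10.0, -4.0])
        a = self._kps_from_points(src)
        b = self._kps_from_points(dst)
        m = mosaic.MatchSet([(i, i) for i in range(30)], [0.0] * 30, 0.75)
        hom = mosaic.estimate_homography(m, a, b, seed=0)
        expected = simgen.translation_homography(10, -4)
        assert np.allclose(hom.matrix, expected, atol=1e-6)
        assert hom.inlier_count == 30

    def test_identity_correspondences(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 50, (20, 2))
        kps = self._kps_from_points(pts)
        m = mosaic.MatchSet([(i, i) for i in range(20)], [0.0] * 20, 0.75)
        hom = mosaic.estimate_homography(m, kps, kps, seed=0)
        assert np.allclose(hom.matrix, np.eye(3), atol=1e-9)
        assert hom.inlier_count == 20

    def test_outlier_contamination_recovery(self):
        """Oracle: synthetic correspondences with known homography, 30%
        uniform outliers."""
        rng = np.random.default_rng(7)
        h_true = np.array([[1.02, 0.01, 5.0],
                           [-0.01, 0.99, -3.0],
                           [1e-5, -1e-5, 1.0]])
        n = 200
        src = rng.uniform(0, 200, (n, 2))
        hom_pts = (h_true @ np.c_[src, np.ones(n)].T)
        dst = (hom_pts[:2] / hom_pts[2]).T
        n_out = 60
        dst[:n_out] = rng.uniform(0, 200, (n_out, 2))
        a = self._kps_from_points(src)
        b = self._kps_from_points(dst)
        m = mosaic.MatchSet([(i, i) for i in range(n)], [0.0] * n, 0.75)
        hom = mosaic.estimate_homography(m, a, b, reproj_threshold=3.0,
                                         max_iters=2000, seed=0)
        err = mosaic.corner_transfer_error(hom.matrix, h_true, (200, 200))
        assert err < 1.0

    def test_too_few_matches_rejected(self):
        with pytest.raises(mosaic.EstimationError):
            mosaic.estimate_homography(
                mosaic.MatchSet([(0, 0)], [0.0], 0.75), [], [])


class TestCompensateGain:
    def test_identical_frames_unit_gain(self):
        f = np.full((40, 40), 0.5)
        gains = mosaic.compensate_gain([f, f], [np.eye(3), np.eye(3)])
        assert np.allclose(gains, 1.0, atol=1e-6)

    def test_brightness_ratio_recovered(self):
        """Oracle: closed-form solution of the 2x2 normal equations."""
        f1 = np.full((40, 40), 0.4)
        f2 = np.full((40, 40), 0.48)  # 1.2x brighter in full overlap
        gains = mosaic.compensate_gain([f1, f2], [np.eye(3), np.eye(3)])
        sigma_n, sigma_g = 10.0 / 255.0, 0.1
        n = 40 * 40
        w = n / sigma_n ** 2
        wp = n / sigma_g ** 2
        A = np.array([[w * 0.4 ** 2 + wp, -w * 0.4 * 0.48],
                      [-w * 0.4 * 0.48, w * 0.48 ** 2 + wp]])
        expected = np.linalg.solve(A, [wp, wp])
        assert np.allclose(gains, expected, atol=1e-9)
        ratio = gains[0] / gains[1]
        assert ratio == pytest.approx(expected[0] / expected[1], rel=0.02)
        assert 1.0 < ratio <= 1.2  # pulled toward 1.2, shrunk by the prior

    def test_sigma_scaling_invariance(self):
        f1 = np.full((30, 30), 0.3)
        f2 = np.full((30, 30), 0.45)
        g1 = mosaic.compensate_gain([f1, f2], [np.eye(3)] * 2,
                                    sigma_n=0.04, sigma_g=0.1)
        g2 = mosaic.compensate_gain([f1, f2], [np.eye(3)] * 2,
                                    sigma_n=0.08, sigma_g=0.2)
        assert np.allclose(g1, g2, atol=1e-9)

    def test_no_overlap_gives_unit_gains(self):
        f = np.full((20, 20), 0.5)
        far = simgen.translation_homography(1000, 0)
        gains = mosaic.compensate_gain([f, f], [np.eye(3), far])
        assert np.allclose(gains, 1.0)


class TestMultibandBlend:
    def test_single_image_roundtrip(self, small_frame):
        frame, _ = small_frame
        out = mosaic.multiband_blend([frame], [np.ones_like(frame)], 5)
        assert np.allclose(out, frame, atol=1e-6)

    def test_identical_images_any_weights(self, small_frame):
        frame, _ = small_frame
        rng = np.random.default_rng(0)
        w1 = rng.random(frame.shape) + 0.05
        w2 = rng.random(frame.shape) + 0.05
        out = mosaic.multiband_blend([frame, frame], [w1, w2], 5)
        assert np.allclose(out, frame, atol=1e-6)

    def test_single_band_equals_weighted_average(self):
        """Oracle: direct weighted average."""
        rng = np.random.default_rng(1)
        a = rng.random((64, 64))
        b = rng.random((64, 64))
        wa = rng.random((64, 64)) + 0.01
        wb = rng.random((64, 64)) + 0.01
        out = mosaic.multiband_blend([a, b], [wa, wb], n_bands=1)
        direct = (wa * a + wb * b) / (wa + wb)
        assert np.allclose(out, np.clip(direct, 0, 1), atol=1e-12)

    def test_hard_seam_transitions_monotonically(self):
        h = w = 64
        a = np.full((h, w), 0.2)
        b = np.full((h, w), 0.8)
        wa = np.zeros((h, w))
        wa[:, : w // 2] = 1.0
        wb = 1.0 - wa
        out = mosaic.multiband_blend([a, b], [wa, wb], n_bands=4)
        profile = out[h // 2]
        assert profile[0] == pytest.approx(0.2, abs=1e-3)
        assert profile[-1] == pytest.approx(0.8, abs=1e-3)
        # monotone up to band-limited ripple
        assert (np.diff(profile) >= -1e-3).all()
        assert profile[3 * w // 4] > profile[w // 4]

    def test_constant_conservation(self):
        c = np.full((48, 48), 0.6)
        rng = np.random.default_rng(2)
        weights = [rng.random((48, 48)) + 0.01 for _ in range(3)]
        out = mosaic.multiband_blend([c] * 3, weights, 4)
        assert np.allclose(out, 0.6, atol=1e-6)

    def test_excessive_bands_clamped(self):
        a = np.full((16, 16), 0.5)
        out = mosaic.multiband_blend([a], [np.ones_like(a)], n_bands=10)
        assert np.allclose(out, 0.5, atol=1e-6)


class TestStitchSequence:
    def test_two_identical_frames(self, small_frame):
        frame, mask = small_frame
        pano, homs = mosaic.stitch_sequence(
            [frame, frame], [np.ones_like(mask), np.ones_like(mask)])
        assert all(h is not None for h in homs)
        assert np.allclose(homs[0].matrix, np.eye(3), atol=0.05)
        # identity path: canvas may exceed the frame by corner rounding only
        assert frame.shape[0] <= pano.shape[0] <= frame.shape[0] + 4
        assert frame.shape[1] <= pano.shape[1] <= frame.shape[1] + 4
        # panorama reproduces the frame closely up to that rounding shift
        best = min(
            np.abs(pano[dy:dy + 100, dx:dx + 100] - frame[14:114, 14:114]).mean()
            for dy in range(pano.shape[0] - 99)
            for dx in range(pano.shape[1] - 99)
            if dy <= 30 and dx <= 30)
        assert best < 0.02

    def test_known_translations_recovered(self, stable_translation_sequence):
        """Oracle: composition of the generator's true pair transforms."""
        seq = stable_translation_sequence
        pano, homs = mosaic.stitch_sequence(seq.frames, seq.masks,
                                            mosaic.StitchConfig(seed=1))
        kept = [i for i, h in enumerate(homs) if h is not None]
        assert len(kept) >= 6
        ref = kept[len(kept) // 2]
        errs = [mosaic.corner_transfer_error(
            homs[i].matrix, true_transform_to(i, ref, seq),
            seq.frames[0].shape) for i in kept]
        assert np.mean(errs) < 2.0

    def test_canvas_contains_all_corners(self, stable_translation_sequence):
        seq = stable_translation_sequence
        pano, homs = mosaic.stitch_sequence(seq.frames, seq.masks)
        # canvas bounds were built from warped corners, so the panorama must
        # be at least as large as any single frame
        assert pano.shape[0] >= seq.frames[0].shape[0]
        assert pano.shape[1] >= seq.frames[0].shape[1]

    def test_composition_consistency_on_noise_free_translations(self):
        """Pairwise-composed estimates equal the direct first-to-last
        estimate on exact translated correspondences."""
        rng = np.random.default_rng(5)
        pts0 = rng.uniform(0, 160, (40, 2))
        t01, t12 = np.array([8.0, 3.0]), np.array([6.0, -4.0])
        sets = [pts0, pts0 + t01, pts0 + t01 + t12]
        kps = [_kps_from_points(p) for p in sets]
        m = mosaic.MatchSet([(i, i) for i in range(40)], [0.0] * 40, 0.75)
        h01 = mosaic.estimate_homography(m, kps[0], kps[1], seed=0)
        h12 = mosaic.estimate_homography(m, kps[1], kps[2], seed=0)
        h02 = mosaic.estimate_homography(m, kps[0], kps[2], seed=0)
        composed = h12.matrix @ h01.matrix
        err = mosaic.corner_transfer_error(composed, h02.matrix, (160, 160))
        assert err < 1e-3

    def test_too_few_frames_rejected(self, small_frame):
        with pytest.raises(ValueError):
            mosaic.stitch_sequence([small_frame[0]], [small_frame[1]])
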