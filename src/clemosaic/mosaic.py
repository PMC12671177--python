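"""Mask-constrained feature-based mosaicking.

Keypoints are detected on the full frame with SIFT, but only those whose
(rounded) position falls on gland-mask foreground are kept — background
clutter and free-floating debris therefore never contribute correspondences.
Matching uses Lowe's ratio test (default 0.75); pairwise homographies are
estimated with seeded RANSAC over 4-point DLT solves and composed to a
central reference frame; per-frame multiplicative gains are solved in the
Brown-Lowe least-squares form; and the warped frames are fused by multi-band
(frequency-band) blending.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import SIFT
from skimage.measure import ransac
from skimage.transform import ProjectiveTransform

from .simgen import warp_with_homography

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Keypoint:
    x: float
    y: float
    scale: float
    orientation: float
    descriptor: np.ndarray  # 128-vector


@dataclass(frozen=True)
class MatchSet:
    pairs: list[tuple[int, int]]
    distances: list[float]
    ratio_used: float


@dataclass(frozen=True)
class Homography:
    matrix: np.ndarray  # 3x3, normalized so matrix[2, 2] == 1
    inlier_count: int = 0
    inlier_mask: np.ndarray | None = None


@dataclass(frozen=True)
class StitchConfig:
    ratio: float = 0.75
    reproj_threshold: float = 3.0
    max_iters: int = 2000
    seed: int = 0
    n_bands: int = 5
    sigma_n: float = 10.0 / 255.0  # gain solver, intensity units on [0,1]
    sigma_g: float = 0.1
    min_matches: int = 4


class EstimationError(RuntimeError):
    """Raised when a homography cannot be estimated for a pair."""


# -------------------------------------------------------------- keypoints

def extract_masked_keypoints(frame: np.ndarray, mask: np.ndarray,
                             upsampling: int = 1) -> list[Keypoint]:
    """SIFT keypoints restricted to mask foreground.

    Detection runs on the full frame; a keypoint is kept iff the mask at its
    rounded position equals 1.  An all-zero mask yields an empty list.
    """
    frame = np.asarray(frame, dtype=float)
    mask = np.asarray(mask)
    if frame.shape != mask.shape:
        raise ValueError("frame and mask dims differ")
    if not mask.any():
        log.warning("all-zero mask: no keypoints retained")
        return []
    det = SIFT(upsampling=upsampling)
    try:
        det.detect_and_extract(frame)
    except RuntimeError:  # no keypoints found at all
        return []
    kps = []
    h, w = mask.shape
    for (r, c), s, o, d in zip(det.keypoints, det.sigmas,
                               det.orientations, det.descriptors):
        ri, ci = int(round(float(r))), int(round(float(c)))
        if 0 <= ri < h and 0 <= ci < w and mask[ri, ci]:
            kps.append(Keypoint(x=float(c), y=float(r), scale=float(s),
                                orientation=float(o),
                                descriptor=d.astype(np.float32)))
    return kps


def match_features(a: list[Keypoint], b: list[Keypoint],
                   ratio: float = 0.75) -> MatchSet:
    """Exhaustive nearest-neighbour matching with Lowe's ratio test.

    Each descriptor in ``a`` is paired with its nearest neighbour in ``b``
    iff the best distance is below ``ratio`` times the second best; each
    a-index appears at most once.
    """
    if not a or not b:
        return MatchSet([], [], ratio)
    da = np.stack([k.descriptor for k in a]).astype(float)
    db = np.stack([k.descriptor for k in b]).astype(float)
    # squared euclidean distances
    d2 = ((da * da).sum(1)[:, None] + (db * db).sum(1)[None, :]
          - 2.0 * da @ db.T)
    np.maximum(d2, 0.0, out=d2)
    pairs, dists = [], []
    if db.shape[0] == 1:
        return MatchSet([], [], ratio)  # no second neighbour to test against
    idx = np.argpartition(d2, 1, axis=1)[:, :2]
    for i in range(da.shape[0]):
        j0, j1 = idx[i]
        d0, d1 = np.sqrt(d2[i, j0]), np.sqrt(d2[i, j1])
        if d0 > d1:
            j0, d0, d1 = j1, d1, d0
        if d0 < ratio * d1:
            pairs.append((i, int(j0)))
            dists.append(float(d0))
    return MatchSet(pairs, dists, ratio)


# ------------------------------------------------------------- homography

def _normalize(mat: np.ndarray) -> np.ndarray:
    if abs(mat[2, 2]) < 1e-12:
        raise EstimationError("degenerate homography (zero scale)")
    return mat / mat[2, 2]


def estimate_homography(m: MatchSet, a: list[Keypoint], b: list[Keypoint],
                        reproj_threshold: float = 3.0, max_iters: int = 2000,
                        seed: int = 0) -> Homography:
    """Seeded RANSAC homography from matched keypoints, refit on inliers.

    The returned matrix maps frame-A pixel coordinates (x, y) into frame-B
    coordinates.
    """
    if len(m.pairs) < 4:
        raise EstimationError(f"need >= 4 matches, got {len(m.pairs)}")
    src = np.array([[a[i].x, a[i].y] for i, _ in m.pairs])
    dst = np.array([[b[j].x, b[j].y] for _, j in m.pairs])
    model, inliers = ransac(
        (src, dst), ProjectiveTransform, min_samples=4,
        residual_threshold=reproj_threshold, max_trials=max_iters,
        rng=seed,
    )
    if model is None or inliers is None or inliers.sum() < 4:
        raise EstimationError("RANSAC failed to find a consistent model")
    refit = ProjectiveTransform.from_estimate(src[inliers], dst[inliers])
    if not refit:
        raise EstimationError("inlier refit failed")
    if not np.isfinite(refit.params).all():
        raise EstimationError("non-finite homography")
    return Homography(matrix=_normalize(refit.params),
                      inlier_count=int(inliers.sum()),
                      inlier_mask=inliers)


def compose_to_reference(pair_homs: list[np.ndarray], ref: int) -> list[np.ndarray]:
    """Per-frame homographies to a reference frame from consecutive-pair
    transforms ``pair_homs[i]`` : frame i -> frame i+1."""
    n = len(pair_homs) + 1
    homs = [None] * n
    homs[ref] = np.eye(3)
    for i in range(ref - 1, -1, -1):
        homs[i] = _normalize(homs[i + 1] @ pair_homs[i])
    for i in range(ref + 1, n):
        homs[i] = _normalize(homs[i - 1] @ np.linalg.inv(pair_homs[i - 1]))
    return homs


def corner_transfer_error(h_est: np.ndarray, h_true: np.ndarray,
                          frame_shape: tuple[int, int]) -> float:
    """Mean distance between the frame corners mapped by two homographies."""
    h, w = frame_shape
    corners = np.array([[0, 0, 1], [w - 1, 0, 1], [0, h - 1, 1],
                        [w - 1, h - 1, 1]], dtype=float).T
    pe = h_est @ corners
    pt = h_true @ corners
    pe = pe[:2] / pe[2]
    pt = pt[:2] / pt[2]
    return float(np.mean(np.linalg.norm(pe - pt, axis=0)))


# ------------------------------------------------------------------- gain

def compensate_gain(frames, homs, sigma_n: float = 10.0 / 255.0,
                    sigma_g: float = 0.1,
                    canvas=None) -> np.ndarray:
    """Per-frame multiplicative gains (Brown-Lowe least squares).

    Minimizes, over all overlapping pairs (i, j),
    ``N_ij (g_i Ibar_ij - g_j Ibar_ji)^2 / sigma_N^2`` plus the prior
    ``(sum_j N_ij) (1 - g_i)^2 / sigma_g^2`` pulling gains toward one.
    With no overlaps all gains are exactly 1.
    """
    n = len(frames)
    mats = [h if isinstance(h, np.ndarray) else h.matrix for h in homs]
    if canvas is None:
        canvas = _canvas_geometry(frames, mats)
    warped, valid = [], []
    for f, h in zip(frames, mats):
        wf, vm = _warp_to_canvas(f, np.ones_like(f), h, canvas)
        warped.append(wf)
        valid.append(vm > 0.5)

    A = np.zeros((n, n))
    rhs = np.zeros(n)
    prior_w = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            ov = valid[i] & valid[j]
            nij = int(ov.sum())
            if nij == 0:
                continue
            mi = float(warped[i][ov].mean())
            mj = float(warped[j][ov].mean())
            w = nij / sigma_n ** 2
            A[i, i] += w * mi * mi
            A[j, j] += w * mj * mj
            A[i, j] -= w * mi * mj
            A[j, i] -= w * mi * mj
            prior_w[i] += nij
            prior_w[j] += nij
    if prior_w.sum() == 0:
        return np.ones(n)
    for i in range(n):
        wi = max(prior_w[i], 1.0) / sigma_g ** 2
        A[i, i] += wi
        rhs[i] += wi
    g = np.linalg.solve(A, rhs)
    if (g <= 0).any():
        log.warning("non-positive gain solved; clamping")
        g = np.clip(g, 1e-3, None)
    return g


# --------------------------------------------------------------- blending

def _canvas_geometry(frames, mats):
    """Bounding box of all warped frame corners -> (offset_x, offset_y, H, W)."""
    xs, ys = [], []
    for f, h in zip(frames, mats):
        hh, ww = f.shape
        corners = np.array([[0, 0, 1], [ww - 1, 0, 1], [0, hh - 1, 1],
                            [ww - 1, hh - 1, 1]], dtype=float).T
        p = h @ corners
        p = p[:2] / p[2]
        xs.extend(p[0])
        ys.extend(p[1])
    x0, y0 = int(np.floor(min(xs))), int(np.floor(min(ys)))
    x1, y1 = int(np.ceil(max(xs))), int(np.ceil(max(ys)))
    return (x0, y0, y1 - y0 + 1, x1 - x0 + 1)


def _warp_to_canvas(frame, weight, mat, canvas):
    x0, y0, h, w = canvas
    shift = np.eye(3)
    shift[0, 2] = -x0
    shift[1, 2] = -y0
    m = shift @ mat
    wf = warp_with_homography(frame, m, (h, w))
    wm = warp_with_homography(weight, m, (h, w))
    return wf, wm


def feather_weight(shape: tuple[int, int]) -> np.ndarray:
    """Border-distance weight map (1 at center, ->0 at frame edge)."""
    h, w = shape
    base = np.zeros((h + 2, w + 2))
    base[1:-1, 1:-1] = 1.0
    d = ndimage.distance_transform_edt(base)[1:-1, 1:-1]
    return d / d.max()


def multiband_blend(warped, weights, n_bands: int = 5) -> np.ndarray:
    """Blend canvas-aligned images band-by-band.

    Images are split into frequency bands with Gaussian low-pass filters of
    doubling scale (band sums telescope back to the original image); each
    band is averaged with the per-image weights smoothed at that band's
    scale, so low frequencies blend over wide regions and high frequencies
    stay local.  ``n_bands=1`` reduces to plain weighted averaging.
    Uncovered pixels are 0.
    """
    warped = [np.asarray(f, dtype=float) for f in warped]
    weights = [np.asarray(w, dtype=float) for w in weights]
    if len(warped) != len(weights) or not warped:
        raise ValueError("need equal numbers of images and weights")
    shape = warped[0].shape
    max_bands = max(1, int(np.log2(min(shape))))
    if n_bands > max_bands:
        log.warning("n_bands=%d clamped to %d for canvas %s",
                    n_bands, max_bands, shape)
        n_bands = max_bands
    covered = np.zeros(shape, dtype=bool)
    for w in weights:
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        covered |= w > 0
    sigma0 = 2.0

    out = np.zeros(shape)
    wsum_bands = [np.zeros(shape) for _ in range(n_bands)]
    band_acc = [np.zeros(shape) for _ in range(n_bands)]
    for img, wt in zip(warped, weights):
        valid = (wt > 0).astype(float)
        # normalized-convolution extension so blurring never mixes in the
        # zero background beyond this image's coverage
        levels = [img]
        v = valid
        for k in range(1, n_bands):
            s = sigma0 * 2 ** (k - 1)
            num = ndimage.gaussian_filter(levels[-1] * v, s)
            den = ndimage.gaussian_filter(v, s)
            ext = np.divide(num, den, out=np.zeros_like(num), where=den > 1e-12)
            levels.append(ext)
            v = np.ones_like(v)  # after first extension the field is dense
        ws = wt
        for k in range(n_bands):
            band = levels[k] - levels[k + 1] if k < n_bands - 1 else levels[k]
            if k > 0:
                ws = ndimage.gaussian_filter(wt, sigma0 * 2 ** (k - 1))
            band_acc[k] += ws * band
            wsum_bands[k] += ws
    for k in range(n_bands):
        out += np.divide(band_acc[k], wsum_bands[k],
                         out=np.zeros_like(out), where=wsum_bands[k] > 1e-12)
    out[~covered] = 0.0
    return np.clip(out, 0.0, 1.0)


# ------------------------------------------------------------------ stitch

def stitch_sequence(frames, masks, cfg: StitchConfig = StitchConfig()):
    """Full mosaicking pipeline.

    masked keypoints -> consecutive-pair matching -> pairwise RANSAC
    homographies -> composition to the middle reference frame -> canvas from
    warped corners -> gain compensation -> multi-band blending.

    Frames whose pairwise estimation fails are dropped (with a logged gap,
    the chain is re-linked through the next estimable pair by matching
    across the gap).  Returns ``(panorama, homs)`` where ``homs[i]`` is the
    frame-i -> reference Homography (None for dropped frames).
    """
    n = len(frames)
    if n < 2:
        raise ValueError("need at least 2 frames")
    if len(masks) != n:
        raise ValueError("masks must align with frames")
    kps = [extract_masked_keypoints(f, m) for f, m in zip(frames, masks)]

    # chain pairwise homographies, skipping unmatchable frames
    kept = [0]
    pair_mats = []  # maps kept[k] -> kept[k+1]
    i = 0
    while i < n - 1:
        linked = False
        for j in range(i + 1, n):
            try:
                ms = match_features(kps[i], kps[j], cfg.ratio)
                if len(ms.pairs) < cfg.min_matches:
                    raise EstimationError("too few matches")
                hom = estimate_homography(ms, kps[i], kps[j],
                                          cfg.reproj_threshold,
                                          cfg.max_iters, cfg.seed)
            except EstimationError as e:
                log.warning("pair (%d,%d) failed: %s", i, j, e)
                continue
            pair_mats.append(hom.matrix)
            kept.append(j)
            i = j
            linked = True
            break
        if not linked:
            break
    if len(kept) < 2:
        raise EstimationError("fewer than 2 stitchable frames")
    dropped = sorted(set(range(n)) - set(kept))
    if dropped:
        log.warning("dropped frames: %s", dropped)

    ref_pos = len(kept) // 2
    mats = compose_to_reference(pair_mats, ref_pos)
    canvas = _canvas_geometry([frames[k] for k in kept], mats)

    gains = compensate_gain([frames[k] for k in kept], mats,
                            cfg.sigma_n, cfg.sigma_g, canvas)
    warped, weights = [], []
    for k, mat, g in zip(kept, mats, gains):
        wf, wm = _warp_to_canvas(np.asarray(frames[k], dtype=float) * g,
                                 feather_weight(frames[k].shape), mat, canvas)
        warped.append(np.clip(wf, 0, 1))
        weights.append(wm)
    panorama = multiband_blend(warped, weights, cfg.n_bands)

    homs = [None] * n
    for k, mat in zip(kept, mats):
        homs[k] = Homography(matrix=_normalize(mat))
    return panorama, homs


def to_uint8(img: np.ndarray) -> np.ndarray:
    """[0,1] float to 8-bit with round-half-up."""
    return np.floor(np.clip(img, 0, 1) * 255.0 + 0.5).astype(np.uint8)
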