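"""Stabilization and stitching-quality evaluation battery.

Covers four instruments:

* dense-optical-flow frame interpolation, used to restore the frame count of
  a stable-selected sequence before comparing it with the original
  (``interpolate_frame`` / ``align_frame_count``);
* camera-path estimation by accumulating per-pair affine transforms, and the
  frame-to-frame displacement (jitter) variance of that path
  (``estimate_camera_path`` / ``jitter_variance``);
* block-wise sharpness maps of a stitched panorama (Laplacian variance,
  Sobel and Brenner focus measures) and their across-block variance as a
  sharpness-uniformity score (``block_sharpness`` / ``sharpness_uniformity``);
* registered consecutive-pair SSIM and RMSE over a sequence
  (``sequence_quality``).

Dense flow uses iterative Lucas-Kanade (scikit-image); flow fields are
returned as (Fx, Fy) pixel displacements of content from the first to the
second frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity
from skimage.registration import optical_flow_ilk

log = logging.getLogger(__name__)

SHARPNESS_METRICS = ("laplacian", "sobel", "brenner")
BLOCK_SIZES = (64, 128, 256)


# ------------------------------------------------------------------- flow

def estimate_flow(i1: np.ndarray, i2: np.ndarray,
                  radius: int = 15) -> tuple[np.ndarray, np.ndarray]:
    """Dense flow (Fx, Fy): content at (x, y) in ``i1`` appears at
    (x + Fx, y + Fy) in ``i2``."""
    # optical_flow_ilk(reference, moving) returns (vr, vc) with
    # moving(coords + flow) ~= reference; for a feature at p in the
    # reference appearing at p + d in the moving frame this yields
    # flow = +d, i.e. exactly the content displacement reference -> moving.
    vr, vc = optical_flow_ilk(i1.astype(np.float32), i2.astype(np.float32),
                              radius=radius)
    return vc, vr


@dataclass(frozen=True)
class InterpolationSpec:
    """Temporal weight for one interpolated frame: alpha = t / (T + 1)."""

    t: int
    T: int

    def __post_init__(self):
        if not (1 <= self.t <= self.T):
            raise ValueError("need 1 <= t <= T")

    @property
    def alpha(self) -> float:
        return self.t / (self.T + 1)


def _remap(img: np.ndarray, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    return ndimage.map_coordinates(img, [yy + dy, xx + dx], order=1,
                                   mode="nearest")


def interpolate_frame(i1: np.ndarray, i2: np.ndarray,
                      flow_fwd: tuple[np.ndarray, np.ndarray],
                      flow_bwd: tuple[np.ndarray, np.ndarray],
                      alpha: float) -> np.ndarray:
    """Convex flow-compensated blend between two frames.

    ``flow_fwd`` carries content from i1 to i2 and ``flow_bwd`` from i2 to
    i1.  i1 is sampled at coords - alpha * flow_fwd and i2 at
    coords - (1 - alpha) * flow_bwd, then blended as
    (1 - alpha) * warped1 + alpha * warped2; alpha in [0, 1].
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    i1 = np.asarray(i1, dtype=float)
    i2 = np.asarray(i2, dtype=float)
    if alpha == 0.0:
        return i1.copy()
    if alpha == 1.0:
        return i2.copy()
    fx1, fy1 = flow_fwd
    fx2, fy2 = flow_bwd
    w1 = _remap(i1, -alpha * fx1, -alpha * fy1)
    w2 = _remap(i2, -(1.0 - alpha) * fx2, -(1.0 - alpha) * fy2)
    return (1.0 - alpha) * w1 + alpha * w2


def align_frame_count(stable: list[np.ndarray], stable_indices: list[int],
                      original_count: int) -> list[np.ndarray]:
    """Rebuild a sequence of ``original_count`` frames from the stable subset.

    Gaps between consecutive retained frames are filled with flow-compensated
    interpolants at alpha = t / (T + 1); leading/trailing gaps repeat the
    nearest stable frame.
    """
    if not stable:
        raise ValueError("empty stable list")
    if list(stable_indices) != sorted(set(stable_indices)):
        raise ValueError("stable_indices must be strictly increasing")
    if stable_indices[-1] >= original_count:
        raise ValueError("stable index beyond original count")
    out: list[np.ndarray | None] = [None] * original_count
    for f, i in zip(stable, stable_indices):
        out[i] = np.asarray(f, dtype=float)
    for a, b in zip(stable_indices[:-1], stable_indices[1:]):
        T = b - a - 1
        if T == 0:
            continue
        f_fwd = estimate_flow(out[a], out[b])
        f_bwd = estimate_flow(out[b], out[a])
        for t in range(1, T + 1):
            alpha = InterpolationSpec(t, T).alpha
            out[a + t] = interpolate_frame(out[a], out[b], f_fwd, f_bwd, alpha)
    for i in range(stable_indices[0]):
        out[i] = out[stable_indices[0]].copy()
    for i in range(stable_indices[-1] + 1, original_count):
        out[i] = out[stable_indices[-1]].copy()
    return out


# ------------------------------------------------------------ camera path

@dataclass
class CameraPath:
    transforms: list[np.ndarray]  # accumulated 3x3 (affine) per frame
    tx: np.ndarray
    ty: np.ndarray


def _pair_affine(a: np.ndarray, b: np.ndarray, seed: int = 0) -> np.ndarray:
    """Affine transform mapping frame-b coords into frame-a coords.

    Feature-based (SIFT + ratio test + RANSAC); falls back to the median
    dense-flow translation when features are insufficient.
    """
    from skimage.measure import ransac
    from skimage.transform import AffineTransform

    from .mosaic import extract_masked_keypoints, match_features

    ones = np.ones(a.shape, dtype=np.uint8)
    ka = extract_masked_keypoints(a, ones)
    kb = extract_masked_keypoints(b, ones)
    ms = match_features(kb, ka, 0.8)
    if len(ms.pairs) >= 6:
        src = np.array([[kb[i].x, kb[i].y] for i, _ in ms.pairs])
        dst = np.array([[ka[j].x, ka[j].y] for _, j in ms.pairs])
        model, inliers = ransac((src, dst), AffineTransform, min_samples=3,
                                residual_threshold=2.0, max_trials=500,
                                rng=seed)
        if model is not None and inliers is not None and inliers.sum() >= 3:
            m = np.asarray(model.params, dtype=float)
            if np.isfinite(m).all():
                return m
    # dense-flow fallback: median displacement of content b -> a is the
    # negative of a -> b
    fx, fy = estimate_flow(a, b)
    m = np.eye(3)
    m[0, 2] = -float(np.median(fx))
    m[1, 2] = -float(np.median(fy))
    return m


def estimate_camera_path(frames: list[np.ndarray], seed: int = 0) -> CameraPath:
    """Accumulated affine camera path; path[0] = identity,
    path[i] = path[i-1] @ T_i with T_i the frame-i -> frame-(i-1) transform."""
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    acc = [np.eye(3)]
    for i in range(1, len(frames)):
        try:
            t = _pair_affine(frames[i - 1], frames[i], seed)
        except Exception as e:  # estimation failure: substitute identity
            log.warning("camera-path pair %d failed (%s); identity used", i, e)
            t = np.eye(3)
        acc.append(acc[-1] @ t)
    tx = np.array([m[0, 2] for m in acc])
    ty = np.array([m[1, 2] for m in acc])
    return CameraPath(acc, tx, ty)


def jitter_variance(path: CameraPath) -> tuple[float, float]:
    """Variance of frame-to-frame displacements along the accumulated path.

    First differences isolate jitter from intended slow translation: a
    constant-velocity path has zero variance.
    """
    if len(path.transforms) < 2:
        raise ValueError("path too short")
    return (float(np.var(np.diff(path.tx))), float(np.var(np.diff(path.ty))))


# -------------------------------------------------------------- sharpness

@dataclass
class SharpnessGrid:
    scores: np.ndarray
    valid: np.ndarray
    block_size: int
    metric: str


_LAPLACIAN = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)


def _block_score(block: np.ndarray, metric: str) -> float:
    if metric == "laplacian":
        resp = ndimage.convolve(block, _LAPLACIAN, mode="reflect")
        return float(resp.var())
    if metric == "sobel":
        gx = ndimage.sobel(block, axis=1, mode="reflect")
        gy = ndimage.sobel(block, axis=0, mode="reflect")
        return float(np.mean(gx * gx + gy * gy))
    if metric == "brenner":
        d = block[:, 2:] - block[:, :-2]
        return float(np.mean(d * d))
    raise ValueError(f"unknown metric {metric!r}")


def block_sharpness(image: np.ndarray, block_size: int = 128,
                    metric: str = "laplacian",
                    margin_fraction: float = 0.05) -> SharpnessGrid:
    """Per-block sharpness over a non-overlapping tiling.

    Partial edge blocks are invalid, as are blocks where more than
    ``margin_fraction`` of pixels are exactly 0 (uncovered canvas margins).
    """
    if block_size < 8:
        raise ValueError("block_size must be >= 8")
    if metric not in SHARPNESS_METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    nby, nbx = h // block_size, w // block_size
    scores = np.zeros((nby, nbx))
    valid = np.zeros((nby, nbx), dtype=bool)
    for by in range(nby):
        for bx in range(nbx):
            blk = img[by * block_size:(by + 1) * block_size,
                      bx * block_size:(bx + 1) * block_size]
            if np.mean(blk == 0.0) > margin_fraction:
                continue
            scores[by, bx] = _block_score(blk, metric)
            valid[by, bx] = True
    return SharpnessGrid(scores, valid, block_size, metric)


def sharpness_uniformity(grid: SharpnessGrid) -> float:
    """Variance of block scores over valid blocks (lower = more uniform)."""
    vals = grid.scores[grid.valid]
    if vals.size < 2:
        raise ValueError("need at least 2 valid blocks")
    return float(np.var(vals))


# ----------------------------------------------------------- pair quality

def sequence_quality(frames: list[np.ndarray], homs) -> dict:
    """Registered consecutive-pair SSIM and RMSE.

    ``homs[i]`` maps frame i into a common reference; frame i+1 is warped
    into frame i via the relative homography and both metrics are computed
    over the valid overlap (SSIM on its bounding box, window 7, data range
    1.0; RMSE on the 8-bit [0, 255] scale).  Returns means and standard
    deviations over pairs.
    """
    from .simgen import warp_with_homography

    mats = [h if h is None or isinstance(h, np.ndarray) else h.matrix
            for h in homs]
    ssims, rmses = [], []
    for i in range(len(frames) - 1):
        if mats[i] is None or mats[i + 1] is None:
            continue
        rel = np.linalg.inv(mats[i]) @ mats[i + 1]  # frame i+1 -> frame i
        f1 = np.asarray(frames[i], dtype=float)
        f2 = np.asarray(frames[i + 1], dtype=float)
        w2 = warp_with_homography(f2, rel, f1.shape)
        v2 = warp_with_homography(np.ones_like(f2), rel, f1.shape) > 0.99
        if v2.sum() < 64:
            log.warning("pair (%d,%d): empty overlap, skipped", i, i + 1)
            continue
        ys, xs = np.nonzero(v2)
        y0, y1, x0, x1 = ys.min(), ys.max() + 1, xs.min(), xs.max() + 1
        a = f1[y0:y1, x0:x1]
        b = w2[y0:y1, x0:x1]
        if min(a.shape) < 7:
            continue
        ssims.append(structural_similarity(a, b, win_size=7,
                                           gaussian_weights=True,
                                           data_range=1.0))
        m = v2[y0:y1, x0:x1]
        rmses.append(float(np.sqrt(np.mean((255.0 * (a[m] - b[m])) ** 2))))
    if not ssims:
        raise ValueError("no valid registered pairs")
    return {
        "ssim_mean": float(np.mean(ssims)), "ssim_sd": float(np.std(ssims)),
        "rmse_mean": float(np.mean(rmses)), "rmse_sd": float(np.std(rmses)),
        "n_pairs": len(ssims),
    }
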