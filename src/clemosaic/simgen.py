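"""Seeded generator of synthetic gland-bearing endomicroscopy sequences.

Real confocal laser endomicroscopy (CLE) of gastric mucosa shows bright
tubular/elliptical glandular structures on a darker speckled background; the
probe is moved in a "slow translation - brief pause" rhythm, and frames
acquired while the probe moves are sheared row-progressively by the line-scan
(rolling-shutter) acquisition.  This module renders that phenomenology with
fully known ground truth: binary gland masks, per-frame stability labels, and
exact inter-frame translation homographies — the substrate every other module
is tested against.

The global scene is rendered once at twice the frame size; each frame is a
translated window into it, so pairwise transforms are known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class GlandSceneParams:
    """Parameters of one synthetic glandular scene.

    Defaults emulate CLE appearance: bright glands (~0.75) over a dark
    (~0.25) background with multiplicative-looking speckle and mild
    vignetting.
    """

    image_size: tuple[int, int] = (128, 128)  # (H, W)
    n_glands: int = 6
    gland_axis_range: tuple[float, float] = (8.0, 22.0)  # semi-axes, px
    gland_intensity: float = 0.75
    background_intensity: float = 0.25
    speckle_sigma: float = 0.06
    vignetting_strength: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        lo, hi = self.gland_axis_range
        if self.n_glands < 1:
            raise ValueError("n_glands must be >= 1")
        if not (0.0 <= self.background_intensity < self.gland_intensity <= 1.0):
            raise ValueError("need 0 <= background_intensity < gland_intensity <= 1")
        if lo <= 0 or hi < lo:
            raise ValueError("gland_axis_range must be positive and ordered")
        if 2 * hi >= min(h, w):
            raise ValueError("gland axes exceed image size")
        if self.speckle_sigma < 0 or not (0.0 <= self.vignetting_strength <= 1.0):
            raise ValueError("invalid noise/vignetting parameters")


@dataclass(frozen=True)
class MotionScript:
    """Per-frame probe displacement and ground-truth stability labels.

    ``displacements[i]`` is the (dx, dy) window translation applied *before*
    frame ``i`` is acquired (frame 0 has displacement (0, 0)).  A frame is
    labelled stable iff its displacement magnitude is below
    ``pause_threshold``; the labels are a pure function of the script.
    ``shear_gain`` converts probe velocity into bottom-row rolling-shutter
    displacement.
    """

    displacements: tuple[tuple[float, float], ...]
    pause_threshold: float = 0.5
    shear_gain: float = 1.0

    def __post_init__(self):
        if len(self.displacements) < 2:
            raise ValueError("script length must be >= 2")
        if self.pause_threshold < 0 or self.shear_gain < 0:
            raise ValueError("pause_threshold and shear_gain must be >= 0")

    @property
    def stability_labels(self) -> list[bool]:
        return [float(np.hypot(dx, dy)) < self.pause_threshold
                for dx, dy in self.displacements]

    def __len__(self):
        return len(self.displacements)


@dataclass
class SyntheticSequence:
    frames: list[np.ndarray]
    masks: list[np.ndarray]
    stability_labels: list[bool]
    true_pair_transforms: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.frames)
        if not (len(self.masks) == len(self.stability_labels) == n):
            raise ValueError("frames/masks/labels length mismatch")
        if self.true_pair_transforms and len(self.true_pair_transforms) != n - 1:
            raise ValueError("need n-1 pair transforms")


def translation_homography(dx: float, dy: float) -> np.ndarray:
    h = np.eye(3)
    h[0, 2] = dx
    h[1, 2] = dy
    return h


@dataclass(frozen=True)
class GlandGeometry:
    """Center, semi-axes and orientation of one rendered gland ellipse."""

    cx: float
    cy: float
    a: float
    b: float
    theta: float

    def contains(self, x, y) -> np.ndarray:
        ct, st = np.cos(self.theta), np.sin(self.theta)
        u = (x - self.cx) * ct + (y - self.cy) * st
        v = -(x - self.cx) * st + (y - self.cy) * ct
        return (u / self.a) ** 2 + (v / self.b) ** 2 <= 1.0


def _render_scene(params: GlandSceneParams, size: tuple[int, int],
                  rng: np.random.Generator, with_geometry: bool = False):
    """Render glands + noise at an arbitrary canvas size (H, W)."""
    h, w = size
    lo, hi = params.gland_axis_range
    mask = np.zeros((h, w), dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w]
    geoms: list[GlandGeometry] = []
    placed = 0
    attempts = 0
    while placed < params.n_glands:
        attempts += 1
        if attempts > 500 * params.n_glands:
            raise ValueError("cannot place glands without overlap; reduce n_glands")
        a = rng.uniform(lo, hi)
        b = rng.uniform(lo, hi)
        theta = rng.uniform(0, np.pi)
        r = max(a, b)
        cy = rng.uniform(r + 1, h - r - 1)
        cx = rng.uniform(r + 1, w - r - 1)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        # 2-px clearance keeps components separable
        grown = (u / (a + 2)) ** 2 + (v / (b + 2)) ** 2 <= 1.0
        if (mask[grown] > 0).any():
            continue
        mask[inside] = 1
        geoms.append(GlandGeometry(cx=cx, cy=cy, a=a, b=b, theta=theta))
        placed += 1

    frame = np.where(mask > 0, params.gland_intensity,
                     params.background_intensity).astype(float)
    if params.speckle_sigma > 0:
        # correlated speckle: low-pass filtered gaussian field
        noise = rng.normal(0, 1.0, (h, w))
        noise = ndimage.gaussian_filter(noise, 1.0)
        noise *= params.speckle_sigma / max(noise.std(), 1e-12)
        frame = frame + noise
    if params.vignetting_strength > 0:
        cy, cx = (h - 1) / 2, (w - 1) / 2
        r2 = ((yy - cy) / (h / 2)) ** 2 + ((xx - cx) / (w / 2)) ** 2
        frame = frame * (1.0 - params.vignetting_strength * 0.5 * r2)
    frame = np.clip(frame, 0.0, 1.0)
    if with_geometry:
        return frame, mask, geoms
    return frame, mask


def generate_gland_image(params: GlandSceneParams, with_geometry: bool = False):
    """Render one frame and its ground-truth gland mask.

    Returns ``(frame, mask)`` with the frame in [0, 1] and the mask binary
    uint8 — plus the list of rendered :class:`GlandGeometry` when
    ``with_geometry`` is set.  Identical params (including seed) give
    bit-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    return _render_scene(params, params.image_size, rng, with_geometry)


def apply_rolling_shutter(frame: np.ndarray, mask: np.ndarray,
                          velocity: tuple[float, float],
                          shear_gain: float) -> tuple[np.ndarray, np.ndarray]:
    """Emulate line-scan distortion of a frame acquired while the probe moves.

    Rows are acquired top to bottom; row ``y`` of the output samples the
    input displaced by ``shear_gain * (y / H) * velocity`` — the top row is
    undisplaced and displacement grows linearly with the row index.
    Out-of-bounds samples take the nearest border value.  The mask is warped
    identically and re-binarized at 0.5.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != mask.shape:
        raise ValueError("frame and mask dims differ")
    vx, vy = velocity
    if (vx == 0 and vy == 0) or shear_gain == 0:
        return frame.copy(), (np.asarray(mask) > 0).astype(np.uint8)
    h, w = frame.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    frac = yy / h
    sx = xx + shear_gain * frac * vx
    sy = yy + shear_gain * frac * vy
    coords = np.stack([sy, sx])
    out = ndimage.map_coordinates(frame, coords, order=1, mode="nearest")
    m = ndimage.map_coordinates((np.asarray(mask) > 0).astype(float), coords,
                                order=1, mode="constant", cval=0.0)
    return out, (m >= 0.5).astype(np.uint8)


def generate_sequence(scene: GlandSceneParams,
                      script: MotionScript) -> SyntheticSequence:
    """Render a motion-scripted sequence with exact ground truth.

    A global scene twice the frame size is rendered once; each frame is the
    window at the script's cumulative displacement.  Frames labelled unstable
    receive rolling-shutter shear at that frame's velocity.  The returned
    pair transforms map frame ``i`` pixel coordinates into frame ``i+1``
    coordinates (pure translations, exact).
    """
    scene.validate()
    h, w = scene.image_size
    big = GlandSceneParams(
        image_size=(2 * h, 2 * w),
        n_glands=scene.n_glands * 4,  # keep gland density constant on 4x area
        gland_axis_range=scene.gland_axis_range,
        gland_intensity=scene.gland_intensity,
        background_intensity=scene.background_intensity,
        speckle_sigma=scene.speckle_sigma,
        vignetting_strength=0.0,  # vignetting is per-frame, applied below
        seed=scene.seed,
    )
    rng = np.random.default_rng(scene.seed)
    global_frame, global_mask = _render_scene(big, big.image_size, rng)

    if scene.vignetting_strength > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = (h - 1) / 2, (w - 1) / 2
        r2 = ((yy - cy) / (h / 2)) ** 2 + ((xx - cx) / (w / 2)) ** 2
        vig = 1.0 - scene.vignetting_strength * 0.5 * r2
    else:
        vig = None

    ox, oy = w / 2.0, h / 2.0  # start window centered in the global scene
    labels = script.stability_labels
    frames, masks, transforms = [], [], []
    offsets = []
    for i, (dx, dy) in enumerate(script.displacements):
        ox += dx
        oy += dy
        if not (0 <= ox <= w and 0 <= oy <= h):
            raise ValueError(
                f"frame {i}: cumulative displacement pushes window outside scene"
            )
        offsets.append((ox, oy))
        iox, ioy = int(round(ox)), int(round(oy))
        sub_f = global_frame[ioy : ioy + h, iox : iox + w].copy()
        sub_m = global_mask[ioy : ioy + h, iox : iox + w].copy()
        if not labels[i]:
            sub_f, sub_m = apply_rolling_shutter(
                sub_f, sub_m, (dx, dy), script.shear_gain
            )
        if vig is not None:
            sub_f = np.clip(sub_f * vig, 0.0, 1.0)
        frames.append(sub_f)
        masks.append(sub_m.astype(np.uint8))

    for i in range(len(offsets) - 1):
        # pixel p in frame i sits at global offset_i + p; in frame i+1 coords
        # it is p + (offset_i - offset_{i+1})
        dx = round(offsets[i][0]) - round(offsets[i + 1][0])
        dy = round(offsets[i][1]) - round(offsets[i + 1][1])
        transforms.append(translation_homography(dx, dy))

    return SyntheticSequence(frames, masks, list(labels), transforms)


def warp_with_homography(frame: np.ndarray, h: np.ndarray,
                         out_size: tuple[int, int]) -> np.ndarray:
    """Warp a frame by a forward homography onto an (H, W) output grid.

    ``h`` maps input pixel coordinates (x, y) to output coordinates; the
    output is produced by inverse-mapped bilinear resampling, zero outside.
    """
    from skimage.transform import ProjectiveTransform, warp

    h = np.asarray(h, dtype=float)
    if abs(np.linalg.det(h)) < 1e-12:
        raise ValueError("singular homography")
    tf = ProjectiveTransform(matrix=np.linalg.inv(h))
    return warp(np.asarray(frame, dtype=float), tf,
                output_shape=out_size, order=1, mode="constant", cval=0.0)


def default_motion_script(n_frames: int, unstable_fraction: float = 0.2,
                          seed: int = 0, step_px: float = 8.0,
                          jitter_px: float = 2.0,
                          shear_gain: float = 4.0,
                          max_drift: float = 48.0) -> MotionScript:
    """Slow-translation / brief-pause script with a bounded drift.

    Pauses (stable frames) have sub-pixel tremor; moves (unstable frames)
    displace ``step_px`` +/- jitter along a drift direction that reflects
    off the scene boundary, so cumulative motion stays inside the global
    canvas for any frame count.
    """
    if not (0.0 <= unstable_fraction < 1.0):
        raise ValueError("unstable_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_unstable = int(round(unstable_fraction * n_frames))
    # spread moves over the sequence, never at frame 0
    move_at = set()
    if n_unstable:
        idx = np.linspace(1, n_frames - 1, n_unstable)
        move_at = {int(round(i)) for i in idx}
    angle = rng.uniform(0, 2 * np.pi)
    pos = np.zeros(2)
    bound = max_drift  # reflecting walk: cumulative drift stays within +/- bound
    disps = []
    for i in range(n_frames):
        if i in move_at:
            step = step_px + rng.normal(0, jitter_px)
            step = max(1.0, step)
            d = np.array([np.cos(angle), np.sin(angle)]) * step
            for _ in range(8):
                if np.all(np.abs(pos + d) < bound):
                    break
                angle = rng.uniform(0, 2 * np.pi)
                d = np.array([np.cos(angle), np.sin(angle)]) * step
            angle += rng.normal(0, 0.3)  # slow heading drift
            pos += d
            disps.append((float(d[0]), float(d[1])))
        else:
            tremor = rng.normal(0, 0.08, 2)  # sub-pixel pause tremor
            disps.append((float(tremor[0]), float(tremor[1])))
    return MotionScript(tuple(disps), pause_threshold=0.5, shear_gain=shear_gain)
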