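"""Sequence I/O, configuration and the end-to-end pipeline.

The pipeline ties the stages together: (1) gland segmentation masks — from a
trained network checkpoint or supplied externally, (2) mask-projection
stable-frame selection, (3) mask-constrained stitching of the stable subset,
(4) the stabilization/sharpness evaluation battery.  All outputs are plain
PNG/JSON; every stage logs its parameters and the run seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import dgunet, mosaic, stabeval, stableframes

log = logging.getLogger(__name__)


def load_image(path) -> np.ndarray:
    """One grayscale frame in [0, 1]; multi-channel input is reduced by
    luminance."""
    try:
        arr = iio.imread(path)
    except Exception as e:
        raise IOError(f"unreadable image file: {path}") from e
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        arr = arr[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    if arr.max() > 1.0:
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def load_sequence(directory, pattern: str = "*.png") -> list[np.ndarray]:
    """All frames matching the glob, sorted lexicographically by name."""
    directory = Path(directory)
    if not directory.is_dir():
        raise IOError(f"not a directory: {directory}")
    paths = sorted(directory.glob(pattern))
    if not paths:
        raise IOError(f"empty sequence: no files match {pattern} in {directory}")
    frames = [load_image(p) for p in paths]
    dims = {f.shape for f in frames}
    if len(dims) > 1:
        raise IOError(f"inconsistent frame dims in {directory}: {dims}")
    return frames


def save_image(path, img: np.ndarray) -> None:
    iio.imwrite(Path(path), mosaic.to_uint8(img))


def save_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


def load_mask(path) -> np.ndarray:
    return (load_image(path) >= 0.5).astype(np.uint8)


@dataclass
class PipelineConfig:
    frames_dir: str = ""
    masks_dir: str | None = None
    model_path: str | None = None
    output_dir: str = "out"
    pattern: str = "*.png"
    mask_pattern: str = "*.png"
    threshold: float = stableframes.DEFAULT_THRESHOLD
    normalization: str = "fraction"
    predict_threshold: float = 0.5
    ratio: float = 0.75
    reproj_threshold: float = 3.0
    ransac_iters: int = 2000
    n_bands: int = 5
    sigma_n: float = 10.0 / 255.0
    sigma_g: float = 0.1
    block_sizes: tuple = (128,)
    sharpness_metrics: tuple = stabeval.SHARPNESS_METRICS
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def run_pipeline(cfg: PipelineConfig) -> tuple[Path, Path]:
    """Execute segmentation -> selection -> stitching -> evaluation.

    Returns (panorama path, report path).  Masks may be supplied externally
    (``masks_dir``) to bypass the network; otherwise ``model_path`` must
    point at a trained checkpoint.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in asdict(cfg).items()},
                    "stages": []}

    def stage(name):
        log.info("stage: %s", name)
        report["stages"].append(name)
        return time.time()

    t0 = stage("load")
    frames = load_sequence(cfg.frames_dir, cfg.pattern)
    if cfg.masks_dir:
        masks = [load_mask(p) for p in sorted(Path(cfg.masks_dir).glob(cfg.mask_pattern))]
        if len(masks) != len(frames):
            raise ValueError("mask count does not match frame count")
    elif cfg.model_path:
        t0 = stage("segment")
        net = dgunet.load_checkpoint(cfg.model_path)
        masks = [dgunet.predict_mask(net, f, cfg.predict_threshold)
                 for f in frames]
    else:
        raise ValueError("configuration error: need masks_dir or model_path")

    t0 = stage("select")
    stable_idx, scores = stableframes.select_stable_frames(
        masks, cfg.threshold, cfg.normalization)
    report["selection"] = {
        "threshold": cfg.threshold,
        "normalization": cfg.normalization,
        "stable_indices": stable_idx,
        "dropped_indices": sorted(set(range(len(frames))) - set(stable_idx)),
        "scores": [{"pair": list(s.pair_index), "d": s.d} for s in scores],
    }
    if len(stable_idx) < 2:
        raise RuntimeError("selection stage left fewer than 2 frames")

    t0 = stage("stitch")
    scfg = mosaic.StitchConfig(ratio=cfg.ratio,
                               reproj_threshold=cfg.reproj_threshold,
                               max_iters=cfg.ransac_iters, seed=cfg.seed,
                               n_bands=cfg.n_bands, sigma_n=cfg.sigma_n,
                               sigma_g=cfg.sigma_g)
    sframes = [frames[i] for i in stable_idx]
    smasks = [masks[i] for i in stable_idx]
    panorama, homs = mosaic.stitch_sequence(sframes, smasks, scfg)
    report["stitch"] = {
        "n_input": len(sframes),
        "homographies": [None if h is None else h.matrix.tolist()
                         for h in homs],
    }

    t0 = stage("evaluate")
    aligned = stabeval.align_frame_count(sframes, stable_idx, len(frames))
    path_orig = stabeval.estimate_camera_path(frames, cfg.seed)
    path_stab = stabeval.estimate_camera_path(aligned, cfg.seed)
    jx_o, jy_o = stabeval.jitter_variance(path_orig)
    jx_s, jy_s = stabeval.jitter_variance(path_stab)
    report["stability"] = {
        "jitter_variance_original": {"x": jx_o, "y": jy_o},
        "jitter_variance_stabilized": {"x": jx_s, "y": jy_s},
    }
    sharp = {}
    for bs in cfg.block_sizes:
        for metric in cfg.sharpness_metrics:
            try:
                grid = stabeval.block_sharpness(panorama, bs, metric)
                sharp[f"{metric}_{bs}"] = stabeval.sharpness_uniformity(grid)
            except ValueError as e:
                sharp[f"{metric}_{bs}"] = None
                log.warning("sharpness %s@%d skipped: %s", metric, bs, e)
    report["sharpness_uniformity"] = sharp
    try:
        report["sequence_quality"] = stabeval.sequence_quality(sframes, homs)
    except ValueError as e:
        log.warning("sequence quality skipped: %s", e)

    pano_path = out / "panorama.png"
    save_image(pano_path, panorama)
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return pano_path, report_path
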