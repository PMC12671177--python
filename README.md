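# clemosaic

Rolling-shutter-resistant mosaicking of confocal laser endomicroscopy (CLE)
video.

CLE probes image gastrointestinal mucosa at micron scale through a
line-scanning mechanism: rows of each frame are acquired sequentially, so
probe motion shears and stretches glandular structures differently across the
frame (the rolling-shutter effect). Those distortions break feature matching
and produce misaligned panoramas. `clemosaic` implements a stitching pipeline
that suppresses them in three stages:

1. **Gland segmentation** with a dual-path Gaussian U-Net: two parallel
   encoder paths — one preceded by fixed, unit-sum Gaussian convolutions
   (9×9, `G(x,y) ∝ exp(−((x−μ)² + (y−μ)²)/2σ²)`), one plain — fused by
   channel concatenation at the two deepest stages, with a mirrored dual
   decoder. Ablation variants (plain U-Net, Gaussian-only, dual-path-only)
   share the skeleton. Training is BCE + Adam on a small numpy autodiff
   engine (no GPU framework required).
2. **Stable-frame selection** from the binary masks `M(x,y)` via projection
   profiles `R(y) = Σₓ M(x,y)`, `C(x) = Σ_y M(x,y)` and the pair score
   `D(i,i+1) = Σ_y (Rᵢ−Rᵢ₊₁)² + Σₓ (Cᵢ−Cᵢ₊₁)²`. Scores are bimodal under
   the clinical "slow translation – brief pause" probe rhythm; frames whose
   adjacent scores all exceed a threshold (default 0.8 on per-line foreground
   fractions, or an Otsu-style suggested split) are discarded as
   motion-corrupted.
3. **Mask-constrained stitching**: SIFT keypoints filtered to mask foreground
   (`K = {(x,y) | M(x,y)=1}`), Lowe ratio matching (0.75), seeded RANSAC
   homographies composed to a central reference, Brown–Lowe gain
   compensation, and multi-band (Laplacian-band) blending.

An evaluation battery quantifies the benefit: dense-flow frame interpolation
`I_interp = (1−α)·I₁(x′,y′) + α·I₂(x′,y′)` to restore frame counts,
accumulated-affine camera paths and their jitter (first-difference) variance,
block-wise sharpness maps (Laplacian variance, Sobel, Brenner), and
registered-pair SSIM/RMSE.

Because clinical CLE recordings are not redistributable, the package ships a
seeded synthetic generator (`clemosaic.simgen`) that renders gland-like
scenes with exact ground truth: binary masks, per-frame stability labels,
known inter-frame translations, and a row-progressive shear model of the
line-scan distortion. Every claim the test suite checks is measured on that
substrate.

## Worked example

```python
import numpy as np
from clemosaic import simgen, stableframes, mosaic, stabeval

scene = simgen.GlandSceneParams(image_size=(256, 256), n_glands=14, seed=100)
script = simgen.default_motion_script(40, unstable_fraction=0.2, seed=101)
seq = simgen.generate_sequence(scene, script)

idx, scores = stableframes.select_stable_frames(seq.masks, threshold=0.8)
print(f"stable frames: {len(idx)}/40")

pano, homs = mosaic.stitch_sequence(
    [seq.frames[i] for i in idx], [seq.masks[i] for i in idx],
    mosaic.StitchConfig(seed=0))
print("panorama:", pano.shape)

aligned = stabeval.align_frame_count([seq.frames[i] for i in idx], idx, 40)
jo = stabeval.jitter_variance(stabeval.estimate_camera_path(seq.frames))
js = stabeval.jitter_variance(stabeval.estimate_camera_path(aligned))
print(f"jitter variance x: {jo[0]:.2f} -> {js[0]:.2f}")
print(f"jitter variance y: {jo[1]:.2f} -> {js[1]:.2f}")
```

Output:

```
stable frames: 31/40
panorama: (273, 296)
jitter variance x: 12.90 -> 3.86
jitter variance y: 1.34 -> 0.51
```

31 of 40 frames survive selection (the script-labelled moving frames are
rejected, plus one borderline neighbour); stitching the stable subset yields
a panorama a little larger than one frame, and the stabilized,
flow-interpolated sequence shows roughly 3× lower frame-to-frame displacement
variance on both axes — the jitter that rolling-shutter-distorted frames
inject into the camera path is gone.

A command-line interface mirrors the library:

```sh
clemosaic simulate --out seq/ --frames 60 --size 256 --seed 1
clemosaic select --masks seq/ --threshold 0.8 --out selection.json
clemosaic stitch --frames seq/ --masks seq/ --out panorama.png
clemosaic segment train --data seq/ --variant dgu_net --epochs 100 \
    --batch 2 --lr 5e-5 --out model.npz
clemosaic run --config pipeline.yaml
```

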