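# Methods

This note documents the models and procedures `clemosaic` implements, the
design choices made where the design was genuinely open, the synthetic-study
conditions the tests run under, and the known limitations. It states no
empirical number that the test suite or `scripts/acceptance.py` does not
itself compute.

## The segmentation network

The segmenter is a fully convolutional U-shaped network operating on
single-channel frames in [0, 1], with four variants:

| variant   | paths | Gaussian layers |
|-----------|-------|-----------------|
| `unet`    | 1     | none            |
| `gu_net`  | 1     | every block     |
| `du_net`  | 2     | none            |
| `dgu_net` | 2     | path A blocks; decoder A stage 1, decoder B stage 4 |

**Gaussian convolution.** A fixed (non-trainable) isotropic Gaussian kernel,
default 9×9 with the center at μ=(k−1)/2, applied depthwise per channel with
reflective padding and renormalized to unit sum, so constant feature maps are
preserved. σ is not determined by the kernel size alone; the default σ=1.7
is the usual size-derived value for a 9×9 support (≈ k/5) and is
configurable. The layer is implemented separably (two 1-D passes) in both
the plain-numpy path and the autodiff path; the adjoint of the reflective
gather is realized by scatter-adding along the same indices, so gradients
are exact (checked against central finite differences in float64).

**Topology.** Five downsampling stages (2×2 max-pool), channel widths
doubling from `base_channels` and capped at 16×. Each block is a DoubleConv:
two (3×3 conv → batch norm → ReLU) units, optionally preceded by the
Gaussian layer. In the dual-path variants, the two encoder streams are fused
at the two deepest stages by channel concatenation followed by a 1×1
reduction (concatenation alone would double decoder widths); each decoder
mirrors its encoder using that path's skip connections, the two decoder
outputs are concatenated at half resolution, and a final bilinear upsample
plus two 3×3 convolutions and a 1×1 projection produce the logit map. A
sigmoid yields the probability map; `predict_mask` thresholds it (default
0.5) and reflect-pads inputs whose dimensions are not divisible by 2^depth
(e.g. native 892×892 frames are padded to 896×896 and cropped back).

**Training.** Binary cross-entropy on logits, Adam (β = 0.9/0.999),
deterministic train/validation split by a fixed seed (default 80/20).
The clinical protocol constants — lr 5·10⁻⁵, 100 epochs, batch 2 — are the
defaults of `TrainConfig` and of the CLI; the synthetic studies (below) use
scaled settings. The best-validation-Dice weights are restored at the end.
The engine is a small reverse-mode autodiff over NCHW float32 numpy arrays:
convolutions as per-tap tensordot GEMMs, the input gradient as a transposed
convolution through the same path, 2× bilinear up/down sampling with exact
scatter adjoints. A ~1-second training step on a 128×128 pair (batch 2,
`base_channels=8`) makes the desk-scale studies practical on one CPU core.

**Metrics.** Accuracy, Dice, Jaccard, sensitivity, specificity in percent
from the confusion counts of a mask pair; evaluation-set values are
per-image means by default (pooled counts available). A ratio whose
denominator vanishes is reported as 100 when both masks are empty for that
class, else 0. Dice and Jaccard from the same counts satisfy
Dice = 200·JA/(100+JA) exactly.

## Stable-frame selection

Projection profiles of a binary mask are per-row and per-column foreground
counts. Two normalizations are provided: `raw` (counts, used by the exact
hand-checkable tests) and `fraction` (row counts divided by width, column
counts by height — per-line foreground fractions). `fraction` is the
default: the pair score D on raw counts scales with (image size)³ and no
single threshold could be meaningful across sizes, whereas on fractions D is
size-independent and the default threshold 0.8 discriminates well.

The score D(i, i+1) is the sum of squared profile differences of consecutive
masks. Under the "slow translation – brief pause" probe rhythm its empirical
distribution is bimodal: near zero for pause pairs, large for any pair
involving a moving (sheared) frame. A frame is discarded iff **all** of its
adjacent pair scores reach the threshold: a motion-corrupted frame disturbs
both of its pairs, so it is removed exactly, while its neighbours retain
their other low score and stay. `suggest_threshold` returns the exact
two-class between-class-variance maximizer over midpoints of sorted unique
scores (Otsu on the empirical distribution, no histogram binning), flagging
the result as degenerate when the best split explains less than 70% of the
total variance — approximately what the optimal split of a unimodal normal
sample achieves (2/π ≈ 0.64), so genuinely bimodal score sets are well above
it. Empty masks score D = 0 against empty masks and are "stable"; they carry
no features, which the stitcher logs and tolerates.

## Mask-constrained stitching

* **Keypoints**: SIFT (128-d descriptors) detected on the full frame; a
  keypoint survives iff the mask at its rounded center position is 1 (the
  descriptor support region is not tested — the filter is pointwise).
* **Matching**: exhaustive nearest-neighbour search with Lowe's ratio test,
  default 0.75, uniqueness on the query side.
* **Homographies**: seeded RANSAC over 4-point DLT solves (reprojection
  threshold 3 px, 2000 iterations), refit on the inlier set, normalized to
  unit bottom-right entry. Consecutive-pair estimates are composed to the
  middle retained frame (the reference), which minimizes compounded drift;
  frames whose pair cannot be estimated are dropped and the chain re-linked
  across the gap.
* **Gain compensation**: per-frame multiplicative gains minimizing
  Σ N_ij (g_i Ī_ij − g_j Ī_ji)²/σ_N² + Σ (Σ_j N_ij)(1−g_i)²/σ_g² over
  canvas overlaps (Ī_ij = mean intensity of frame i in its overlap with j),
  solved as a linear system. Defaults σ_N = 10/255 (the classical 8-bit
  value expressed on the [0, 1] intensity scale) and σ_g = 0.1. Note the
  prior deliberately shrinks gains toward 1: a pair differing by a genuine
  1.2× brightness factor is compensated to a smaller ratio.
* **Blending**: multi-band in the image plane — each warped frame is split
  into frequency bands by successive Gaussian low-passes of doubling scale
  (σ₀ = 2), with normalized-convolution extension beyond each frame's
  coverage so blurring never mixes in canvas background; band k is averaged
  with the per-frame feather weights smoothed at that band's scale. The
  band sum telescopes, so a single image round-trips exactly and
  `n_bands=1` reduces to plain weighted averaging. Default 5 bands.
  Panoramas are written as 8-bit with round-half-up.

## Evaluation battery

* **Frame interpolation**: dense flow between flanking stable frames
  (iterative Lucas–Kanade, radius 15 — the package's dense-flow choice),
  then the convex blend I_interp = (1−α)·I₁ + α·I₂ of the forward- and
  backward-warped frames; a gap of T frames uses α = t/(T+1), t = 1..T.
  With exact flows, a half-step interpolation of a translated pair equals
  the half-translated frame (tested).
* **Camera path**: per-pair affine transforms from ratio-matched SIFT
  features with RANSAC (median dense-flow translation as fallback, identity
  with a warning on failure), accumulated by right multiplication;
  the translation components (tx, ty) trace apparent probe motion.
* **Jitter**: variance of the *first differences* of tx and ty. Raw-position
  variance would conflate intended slow translation with jitter; first
  differences make a constant-velocity path score zero.
* **Block sharpness**: non-overlapping blocks (64/128/256 px); per valid
  block the variance of the 3×3 Laplacian response, the mean squared Sobel
  gradient magnitude, or the mean squared two-pixel horizontal difference
  (Brenner). Partial edge blocks, and blocks with more than 5% exactly-zero
  pixels (uncovered canvas margins), are invalid. Sharpness uniformity is
  the raw variance of valid block scores (lower = more uniform).
* **Pair quality**: frame i+1 warped into frame i by the relative
  homography; SSIM (window 7, Gaussian-weighted, data range 1.0) on the
  overlap bounding box and RMSE on the 8-bit scale over overlap pixels,
  reported as mean ± sd over pairs.

## Synthetic data and study conditions

The generator renders bright elliptical glands (non-overlapping, 2 px
clearance) on a darker background with correlated speckle and optional
vignetting; defaults: gland intensity 0.75, background 0.25, speckle σ 0.06,
semi-axes 8–22 px. A sequence renders one global scene at twice the frame
size and windows it per a motion script, so inter-frame translations are
known exactly. Rolling shutter is modelled as per-row linear shear: row y of
a moving frame samples the scene displaced by `shear_gain · (y/H) · velocity`
(top-origin scan, configurable). Stability labels derive from the script
alone, never from pixels.

The default motion script emulates the clinical rhythm: pauses with
sub-pixel tremor (σ 0.08 px) interrupted by moves of 8 ± 2 px along a slowly
drifting heading, reflected at a drift bound so any sequence length stays
inside the global scene. `shear_gain = 4` was calibrated once so that the
D-score distribution is robustly bimodal — move-adjacent pair scores stay
well above both the 0.8 default threshold and the Otsu split across seeds
(worst selection precision 0.94, recall 0.98 over a 12-seed sweep at 60
frames, 20% unstable).

Frozen studies (in `clemosaic.protocols`, used by both the test suite and
`scripts/acceptance.py`; sizes are the package's desk-scale benchmark
design):

* **Overfit**: 4 scenes at 128×128, `dgu_net` with `base_channels=8`,
  lr 3·10⁻³, ≤200 Adam steps — a wiring check that must reach near-perfect
  training Dice and near-zero BCE. The narrow width is deliberate: the
  study measures correctness, not capacity.
* **Benchmark**: 40 scenes, 80/20 split, 6 epochs, lr 10⁻³ — held-out Dice.
* **Selection**: 60 frames at 160×160, 20% unstable, Otsu-suggested
  threshold — precision/recall against script labels.
* **Stabilization battery**: 40 frames at 288×288, 20% unstable; stitches
  the stable subset and the full sequence, then measures corner-transfer
  error against the generator's true transforms, block-128 sharpness
  variances of both panoramas, jitter variance of the original vs the
  selected-and-interpolated sequence, and registered-pair SSIM/RMSE.

What passing these studies does and does not show: the synthetic substrate
has uniform speckle statistics, rigid pure-translation motion, and clean
two-level gland contrast. It validates the algorithmic chain — mask-gated
features, bimodal score separation, homography recovery, blending
identities — but not robustness to deformable tissue, fluorescein-leakage
phenomenology, illumination drift, or real CLE texture.

## Known limitations

* **Sharpness-uniformity comparison.** On this synthetic substrate the
  all-frames panorama's misregistration appears as blending blur that
  lowers block sharpness roughly *uniformly* (mean block score about half
  the stable panorama's). Because sharpness uniformity is a raw variance —
  not scale-invariant — the blurrier mosaic often gets the *lower* variance,
  so the stable-subset panorama is not reliably "more uniform" by this
  measure here, even though its registration error is several times smaller.
  The measure discriminates mosaics with gross, spatially localized
  misplacements (sharp patches next to ruined ones); a robust RANSAC chain
  over mask-gated features does not produce such failures. Both variances
  are computed and reported as-is.
* The rolling-shutter model is a linear row shear from a global velocity;
  real line-scan distortion varies within the frame when the probe
  accelerates mid-scan.
* Pairwise composition accumulates drift over very long sequences; there is
  no bundle adjustment or loop closure.
* The camera-path estimator assumes feature-trackable content; on nearly
  empty masks it falls back to dense-flow translation.
* Nothing is real-time: SIFT, RANSAC and band blending run at seconds per
  frame on one CPU core.
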