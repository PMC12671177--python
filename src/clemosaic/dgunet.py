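"""Dual-path Gaussian U-Net gland segmentation.

The network segments glandular foreground in single-channel endomicroscopy
frames.  Its distinguishing elements are (a) fixed, non-trainable Gaussian
convolution layers (unit-sum 9x9 kernel by default) that smooth feature maps
while preserving structure, and (b) a dual-encoder/dual-decoder layout in
which one path sees Gaussian-smoothed features and the other plain features,
fused by channel concatenation at the two deepest encoder stages.  Ablation
variants — plain U-Net, Gaussian-only (GU-Net) and dual-path-only (DU-Net) —
share the same skeleton.

Training uses binary cross-entropy with Adam; evaluation reports the five
standard segmentation scores (accuracy, Dice, Jaccard, sensitivity,
specificity) as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

VARIANTS = ("unet", "gu_net", "du_net", "dgu_net")


# ------------------------------------------------------------ Gaussian kernel

@dataclass(frozen=True)
class GaussianKernelSpec:
    """Isotropic 2-D Gaussian kernel of odd size ``size`` and std ``sigma``.

    The kernel center is at mu = (size - 1) / 2 in both axes.
    """

    size: int = 9
    sigma: float = 1.7

    def __post_init__(self):
        if self.size < 1 or self.size % 2 == 0:
            raise ValueError("kernel size must be odd and >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    @property
    def mu(self) -> float:
        return (self.size - 1) / 2.0


def gaussian_kernel(spec: GaussianKernelSpec) -> np.ndarray:
    """Realize the kernel: G(x, y) ∝ exp(-((x-mu)^2 + (y-mu)^2) / (2 sigma^2)),
    renormalized so the entries sum to one."""
    k, s, mu = spec.size, spec.sigma, spec.mu
    x = np.arange(k, dtype=float)
    g2 = np.exp(-((x[:, None] - mu) ** 2 + (x[None, :] - mu) ** 2) / (2 * s * s))
    g2 /= 2 * np.pi * s * s  # Gaussian normalizer; removed again by unit-sum
    return g2 / g2.sum()


def gaussian_kernel_1d(spec: GaussianKernelSpec) -> np.ndarray:
    """Separable factor of the (unit-sum) isotropic kernel."""
    x = np.arange(spec.size, dtype=float)
    g = np.exp(-((x - spec.mu) ** 2) / (2 * spec.sigma ** 2))
    return g / g.sum()


def gaussian_smooth(features: np.ndarray, spec: GaussianKernelSpec) -> np.ndarray:
    """Smooth each channel of an (H, W) or (C, H, W) raster with the fixed
    kernel, reflective padding; output dims equal input dims."""
    from scipy import ndimage

    arr = np.asarray(features, dtype=float)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
    k1d = gaussian_kernel_1d(spec)
    out = np.empty_like(arr)
    for c in range(arr.shape[0]):
        # scipy "mirror" = reflection about the edge sample (numpy "reflect")
        tmp = ndimage.correlate1d(arr[c], k1d, axis=0, mode="mirror")
        out[c] = ndimage.correlate1d(tmp, k1d, axis=1, mode="mirror")
    return out[0] if squeeze else out


# ------------------------------------------------------------------- network

@dataclass(frozen=True)
class NetworkConfig:
    variant: str = "dgu_net"
    in_channels: int = 1
    base_channels: int = 64
    depth: int = 5
    gauss_kernel: GaussianKernelSpec = field(default_factory=GaussianKernelSpec)
    input_size: tuple[int, int] = (892, 892)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.depth < 1 or self.base_channels < 1 or self.in_channels < 1:
            raise ValueError("invalid channel/depth configuration")


class DoubleConv(nn.Module):
    """(3x3 conv -> batch norm -> ReLU) x 2, optionally preceded by fixed
    Gaussian smoothing of the incoming features."""

    def __init__(self, cin, cout, rng, gauss_k1d=None):
        self.gauss_k1d = gauss_k1d  # numpy array or None; not a parameter
        self.conv1 = nn.Conv2d(cin, cout, 3, rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng)
        self.bn2 = nn.BatchNorm2d(cout)

    def __call__(self, x):
        if self.gauss_k1d is not None:
            x = nn.gaussian_smooth_op(x, self.gauss_k1d)
        x = nn.relu(self.bn1(self.conv1(x)))
        return nn.relu(self.bn2(self.conv2(x)))


class _Encoder(nn.Module):
    """Stem + ``depth`` down stages (2x2 max-pool then DoubleConv)."""

    def __init__(self, cin, widths, rng, gauss_k1d):
        self.stem = DoubleConv(cin, widths[0], rng, gauss_k1d)
        self.downs = [DoubleConv(widths[i], widths[i + 1], rng, gauss_k1d)
                      for i in range(len(widths) - 1)]

    def __call__(self, x):
        feats = [self.stem(x)]
        for blk in self.downs:
            feats.append(blk(nn.maxpool2x2(feats[-1])))
        return feats  # [stem, d1, ..., d_depth]


class _Decoder(nn.Module):
    """Mirrored up path: upsample, concat skip, DoubleConv.

    ``gauss_stage`` (1-based, or None) marks the single up stage whose block
    applies Gaussian smoothing.
    """

    def __init__(self, widths, rng, gauss_k1d, gauss_stage):
        # widths = [W1 .. Wd]: W1..W(d-1) skip widths shallow->deep, Wd bottom
        n = len(widths) - 1  # number of up stages
        self.ups = []
        x_width = widths[-1]
        for s in range(n):
            skip_w = widths[n - 1 - s]
            out_w = widths[max(n - 2 - s, 0)]
            k = gauss_k1d if (gauss_stage is not None and s + 1 == gauss_stage) else None
            self.ups.append(DoubleConv(x_width + skip_w, out_w, rng, k))
            x_width = out_w

    def __call__(self, bottom, skips):
        x = bottom
        for blk, skip in zip(self.ups, reversed(skips)):
            x = nn.concat([nn.upsample2x(x), skip], axis=1)
            x = blk(x)
        return x


class SegmentationNet(nn.Module):
    """The four-variant segmentation network (fully convolutional).

    Widths double per stage from ``base_channels`` and cap at 16x base.  For
    dual-path variants, encoder features of both paths are concatenated and
    1x1-reduced at the two deepest stages; each decoder path mirrors its
    encoder and the two decoder outputs are concatenated before a final
    upsample and two output convolutions.
    """

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        b, d = cfg.base_channels, cfg.depth
        widths = [min(b * 2 ** i, 16 * b) for i in range(d + 1)]
        self._widths = widths
        k1d = gaussian_kernel_1d(cfg.gauss_kernel).astype(np.float32)
        dual = cfg.variant in ("du_net", "dgu_net")
        gauss = cfg.variant in ("gu_net", "dgu_net")
        self.dual = dual

        if not dual:
            self.enc = _Encoder(cfg.in_channels, widths, rng, k1d if gauss else None)
            self.dec = _Decoder(widths[1:], rng, k1d if gauss else None,
                                gauss_stage=1 if gauss else None)
            head_in = widths[1]
        else:
            # path A: Gaussian (for dgu_net), path B: plain
            self.enc_a = _Encoder(cfg.in_channels, widths, rng, k1d if gauss else None)
            self.enc_b = _Encoder(cfg.in_channels, widths, rng, None)
            # fuse the two deepest stages (concat + 1x1 reduction)
            self.fuse4 = nn.Conv2d(2 * widths[-2], widths[-2], 1, rng)
            self.fuse5 = nn.Conv2d(2 * widths[-1], widths[-1], 1, rng)
            self.dec_a = _Decoder(widths[1:], rng, k1d if gauss else None,
                                  gauss_stage=1 if gauss else None)
            self.dec_b = _Decoder(widths[1:], rng, k1d if gauss else None,
                                  gauss_stage=(d - 1) if gauss else None)
            head_in = 2 * widths[1]

        self.head1 = nn.Conv2d(head_in, widths[0], 3, rng)
        self.head_bn = nn.BatchNorm2d(widths[0])
        self.head2 = nn.Conv2d(widths[0], widths[0], 3, rng)
        self.head_bn2 = nn.BatchNorm2d(widths[0])
        self.out_conv = nn.Conv2d(widths[0], 1, 1, rng)
        self.training = True

    def forward_logits(self, x: np.ndarray) -> nn.Tensor:
        """x: (N, C, H, W) with H, W divisible by 2**depth; returns logits."""
        h, w = x.shape[2], x.shape[3]
        f = 2 ** self.cfg.depth
        if h % f or w % f:
            raise ValueError(f"input dims must be divisible by {f}")
        t = nn.Tensor(x, requires_grad=True)
        if not self.dual:
            feats = self.enc(t)
            y = self.dec(feats[-1], feats[1:-1])
        else:
            fa = self.enc_a(t)
            fb = self.enc_b(t)
            f4 = self.fuse4(nn.concat([fa[-2], fb[-2]], axis=1))
            f5 = self.fuse5(nn.concat([fa[-1], fb[-1]], axis=1))
            ya = self.dec_a(f5, fa[1:-2] + [f4])
            yb = self.dec_b(f5, fb[1:-2] + [f4])
            y = nn.concat([ya, yb], axis=1)
        # final upsample restores full resolution; two convs produce the mask
        y = nn.upsample2x(y)
        y = nn.relu(self.head_bn(self.head1(y)))
        y = nn.relu(self.head_bn2(self.head2(y)))
        return self.out_conv(y)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Probability map in (0, 1), same H x W as the input batch."""
        return nn.sigmoid(self.forward_logits(x)).data


def build_network(cfg: NetworkConfig, seed: int = 0) -> SegmentationNet:
    return SegmentationNet(cfg, seed=seed)


# ------------------------------------------------------------------ training

@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 5e-5
    epochs: int = 100
    batch_size: int = 2
    split_fraction: float = 0.8
    split_seed: int = 0
    loss: str = "bce"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must be in (0, 1)")


def _to_batch(frames, masks, idx):
    x = np.stack([frames[i] for i in idx])[:, None, :, :].astype(np.float32)
    t = np.stack([(np.asarray(masks[i]) > 0) for i in idx])[:, None, :, :]
    return x, t.astype(np.float32)


def train(net: SegmentationNet, dataset, tc: TrainConfig,
          log=None, max_steps: int | None = None):
    """Train on (frame, mask) pairs; returns (net, history).

    The dataset is split deterministically by ``split_seed`` into train and
    validation shares; the per-epoch mean training BCE and validation Dice
    are recorded and the weights achieving the best validation Dice are
    restored before returning.  ``max_steps`` caps total optimizer steps
    (useful for overfit checks).
    """
    frames = [np.asarray(f, dtype=np.float32) for f, _ in dataset]
    masks = [m for _, m in dataset]
    n = len(frames)
    if n == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(tc.split_seed)
    perm = rng.permutation(n)
    n_train = max(1, int(round(tc.split_fraction * n)))
    train_idx = perm[:n_train]
    val_idx = perm[n_train:]
    if len(train_idx) == 0:
        raise ValueError("empty training split")
    if log:
        log(f"train: n={n} train={len(train_idx)} val={len(val_idx)} "
            f"lr={tc.learning_rate} epochs={tc.epochs} batch={tc.batch_size} "
            f"loss={tc.loss}")

    opt = nn.Adam(net.parameters(), lr=tc.learning_rate)
    history = {"train_loss": [], "val_dice": []}
    best = (-1.0, None)
    steps = 0
    for epoch in range(tc.epochs):
        net.train()
        order = rng.permutation(train_idx)
        losses = []
        for s in range(0, len(order), tc.batch_size):
            if max_steps is not None and steps >= max_steps:
                break
            x, t = _to_batch(frames, masks, order[s : s + tc.batch_size])
            z = net.forward_logits(x)
            loss = nn.bce_with_logits(z, t)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            steps += 1
        if not losses:
            break
        mean_loss = float(np.mean(losses))
        if not np.isfinite(mean_loss):
            raise FloatingPointError("training loss diverged")
        history["train_loss"].append(mean_loss)

        eval_idx = val_idx if len(val_idx) else train_idx
        net.eval()
        dices = []
        for i in eval_idx:
            pred = predict_mask(net, frames[i], threshold=0.5)
            dices.append(segmentation_metrics(pred, masks[i]).dice)
        vd = float(np.mean(dices))
        history["val_dice"].append(vd)
        if log:
            log(f"epoch {epoch + 1}: loss={mean_loss:.4f} val_dice={vd:.2f}")
        if vd > best[0]:
            best = (vd, {k: v.copy() for k, v in net.state_dict().items()})
        if max_steps is not None and steps >= max_steps:
            break
    if best[1] is not None:
        net.load_state_dict(best[1])
    net.eval()
    return net, history


def predict_mask(net: SegmentationNet, frame: np.ndarray,
                 threshold: float = 0.5) -> np.ndarray:
    """Binary gland mask for one frame; reflect-pads to the divisibility
    constraint and crops back."""
    f = 2 ** net.cfg.depth
    frame = np.asarray(frame, dtype=np.float32)
    h, w = frame.shape
    ph = (-h) % f
    pw = (-w) % f
    if ph or pw:
        frame_p = np.pad(frame, ((0, ph), (0, pw)), mode="reflect")
    else:
        frame_p = frame
    prob = net.forward(frame_p[None, None])[0, 0, :h, :w]
    return (prob >= threshold).astype(np.uint8)


# ------------------------------------------------------------------- metrics

@dataclass(frozen=True)
class SegMetrics:
    ac: float
    dice: float
    ja: float
    se: float
    sp: float


def _safe_ratio(num, den, both_empty):
    if den == 0:
        return 100.0 if both_empty else 0.0
    return 100.0 * num / den


def segmentation_metrics(pred: np.ndarray, truth: np.ndarray) -> SegMetrics:
    """Accuracy, Dice, Jaccard, sensitivity, specificity (percent) from the
    pooled confusion counts of one mask pair."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("mask dims differ")
    p = pred > 0
    t = truth > 0
    tp = int(np.sum(p & t))
    tn = int(np.sum(~p & ~t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    total = tp + tn + fp + fn
    fg_empty = (tp + fp + fn) == 0   # neither mask has foreground
    bg_empty = (tn + fp + fn) == 0   # neither mask has background
    return SegMetrics(
        ac=100.0 * (tp + tn) / total,
        dice=_safe_ratio(2 * tp, 2 * tp + fp + fn, fg_empty),
        ja=_safe_ratio(tp, tp + fp + fn, fg_empty),
        se=_safe_ratio(tp, tp + fn, fg_empty),
        sp=_safe_ratio(tn, tn + fp, bg_empty),
    )


def mean_metrics(pairs, pooled: bool = False) -> SegMetrics:
    """Evaluation-set metrics: per-image mean (default) or pooled counts."""
    if pooled:
        preds = np.concatenate([np.asarray(p).ravel() for p, _ in pairs])
        truths = np.concatenate([np.asarray(t).ravel() for _, t in pairs])
        return segmentation_metrics(preds, truths)
    ms = [segmentation_metrics(p, t) for p, t in pairs]
    return SegMetrics(*[float(np.mean([getattr(m, f) for m in ms]))
                        for f in ("ac", "dice", "ja", "se", "sp")])


# --------------------------------------------------------------- checkpoints

def save_checkpoint(path, net: SegmentationNet):
    cfg = net.cfg
    np.savez_compressed(
        path,
        __variant=cfg.variant,
        __in_channels=cfg.in_channels,
        __base_channels=cfg.base_channels,
        __depth=cfg.depth,
        __gauss_size=cfg.gauss_kernel.size,
        __gauss_sigma=cfg.gauss_kernel.sigma,
        __input_h=cfg.input_size[0],
        __input_w=cfg.input_size[1],
        **net.state_dict(),
    )


def load_checkpoint(path) -> SegmentationNet:
    z = np.load(path, allow_pickle=False)
    cfg = NetworkConfig(
        variant=str(z["__variant"]),
        in_channels=int(z["__in_channels"]),
        base_channels=int(z["__base_channels"]),
        depth=int(z["__depth"]),
        gauss_kernel=GaussianKernelSpec(int(z["__gauss_size"]),
                                        float(z["__gauss_sigma"])),
        input_size=(int(z["__input_h"]), int(z["__input_w"])),
    )
    net = SegmentationNet(cfg)
    net.load_state_dict({k: z[k] for k in z.files if not k.startswith("__")})
    net.eval()
    return net
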