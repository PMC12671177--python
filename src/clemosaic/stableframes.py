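"""Mask-projection stability scoring and stable-frame selection.

A frame acquired while the probe pauses looks almost identical to its
neighbours; a frame acquired during motion is sheared by the line-scan
acquisition and its gland layout changes abruptly.  Both effects are visible
in the row/column projection profiles of the binary gland masks, so the
squared projection difference between consecutive frames

    D(i, i+1) = sum_y (R_i(y) - R_{i+1}(y))^2 + sum_x (C_i(x) - C_{i+1}(x))^2

separates stable from motion-corrupted frames into a bimodal score
distribution.  Frames whose adjacent pair scores all fall below a threshold
(default 0.8 on per-line foreground fractions) are kept.

Normalization modes
-------------------
``raw``       profiles are foreground pixel counts per row/column.
``fraction``  row counts divided by the width W and column counts by the
              height H (per-line foreground fractions in [0, 1]); keeps D on
              an image-size-independent scale compatible with the default
              threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_THRESHOLD = 0.8
NORMALIZATIONS = ("raw", "fraction")


@dataclass(frozen=True)
class ProjectionProfile:
    row: np.ndarray  # length H
    col: np.ndarray  # length W
    normalization: str = "raw"


@dataclass(frozen=True)
class StabilityScore:
    pair_index: tuple[int, int]
    d: float
    threshold: float
    stable: bool  # d < threshold


def projection_profiles(mask: np.ndarray,
                        normalization: str = "fraction") -> ProjectionProfile:
    """Row and column foreground profiles of one binary mask."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary {0,1}")
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
    h, w = mask.shape
    row = mask.sum(axis=1).astype(float)  # R(y): count per row
    col = mask.sum(axis=0).astype(float)  # C(x): count per column
    if normalization == "fraction":
        row = row / w
        col = col / h
    return ProjectionProfile(row=row, col=col, normalization=normalization)


def projection_difference(a: ProjectionProfile, b: ProjectionProfile) -> float:
    """Squared projection difference D between two profiles."""
    if a.row.shape != b.row.shape or a.col.shape != b.col.shape:
        raise ValueError("profile lengths differ")
    if a.normalization != b.normalization:
        raise ValueError("profiles use different normalizations")
    return float(np.sum((a.row - b.row) ** 2) + np.sum((a.col - b.col) ** 2))


def pair_scores(masks, threshold: float = DEFAULT_THRESHOLD,
                normalization: str = "fraction") -> list[StabilityScore]:
    """D scores for all consecutive mask pairs."""
    if len(masks) < 2:
        raise ValueError("need at least 2 masks")
    profiles = [projection_profiles(m, normalization) for m in masks]
    out = []
    for i in range(len(profiles) - 1):
        d = projection_difference(profiles[i], profiles[i + 1])
        out.append(StabilityScore((i, i + 1), d, threshold, d < threshold))
    return out


def select_stable_frames(masks, threshold: float = DEFAULT_THRESHOLD,
                         normalization: str = "fraction"):
    """Classify frames as stable or motion-corrupted.

    A motion-corrupted frame disturbs *every* pair score it participates in,
    so frame ``i`` is discarded iff all of its adjacent pair scores reach the
    threshold — an isolated bad frame is removed exactly, while its
    neighbours retain their other low score and stay.  Boundary frames have
    a single adjacent pair.

    Returns ``(stable_indices, scores)``.
    """
    scores = pair_scores(masks, threshold, normalization)
    n = len(masks)
    ok = [s.stable for s in scores]
    stable = []
    for i in range(n):
        adjacent = []
        if i > 0:
            adjacent.append(ok[i - 1])
        if i < n - 1:
            adjacent.append(ok[i])
        if any(adjacent):
            stable.append(i)
    return stable, scores


def suggest_threshold(scores) -> tuple[float, bool]:
    """Otsu-style split of the empirical D distribution.

    Evaluates every midpoint between consecutive sorted unique scores and
    returns the one maximizing the between-class variance
    ``w0 * w1 * (mu0 - mu1)^2``, together with a degeneracy flag (set when
    the scores cannot be split, e.g. all equal or effectively unimodal).
    """
    d = np.array([s.d if isinstance(s, StabilityScore) else float(s)
                  for s in scores], dtype=float)
    if d.size < 4:
        raise ValueError("need at least 4 scores")
    uniq = np.unique(d)
    if uniq.size == 1:
        return float(uniq[0]), True
    best_t, best_v = None, -1.0
    for a, b in zip(uniq[:-1], uniq[1:]):
        t = 0.5 * (a + b)
        lo, hi = d[d <= t], d[d > t]
        w0, w1 = lo.size / d.size, hi.size / d.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    # degenerate when the best split explains no more of the variance than
    # the optimal split of a unimodal (normal) sample would (~2/pi)
    total = d.var()
    degenerate = bool(total <= 0 or best_v / total < 0.7)
    return float(best_t), degenerate
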