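"""The density-based outlier-region loss.

Small, isolated foreground blobs in a predicted segmentation mask are almost
always errors ("noise regions").  The outlier loss rewards nothing but
detects them through a local density statistic: for each pixel, the ratio of
same-coloured pixels in the inner window ``N_i`` to opposite-coloured pixels
in the gap region between ``N_j`` and ``N_i``.  A pixel inside a small
isolated blob sees few white neighbours and an almost entirely black gap, so
its white density is low; a pixel inside (or at the edge of) a normal, large
segmented object sees a gap full of white and is excluded from the
computation altogether by an edge mask.

The exclusion threshold is the gap-region same-colour count at the corner of
an isolated solid ``i x i`` block — the boundary case of a maximal noise
region.  Pixels whose gap count strictly exceeds it belong to larger
structures and have their density zeroed out.

The final per-pixel loss is binary cross-entropy minus the density map:
low-density (i.e. likely-noise) foreground pixels subtract little, leaving
their loss comparatively high, while confident correct pixels of retained
small regions subtract more.  All density quantities are computed on the
*binarized* prediction; they are piecewise-constant in the prediction, so in
a training framework gradients flow only through the BCE term and the
density map acts as a per-pixel additive penalty.
"""

from __future__ import annotations

import math

import numpy as np

from .config import EPS, LossConfig
from .losses import bce_map
from .windows import as_binary_mask, count_black, count_white, gap_counts

__all__ = [
    "binarize",
    "clamp_probabilities",
    "edge_threshold",
    "density_white",
    "density_black",
    "edge_masks",
    "density_map",
    "outlier_loss_map",
    "outlier_loss",
]


def clamp_probabilities(pred) -> np.ndarray:
    """Clamp a prediction grid into the open interval via ``[EPS, 1 - EPS]``."""
    arr = np.asarray(pred, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D prediction mask, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError("prediction mask contains non-finite values")
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("prediction values must lie in [0, 1] before clamping")
    return np.clip(arr, EPS, 1.0 - EPS)


def binarize(pred) -> np.ndarray:
    """Round a probability mask to {0,1}; ties at 0.5 go to white."""
    arr = np.asarray(pred, dtype=np.float64)
    return (arr >= 0.5).astype(np.int64)


def edge_threshold(i: int, rounding: str = "ceil") -> int:
    """Edge-exclusion threshold ``i**2 - round(i/2)**2``.

    With the default round-up this equals the white gap count at the corner
    pixel of an isolated solid ``i x i`` block (e.g. 33 for ``i = 7``): the
    boundary case of a maximal noise region. Gap counts strictly above it
    mark edge/interior pixels of larger objects.
    """
    i = int(i)
    if i < 1 or i % 2 == 0:
        raise ValueError(f"i must be a positive odd integer, got {i}")
    if rounding == "ceil":
        half = math.ceil(i / 2)
    elif rounding == "floor":
        half = i // 2
    else:
        raise ValueError(f"rounding must be 'ceil' or 'floor', got {rounding!r}")
    return i * i - half * half


def density_white(mask, cfg: LossConfig | None = None) -> np.ndarray:
    """White-point density: ``(CountWhite(N_i) + smooth) / (CountGapBlack + smooth)``.

    Strictly positive everywhere (the smoothing keeps numerator and
    denominator positive).
    """
    cfg = cfg or LossConfig()
    m = as_binary_mask(mask)
    gaps = gap_counts(m, cfg.i, cfg.j)
    return (count_white(m, cfg.i) + cfg.smooth) / (gaps.gap_black + cfg.smooth)


def density_black(mask, cfg: LossConfig | None = None) -> np.ndarray:
    """Black-point density: ``(CountBlack(N_i) + smooth) / (CountGapWhite + smooth)``."""
    cfg = cfg or LossConfig()
    m = as_binary_mask(mask)
    gaps = gap_counts(m, cfg.i, cfg.j)
    return (count_black(m, cfg.i) + cfg.smooth) / (gaps.gap_white + cfg.smooth)


def edge_masks(mask, cfg: LossConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Auxiliary masks excluding edges/interiors of large objects.

    Returns ``(mask_white, mask_black)``: binary grids that are 0 where the
    corresponding gap count *strictly* exceeds the edge threshold and 1
    otherwise.  Strict inequality keeps the corner of an isolated ``i x i``
    block (whose gap_white equals the threshold exactly) in the density
    computation.
    """
    cfg = cfg or LossConfig()
    m = as_binary_mask(mask)
    thr = edge_threshold(cfg.i, cfg.threshold_rounding)
    gaps = gap_counts(m, cfg.i, cfg.j)
    mask_white = (gaps.gap_white <= thr).astype(np.int64)
    mask_black = (gaps.gap_black <= thr).astype(np.int64)
    return mask_white, mask_black


def density_map(pred, cfg: LossConfig | None = None) -> np.ndarray:
    """Per-pixel masked density of the binarized prediction.

    Let ``R = binarize(pred)``. The map is::

        R * DensityWhite(R) * MaskWhite + (1 - R) * DensityBlack(R) * MaskBlack

    so each pixel reports the density of its own colour, zeroed wherever the
    edge mask excludes it.  Nonnegative everywhere; exactly zero wherever the
    selected branch's mask is zero.
    """
    cfg = cfg or LossConfig()
    r = binarize(clamp_probabilities(pred))
    mask_white, mask_black = edge_masks(r, cfg)
    dw = density_white(r, cfg)
    db = density_black(r, cfg)
    return r * dw * mask_white + (1 - r) * db * mask_black


def outlier_loss_map(pred, label, cfg: LossConfig | None = None) -> np.ndarray:
    """Per-pixel outlier-region loss: ``BCE(pred, label) - density_map(pred)``.

    The density enters with a negative sign because point density is
    inversely related to the loss a pixel should receive: low-density
    (likely-noise) pixels keep a comparatively high loss.
    """
    cfg = cfg or LossConfig()
    pred = clamp_probabilities(pred)
    lab = as_binary_mask(label)
    if pred.shape != lab.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs label {lab.shape}")
    return bce_map(pred, lab) - density_map(pred, cfg)


def outlier_loss(pred, label, cfg: LossConfig | None = None, reduction: str | None = None) -> float:
    """Scalar outlier loss: mean or sum of :func:`outlier_loss_map`."""
    cfg = cfg or LossConfig()
    reduction = reduction or cfg.reduction
    lmap = outlier_loss_map(pred, label, cfg)
    if reduction == "mean":
        return float(lmap.mean())
    if reduction == "sum":
        return float(lmap.sum())
    raise ValueError(f"reduction must be 'mean' or 'sum', got {reduction!r}")
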