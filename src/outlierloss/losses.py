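"""Binary cross-entropy, Dice loss, and the weighted composite loss."""

from __future__ import annotations

import numpy as np

from .config import EPS, LossConfig

__all__ = ["bce_map", "dice_loss", "combined_loss", "reduce_map"]


def _coerce_pair(pred, label) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=np.float64)
    y = np.asarray(label, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs label {y.shape}")
    return p, y


def bce_map(pred, label) -> np.ndarray:
    """Per-pixel binary cross-entropy ``-(Y log X + (1-Y) log(1-X))``.

    Predictions are clamped to ``[EPS, 1 - EPS]`` so the map is finite and
    nonnegative everywhere. Natural logarithm.
    """
    p, y = _coerce_pair(pred, label)
    p = np.clip(p, EPS, 1.0 - EPS)
    return -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


def dice_loss(pred, label) -> float:
    """Smoothed Dice loss ``1 - (2 sum(XY) + 1) / (sum(X) + sum(Y) + 1)``.

    Uses the soft intersection ``sum(X * Y)`` so probability masks are
    accepted; the ``+1`` smoothing makes the empty-vs-empty case 0. Values
    lie in ``[0, 1)``.
    """
    p, y = _coerce_pair(pred, label)
    inter = float((p * y).sum())
    return 1.0 - (2.0 * inter + 1.0) / (float(p.sum()) + float(y.sum()) + 1.0)


def reduce_map(loss_map: np.ndarray, reduction: str = "mean") -> float:
    """Reduce a per-pixel loss map to a scalar by mean or sum."""
    if reduction == "mean":
        return float(np.mean(loss_map))
    if reduction == "sum":
        return float(np.sum(loss_map))
    raise ValueError(f"reduction must be 'mean' or 'sum', got {reduction!r}")


def combined_loss(pred, label, cfg: LossConfig | None = None) -> float:
    """Weighted fusion ``alpha*BCE + beta*Dice + gamma*L_outlier``.

    The per-pixel components (BCE, outlier) are reduced to scalars with
    ``cfg.reduction`` before weighting, since Dice is already a scalar —
    the only well-typed composition of the three.
    """
    from .outlier import outlier_loss  # deferred: outlier imports bce_map

    cfg = cfg or LossConfig()
    total = 0.0
    if cfg.alpha != 0:
        total += cfg.alpha * reduce_map(bce_map(pred, label), cfg.reduction)
    if cfg.beta != 0:
        total += cfg.beta * dice_loss(pred, label)
    if cfg.gamma != 0:
        total += cfg.gamma * outlier_loss(pred, label, cfg)
    return total
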