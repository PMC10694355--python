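"""Hyperparameter container for the loss family."""

from __future__ import annotations

from dataclasses import dataclass

#: Clamping epsilon applied to probability masks before any logarithm.
EPS = 1e-7

_REDUCTIONS = ("mean", "sum")
_ROUNDINGS = ("ceil", "floor")


@dataclass(frozen=True)
class LossConfig:
    """Hyperparameters of the outlier-region and composite losses.

    Parameters
    ----------
    i : int
        Odd inner window size; a connected foreground blob whose bounding box
        fits within ``i x i`` is treated as a probable noise region.
        Default 7 (the size below which real-data regions are almost surely
        segmentation errors).
    j : int
        Odd outer window size delimiting the gap region used for densities
        and edge exclusion; must exceed ``i``. Default 21.
    smooth : float
        Positive smoothing constant added to numerator and denominator of the
        densities to avoid division by zero. Default 1.0.
    alpha, beta, gamma : float
        Nonnegative weights of the BCE, Dice, and outlier terms in the
        composite loss. Defaults 1, 1, 1.
    reduction : {"mean", "sum"}
        How per-pixel loss maps are reduced to scalars.
    threshold_rounding : {"ceil", "floor"}
        Rounding of ``i/2`` in the edge-exclusion threshold
        ``i**2 - round(i/2)**2``. ``"ceil"`` (default) reproduces the corner
        geometry of an isolated ``i x i`` block; ``"floor"`` is provided as a
        variant.
    """

    i: int = 7
    j: int = 21
    smooth: float = 1.0
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    reduction: str = "mean"
    threshold_rounding: str = "ceil"

    def __post_init__(self) -> None:
        if self.i < 1 or self.i % 2 == 0:
            raise ValueError(f"i must be a positive odd integer, got {self.i}")
        if self.j % 2 == 0 or self.j <= self.i:
            raise ValueError(f"j must be odd and exceed i, got i={self.i}, j={self.j}")
        if not self.smooth > 0:
            raise ValueError(f"smooth must be positive, got {self.smooth}")
        for name in ("alpha", "beta", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.reduction not in _REDUCTIONS:
            raise ValueError(f"reduction must be one of {_REDUCTIONS}, got {self.reduction!r}")
        if self.threshold_rounding not in _ROUNDINGS:
            raise ValueError(
                f"threshold_rounding must be one of {_ROUNDINGS}, got {self.threshold_rounding!r}"
            )
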