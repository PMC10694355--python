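"""Per-pixel white/black counting in square sliding windows.

The density-based outlier loss is built on two local statistics of a binary
mask: the number of foreground ("white") pixels in the ``k x k`` neighborhood
``N_k`` centred on each pixel, and the counts in the *gap* (interval) region
between an inner window ``N_i`` and an outer window ``N_j``.  Pixels outside
the image are counted as black (background), which matches the black MRI
background and preserves the identity ``count_white + count_black == k**2``
at every pixel.

The fast path uses an integral image (summed-area table), which is exact in
integer arithmetic.  :func:`brute_force_window_count` is the independent,
loop-based oracle used by the test suite; it is the contract of record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GapCounts",
    "as_binary_mask",
    "count_white",
    "count_black",
    "gap_counts",
    "brute_force_window_count",
]


def as_binary_mask(mask) -> np.ndarray:
    """Validate and return ``mask`` as a 2-D integer {0,1} array.

    Accepts bools, integers, or floats whose values are exactly 0 or 1.
    """
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D mask, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("mask must have at least one pixel")
    if arr.dtype == bool:
        return arr.astype(np.int64)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("binary mask entries must be exactly 0 or 1")
    return arr.astype(np.int64)


def _check_window(k: int) -> int:
    k = int(k)
    if k < 1 or k % 2 == 0:
        raise ValueError(f"window size must be a positive odd integer, got {k}")
    return k


def count_white(mask, k: int) -> np.ndarray:
    """Number of white pixels in the ``k x k`` window centred on each pixel.

    Out-of-image pixels count as black, so values lie in ``[0, k**2]``.

    Parameters
    ----------
    mask : array_like
        2-D binary mask (1 = white/foreground).
    k : int
        Odd window size.

    Returns
    -------
    numpy.ndarray
        ``(H, W)`` integer grid of counts.
    """
    k = _check_window(k)
    m = as_binary_mask(mask)
    h, w = m.shape
    r = k // 2
    # integral image with a zero border: ii[y, x] = sum of m[:y, :x]
    ii = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(m, axis=0, out=ii[1:, 1:])
    np.cumsum(ii[1:, 1:], axis=1, out=ii[1:, 1:])
    y0 = np.clip(np.arange(h) - r, 0, h)
    y1 = np.clip(np.arange(h) + r + 1, 0, h)
    x0 = np.clip(np.arange(w) - r, 0, w)
    x1 = np.clip(np.arange(w) + r + 1, 0, w)
    return (
        ii[y1[:, None], x1[None, :]]
        - ii[y0[:, None], x1[None, :]]
        - ii[y1[:, None], x0[None, :]]
        + ii[y0[:, None], x0[None, :]]
    )


def count_black(mask, k: int) -> np.ndarray:
    """Number of black pixels in ``N_k``, i.e. ``k**2 - count_white``."""
    k = _check_window(k)
    return k * k - count_white(mask, k)


@dataclass(frozen=True)
class GapCounts:
    """White/black counts in the annulus between ``N_j`` and ``N_i``.

    With black padding, ``gap_white + gap_black == j**2 - i**2`` at every
    pixel and both grids are nonnegative.
    """

    gap_white: np.ndarray
    gap_black: np.ndarray
    inner: int
    outer: int


def gap_counts(mask, i: int, j: int) -> GapCounts:
    """Counts in the gap (interval) region between windows ``N_j`` and ``N_i``.

    Parameters
    ----------
    mask : array_like
        2-D binary mask.
    i, j : int
        Odd inner and outer window sizes, ``j > i``.
    """
    i = _check_window(i)
    j = _check_window(j)
    if j <= i:
        raise ValueError(f"outer window must exceed inner window, got i={i}, j={j}")
    gw = count_white(mask, j) - count_white(mask, i)
    gb = count_black(mask, j) - count_black(mask, i)
    return GapCounts(gap_white=gw, gap_black=gb, inner=i, outer=j)


def brute_force_window_count(mask, k: int) -> np.ndarray:
    """Reference implementation of :func:`count_white` by explicit loops.

    Iterates over every pixel and every window offset; used only as a test
    oracle. Out-of-image offsets count as black.
    """
    k = _check_window(k)
    m = as_binary_mask(mask)
    h, w = m.shape
    r = k // 2
    out = np.zeros((h, w), dtype=np.int64)
    for y in range(h):
        for x in range(w):
            total = 0
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w:
                        total += m[yy, xx]
            out[y, x] = total
    return out
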