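"""Reading and writing masks and grayscale map renderings.

Masks travel as single-channel 8- or 16-bit PNG or TIFF.  Binary masks map
any positive pixel to 1; probability masks are scaled by the dtype maximum
into ``[0, 1]`` and clamped into the open interval.  Rendered loss/density
maps are min-max normalised to 0-255 with a JSON sidecar recording the
original range, so the values are recoverable.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .config import EPS

__all__ = ["read_mask", "write_mask", "render_grayscale"]


def _load_single_channel(path) -> np.ndarray:
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - message depends on backend
        raise ValueError(f"could not read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel image, got shape {arr.shape}"
        )
    return arr


def read_mask(path, kind: str = "binary") -> np.ndarray:
    """Read a mask image.

    Parameters
    ----------
    path : str or Path
        Single-channel 8- or 16-bit PNG or TIFF.
    kind : {"binary", "probability"}
        ``binary``: pixels > 0 become 1. ``probability``: values are divided
        by the dtype maximum and clamped to ``[EPS, 1 - EPS]``.
    """
    arr = _load_single_channel(path)
    if kind == "binary":
        return (arr > 0).astype(np.int64)
    if kind == "probability":
        if np.issubdtype(arr.dtype, np.integer):
            scale = float(np.iinfo(arr.dtype).max)
            vals = arr.astype(np.float64) / scale
        else:
            vals = arr.astype(np.float64)
        return np.clip(vals, EPS, 1.0 - EPS)
    raise ValueError(f"kind must be 'binary' or 'probability', got {kind!r}")


def write_mask(mask, path) -> None:
    """Write a binary or probability mask as an 8-bit grayscale image."""
    arr = np.asarray(mask, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D mask, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("mask values must lie in [0, 1]")
    iio.imwrite(Path(path), np.round(arr * 255).astype(np.uint8))


def render_grayscale(grid, path, sidecar: bool = True) -> Path:
    """Render a loss or density map as a min-max normalised 8-bit PNG.

    Lighter shades mean higher values.  A constant grid renders as uniform
    mid-gray (128).  A JSON sidecar ``<path>.json`` records the original
    ``min`` and ``max`` so pixel values can be mapped back.
    """
    arr = np.asarray(grid, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grid, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError("grid contains non-finite values; cannot render")
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:
        img = np.round((arr - lo) / (hi - lo) * 255).astype(np.uint8)
    else:
        img = np.full(arr.shape, 128, dtype=np.uint8)
    path = Path(path)
    iio.imwrite(path, img)
    if sidecar:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"min": lo, "max": hi})
        )
    return path
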