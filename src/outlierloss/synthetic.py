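"""Synthetic fixtures: every input the tests, docs and demos need.

Nothing in the package requires downloading real data.  Three generators
cover the study conditions:

* :func:`figure9_image` — a deterministic 100x100 binary test image with
  five white regions: four noise-sized blobs of different character (a solid
  7x7 block at the exclusion boundary, a lone pixel, two small irregular
  shapes) and one solid 28x28 block standing in for a normal segmented
  object. Regions are separated by more than 21 pixels so their 21x21
  neighborhoods never interact.
* :func:`noisy_prediction` — a probability mask derived from a clean label
  with planted small white blobs on the background, emulating the noisy
  outputs a segmentation network produces.
* :func:`synthetic_lgg_case` — an MRI-like stack of slices with an
  ellipsoidal bright "tumour" (largest cross-section at central slices) and
  a matching patient attribute table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attributes import DEFAULT_SCHEMA, AttributeSchema
from .config import EPS
from .windows import as_binary_mask

__all__ = ["figure9_image", "noisy_prediction", "synthetic_lgg_case", "SyntheticCase"]


def figure9_image() -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Deterministic 100x100 five-region binary test image.

    Returns
    -------
    mask : numpy.ndarray
        100x100 {0,1} image.
    regions : dict
        Maps ``"area1"`` .. ``"area5"`` to boolean pixel masks:

        - ``area1`` — solid 7x7 block (the edge-exclusion boundary case);
        - ``area2`` — a single isolated pixel (the lowest-density case);
        - ``area3`` — an L-shaped blob, bounding box 5x5;
        - ``area4`` — a diagonal staircase, bounding box 5x6;
        - ``area5`` — solid 28x28 block (a normal segmentation region).
    """
    mask = np.zeros((100, 100), dtype=np.int64)
    regions: dict[str, np.ndarray] = {}

    def paint(name: str, painter) -> None:
        sel = np.zeros_like(mask, dtype=bool)
        painter(sel)
        mask[sel] = 1
        regions[name] = sel

    def block(sel, r, c, h, w):
        sel[r : r + h, c : c + w] = True

    paint("area1", lambda s: block(s, 5, 5, 7, 7))
    paint("area2", lambda s: block(s, 8, 55, 1, 1))

    def l_shape(s):
        s[41:46, 6] = True
        s[45, 6:11] = True

    paint("area3", l_shape)

    def staircase(s):
        for t in range(5):
            s[40 + t, 45 + t] = True
            s[40 + t, 46 + t] = True

    paint("area4", staircase)
    paint("area5", lambda s: block(s, 70, 60, 28, 28))
    return mask, regions


def noisy_prediction(
    label,
    n_noise: int = 5,
    max_noise_size: int = 7,
    flip_prob: float = 0.0,
    seed: int = 0,
    max_tries: int = 200,
) -> tuple[np.ndarray, list[dict]]:
    """Soften a label into (0,1) and plant small white noise blobs.

    Foreground pixels get probabilities in (0.8, 1) and background pixels in
    (0, 0.2), so with ``n_noise=0`` and ``flip_prob=0`` binarizing the output
    recovers the label exactly.  Each planted blob is a solid rectangle with
    both sides <= ``max_noise_size``, placed on background at Chebyshev
    distance >= 2 from all existing foreground and earlier blobs, so every
    blob binarizes to its own connected component.  ``flip_prob`` flips each
    remaining pixel's side independently.

    Returns the probability mask and a list of blob annotations
    ``{"row", "col", "height", "width"}``.

    Raises
    ------
    RuntimeError
        If a blob cannot be placed after ``max_tries`` attempts.
    """
    lab = as_binary_mask(label)
    if n_noise < 0 or max_noise_size < 1 or not 0 <= flip_prob <= 1:
        raise ValueError("invalid noise parameters")
    h, w = lab.shape
    rng = np.random.default_rng(seed)
    binary = lab.copy()

    # forbid placement adjacent (8-conn) to any current foreground
    def forbidden() -> np.ndarray:
        occ = binary.astype(bool)
        grown = occ.copy()
        grown[:-1, :] |= occ[1:, :]
        grown[1:, :] |= occ[:-1, :]
        grown[:, :-1] |= occ[:, 1:]
        grown[:, 1:] |= occ[:, :-1]
        grown[:-1, :-1] |= occ[1:, 1:]
        grown[1:, 1:] |= occ[:-1, :-1]
        grown[:-1, 1:] |= occ[1:, :-1]
        grown[1:, :-1] |= occ[:-1, 1:]
        return grown

    blobs = []
    for _ in range(n_noise):
        placed = False
        for _ in range(max_tries):
            bh = int(rng.integers(1, max_noise_size + 1))
            bw = int(rng.integers(1, max_noise_size + 1))
            if h - bh < 0 or w - bw < 0:
                continue
            r = int(rng.integers(0, h - bh + 1))
            c = int(rng.integers(0, w - bw + 1))
            if forbidden()[r : r + bh, c : c + bw].any():
                continue
            binary[r : r + bh, c : c + bw] = 1
            blobs.append({"row": r, "col": c, "height": bh, "width": bw})
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place noise blob after {max_tries} attempts"
            )

    if flip_prob > 0:
        flips = rng.random(binary.shape) < flip_prob
        binary = np.where(flips, 1 - binary, binary)

    low = rng.uniform(EPS, 0.2, size=binary.shape)
    high = rng.uniform(0.8, 1.0 - EPS, size=binary.shape)
    prob = np.where(binary == 1, high, low)
    return prob, blobs


@dataclass(frozen=True)
class SyntheticCase:
    """One synthetic patient: image stack, masks, and attribute table."""

    images: np.ndarray  # (n_slices, H, W) grayscale in [0, 1]
    masks: np.ndarray  # (n_slices, H, W) {0,1}
    attributes: pd.DataFrame  # one row per slice, schema columns + position


def synthetic_lgg_case(
    seed: int = 0,
    H: int = 256,
    W: int = 256,
    n_slices: int = 30,
    schema: AttributeSchema = DEFAULT_SCHEMA,
) -> SyntheticCase:
    """Generate an MRI-like slice stack with an ellipsoidal bright tumour.

    The tumour is an axis-aligned ellipsoid centred mid-stack, so central
    slices carry larger mask cross-sections than edge slices — the property
    that makes slice position informative for segmentation.  Slice counts of
    real scans range from a few dozen to under a hundred; the default of 30
    sits in that range.  The attribute table has one row per slice with the
    patient's cluster assignments (constant across slices), the slice index,
    and the slice count.
    """
    if H % 16 or W % 16:
        raise ValueError(f"H and W must be divisible by 16, got {H}x{W}")
    if n_slices < 1:
        raise ValueError(f"n_slices must be >= 1, got {n_slices}")
    rng = np.random.default_rng(seed)

    cy = H / 2 + rng.uniform(-H / 16, H / 16)
    cx = W / 2 + rng.uniform(-W / 16, W / 16)
    cz = (n_slices - 1) / 2
    ry = rng.uniform(H / 10, H / 6)
    rx = rng.uniform(W / 10, W / 6)
    rz = max(1.0, 0.8 * n_slices / 2)

    yy, xx = np.mgrid[0:H, 0:W]
    brain = ((yy - H / 2) / (0.45 * H)) ** 2 + ((xx - W / 2) / (0.42 * W)) ** 2 <= 1.0

    images = np.zeros((n_slices, H, W))
    masks = np.zeros((n_slices, H, W), dtype=np.int64)
    for z in range(n_slices):
        scale_sq = 1.0 - ((z - cz) / rz) ** 2
        img = np.where(brain, 0.35, 0.02) + rng.normal(0.0, 0.02, size=(H, W))
        if scale_sq > 0:
            tumour = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= scale_sq
            masks[z][tumour] = 1
            img[tumour] += 0.45
        images[z] = np.clip(img, 0.0, 1.0)

    clusters = {
        name: int(rng.integers(1, n_cat + 1)) for name, n_cat in schema.columns
    }
    rows = []
    for z in range(n_slices):
        rows.append(
            {
                "Patient": f"SYN_{seed:04d}",
                **clusters,
                "slice_index": z,
                "slice_count": n_slices,
            }
        )
    return SyntheticCase(images=images, masks=masks, attributes=pd.DataFrame(rows))
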