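"""Overlap metrics (DSC, IoU) and connected-region size analysis.

The region analysis mirrors the QC step used to choose the inner window
size ``i``: count how many connected foreground components of the ground
truth (or a prediction) are small enough to fit in an ``i x i`` box and are
therefore likely noise.
"""

from __future__ import annotations

from dataclasses import dataclass

from skimage import measure

from .windows import as_binary_mask

__all__ = [
    "Region",
    "dice_coefficient",
    "iou",
    "find_regions",
    "count_small_regions",
    "region_report",
]


def _overlap_counts(a, b) -> tuple[int, int, int]:
    ma = as_binary_mask(a)
    mb = as_binary_mask(b)
    if ma.shape != mb.shape:
        raise ValueError(f"shape mismatch: {ma.shape} vs {mb.shape}")
    inter = int((ma & mb).sum())
    return inter, int(ma.sum()), int(mb.sum())


def dice_coefficient(a, b) -> float:
    """Dice similarity coefficient ``2|A & B| / (|A| + |B|)``.

    Two empty masks agree perfectly and score 1; empty vs nonempty scores 0.
    """
    inter, na, nb = _overlap_counts(a, b)
    if na + nb == 0:
        return 1.0
    return 2.0 * inter / (na + nb)


def iou(a, b) -> float:
    """Intersection over union ``|A & B| / (A | B)``; empty-vs-empty is 1."""
    inter, na, nb = _overlap_counts(a, b)
    union = na + nb - inter
    if union == 0:
        return 1.0
    return inter / union


@dataclass(frozen=True)
class Region:
    """One connected foreground component."""

    id: int
    area: int
    bbox_h: int
    bbox_w: int
    centroid: tuple[float, float]


def find_regions(mask, connectivity: int = 8) -> list[Region]:
    """Connected foreground components with area, bounding box and centroid.

    Parameters
    ----------
    mask : array_like
        2-D binary mask.
    connectivity : {4, 8}
        Pixel adjacency; 8 (default) joins diagonal neighbours.

    Components are ordered row-major by their first (topmost-then-leftmost)
    pixel, so the ordering is deterministic.
    """
    m = as_binary_mask(mask)
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    labels = measure.label(m, connectivity=1 if connectivity == 4 else 2)
    props = measure.regionprops(labels)
    # skimage labels in raster-scan order already; sort by first pixel to pin it
    props.sort(key=lambda p: min(map(tuple, p.coords)))
    regions = []
    for idx, p in enumerate(props, start=1):
        r0, c0, r1, c1 = p.bbox
        regions.append(
            Region(
                id=idx,
                area=int(p.area),
                bbox_h=r1 - r0,
                bbox_w=c1 - c0,
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
            )
        )
    return regions


def _is_small(region: Region, k: int, predicate: str) -> bool:
    if predicate == "fits_within":
        return region.bbox_h <= k and region.bbox_w <= k
    if predicate == "strictly_smaller":
        return region.bbox_h < k and region.bbox_w < k
    raise ValueError(
        f"predicate must be 'fits_within' or 'strictly_smaller', got {predicate!r}"
    )


def count_small_regions(
    masks,
    k: int = 7,
    predicate: str = "fits_within",
    connectivity: int = 8,
) -> tuple[int, list[dict]]:
    """Count connected components whose bounding box is small against ``k x k``.

    Parameters
    ----------
    masks : iterable of array_like
        Sequence of binary masks (e.g. all ground-truth slices of a dataset).
    k : int
        Box side to compare against.
    predicate : {"fits_within", "strictly_smaller"}
        ``fits_within``: both bbox sides <= k (default; treats an exactly
        ``k x k`` block as noise-sized). ``strictly_smaller``: both sides < k.

    Returns
    -------
    total : int
        Number of small components over all masks.
    reports : list of dict
        Per-mask report with component inventory and both small-region counts.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    _is_small(Region(0, 1, 1, 1, (0.0, 0.0)), k, predicate)  # validate early
    total = 0
    reports = []
    for idx, mask in enumerate(masks):
        rep = region_report(mask, mask_id=str(idx), k=k, connectivity=connectivity)
        key = "n_small_fits_within" if predicate == "fits_within" else "n_small_strict"
        total += rep[key]
        reports.append(rep)
    return total, reports


def region_report(mask, mask_id: str = "", k: int = 7, connectivity: int = 8) -> dict:
    """JSON-ready component inventory for one mask, with both small-counts."""
    regions = find_regions(mask, connectivity=connectivity)
    return {
        "mask_id": mask_id,
        "n_components": len(regions),
        "components": [
            {"area": r.area, "bbox_h": r.bbox_h, "bbox_w": r.bbox_w} for r in regions
        ],
        "n_small_fits_within": sum(_is_small(r, k, "fits_within") for r in regions),
        "n_small_strict": sum(_is_small(r, k, "strictly_smaller") for r in regions),
    }
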