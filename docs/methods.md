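# Methods

## Model

The outlier-region loss treats segmentation noise as a *density* anomaly.
Given a post-sigmoid prediction `X ∈ (0,1)` it binarizes to `R` and, for
each pixel, compares the same-coloured mass in the inner window `N_i` with
the opposite-coloured mass in the annulus between `N_j` and `N_i`. Small
isolated blobs score a low density; pixels of large objects are removed
from the computation by an edge-exclusion mask so that only noise-sized
structures contribute. The density map is subtracted from the per-pixel
binary cross-entropy, and the composite training loss weights BCE, Dice,
and the outlier term as `α·BCE + β·Dice + γ·L_outlier`.

Assumptions: 2-D single-channel masks; binary foreground/background; a
black (zero) background, which motivates counting out-of-image pixels as
black; noise blobs are isolated — the method characterises a blob by its
*local* neighbourhood, so two noise blobs closer than `j` pixels influence
each other's densities.

## Parameters

| name | default | units | meaning |
|---|---|---|---|
| `i` | 7 | px (odd) | inner window; blobs with bounding box ≤ `i×i` are noise-sized |
| `j` | 21 | px (odd, > i) | outer window bounding the gap annulus |
| `smooth` | 1.0 | — | additive smoothing in both density ratios; 1.0 matches the `+1` smoothing of the Dice loss |
| `alpha, beta, gamma` | 1, 1, 1 | — | weights of BCE / Dice / outlier terms |
| `reduction` | `mean` | — | map→scalar reduction; `sum` also supported (`sum = H·W·mean`) |
| `threshold_rounding` | `ceil` | — | rounding of `i/2` in the threshold `i² − round(i/2)²` |

`i=7, j=21` reflect the dataset QC observation that foreground components
fitting within 7×7 are, with very high probability, segmentation errors.
The threshold uses round-up by default because only `⌈7/2⌉ = 4` reproduces
the corner geometry of an isolated 7×7 block (`49 − 16 = 33`); the floor
variant (`49 − 9 = 40`) is exposed for experimentation.

## Numerical choices

- **Clamping.** Probability masks are clamped to `[1e-7, 1 − 1e-7]` before
  any logarithm; BCE is therefore finite and ≤ ~16.1 per pixel.
- **Binarization tie-break.** `value ≥ 0.5 → white`.
- **Boundary handling.** Out-of-image pixels count as black. This preserves
  `count_white + count_black = k²` everywhere but breaks the white/black
  inversion symmetry within `k//2` of the border; the duality tests compare
  interior pixels only (margin `j//2 = 10` for densities).
- **Strict threshold inequality.** Masks zero the density only where the
  gap count strictly exceeds the threshold, so the documented boundary case
  (corner of an isolated `i×i` block, gap count exactly 33) is retained.
- **Mask pairing.** One auxiliary mask thresholds `CountGapWhite` (applied
  to the white branch) and one thresholds `CountGapBlack` (black branch) —
  the only pairing that makes the density-map expression well-formed.
- **Composite typing.** BCE and the outlier loss are per-pixel maps while
  Dice is a scalar; each component is reduced to a scalar first, then
  weighted.
- **Counting.** The fast path is an exact integer integral image; a
  per-pixel/per-offset brute-force loop is kept as the independent oracle
  and the contract of record. Rectangular images are supported — nothing in
  the math requires square inputs. Even window sizes are rejected rather
  than silently shifted.
- **Differentiability.** Counts, masks and `Round` are piecewise-constant
  in the prediction, so the density term carries no gradient; in a training
  framework it acts as an additive per-pixel penalty computed on the
  binarized prediction, with gradients flowing through BCE only.

## Attribute encoding

The multimodal data-prep contract: categorical genomic cluster columns are
one-hot encoded in a fixed schema order (missing values become an all-zero
block), the normalised slice position `slice_index/(slice_count−1)` (0 for
single-slice stacks) is appended to give a sequence of length `N`, and a
seeded one-hidden-layer feed-forward map (tanh, linear output, weights from
`numpy.random.default_rng(seed)`) produces `3·(H/16)·(W/16)` values
reshaped channel-major to `3 × H/16 × W/16` — the spatial grid of a typical
image encoder's high-level features. Depth/width and the position encoding
are configurable; the map is untrained, reproducible plumbing whose only
contract is shape and determinism, not a trained model.

## Synthetic data

- **Five-region test image** (`figure9_image`): 100×100, deterministic.
  Four noise-sized regions of different character — a solid 7×7 block
  (exactly at the exclusion boundary), a lone pixel (lowest density), an
  L-shape, a diagonal staircase — plus a solid 28×28 normal region. All
  regions are mutually ≥ 21 px apart (Chebyshev), so no pixel's `N_21`
  touches another region. The lone-pixel region is a single pixel so the
  image has exactly five connected components.
- **Noisy predictions** (`noisy_prediction`): a clean label softened into
  (0, 0.2) / (0.8, 1) bands plus `n` planted solid rectangles (sides ≤ the
  requested size) on background, each ≥ 2 px (Chebyshev) from all other
  foreground, so each binarizes to its own component and size-based QC
  recovers exactly `n` extra regions. Optional independent pixel flips.
- **MRI-like cases** (`synthetic_lgg_case`): an ellipsoidal bright tumour
  inside an elliptical "brain" with Gaussian noise; central slices have the
  largest mask cross-sections. Default 30 slices per patient, in the range
  typical of clinical stacks (a few dozen). The attribute table carries
  cluster assignments constant across a patient's slices.

What these fixtures do **not** emulate: real MRI texture and intensity
inhomogeneity, anatomically shaped tumours, inter-rater label noise, or the
class imbalance statistics of a real dataset. Passing tests demonstrate the
correctness of the loss computation and the QC machinery, not segmentation
performance on clinical data; headline benchmark scores require training a
network on the real dataset and are out of scope here.

## Problem sizes

The test suite and the acceptance script run on 100×100 fixture images,
batches of 50–100 random 20×20–30×30 masks for the oracle and identity
checks, and 30-slice 128×128 synthetic stacks; these sizes exercise every
code path (borders, boundary cases, empty masks) while keeping the whole
suite in the seconds range.

## Known limitations

- The density term is computed on the binarized prediction only; a soft
  (un-rounded) variant is not provided.
- No 3-D neighbourhoods or multi-class density maps; masks are strictly
  2-D binary.
- Two noise blobs within `j` of each other raise each other's densities
  (and can push each other over the edge threshold); the fixtures keep
  regions separated to stay in the regime the method is designed for.
- Scheduling of the outlier-term weight `γ` over training (ramping it up
  once predictions stabilise) is left to callers.
- DSC/IoU between empty masks is defined as 1 (perfect agreement), empty
  vs non-empty as 0.
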