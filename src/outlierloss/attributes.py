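"""Attribute-encoder data preparation for multimodal MRI segmentation.

Tumour shape on FLAIR MRI correlates with genomic subtype, and slices from
the middle of a scan tend to carry larger tumour cross-sections than edge
slices.  A multimodal segmentation model can therefore fuse per-patient
genomic cluster assignments and the slice position with the image features.
This module implements the deterministic data-prep contract of that fusion:

1. one-hot encode the categorical genomic cluster columns,
2. append the normalised slice position to form a sequence of length ``N``,
3. map the sequence through a small seeded feed-forward network (an untrained
   stand-in for the learned MLP — its weights are reproducible plumbing, not
   a trained model), and
4. reshape channel-major to a ``3 x H/16 x W/16`` grid matching the image
   encoder's high-level feature resolution, so concatenation downstream is
   well-typed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AttributeSchema",
    "AttributeRecord",
    "one_hot_encode",
    "build_attribute_sequence",
    "attribute_features",
    "DEFAULT_SCHEMA",
]


@dataclass(frozen=True)
class AttributeSchema:
    """Ordered categorical columns: (name, n_categories) pairs.

    Categories are integer-coded starting at 1 (the convention of genomic
    cluster tables). Missing values encode as an all-zero block.
    """

    columns: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        for name, n_cat in self.columns:
            if n_cat < 2:
                raise ValueError(f"column {name!r} needs >= 2 categories, got {n_cat}")

    @property
    def encoded_length(self) -> int:
        return sum(n for _, n in self.columns)

    @property
    def sequence_length(self) -> int:
        """One-hot length plus one position slot."""
        return self.encoded_length + 1

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.columns)


#: Genomic cluster columns of the LGG-style patient table.
DEFAULT_SCHEMA = AttributeSchema(
    columns=(
        ("RNASeqCluster", 4),
        ("MethylationCluster", 5),
        ("miRNACluster", 4),
        ("CNCluster", 3),
    )
)


@dataclass(frozen=True)
class AttributeRecord:
    """One slice's worth of patient attributes.

    ``cluster_values`` maps column name to its 1-based category, or ``None``
    for missing. ``slice_index`` is 0-based and must be < ``slice_count``.
    """

    patient_id: str
    cluster_values: dict = field(default_factory=dict)
    slice_index: int = 0
    slice_count: int = 1

    def __post_init__(self) -> None:
        if self.slice_count < 1:
            raise ValueError(f"slice_count must be >= 1, got {self.slice_count}")
        if not 0 <= self.slice_index < self.slice_count:
            raise ValueError(
                f"slice_index {self.slice_index} out of range for {self.slice_count} slices"
            )


def one_hot_encode(record: AttributeRecord, schema: AttributeSchema = DEFAULT_SCHEMA) -> np.ndarray:
    """Concatenated one-hot blocks in schema order.

    Each non-missing column contributes exactly one 1 in its block; a missing
    value contributes an all-zero block.
    """
    blocks = []
    for name, n_cat in schema.columns:
        block = np.zeros(n_cat, dtype=np.float64)
        value = record.cluster_values.get(name)
        if value is not None:
            value = int(value)
            if not 1 <= value <= n_cat:
                raise ValueError(
                    f"column {name!r}: category {value} out of range 1..{n_cat}"
                )
            block[value - 1] = 1.0
        blocks.append(block)
    return np.concatenate(blocks)


def build_attribute_sequence(
    encoded: np.ndarray, slice_index: int, slice_count: int
) -> np.ndarray:
    """Append normalised slice position ``slice_index / (slice_count - 1)``.

    A single-slice stack gets position 0.0. The result has length
    ``len(encoded) + 1``.
    """
    if slice_count < 1:
        raise ValueError(f"slice_count must be >= 1, got {slice_count}")
    if not 0 <= slice_index < slice_count:
        raise ValueError(f"slice_index {slice_index} out of range for {slice_count} slices")
    position = 0.0 if slice_count == 1 else slice_index / (slice_count - 1)
    return np.concatenate([np.asarray(encoded, dtype=np.float64), [position]])


def attribute_features(
    sequence: np.ndarray,
    H: int,
    W: int,
    hidden_sizes: tuple[int, ...] = (64,),
    seed: int = 0,
) -> np.ndarray:
    """Map an attribute sequence to a ``3 x H/16 x W/16`` feature grid.

    The map is a seeded feed-forward network (affine layers with tanh between
    them, linear output) whose weights are drawn once from
    ``numpy.random.default_rng(seed)`` — deterministic, untrained plumbing
    whose only contract is shape and reproducibility. The output vector is
    reshaped channel-major (C order) to ``(3, H // 16, W // 16)``.
    """
    if H % 16 or W % 16:
        raise ValueError(f"H and W must be divisible by 16, got {H}x{W}")
    x = np.asarray(sequence, dtype=np.float64).ravel()
    out_size = 3 * (H // 16) * (W // 16)
    rng = np.random.default_rng(seed)
    sizes = (x.size, *hidden_sizes, out_size)
    n_layers = len(sizes) - 1
    for layer, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        w = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_out, n_in))
        b = rng.normal(0.0, 0.1, size=n_out)
        x = w @ x + b
        if layer < n_layers - 1:
            x = np.tanh(x)
    return x.reshape(3, H // 16, W // 16)
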