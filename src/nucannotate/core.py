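"""Core containers shared across the annotation pipeline.

Conventions used everywhere in this package:

* images and label maps are 2-D ``numpy`` arrays in (row, col) order,
  0-based; bounding boxes are half-open ``[r0, r1) x [c0, c1)``;
* a *label map* is an integer array where 0 is background and each
  positive value ``k`` marks the pixels of instance ``k``; label identity
  is not semantic — operations may renumber, and all comparisons are
  permutation-invariant;
* object tables are :class:`pandas.DataFrame` objects with the columns in
  :data:`OBJECT_TABLE_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Column order of every on-disk and in-memory object table.
OBJECT_TABLE_COLUMNS = [
    "id",
    "area_px",
    "bbox_r0",
    "bbox_c0",
    "bbox_r1",
    "bbox_c1",
    "centroid_r",
    "centroid_c",
    "kept",
    "class",
]

VALID_BIT_DEPTHS = (8, 16)


def dtype_for_depth(bit_depth: int) -> np.dtype:
    if bit_depth == 8:
        return np.dtype(np.uint8)
    if bit_depth == 16:
        return np.dtype(np.uint16)
    raise ValueError(f"unsupported bit depth {bit_depth!r}; expected one of {VALID_BIT_DEPTHS}")


def max_for_depth(bit_depth: int) -> int:
    return int(2**bit_depth - 1)


@dataclass
class IntensityImage:
    """A 2-D grayscale image with a declared bit depth (8 or 16)."""

    pixels: np.ndarray
    bit_depth: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {self.pixels.shape}")
        if self.bit_depth not in VALID_BIT_DEPTHS:
            raise ValueError(f"bit_depth must be one of {VALID_BIT_DEPTHS}, got {self.bit_depth}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def max_value(self) -> int:
        return max_for_depth(self.bit_depth)

    def astype_native(self) -> np.ndarray:
        """Pixels cast to the canonical unsigned dtype of the bit depth."""
        return self.pixels.astype(dtype_for_depth(self.bit_depth), copy=False)

    def copy(self) -> "IntensityImage":
        return IntensityImage(self.pixels.copy(), self.bit_depth)


def as_label_map(arr: np.ndarray) -> np.ndarray:
    """Validate and canonicalize a label map to a 2-D non-negative int array."""
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"label map must be 2-D, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"label map must have an integer dtype, got {arr.dtype}")
    if arr.size and arr.min() < 0:
        raise ValueError("label map contains negative labels")
    return arr


def labels_of(label_map: np.ndarray) -> np.ndarray:
    """Sorted positive labels present in a label map."""
    vals = np.unique(np.asarray(label_map))
    return vals[vals > 0]
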