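"""Pixel-value conversion and tiling ahead of thresholding or network export.

Depth conversion supports min-max scaling and percentile scaling (clip at
the (p_lo, p_hi) intensity percentiles before mapping to the full target
range); both are monotone in the input intensities. Tiling cuts an image
into fixed-size tiles with a configurable overlap, anchoring the last row
and column of tiles to the image edge so no pixels are fabricated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import IntensityImage, dtype_for_depth, max_for_depth


@dataclass(frozen=True)
class PreprocessConfig:
    """Conversion and tiling settings.

    ``normalize`` is one of ``"none"``, ``"minmax"`` or ``"percentile"``
    (with ``percentiles=(p_lo, p_hi)``); ``target_bit_depth`` may be 8,
    16, or ``"keep"``.
    """

    target_bit_depth: int | str = 8
    normalize: str = "percentile"
    percentiles: tuple[float, float] = (1.0, 99.0)
    tile_size: int | None = None
    tile_overlap: int = 0

    def __post_init__(self) -> None:
        if self.normalize not in ("none", "minmax", "percentile"):
            raise ValueError(f"unknown normalize mode {self.normalize!r}")
        if self.target_bit_depth not in (8, 16, "keep"):
            raise ValueError("target_bit_depth must be 8, 16 or 'keep'")
        lo, hi = self.percentiles
        if not 0 <= lo < hi <= 100:
            raise ValueError("percentiles must satisfy 0 <= lo < hi <= 100")
        if self.tile_size is not None:
            if self.tile_size < 64:
                raise ValueError("tile_size must be >= 64")
            if self.tile_size < 2 * self.tile_overlap:
                raise ValueError("tile_size must be >= 2 * tile_overlap")
        if self.tile_overlap < 0:
            raise ValueError("tile_overlap must be >= 0")


def convert_depth(image: IntensityImage, config: PreprocessConfig) -> IntensityImage:
    """Rescale intensities to the target bit depth.

    ``minmax`` maps [min, max] onto the full target range; ``percentile``
    clips at the configured percentiles first. A constant image maps to
    all zeros by convention. The mapping is monotone non-decreasing.
    """
    depth = image.bit_depth if config.target_bit_depth == "keep" else int(config.target_bit_depth)
    vmax_out = max_for_depth(depth)
    pixels = np.asarray(image.pixels, dtype=np.float64)

    if config.normalize == "none":
        out = np.clip(pixels, 0, vmax_out)
    else:
        if config.normalize == "minmax":
            lo, hi = float(pixels.min()), float(pixels.max())
        else:
            lo, hi = (float(v) for v in np.percentile(pixels, config.percentiles))
        if hi <= lo:
            out = np.zeros_like(pixels)
        else:
            out = (np.clip(pixels, lo, hi) - lo) / (hi - lo) * vmax_out
    return IntensityImage(np.rint(out).astype(dtype_for_depth(depth)), depth)


def tile_image(
    image: IntensityImage, config: PreprocessConfig
) -> list[tuple[IntensityImage, tuple[int, int]]]:
    """Cut the image into ``tile_size`` squares covering every pixel.

    Offsets step by ``tile_size - tile_overlap``; the final row/column of
    tiles is anchored to the image edge (possibly overlapping more). An
    image smaller than one tile yields a single zero-padded tile with a
    warning.
    """
    if config.tile_size is None:
        raise ValueError("tile_size must be set to tile an image")
    ts = config.tile_size
    h, w = image.shape
    if h < ts or w < ts:
        warnings.warn(
            f"image {image.shape} smaller than tile size {ts}; emitting one padded tile",
            stacklevel=2,
        )
        pad = np.zeros((ts, ts), dtype=image.astype_native().dtype)
        pad[:h, :w] = image.astype_native()
        return [(IntensityImage(pad, image.bit_depth), (0, 0))]

    def offsets(extent: int) -> list[int]:
        step = ts - config.tile_overlap
        offs = list(range(0, extent - ts + 1, step))
        if offs[-1] != extent - ts:
            offs.append(extent - ts)  # edge-anchored final tile
        return offs

    tiles = []
    arr = image.astype_native()
    for r in offsets(h):
        for c in offsets(w):
            tiles.append((IntensityImage(arr[r : r + ts, c : c + ts].copy(), image.bit_depth), (r, c)))
    return tiles
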