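"""Composition of training images and background-noise augmentation.

The training image paired with a filtered mask keeps only the pixels of
kept objects; everything else is set to 0. That leaves a perfectly
homogeneous black background, which a segmentation network can latch on
to, so random noise is added to re-introduce background inhomogeneity.
By default the noise is Gaussian (mean 0, sd 3 on the 8-bit scale),
restricted to background pixels so the annotated signal is untouched,
and clipped to the bit-depth range (negative draws on a zero background
clip to 0, i.e. the effective background distribution is half-truncated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import IntensityImage, dtype_for_depth


@dataclass(frozen=True)
class NoiseConfig:
    """Background-noise parameters.

    ``sd_or_halfwidth`` is the Gaussian standard deviation or the uniform
    half-width, in intensity units; ``scope`` is ``"background_only"``
    (foreground pixels bit-identical to input) or ``"whole_image"``.
    """

    distribution: str = "gaussian"
    sd_or_halfwidth: float = 3.0
    mean_or_center: float = 0.0
    scope: str = "background_only"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distribution not in ("gaussian", "uniform"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.scope not in ("background_only", "whole_image"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.sd_or_halfwidth < 0:
            raise ValueError("sd_or_halfwidth must be >= 0")


def compose_training_image(image: IntensityImage, filtered: np.ndarray) -> IntensityImage:
    """Keep image pixels where the filtered label map is positive, else 0.

    Idempotent: composing an already-composed image with the same mask
    changes nothing.
    """
    filtered = np.asarray(filtered)
    if filtered.shape != image.shape:
        raise ValueError(f"image {image.shape} and mask {filtered.shape} shapes differ")
    out = np.where(filtered > 0, image.astype_native(), 0)
    return IntensityImage(out.astype(dtype_for_depth(image.bit_depth)), image.bit_depth)


def add_background_noise(
    image: IntensityImage, filtered: np.ndarray, cfg: NoiseConfig
) -> IntensityImage:
    """Add random noise per the config, clipped to the bit-depth range.

    Deterministic given ``cfg.seed``. With ``scope="background_only"``
    the foreground (filtered > 0) is returned bit-identical.
    """
    filtered = np.asarray(filtered)
    if filtered.shape != image.shape:
        raise ValueError(f"image {image.shape} and mask {filtered.shape} shapes differ")
    if cfg.sd_or_halfwidth == 0 and cfg.mean_or_center == 0:
        return image.copy()
    rng = np.random.default_rng(cfg.seed)
    if cfg.distribution == "gaussian":
        noise = rng.normal(cfg.mean_or_center, cfg.sd_or_halfwidth, size=image.shape)
    else:
        noise = rng.uniform(
            cfg.mean_or_center - cfg.sd_or_halfwidth,
            cfg.mean_or_center + cfg.sd_or_halfwidth,
            size=image.shape,
        )
    noisy = np.clip(np.rint(image.pixels.astype(np.float64) + noise), 0, image.max_value)
    if cfg.scope == "background_only":
        out = np.where(filtered > 0, image.astype_native(), noisy)
    else:
        out = noisy
    return IntensityImage(out.astype(dtype_for_depth(image.bit_depth)), image.bit_depth)
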