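"""Global Otsu thresholding of fluorescence images.

Otsu's method picks the intensity threshold ``t*`` that minimizes the
intra-class variance

    sigma_w^2(t) = W0(t) * sigma_0^2(t) + W1(t) * sigma_1^2(t),

where class 0 holds the pixels with value <= t (background), class 1 the
pixels with value > t (fluorescent nuclei), ``W0, W1`` are the class
probabilities and ``sigma_0^2, sigma_1^2`` the class variances. This is
equivalent to maximizing the between-class variance.

The scan runs over a 256-bin histogram regardless of bit depth, but the
per-bin statistics are exact moments of the actual pixel values (count,
sum, sum of squares), not bin-center approximations. On 8-bit data the
value-to-bin mapping is one-to-one, so the scan is numerically identical
to an exhaustive per-value search. Candidate splits that leave one class
empty are skipped (the criterion is undefined there); among equal
minimizers the smallest threshold wins. The returned threshold is the
largest pixel value assigned to class 0, so ``image > t*`` reproduces the
optimal split exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import IntensityImage


class DegenerateImageError(ValueError):
    """Raised when an image has fewer than two distinct values."""


@dataclass
class OtsuResult:
    """Threshold plus the full per-candidate scan (one row per valid split)."""

    threshold: float
    scan: pd.DataFrame  # columns: t, w0, w1, var0, var1, var_within
    n_bins: int


def _pixels_of(image: IntensityImage | np.ndarray) -> np.ndarray:
    if isinstance(image, IntensityImage):
        return np.asarray(image.pixels)
    return np.asarray(image)


def otsu_threshold(image: IntensityImage | np.ndarray, n_bins: int = 256) -> OtsuResult:
    """Scan all histogram splits for the intra-class-variance minimizer.

    Raises
    ------
    DegenerateImageError
        If the image is constant (no two-class split exists).
    """
    values = _pixels_of(image).ravel().astype(np.float64)
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise DegenerateImageError("constant image: no threshold separates two classes")

    counts, edges = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    sums, _ = np.histogram(values, bins=n_bins, range=(vmin, vmax), weights=values)
    sumsq, _ = np.histogram(values, bins=n_bins, range=(vmin, vmax), weights=values**2)

    n = values.size
    c0 = np.cumsum(counts)[:-1]  # class 0 = bins 0..k, split index k = 0..n_bins-2
    s0 = np.cumsum(sums)[:-1]
    q0 = np.cumsum(sumsq)[:-1]
    c1 = n - c0
    s1 = sums.sum() - s0
    q1 = sumsq.sum() - q0

    valid = (c0 > 0) & (c1 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w0 = c0 / n
        w1 = c1 / n
        var0 = q0 / c0 - (s0 / c0) ** 2
        var1 = q1 / c1 - (s1 / c1) ** 2
        var_within = w0 * var0 + w1 * var1
    var_within = np.where(valid, var_within, np.inf)

    best = int(np.argmin(var_within))  # argmin takes the first -> smallest threshold
    if not np.isfinite(var_within[best]):
        raise DegenerateImageError("no candidate split leaves both classes non-empty")

    # threshold = largest value in class 0 (bins 0..best), so (image > t*) is exact
    upper_edge = edges[best + 1]
    class0 = values[values < upper_edge] if best + 1 < n_bins else values[values <= upper_edge]
    threshold = float(class0.max())

    scan = pd.DataFrame(
        {
            "t": edges[1:-1][valid],
            "w0": w0[valid],
            "w1": w1[valid],
            "var0": var0[valid],
            "var1": var1[valid],
            "var_within": var_within[valid],
        }
    )
    return OtsuResult(threshold=threshold, scan=scan, n_bins=n_bins)


def apply_threshold(image: IntensityImage | np.ndarray, threshold: float) -> np.ndarray:
    """Boolean foreground mask: pixels strictly above the threshold."""
    return _pixels_of(image) > threshold


def binarize(image: IntensityImage | np.ndarray, n_bins: int = 256) -> tuple[np.ndarray, OtsuResult]:
    """Convenience: threshold an image and return (mask, OtsuResult)."""
    result = otsu_threshold(image, n_bins=n_bins)
    return apply_threshold(image, result.threshold), result
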