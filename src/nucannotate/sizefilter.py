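"""Median pixel-area filtering of labelled objects.

The dominant object class in a nuclei field — single nuclei — is
identified through the median pixel area ``m`` of all detected objects,
pooled across the whole dataset. Objects whose area deviates from the
median by more than a fraction ``f`` (default 0.5) are excluded: clusters
and merged nuclei fall above ``(1+f)*m``, debris particles and imaging
artefacts below ``(1-f)*m``. Bounds are inclusive; the median is computed
once, on the unfiltered pooled area distribution, so the filter is a
single pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .core import OBJECT_TABLE_COLUMNS, as_label_map


@dataclass(frozen=True)
class FilterReport:
    """Accounting of one area-filter pass over a (multi-image) dataset."""

    median_area: float
    lower: float
    upper: float
    n_total: int
    n_kept: int
    n_excluded_small: int
    n_excluded_large: int

    def __post_init__(self) -> None:
        assert self.n_total == self.n_kept + self.n_excluded_small + self.n_excluded_large

    def to_dict(self) -> dict:
        return {
            "median_area": self.median_area,
            "lower": self.lower,
            "upper": self.upper,
            "n_total": self.n_total,
            "n_kept": self.n_kept,
            "n_excluded_small": self.n_excluded_small,
            "n_excluded_large": self.n_excluded_large,
        }


def object_areas(label_map: np.ndarray) -> pd.DataFrame:
    """One table row per positive label: exact pixel area, bbox, centroid.

    Bounding boxes are half-open ``[r0, r1) x [c0, c1)``. The ``kept``
    flag starts True and the ``class`` tag empty; downstream stages fill
    them in.
    """
    label_map = as_label_map(label_map)
    rows = []
    for prop in regionprops(label_map):
        r0, c0, r1, c1 = prop.bbox
        rows.append(
            {
                "id": int(prop.label),
                "area_px": int(prop.area),
                "bbox_r0": r0,
                "bbox_c0": c0,
                "bbox_r1": r1,
                "bbox_c1": c1,
                "centroid_r": float(prop.centroid[0]),
                "centroid_c": float(prop.centroid[1]),
                "kept": True,
                "class": "",
            }
        )
    return pd.DataFrame(rows, columns=OBJECT_TABLE_COLUMNS).astype(
        {"id": int, "area_px": int, "kept": bool, "class": str}
    )


def area_filter(
    tables: pd.DataFrame | Sequence[pd.DataFrame], fraction: float = 0.5
) -> tuple[list[set[int]], FilterReport]:
    """Keep objects whose area lies within ``fraction`` of the pooled median.

    Parameters
    ----------
    tables
        One object table per image (a single table is treated as a
        one-image dataset). The median is pooled over *all* images.
    fraction
        Allowed relative deviation ``f``; object ``i`` is kept iff
        ``(1-f)*m <= area_i <= (1+f)*m`` (inclusive bounds).

    Returns
    -------
    kept_sets, report
        Per-image sets of kept label ids, and the filter accounting.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    areas = np.concatenate([t["area_px"].to_numpy(float) for t in tables]) if tables else np.array([])
    if areas.size == 0:
        raise ValueError("area filter needs at least one object in the dataset")
    m = float(np.median(areas))
    lower, upper = (1 - fraction) * m, (1 + fraction) * m

    kept_sets: list[set[int]] = []
    n_small = n_large = n_kept = 0
    for t in tables:
        a = t["area_px"].to_numpy(float)
        keep = (a >= lower) & (a <= upper)
        kept_sets.append(set(t.loc[keep, "id"].astype(int)))
        n_kept += int(keep.sum())
        n_small += int((a < lower).sum())
        n_large += int((a > upper).sum())
    report = FilterReport(
        median_area=m,
        lower=lower,
        upper=upper,
        n_total=int(areas.size),
        n_kept=n_kept,
        n_excluded_small=n_small,
        n_excluded_large=n_large,
    )
    return kept_sets, report


def apply_keep(label_map: np.ndarray, kept: set[int]) -> np.ndarray:
    """Zero out non-kept labels and renumber the kept ones sequentially.

    Renumbering preserves the original label order, so results are
    deterministic and instance identity is traceable through sorting.
    """
    label_map = as_label_map(label_map)
    present = np.unique(label_map)
    present = present[present > 0]
    unknown = kept - set(int(p) for p in present)
    if unknown:
        raise ValueError(f"kept set references labels not in the map: {sorted(unknown)}")
    lut = np.zeros(int(present.max()) + 1 if present.size else 1, dtype=label_map.dtype)
    for new, lab in enumerate(sorted(kept), start=1):
        lut[lab] = new
    return lut[label_map]
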