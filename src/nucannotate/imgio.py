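"""Reading and writing every on-disk format the pipeline touches.

Formats: single-channel 8/16-bit TIFF and PNG for images, 16-bit TIFF for
label maps, CSV for object tables, JSON for dataset manifests, and the
Broad Bioimage Benchmark Collection (BBBC038 / Data Science Bowl 2018)
per-instance mask directory layout::

    <id>/images/<id>.png
    <id>/masks/<k>.png      # one binary mask per instance

All integer round-trips are lossless.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import (
    OBJECT_TABLE_COLUMNS,
    IntensityImage,
    as_label_map,
    dtype_for_depth,
    labels_of,
)

MAX_LABELS_16BIT = 65535


class UnsupportedImageError(ValueError):
    """Raised for multi-channel non-grayscale or unknown-dtype inputs."""


class ObjectTableParseError(ValueError):
    """Raised when an object-table CSV is malformed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        suffix = f" (line {line})" if line is not None else ""
        super().__init__(message + suffix)


# ---------------------------------------------------------------------------
# intensity images


def _collapse_channels(arr: np.ndarray, path: Path) -> np.ndarray:
    """Collapse an RGB(A) image with identical channels to one channel."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[:, :, :3]
        if (rgb == rgb[:, :, :1]).all():
            return rgb[:, :, 0]
        raise UnsupportedImageError(
            f"{path}: multi-channel image with non-identical channels is not grayscale"
        )
    raise UnsupportedImageError(f"{path}: unsupported image shape {arr.shape}")


def _depth_of_dtype(dtype: np.dtype, path: Path) -> int:
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    raise UnsupportedImageError(f"{path}: unsupported pixel dtype {dtype}; expected uint8 or uint16")


def read_image(path: str | Path) -> IntensityImage:
    """Read a single-channel 8- or 16-bit TIFF/PNG without rescaling."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = _collapse_channels(np.asarray(arr), path)
    depth = _depth_of_dtype(arr.dtype, path)
    return IntensityImage(arr, depth)


def write_image(image: IntensityImage, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = image.astype_native()
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)
    return path


# ---------------------------------------------------------------------------
# label maps


def write_labelmap(label_map: np.ndarray, path: str | Path) -> Path:
    """Write a label map as a single-channel 16-bit TIFF (background 0)."""
    label_map = as_label_map(label_map)
    n_max = int(label_map.max()) if label_map.size else 0
    if n_max > MAX_LABELS_16BIT:
        raise ValueError(
            f"label map has labels up to {n_max}, exceeding the 16-bit capacity of {MAX_LABELS_16BIT}"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, label_map.astype(np.uint16))
    return path


def read_labelmap(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    return as_label_map(np.asarray(arr).astype(np.int32))


# ---------------------------------------------------------------------------
# BBBC038-style per-instance mask layout


def export_instance_masks(
    image: IntensityImage, label_map: np.ndarray, out_dir: str | Path, sample_id: str
) -> Path:
    """Export one sample in the BBBC038 layout: images/ plus one PNG per instance."""
    label_map = as_label_map(label_map)
    if label_map.shape != image.shape:
        raise ValueError(f"image {image.shape} and label map {label_map.shape} shapes differ")
    root = Path(out_dir) / sample_id
    (root / "images").mkdir(parents=True, exist_ok=True)
    img8 = image.astype_native()
    if image.bit_depth == 16:
        iio.imwrite(root / "images" / f"{sample_id}.png", img8)
    else:
        iio.imwrite(root / "images" / f"{sample_id}.png", img8)
    labels = labels_of(label_map)
    if labels.size == 0:
        warnings.warn(f"{sample_id}: empty label map, exporting no masks", stacklevel=2)
        return root
    masks_dir = root / "masks"
    masks_dir.mkdir(exist_ok=True)
    for k in labels:
        mask = (label_map == k).astype(np.uint8) * 255
        iio.imwrite(masks_dir / f"{int(k)}.png", mask)
    return root


def read_instance_masks(sample_dir: str | Path) -> np.ndarray:
    """Stack a BBBC038-style masks/ folder back into a label map.

    Masks are required to be pairwise disjoint; labels are assigned in
    sorted filename order, so round-trips agree up to label permutation.
    """
    masks_dir = Path(sample_dir) / "masks"
    files = sorted(masks_dir.glob("*.png")) if masks_dir.exists() else []
    if not files:
        img_files = list((Path(sample_dir) / "images").glob("*"))
        if not img_files:
            raise FileNotFoundError(f"{sample_dir}: no masks/ and no images/ found")
        shape = np.asarray(iio.imread(img_files[0])).shape[:2]
        return np.zeros(shape, dtype=np.int32)
    out: np.ndarray | None = None
    for i, f in enumerate(files, start=1):
        mask = np.asarray(iio.imread(f)) > 0
        if mask.ndim != 2:
            raise UnsupportedImageError(f"{f}: instance masks must be single-channel")
        if out is None:
            out = np.zeros(mask.shape, dtype=np.int32)
        if (out[mask] != 0).any():
            raise ValueError(f"{f}: instance masks overlap; label maps require disjoint instances")
        out[mask] = i
    assert out is not None
    return out


# ---------------------------------------------------------------------------
# object tables

_NUMERIC_COLUMNS = {
    "id": int,
    "area_px": int,
    "bbox_r0": int,
    "bbox_c0": int,
    "bbox_r1": int,
    "bbox_c1": int,
    "centroid_r": float,
    "centroid_c": float,
}


def write_object_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = table.reindex(columns=OBJECT_TABLE_COLUMNS)
    out.to_csv(path, index=False)
    return path


def read_object_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if header.split(",") != OBJECT_TABLE_COLUMNS:
        raise ObjectTableParseError(f"{path}: unexpected header {header!r}", line=1)
    try:
        df = pd.read_csv(path, dtype={"class": "string"})
    except Exception as exc:  # pandas raises several parser error types
        raise ObjectTableParseError(f"{path}: {exc}") from exc
    for col, typ in _NUMERIC_COLUMNS.items():
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and len(df):
            bad = int(coerced.isna().idxmax())
            raise ObjectTableParseError(
                f"{path}: non-numeric value {df[col].iloc[bad]!r} in column {col!r}",
                line=bad + 2,  # +1 header, +1 one-based
            )
        df[col] = coerced.astype(typ)
    df["kept"] = df["kept"].astype(bool)
    df["class"] = df["class"].fillna("").astype(str)
    return df[OBJECT_TABLE_COLUMNS]


# ---------------------------------------------------------------------------
# dataset manifest


def write_manifest(
    entries: Sequence[dict], root: str | Path, path: str | Path | None = None
) -> Path:
    """Write a JSON manifest; entries have image_path, optional labelmap_path, split."""
    root = Path(root)
    path = Path(path) if path is not None else root / "manifest.json"
    payload = {"root": str(root), "entries": list(entries)}
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_manifest(path: str | Path) -> dict:
    """Load and validate a manifest: paths exist, image/label shapes match."""
    path = Path(path)
    payload = json.loads(path.read_text())
    root = Path(payload["root"])
    for entry in payload["entries"]:
        img_path = root / entry["image_path"]
        if not img_path.exists():
            raise FileNotFoundError(f"manifest references missing image {img_path}")
        lbl = entry.get("labelmap_path")
        if lbl:
            lbl_path = root / lbl
            if not lbl_path.exists():
                raise FileNotFoundError(f"manifest references missing label map {lbl_path}")
            img = read_image(img_path)
            lab = read_labelmap(lbl_path)
            if img.shape != lab.shape:
                raise ValueError(
                    f"{img_path} shape {img.shape} != label map shape {lab.shape}"
                )
    return payload
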