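"""File I/O for images, tables and reports.

Images are exchanged as PNG/TIFF/JPEG (8- or 16-bit integers or float
TIFF); tables as UTF-8 CSV with a header row; reports as JSON.  Alpha-images
are written as 32-bit float TIFF so downstream tools can re-threshold them
without recomputation.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .multifractal import AlphaImage, MfSpectrum
from .segmentation import RegionStats

__all__ = [
    "read_rgb",
    "write_alpha_tiff",
    "read_alpha_tiff",
    "write_mask_png",
    "write_labels_tiff",
    "read_labels_tiff",
    "write_rgb_png",
    "write_regions_csv",
    "write_spectrum_csv",
    "write_json",
]


def read_rgb(path: str | Path) -> np.ndarray:
    """Read an RGB image and return float64 values in [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha plane
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / float(np.iinfo(arr.dtype).max)
    return np.clip(arr.astype(float), 0.0, 1.0)


def write_alpha_tiff(path: str | Path, alpha_img: AlphaImage) -> None:
    tifffile.imwrite(str(path), alpha_img.alpha.astype(np.float32))


def read_alpha_tiff(path: str | Path) -> AlphaImage:
    return AlphaImage(alpha=tifffile.imread(str(path)).astype(float))


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(str(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def write_labels_tiff(path: str | Path, labels: np.ndarray) -> None:
    lab = np.asarray(labels)
    if lab.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels")
    tifffile.imwrite(str(path), lab.astype(np.uint16))


def read_labels_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


def write_rgb_png(path: str | Path, rgb: np.ndarray) -> None:
    arr = np.asarray(rgb)
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.clip(arr * 255.0 + 0.5, 0, 255).astype(np.uint8)
    iio.imwrite(str(path), arr)


def write_regions_csv(path: str | Path, regions: list[RegionStats]) -> None:
    rows = [
        {
            "label": r.label,
            "area": r.area,
            "eccentricity": r.eccentricity,
            "centroid_row": r.centroid[0],
            "centroid_col": r.centroid[1],
            "touches_border": r.touches_border,
            "rejection_reason": r.rejection_reason or "",
        }
        for r in regions
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_spectrum_csv(path: str | Path, spectrum: MfSpectrum) -> None:
    pd.DataFrame(
        {"alpha": spectrum.alpha_bins, "f": spectrum.f_values}
    ).to_csv(path, index=False)


def write_json(path: str | Path, payload: dict) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")
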