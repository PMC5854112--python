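"""File formats: contour CSV dialect, ground-truth JSON sidecars, rasters.

Contours are exchanged as CSV with header ``x_um,y_um``, vertices ordered
counter-clockwise (positive shoelace area), first vertex not repeated at the
end.  Binary masks are written as 8-bit PNG (foreground 255), fluorescence
images as 16-bit TIFF.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .contour import Contour
from .synthetic import LeafTruth

__all__ = [
    "write_contour_csv",
    "read_contour_csv",
    "write_truth_json",
    "read_truth_json",
    "write_mask_png",
    "read_mask",
    "write_fluor_tiff",
    "read_fluor_tiff",
    "read_seeds_csv",
]


def write_contour_csv(c: Contour, path) -> None:
    df = pd.DataFrame(c.vertices, columns=["x_um", "y_um"])
    df.to_csv(path, index=False)


def read_contour_csv(path, pixel_size: float | None = None) -> Contour:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["x_um", "y_um"]:
        raise ValueError(f"{path}: expected header x_um,y_um, got {list(df.columns)}")
    return Contour(df[["x_um", "y_um"]].to_numpy(float), pixel_size=pixel_size)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_truth_json(truth: LeafTruth, path) -> None:
    """Ground-truth sidecar: everything except the polygon (stored as CSV)."""
    d = {
        "true_area": truth.true_area,
        "true_perimeter": truth.true_perimeter,
        "tooth_apices": truth.tooth_apices.tolist(),
        "sinus_points": truth.sinus_points.tolist(),
        "true_tooth_heights": truth.true_tooth_heights.tolist(),
        "base_point": truth.base_point.tolist(),
        "apex_point": truth.apex_point.tolist(),
        "true_blade_length": truth.true_blade_length,
        "teeth": [asdict(t) for t in truth.teeth],
    }
    Path(path).write_text(json.dumps(d, indent=1))


def read_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_mask_png(mask: np.ndarray, path) -> None:
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return img > (img.max() / 2 if img.max() > 0 else 0)


def write_fluor_tiff(image: np.ndarray, path) -> None:
    img = np.asarray(image, dtype=float)
    tifffile.imwrite(path, np.clip(np.round(img), 0, 65535).astype(np.uint16))


def read_fluor_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def read_seeds_csv(path) -> pd.DataFrame:
    """Batch seed table: columns image, seed_x (col), seed_y (row), label."""
    df = pd.read_csv(path)
    required = {"image", "seed_x", "seed_y"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: seeds CSV needs columns {sorted(required)}")
    return df
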