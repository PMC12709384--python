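"""File I/O and mask-based region summaries.

Conventions: distances in um, times in s, diffusion in um^2/s.  Point
tables are CSV with header ``x_um,y_um,D_um2_s`` (spot lists additionally
``diameter_um``); maps are 32-bit float TIFF; masks are TIFF/PNG rasters
with nonzero = in-region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import ValidationError
from .variogram import PointSamples

__all__ = [
    "read_points_csv",
    "write_points_csv",
    "read_mask",
    "read_stack",
    "write_map_tiff",
    "read_map_tiff",
    "write_report_json",
    "RegionSummary",
    "summarize_regions",
]

POINT_COLUMNS = ("x_um", "y_um", "D_um2_s")


def read_points_csv(path) -> PointSamples:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(POINT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    return PointSamples(
        u=df[["x_um", "y_um"]].to_numpy(float), z=df["D_um2_s"].to_numpy(float)
    )


def write_points_csv(path, points: PointSamples, extra: pd.DataFrame | None = None):
    df = pd.DataFrame({"x_um": points.u[:, 0], "y_um": points.u[:, 1], "D_um2_s": points.z})
    if extra is not None:
        df = pd.concat([df, extra.reset_index(drop=True)], axis=1)
    # 17 significant digits: float64 survives the text round trip exactly
    df.to_csv(path, index=False, float_format="%.17g")


def read_mask(path) -> np.ndarray:
    """Binary mask from TIFF/PNG: nonzero pixels are in-region."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        from imageio.v3 import imread

        arr = imread(path)
    if arr.ndim == 3:  # collapse RGB(A)
        arr = arr[..., :3].max(axis=-1)
    if arr.ndim != 2:
        raise ValidationError(f"{path}: expected a 2-D mask, got shape {arr.shape}")
    return arr != 0


def read_stack(path) -> np.ndarray:
    """Multi-page TIFF as a (time, row, col) float array."""
    arr = tifffile.imread(path).astype(float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValidationError(f"{path}: expected a (time, row, col) stack, got {arr.shape}")
    return arr


def write_map_tiff(path, data: np.ndarray):
    tifffile.imwrite(path, np.asarray(data, dtype=np.float32))


def read_map_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.float32)


def write_report_json(path, report: dict):
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default) + "\n")


# --------------------------------------------------------------------------
# region summaries
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSummary:
    """Per-label distribution statistics of a mapped quantity."""

    table: pd.DataFrame  # columns: label, name, count, mean, median, q25, q75

    def __str__(self) -> str:
        return self.table.to_string(index=False)


def summarize_regions(value_map, label_mask, labels: dict | None = None) -> RegionSummary:
    """Summarize a value map over an integer label mask.

    ``labels`` maps label integers to names (e.g. {1: "nucleoplasm",
    2: "ER", 3: "cytoplasm"}); unnamed labels found in the mask are reported
    under their integer.  NaN map values (outside the simulation mask) are
    ignored; labels with no finite values get count 0 and null statistics.
    """
    value_map = np.asarray(value_map, dtype=float)
    label_mask = np.asarray(label_mask)
    if value_map.shape != label_mask.shape:
        raise ValidationError(
            f"map shape {value_map.shape} does not match label mask {label_mask.shape}"
        )
    present = [int(v) for v in np.unique(label_mask) if v != 0]
    if labels is None:
        labels = {}
    all_labels = sorted(set(present) | set(int(k) for k in labels))
    rows = []
    for lab in all_labels:
        vals = value_map[(label_mask == lab) & np.isfinite(value_map)]
        if vals.size:
            rows.append(
                {
                    "label": lab,
                    "name": labels.get(lab, str(lab)),
                    "count": int(vals.size),
                    "mean": float(vals.mean()),
                    "median": float(np.median(vals)),
                    "q25": float(np.percentile(vals, 25)),
                    "q75": float(np.percentile(vals, 75)),
                }
            )
        else:
            rows.append(
                {
                    "label": lab, "name": labels.get(lab, str(lab)), "count": 0,
                    "mean": np.nan, "median": np.nan, "q25": np.nan, "q75": np.nan,
                }
            )
    return RegionSummary(table=pd.DataFrame(rows))
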