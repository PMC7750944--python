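"""File I/O: single-channel TIFF images, centroid/detection CSVs, reports.

Conventions
-----------
* Images are single-channel TIFF, 8/16-bit unsigned or float32; in memory
  they are 2D numpy arrays.  Multi-channel files are rejected with a hint to
  extract the bead channel first.
* Centroid files are CSV with header ``bead_id,row,col[,diameter,
  fully_visible]``; coordinates are 0-based (row, col).  Whether they live in
  the original or the upsampled frame is recorded in an optional leading
  comment line ``# frame: original|upsampled``.
* Detections are CSV with header ``detection_id,row,col,area``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


class FormatError(ValueError):
    """An input file does not match the expected on-disk format."""


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-channel TIFF as a 2D array (dtype preserved)."""
    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:  # pragma: no cover - tifffile message passthrough
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(
            f"{path}: expected a single-channel 2D image, got shape {arr.shape}; "
            "extract the bead channel before processing"
        )
    return arr


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a 2D array as TIFF (lossless for uint8/uint16/float32)."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise FormatError(f"expected 2D image, got shape {image.shape}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), image)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as 8-bit TIFF (0/255 on disk)."""
    write_image((np.asarray(mask) > 0).astype(np.uint8) * 255, path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read an 8-bit mask TIFF back to 0/1."""
    return (read_image(path) > 0).astype(np.uint8)


_CENTROID_COLS = ["bead_id", "row", "col"]


def read_centroid_table(path: str | Path) -> pd.DataFrame:
    """Read a centroid CSV; raises FormatError naming the offending line."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    frame = "original"
    start = 0
    if lines and lines[0].startswith("#"):
        if "upsampled" in lines[0]:
            frame = "upsampled"
        start = 1
    header = lines[start].strip().split(",") if len(lines) > start else []
    missing = [c for c in _CENTROID_COLS if c not in header]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    for lineno, line in enumerate(lines[start + 1 :], start=start + 2):
        if not line.strip():
            continue
        parts = line.strip().split(",")
        if len(parts) != len(header):
            raise FormatError(f"{path}: malformed row at line {lineno}")
        try:
            records.append([float(x) for x in parts])
        except ValueError as exc:
            raise FormatError(f"{path}: malformed row at line {lineno}") from exc
    df = pd.DataFrame(records, columns=header)
    if not df.empty:
        df["bead_id"] = df["bead_id"].astype(int)
        if "fully_visible" in df:
            df["fully_visible"] = df["fully_visible"].astype(int)
    else:
        df = pd.DataFrame({c: pd.Series(dtype=float) for c in header})
    df.attrs["frame"] = frame
    return df


def write_centroid_table(df: pd.DataFrame, path: str | Path, frame: str = "original") -> None:
    """Write a centroid table with a frame comment; 6-decimal coordinates."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# frame: {frame}\n")
        df.to_csv(fh, index=False, float_format="%.6f", lineterminator="\n")


def read_centroids(path: str | Path) -> np.ndarray:
    """Centroid CSV -> (n, 2) array of (row, col)."""
    df = read_centroid_table(path)
    return df[["row", "col"]].to_numpy(dtype=float).reshape(-1, 2)


def write_centroids(centroids: np.ndarray, path: str | Path, frame: str = "original") -> None:
    centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
    df = pd.DataFrame(
        {
            "bead_id": np.arange(len(centroids)),
            "row": centroids[:, 0],
            "col": centroids[:, 1],
        }
    )
    write_centroid_table(df, path, frame=frame)


def write_detections(detections, path: str | Path) -> None:
    """DetectionSet -> CSV ``detection_id,row,col,area``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cents = np.asarray(detections.centroids, dtype=float).reshape(-1, 2)
    df = pd.DataFrame(
        {
            "detection_id": np.arange(len(cents)),
            "row": cents[:, 0],
            "col": cents[:, 1],
            "area": np.asarray(detections.sizes, dtype=int)
            if len(detections.sizes)
            else np.array([], dtype=int),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


def write_json(obj: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))
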