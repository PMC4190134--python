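"""File I/O for gray images, contour maps, label mosaics and result tables."""

from __future__ import annotations

import csv
import json
import logging
import os

import numpy as np
import tifffile
from PIL import Image

logger = logging.getLogger("endoseg")


def read_gray_image(path: str) -> np.ndarray:
    """Read an 8/16-bit single-channel PNG or TIFF as a [0, 255] float field.

    16-bit inputs are rescaled linearly to [0, 255]; RGB inputs are
    converted by luminance with a logged warning.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(path)
        if arr.ndim == 3 and arr.shape[0] not in (3, 4) and arr.shape[-1] not in (3, 4):
            raise ValueError(f"multi-frame TIFF not supported: {path}")
    else:
        with Image.open(path) as im:
            if getattr(im, "n_frames", 1) > 1:
                raise ValueError(f"multi-frame image not supported: {path}")
            arr = np.asarray(im)
    if arr.ndim == 3:
        logger.warning("%s is multi-channel; converting by luminance", path)
        arr = arr[..., :3].astype(np.float64) @ np.array([0.2126, 0.7152, 0.0722])
    arr = arr.astype(np.float64)
    if arr.max() > 255:  # 16-bit range
        arr = arr * (255.0 / 65535.0)
    return arr


def write_gray_image(img: np.ndarray, path: str) -> None:
    """Write a [0, 255] gray image as 8-bit PNG/TIFF."""
    data = np.clip(np.asarray(img), 0, 255).astype(np.uint8)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, data)
    else:
        Image.fromarray(data, mode="L").save(path)


def read_contour_map(path: str) -> np.ndarray:
    """Read a binary contour map (nonzero = contour pixel).

    More than two distinct gray values is an ambiguous mask and rejected;
    an all-zero mask is accepted but flagged with a warning.
    """
    arr = read_gray_image(path)
    values = np.unique(arr)
    if len(values) > 2:
        raise ValueError(f"{path} has {len(values)} gray values; not a binary mask")
    mask = arr > 0
    if not mask.any():
        logger.warning("%s is an empty contour map", path)
    return mask


def write_contour_map(contours: np.ndarray, path: str) -> None:
    write_gray_image(np.where(np.asarray(contours, dtype=bool), 255, 0), path)


def read_labels(path: str) -> np.ndarray:
    """Read a 16-bit label image."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(path)
    else:
        with Image.open(path) as im:
            arr = np.asarray(im)
    return arr.astype(np.int32)


def write_labels(labels: np.ndarray, path: str) -> None:
    """Write a label mosaic as 16-bit PNG/TIFF."""
    data = np.asarray(labels)
    if data.max() > 65535:
        raise ValueError("more than 65535 labels cannot be stored at 16 bits")
    data = data.astype(np.uint16)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, data)
    else:
        Image.fromarray(data).save(path)


CSV_HEADER = ["image_id", "method", "params", "criterion", "rho", "value"]


def write_results_csv(rows: list[dict], path: str) -> None:
    """UTF-8 CSV of evaluation rows; numeric values keep 6+ significant digits."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_HEADER)
        writer.writeheader()
        for row in rows:
            out = dict(row)
            if isinstance(out.get("value"), float):
                out["value"] = f"{out['value']:.6g}"
            writer.writerow(out)


def read_results_csv(path: str) -> list[dict]:
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def write_report_json(report, path: str) -> None:
    """JSON serialisation of tuning / CV / morphometry reports."""
    if hasattr(report, "to_dict"):
        report = report.to_dict()
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "astuple"):
        return list(obj.astuple())
    raise TypeError(f"cannot serialise {type(obj)}")
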