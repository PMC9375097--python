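"""Image, CSV and JSON input/output for masks, profiles and results.

Quantitative grayscale output defaults to 16-bit TIFF; 8-bit PNG serves as
preview. Binary masks round-trip losslessly through either format.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Union

import numpy as np
import tifffile
from PIL import Image

from .numeric_psf import WindowProfile

__all__ = [
    "save_grayscale",
    "load_grayscale",
    "profile_to_csv",
    "amplitude_profile_to_csv",
    "save_json",
]

PathLike = Union[str, Path]


def save_grayscale(array: np.ndarray, path: PathLike, bit_depth: int = 16) -> None:
    """Write a [0, 1] array as 8- or 16-bit grayscale PNG/TIFF (linear scale)."""
    a = np.asarray(array, dtype=np.float64)
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    full = 255 if bit_depth == 8 else 65535
    scaled = np.clip(np.round(a * full), 0, full)
    out = scaled.astype(np.uint8 if bit_depth == 8 else np.uint16)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        Image.fromarray(out).save(path)


def load_grayscale(path: PathLike) -> np.ndarray:
    """Read a grayscale PNG/TIFF back to a float array on [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        raw = tifffile.imread(path)
    else:
        raw = np.asarray(Image.open(path))
    if raw.dtype == np.uint8:
        return raw.astype(np.float64) / 255.0
    if raw.dtype == np.uint16:
        return raw.astype(np.float64) / 65535.0
    return raw.astype(np.float64)


def profile_to_csv(profile: WindowProfile, path: PathLike) -> None:
    """Write a windowed line profile as (position_1based, value) CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["position_1based", "value"])
        for offset, value in enumerate(profile.values):
            writer.writerow([profile.window_start + offset, f"{value:.12g}"])


def amplitude_profile_to_csv(w: np.ndarray, h: np.ndarray, path: PathLike) -> None:
    """Write an analytic amplitude profile as two-column (w, h) CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["w", "h"])
        for wi, hi in zip(w, h):
            writer.writerow([f"{wi:.12g}", f"{hi:.12g}"])


def save_json(obj: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
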