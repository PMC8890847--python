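"""Raster image input/output and luminance conversion.

Images are represented throughout the package as 2-D ``float64`` arrays of
luminance values on a 0-255 scale (row-major: axis 0 is the vertical/row
direction, axis 1 the horizontal/column direction).  Color inputs are reduced
to luminance with the ITU-R BT.601 weights.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

#: ITU-R BT.601 luma weights for R, G, B.
BT601_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Minimum height/width for images entering the metric pipeline.
MIN_IMAGE_SIZE = 3


def validate_image(pixels: np.ndarray, min_size: int = MIN_IMAGE_SIZE) -> np.ndarray:
    """Check that ``pixels`` is a finite 2-D luminance field and return it as float64.

    Raises
    ------
    ValueError
        If the array is not 2-D, smaller than ``min_size`` in either
        dimension, or contains non-finite values.
    """
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D luminance array, got shape {arr.shape}")
    if arr.shape[0] < min_size or arr.shape[1] < min_size:
        raise ValueError(
            f"image of shape {arr.shape} is smaller than the minimum {min_size}x{min_size}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Load a PNG/PGM/JPEG image as a 2-D luminance array on a 0-255 scale.

    Grayscale files are decoded as-is; RGB(A) files are converted to luminance
    with the BT.601 weights 0.299/0.587/0.114 (alpha is ignored).

    Raises
    ------
    IOError
        If the file does not exist or cannot be decoded as an image.
    """
    p = Path(path)
    if not p.is_file():
        raise IOError(f"cannot read image file: {p}")
    try:
        with Image.open(p) as im:
            im.load()
            if im.mode in ("1", "L", "I", "I;16", "F"):
                arr = np.asarray(im.convert("F"), dtype=np.float64)
                if im.mode == "1":
                    arr = arr * 255.0
            else:
                rgb = np.asarray(im.convert("RGB"), dtype=np.float64)
                arr = rgb @ BT601_WEIGHTS
    except UnidentifiedImageError as exc:
        raise IOError(f"unsupported or corrupt image file: {p}") from exc
    return validate_image(arr)


def save_image(pixels: np.ndarray, path: str | os.PathLike) -> None:
    """Write a luminance array (0-255 scale) as an 8-bit grayscale PNG."""
    arr = validate_image(pixels, min_size=1)
    data = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    Image.fromarray(data, mode="L").save(Path(path), format="PNG")


def save_map(values: np.ndarray, path: str | os.PathLike) -> None:
    """Write a similarity map (values in [0, 1]) as an 8-bit grayscale PNG."""
    arr = np.asarray(values, dtype=np.float64)
    save_image(np.clip(arr, 0.0, 1.0) * 255.0, path)
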