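"""Raster image I/O and RGB/HSV conversion.

Conventions used throughout the package:

* Images are ``float64`` arrays of shape ``(h, w, 3)`` on a [0, 255]
  working scale, row-major, ``(row, col)`` = ``(y, x)``, 0-based.
  Intermediate results of the decomposition may leave [0, 255]; values
  are clipped only when written to disk.
* HSV channels are always on [0, 1] regardless of the RGB working
  scale, so the masking thresholds are scale-free.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
from skimage import color

__all__ = [
    "read_image",
    "write_image",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "validate_rgb",
    "WORKING_SCALE",
]

#: Maximum intensity of the real-valued working scale.
WORKING_SCALE = 255.0

MIN_SIDE = 8


def validate_rgb(image: np.ndarray) -> np.ndarray:
    """Check that ``image`` is a finite (h, w, 3) float array and return it.

    Raises
    ------
    ValueError
        If the array is not three-channel, too small, or non-finite.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (h, w, 3) RGB array, got shape {image.shape}")
    h, w = image.shape[:2]
    if h < MIN_SIDE or w < MIN_SIDE:
        raise ValueError(f"image too small: {w}x{h}, need at least {MIN_SIDE}x{MIN_SIDE}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    return image


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/JPEG file into a float RGB array on the [0, 255] scale.

    Alpha channels are dropped. True single-channel (grayscale) images
    are rejected: the highlight mask criteria are chromatic and need
    three independent channels.
    """
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder failures vary by backend
        raise OSError(f"could not decode image file {path!r}: {exc}") from exc
    if raw.ndim == 2:
        raise ValueError(f"{path!r} is grayscale; RGB input required")
    if raw.ndim != 3:
        raise ValueError(f"{path!r}: unsupported image layout with shape {raw.shape}")
    if raw.shape[2] == 4:
        raw = raw[:, :, :3]
    elif raw.shape[2] == 2:  # luminance+alpha
        raise ValueError(f"{path!r} has no chroma channels; RGB input required")
    elif raw.shape[2] != 3:
        raise ValueError(f"{path!r}: unsupported channel count {raw.shape[2]}")
    if raw.dtype != np.uint8:
        # 16-bit imagery is out of scope; scale anything wider down to 8-bit range
        raw = (raw.astype(np.float64) / np.iinfo(raw.dtype).max * WORKING_SCALE)
    return validate_rgb(raw)


def write_image(image: np.ndarray, path: str | os.PathLike) -> str:
    """Clip to [0, 255], round, and write as an 8-bit PNG. Returns ``path``.

    PNG is used for all outputs so that decomposition results are never
    degraded by lossy recompression.
    """
    image = np.asarray(image, dtype=np.float64)
    quantized = np.clip(np.rint(image), 0.0, WORKING_SCALE).astype(np.uint8)
    iio.imwrite(os.fspath(path), quantized, extension=".png")
    return os.fspath(path)


def rgb_to_hsv(image: np.ndarray) -> np.ndarray:
    """Convert a working-scale RGB image to hexcone HSV on [0, 1].

    S = (max - min) / max (0 where max = 0) and V = max / 255. Returns
    an (h, w, 3) array with channels (H, S, V).
    """
    image = validate_rgb(image)
    return color.rgb2hsv(np.clip(image, 0.0, WORKING_SCALE) / WORKING_SCALE)


def hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_hsv`; returns RGB on the [0, 255] scale."""
    hsv = np.asarray(hsv, dtype=np.float64)
    if hsv.ndim != 3 or hsv.shape[2] != 3:
        raise ValueError(f"expected (h, w, 3) HSV array, got shape {hsv.shape}")
    return color.hsv2rgb(hsv) * WORKING_SCALE
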