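"""Image containers, grayscale conversion, tie-breaking noise, and PNG/JPEG I/O.

Images are plain numpy arrays throughout the package:

* RGB images are ``(H, W, 3)`` integer arrays with channels in ``[0, 255]``.
* Grayscale images are ``(H, W)`` float arrays on the ``[0, 1]`` scale.
* Binary masks are ``(H, W)`` boolean arrays.

The internal intensity scale is ``[0, 1]``: the linear luma formula is applied
on the byte scale and divided by 255, and full float precision is kept inside
the pipeline.  Quantization to 8-bit happens only when writing to disk.
"""

from __future__ import annotations

import math
import os

import numpy as np
from PIL import Image

__all__ = [
    "to_gray",
    "add_noise",
    "diagonal",
    "read_image",
    "write_gray",
    "write_mask",
    "validate_gray",
]

#: Coefficients of the standard linear RGB->luma converter, per mille.
LUMA_WEIGHTS = (299.0, 587.0, 114.0)


def validate_gray(img: np.ndarray) -> np.ndarray:
    """Check that ``img`` is a finite 2D grayscale array and return it as float64."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a non-empty 2D grayscale array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("grayscale image contains non-finite values")
    return arr


def diagonal(img: np.ndarray) -> float:
    """Diagonal length Delta(I) = sqrt(H^2 + W^2) of an image, in pixels."""
    h, w = np.asarray(img).shape[:2]
    return math.hypot(h, w)


def to_gray(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to grayscale on the [0, 1] scale.

    Uses the standard linear luma converter
    ``gray(p) = (299 R + 587 G + 114 B) / 1000`` on byte-valued channels,
    rescaled by 255 so that white maps to 1.0 and black to 0.0.  A channel-equal
    input (R = G = B = v) maps exactly to ``v / 255``.  2D inputs are assumed
    to already be grayscale: byte arrays are rescaled by 255, float arrays are
    validated and passed through.
    """
    arr = np.asarray(img)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 2:
        if np.issubdtype(arr.dtype, np.integer):
            return arr.astype(np.float64) / 255.0
        return validate_gray(arr)
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {arr.shape}")
    rgb = arr[..., :3].astype(np.float64)
    if rgb.min() < 0 or rgb.max() > 255:
        raise ValueError("RGB channel values must lie in [0, 255]")
    wr, wg, wb = LUMA_WEIGHTS
    luma = (wr * rgb[..., 0] + wg * rgb[..., 1] + wb * rgb[..., 2]) / 1000.0
    return luma / 255.0


def add_noise(
    img: np.ndarray,
    sigma: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise of standard deviation ``sigma``.

    The noise serves one purpose: making all pixel values distinct so that
    every birth in the persistence diagram maps to a unique pixel.  With
    ``sigma > 0`` uniqueness is verified and the noise is redrawn once if (with
    probability zero for continuous draws) duplicate values occur.  Values are
    not clamped to [0, 1]; the sublevel filtration is unaffected by range.

    ``seed`` may be an integer or a ``numpy.random.Generator`` so that a single
    generator can be threaded through a pipeline.
    """
    arr = validate_gray(img)
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return arr.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = arr + rng.normal(0.0, sigma, size=arr.shape)
    if np.unique(out).size != out.size:
        out = arr + rng.normal(0.0, sigma, size=arr.shape)
    return out


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/JPEG file.

    Returns an ``(H, W, 3)`` uint8 array for color images and an ``(H, W)``
    float array on [0, 1] for single-channel images.
    """
    with Image.open(path) as im:
        if im.mode in ("1", "L", "I", "I;16", "F"):
            gray = np.asarray(im.convert("F"), dtype=np.float64)
            if im.mode == "1":
                return np.asarray(im, dtype=np.float64)
            scale = 65535.0 if im.mode in ("I", "I;16") else 255.0
            if im.mode == "F":
                return gray
            return gray / scale
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def write_gray(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write a [0, 1] grayscale image as an 8-bit PNG (nearest-level quantization)."""
    arr = validate_gray(img)
    quantized = np.clip(np.rint(arr * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(quantized, mode="L").save(path)


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError("mask must be 2D")
    Image.fromarray((arr.astype(bool) * np.uint8(255)), mode="L").save(path)


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG mask as a boolean array (any nonzero pixel is True)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 127
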