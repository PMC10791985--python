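"""Canonical image representation and PNG persistence.

An Image is an (H, W, 3) float64 array with values in [0, 1], RGB channel
order. Quantisation to 8 bits happens only when writing PNG files.
"""

from __future__ import annotations

import os

import numpy as np
import imageio.v3 as iio

CANONICAL_DTYPE = np.float64


def validate_image(img: np.ndarray) -> np.ndarray:
    """Check shape/range and return the array as float64."""
    img = np.asarray(img, dtype=CANONICAL_DTYPE)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {img.shape}")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("image values outside canonical range [0, 1]")
    return img


def to_uint8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(np.asarray(img) * 255.0), 0, 255).astype(np.uint8)


def from_uint8(arr: np.ndarray) -> np.ndarray:
    return arr.astype(CANONICAL_DTYPE) / 255.0


def write_png(path: str | os.PathLike, img: np.ndarray) -> None:
    iio.imwrite(os.fspath(path), to_uint8(validate_image(img)), extension=".png")


def read_png(path: str | os.PathLike) -> np.ndarray:
    arr = iio.imread(os.fspath(path))
    if arr.ndim == 2:  # greyscale -> RGB
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return from_uint8(arr)


def as_batch(images: np.ndarray) -> np.ndarray:
    """(H,W,3) or (N,H,W,3) -> (N,H,W,3) float64 batch (the network layout)."""
    arr = np.asarray(images, dtype=CANONICAL_DTYPE)
    if arr.ndim == 3:
        arr = arr[None]
    return arr
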