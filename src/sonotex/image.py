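"""Grayscale image container and PNG/TIFF I/O.

All feature extraction in this package operates on :class:`GrayImage`: an
8-bit single-channel raster with an optional boolean region-of-interest mask
(``True`` = inside the liver).  Pixels outside the mask are never fed to any
feature counter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["GrayImage", "read_image", "write_image", "read_mask", "write_mask"]


@dataclass
class GrayImage:
    """2-D grid of 8-bit intensities with an optional binary ROI mask."""

    pixels: np.ndarray
    mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected 2-D pixel array, got shape {self.pixels.shape}")
        h, w = self.pixels.shape
        if h < 2 or w < 2:
            raise ValueError(f"image too small ({h}x{w}); need at least 2x2")
        if self.pixels.dtype != np.uint8:
            arr = np.asarray(self.pixels)
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.pixels = arr.astype(np.uint8)
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.pixels.shape:
                raise ValueError("mask dimensions must match image dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def masked_values(self) -> np.ndarray:
        """In-mask intensities as a flat array (all pixels if no mask)."""
        if self.mask is None:
            return self.pixels.ravel()
        return self.pixels[self.mask]

    def effective_mask(self) -> np.ndarray:
        """The ROI mask, or an all-true mask when none is attached."""
        if self.mask is None:
            return np.ones(self.pixels.shape, dtype=bool)
        return self.mask


def read_image(path: str | Path) -> GrayImage:
    """Read an 8-bit grayscale PNG/TIFF; non-grayscale input is converted."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        import warnings

        warnings.warn(f"{path}: non-grayscale input converted by channel averaging")
        arr = arr[..., :3].mean(axis=2)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255)
    return GrayImage(arr.astype(np.uint8))


def write_image(image: GrayImage, path: str | Path) -> None:
    iio.imwrite(path, image.pixels)


def read_mask(path: str | Path) -> np.ndarray:
    return iio.imread(path) > 127


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))
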