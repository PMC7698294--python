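"""Raster containers with physical resolution, plus disk I/O.

Convention used throughout the package: solid phase = 1 / True, pore
phase = 0 / False.  Grayscale images are floats in [0, 1], solid bright.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class ImageError(ValueError):
    """Raised for invalid image content or metadata."""


@dataclass
class BinaryImage:
    """2D binary raster; ``pixels`` boolean, True = solid."""

    pixels: np.ndarray
    resolution_um_per_px: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ImageError("binary image must be a non-empty 2D array")
        if self.pixels.dtype != bool:
            self.pixels = self.pixels.astype(bool)
        if not self.resolution_um_per_px > 0:
            raise ImageError("resolution_um_per_px must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area_um2(self) -> float:
        return self.resolution_um_per_px ** 2


@dataclass
class GrayImage:
    """2D grayscale raster with intensities in [0, 1]."""

    pixels: np.ndarray
    resolution_um_per_px: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ImageError("gray image must be a non-empty 2D array")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ImageError("gray image intensities must lie in [0, 1]")
        if not self.resolution_um_per_px > 0:
            raise ImageError("resolution_um_per_px must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def save_image(path: str | Path, image: BinaryImage | GrayImage) -> None:
    """Write a single-channel TIFF or PNG; resolution goes to a JSON sidecar."""
    path = Path(path)
    if isinstance(image, BinaryImage):
        arr = image.pixels.astype(np.uint8) * 255
    else:
        arr = np.clip(image.pixels * 255.0, 0, 255).round().astype(np.uint8)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"resolution_um_per_px": image.resolution_um_per_px})
    )


def load_image(
    path: str | Path, resolution_um_per_px: float | None = None
) -> GrayImage:
    """Read a raster as grayscale; resolution from argument or JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:  # collapse any channel axis
        arr = arr.mean(axis=-1)
    if arr.max() > 1:
        arr = arr / 255.0
    if resolution_um_per_px is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ImageError(
                f"no resolution given and no sidecar found for {path}"
            )
        resolution_um_per_px = json.loads(sidecar.read_text())[
            "resolution_um_per_px"
        ]
    return GrayImage(np.clip(arr, 0.0, 1.0), resolution_um_per_px)
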