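"""Micrograph segmentation and the image -> structure-metrics pathway."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .images import BinaryImage, GrayImage
from .structure_metrics import (
    StructureMetrics,
    compute_metrics,
    fiber_widths,
    pore_areas,
)


class SegmentationError(ValueError):
    pass


@dataclass
class SegmentationConfig:
    """Binarization settings.

    ``global-otsu`` picks the threshold maximising between-class variance;
    ``fixed-threshold`` uses ``threshold`` directly.  Components of either
    phase smaller than ``despeckle_min_px`` are merged into the
    surrounding phase.  ``invert`` flips the phases after thresholding
    (for micrographs where pores image bright).
    """

    method: str = "global-otsu"
    threshold: float | None = None
    despeckle_min_px: int = 4
    invert: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("global-otsu", "fixed-threshold"):
            raise SegmentationError(
                f"method {self.method!r} not in ('global-otsu', 'fixed-threshold')"
            )
        if self.method == "fixed-threshold":
            if self.threshold is None or not 0 < self.threshold < 1:
                raise SegmentationError(
                    "fixed-threshold mode requires threshold in (0, 1), "
                    f"got {self.threshold}"
                )
        if self.despeckle_min_px < 0:
            raise SegmentationError(
                f"despeckle_min_px must be >= 0, got {self.despeckle_min_px}"
            )


def _despeckle(solid: np.ndarray, min_px: int) -> np.ndarray:
    if min_px <= 1:
        return solid
    # speckles of the solid phase first, then of the void phase
    # (max_size removes components <= its value, i.e. strictly below min_px)
    solid = remove_small_objects(solid, max_size=min_px - 1, connectivity=2)
    void = remove_small_objects(~solid, max_size=min_px - 1, connectivity=2)
    return ~void


def binarize(
    gray: GrayImage | BinaryImage, cfg: SegmentationConfig | None = None
) -> BinaryImage:
    """Segment a grayscale image into solid (True) and pore (False)."""
    cfg = cfg or SegmentationConfig()
    if isinstance(gray, BinaryImage):
        pixels = gray.pixels.astype(float)
        res = gray.resolution_um_per_px
    else:
        pixels = gray.pixels
        res = gray.resolution_um_per_px
    if cfg.method == "global-otsu":
        if np.ptp(pixels) == 0:
            raise SegmentationError(
                "constant image: Otsu threshold undefined; use fixed-threshold"
            )
        thr = float(threshold_otsu(pixels))
    else:
        thr = float(cfg.threshold)
    solid = pixels > thr
    if cfg.invert:
        solid = ~solid
    solid = _despeckle(solid, cfg.despeckle_min_px)
    return BinaryImage(solid, res)


def stabilization_report(
    binary: BinaryImage, n_checkpoints: int = 10
) -> dict:
    """Running means of pore areas and fiber widths over growing
    subsamples, to show where the averages stabilise."""
    areas = pore_areas(binary)
    try:
        widths = fiber_widths(binary)
    except Exception:
        widths = np.array([])

    def running(values: np.ndarray) -> list[dict]:
        if values.size == 0:
            return []
        ns = np.unique(
            np.linspace(1, values.size, min(n_checkpoints, values.size))
            .round()
            .astype(int)
        )
        csum = np.cumsum(values)
        return [
            {"n": int(n), "mean": float(csum[n - 1] / n)} for n in ns
        ]

    return {
        "pore_area_running_mean_um2": running(np.asarray(areas)[::-1]),
        "fiber_width_running_mean_um": running(np.sort(widths)),
    }


def analyze_image(
    image: GrayImage | BinaryImage,
    resolution_um_per_px: float | None = None,
    cfg: SegmentationConfig | None = None,
) -> tuple[StructureMetrics, dict]:
    """Full micrograph analysis: segment (if grayscale) then measure.

    Returns the metrics and a stabilization report.  An explicit
    ``resolution_um_per_px`` overrides the one carried by the image.
    """
    cfg = cfg or SegmentationConfig()
    if resolution_um_per_px is not None:
        cls = BinaryImage if isinstance(image, BinaryImage) else GrayImage
        image = cls(image.pixels, resolution_um_per_px)
    if isinstance(image, BinaryImage):
        binary = (
            image
            if cfg.despeckle_min_px <= 1
            else BinaryImage(
                _despeckle(image.pixels, cfg.despeckle_min_px),
                image.resolution_um_per_px,
            )
        )
    else:
        binary = binarize(image, cfg)
    metrics = compute_metrics(binary)
    return metrics, stabilization_report(binary)
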