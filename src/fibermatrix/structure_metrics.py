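"""Structural morphometry of binary images and simulated structures.

Porosity, pore-area distributions (8-connected void components,
border-touching included) and fiber widths (skeleton + Euclidean
distance transform) for 2D binary images; bulk porosity and SEM-style
top views for 3D voxel structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .deposition_sim import Structure3D
from .images import BinaryImage, ImageError

# complementary connectivity pair: pores 8-connected, solid 4-connected
_PORE_STRUCTURE = np.ones((3, 3), dtype=int)


class MetricsError(ValueError):
    pass


@dataclass
class PoreStats:
    count: int
    min_um2: float
    max_um2: float
    p5_um2: float
    p95_um2: float
    mean_um2: float
    cv: float


@dataclass
class FiberWidthStats:
    n_samples: int
    min_um: float
    max_um: float
    mean_um: float
    p5_um: float
    p95_um: float


@dataclass
class StructureMetrics:
    surface_porosity: float
    resolution_um_per_px: float
    pore_areas_um2: list[float] = field(default_factory=list)
    pore_stats: PoreStats | None = None
    fiber_width_stats: FiberWidthStats | None = None
    bulk_porosity: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def surface_porosity(binary: BinaryImage) -> float:
    """Void-pixel fraction of a binary image (solid = 1 / pore = 0)."""
    if binary.pixels.size == 0:
        raise MetricsError("empty image")
    return float((~binary.pixels).mean())


def pore_areas(binary: BinaryImage) -> list[float]:
    """Areas (µm²) of 8-connected void components, border-touching
    included, sorted descending."""
    void = ~binary.pixels
    labels, n = ndimage.label(void, structure=_PORE_STRUCTURE)
    if n == 0:
        return []
    counts = np.bincount(labels.ravel())[1:]
    areas = counts * binary.pixel_area_um2
    return sorted(areas.tolist(), reverse=True)


def pore_statistics(areas: list[float]) -> PoreStats | None:
    if not areas:
        return None
    a = np.asarray(areas, dtype=float)
    mean = float(a.mean())
    # CV of a single pore is degenerate (always 0); report NaN so one-pore
    # images cannot win a uniformity comparison
    if len(areas) < 2 or mean <= 0:
        cv = float("nan")
    else:
        cv = float(a.std() / mean)
    return PoreStats(
        count=len(areas),
        min_um2=float(a.min()),
        max_um2=float(a.max()),
        p5_um2=float(np.percentile(a, 5)),
        p95_um2=float(np.percentile(a, 95)),
        mean_um2=mean,
        cv=cv,
    )


def fiber_widths(
    binary: BinaryImage, exclude_junctions: bool = False
) -> np.ndarray:
    """Per-skeleton-pixel fiber width sample (µm).

    The solid phase is thinned to a topology-preserving skeleton; at each
    skeleton pixel the local width is taken as 2*EDT - 1 pixels (exact
    for odd-width axis-aligned ribbons, within one pixel otherwise),
    where EDT is the Euclidean distance to the nearest void pixel.

    ``exclude_junctions`` drops skeleton pixels within the inscribed
    radius of each skeleton branch point, where crossing fibers inflate
    the local width; overlapping near-parallel fibers still merge and
    can read wider than any single fiber.
    """
    solid = binary.pixels
    if not solid.any():
        raise MetricsError("no solid phase: fiber width undefined")
    if solid.all():
        raise MetricsError("no void phase: fiber width undefined")
    skel = skeletonize(solid)
    if not skel.any():
        raise MetricsError("skeleton empty")
    edt = ndimage.distance_transform_edt(solid)
    if exclude_junctions:
        neighbours = (
            ndimage.convolve(skel.astype(int), np.ones((3, 3), int),
                             mode="constant")
            - skel
        )
        keep = skel.copy()
        ii, jj = np.meshgrid(
            np.arange(skel.shape[0]), np.arange(skel.shape[1]), indexing="ij"
        )
        for x, y in zip(*np.nonzero(skel & (neighbours >= 3))):
            r = edt[x, y] + 1
            keep &= (ii - x) ** 2 + (jj - y) ** 2 > r * r
        if keep.any():  # fall back to the full skeleton if nothing is left
            skel = keep
    widths_px = 2.0 * edt[skel] - 1.0
    return np.maximum(widths_px, 1.0) * binary.resolution_um_per_px


def fiber_width_statistics(sample_um: np.ndarray) -> FiberWidthStats:
    s = np.asarray(sample_um, dtype=float)
    return FiberWidthStats(
        n_samples=int(s.size),
        min_um=float(s.min()),
        max_um=float(s.max()),
        mean_um=float(s.mean()),
        p5_um=float(np.percentile(s, 5)),
        p95_um=float(np.percentile(s, 95)),
    )


def render_top_view(
    structure: Structure3D, depth_voxels: int | None = None
) -> BinaryImage:
    """Binary top view: a column reads solid iff it holds solid within
    ``depth_voxels`` of the global top (an SEM visibility-depth
    surrogate).  Default depth is 2x the median fiber vertical thickness.
    """
    if depth_voxels is None:
        depth_voxels = 2 * structure.median_fiber_thickness_vox()
    if depth_voxels < 1:
        raise MetricsError(f"depth_voxels must be >= 1, got {depth_voxels}")
    h = structure.height_map
    hmax = int(h.max())
    if hmax == 0:
        solid = np.zeros_like(h, dtype=bool)
    else:
        # topmost solid voxel of column (i,j) sits at z = h - 1;
        # empty columns stay void regardless of depth
        solid = (h > 0) & (h - 1 >= hmax - depth_voxels)
    return BinaryImage(solid, structure.resolution_um_per_voxel)


def bulk_porosity(structure: Structure3D, convention: str = "covered") -> float:
    """Volumetric porosity of the structure inside its thickness envelope.

    ``covered`` (default): envelope = covered columns x their mean height;
    ``full``: envelope = all columns x the mean height of covered columns.
    """
    if convention not in ("covered", "full"):
        raise MetricsError(f"unknown convention {convention!r}")
    h = structure.height_map
    covered = h > 0
    n_covered = int(covered.sum())
    if n_covered == 0:
        raise MetricsError("empty structure: bulk porosity undefined")
    z_mean = float(h[covered].mean())
    solid = structure.solid_voxel_count
    if convention == "covered":
        envelope = n_covered * z_mean
    else:
        envelope = h.size * z_mean
    return max(0.0, 1.0 - solid / envelope)


def compute_metrics(
    binary: BinaryImage,
    structure: Structure3D | None = None,
    bulk_convention: str = "covered",
) -> StructureMetrics:
    """All image-level metrics for one binary image, plus bulk porosity
    when the originating 3D structure is supplied.

    Fiber-width stats are left None when undefined (all-solid or
    all-void image) rather than raising, so batch runs degrade gracefully.
    """
    areas = pore_areas(binary)
    try:
        width_stats = fiber_width_statistics(fiber_widths(binary))
    except MetricsError:
        width_stats = None
    return StructureMetrics(
        surface_porosity=surface_porosity(binary),
        resolution_um_per_px=binary.resolution_um_per_px,
        pore_areas_um2=areas,
        pore_stats=pore_statistics(areas),
        fiber_width_stats=width_stats,
        bulk_porosity=(
            bulk_porosity(structure, bulk_convention)
            if structure is not None
            else None
        ),
    )
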