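"""Synthetic inputs with exact ground truth.

Everything the downstream pipeline consumes can be generated here:
fiber populations spanning a configured width range, and phantom
binary/grayscale images whose porosity and pore geometry are known by
construction, so segmentation and morphometry are testable end to end
without external micrographs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .deposition_sim import FiberMorphology
from .images import BinaryImage, GrayImage
from .population import (
    FiberPopulationSpec,
    SpecValidationError,
    sample_widths,
)

__all__ = [
    "FiberPopulationSpec",
    "SpecValidationError",
    "PoreShape",
    "PhantomSpec",
    "GroundTruth",
    "sample_fiber_population",
    "make_phantom_binary",
    "render_sem_like",
]


@dataclass
class PoreShape:
    """One requested pore: ``disc`` (size = diameter) or ``rectangle``
    (size = (width, height)); sizes in µm.  ``position_um`` is the shape
    centre, or None for random placement."""

    shape: str
    size_um: tuple
    position_um: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("disc", "rectangle"):
            raise SpecValidationError(
                f"pore shape: {self.shape!r} not in ('disc', 'rectangle')"
            )
        sizes = (
            self.size_um if isinstance(self.size_um, (tuple, list))
            else (self.size_um,)
        )
        if any(s <= 0 for s in sizes):
            raise SpecValidationError(f"pore size_um: must be > 0, got {self.size_um}")
        self.size_um = tuple(sizes)


@dataclass
class PhantomSpec:
    image_shape_px: tuple[int, int]
    resolution_um_per_px: float
    pore_shapes: list[PoreShape] = field(default_factory=list)
    background: str = "solid"
    background_solid_fraction: float = 0.65
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        h, w = self.image_shape_px
        if h < 1 or w < 1:
            raise SpecValidationError(
                f"image_shape_px: must be positive, got {self.image_shape_px}"
            )
        if not self.resolution_um_per_px > 0:
            raise SpecValidationError(
                f"resolution_um_per_px: must be > 0, got {self.resolution_um_per_px}"
            )
        if self.background not in ("solid", "fibrous-texture"):
            raise SpecValidationError(
                f"background: {self.background!r} not in ('solid', 'fibrous-texture')"
            )
        self.pore_shapes = [
            p if isinstance(p, PoreShape) else PoreShape(**p)
            for p in self.pore_shapes
        ]


@dataclass
class GroundTruth:
    true_porosity: float
    true_pore_areas_um2: list[float]
    true_fiber_widths_um: list[float] | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "true_porosity": self.true_porosity,
                    "pore_areas_um2": list(self.true_pore_areas_um2),
                    "fiber_widths_um": self.true_fiber_widths_um,
                },
                indent=2,
            )
        )


def sample_fiber_population(
    spec: FiberPopulationSpec, n: int, seed: int
) -> list[FiberMorphology]:
    """Sample ``n`` fibers; widths follow the spec's width law, lengths are
    aspect_ratio x width, all other dimensions copied from the spec."""
    if n < 1:
        raise SpecValidationError(f"n: must be >= 1, got {n}")
    spec.validate()
    rng = np.random.default_rng(seed)
    widths = sample_widths(rng, spec, n)
    return [
        FiberMorphology(
            width_um=float(w),
            length_um=float(spec.aspect_ratio * w),
            wall_thickness_um=spec.wall_thickness_um,
            lumen_um=spec.lumen_um,
            flexibility=int(spec.flexibility),
        )
        for w in widths
    ]


def _pore_mask(
    pore: PoreShape, shape_px: tuple[int, int], res: float,
    center_px: tuple[float, float],
) -> np.ndarray:
    h, w = shape_px
    ci, cj = center_px
    ii, jj = np.ogrid[0:h, 0:w]
    if pore.shape == "disc":
        r_px = pore.size_um[0] / 2.0 / res
        return (ii - ci) ** 2 + (jj - cj) ** 2 <= r_px**2
    ph = pore.size_um[0] / res  # rectangle extent along axis 0
    pw = (pore.size_um[1] if len(pore.size_um) > 1 else pore.size_um[0]) / res
    return (np.abs(ii - ci) < ph / 2.0) & (np.abs(jj - cj) < pw / 2.0)


def _fibrous_background(
    shape_px: tuple[int, int], solid_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Random thick line segments on void until the target solid fraction."""
    h, w = shape_px
    solid = np.zeros(shape_px, dtype=bool)
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    guard = 0
    while solid.mean() < solid_fraction and guard < 10_000:
        guard += 1
        ci, cj = rng.uniform(0, h), rng.uniform(0, w)
        angle = rng.uniform(0, math.pi)
        length = rng.uniform(0.3, 1.0) * max(h, w)
        width = rng.uniform(1.5, 6.0)
        c, s = math.cos(angle), math.sin(angle)
        u = (ii - ci) * c + (jj - cj) * s
        v = -(ii - ci) * s + (jj - cj) * c
        solid |= (np.abs(u) <= length / 2) & (np.abs(v) <= width / 2)
    return solid


def make_phantom_binary(
    spec: PhantomSpec, seed: int = 0
) -> tuple[BinaryImage, GroundTruth]:
    """Build a phantom binary image (1 = solid, 0 = pore) plus its exact
    ground truth.

    Requested pores are carved out of the background.  Unless
    ``allow_overlap`` is set, pores must stay disjoint and separated by
    at least one pixel so each survives as a distinct connected
    component; randomly placed pores are rejection-sampled to satisfy
    this and explicit overlapping positions raise an error.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.image_shape_px
    res = spec.resolution_um_per_px
    if spec.background == "solid":
        solid = np.ones((h, w), dtype=bool)
    else:
        solid = _fibrous_background(
            (h, w), spec.background_solid_fraction, rng
        )

    taken = np.zeros((h, w), dtype=bool)  # pore pixels + 1-px guard ring
    pore_areas: list[float] = []
    for k, pore in enumerate(spec.pore_shapes):
        if pore.position_um is not None:
            ci = pore.position_um[0] / res
            cj = pore.position_um[1] / res
            mask = _pore_mask(pore, (h, w), res, (ci, cj))
            if not spec.allow_overlap and (mask & taken).any():
                raise SpecValidationError(
                    f"pore_shapes[{k}]: overlaps a previous pore but "
                    "allow_overlap is False"
                )
        else:
            mask = None
            for _ in range(200):
                ci, cj = rng.uniform(0, h), rng.uniform(0, w)
                cand = _pore_mask(pore, (h, w), res, (ci, cj))
                if spec.allow_overlap or not (cand & taken).any():
                    mask = cand
                    break
            if mask is None:
                raise SpecValidationError(
                    f"pore_shapes[{k}]: could not place without overlap "
                    "after 200 attempts"
                )
        if not mask.any():
            raise SpecValidationError(
                f"pore_shapes[{k}]: lies outside the image"
            )
        solid &= ~mask
        pore_areas.append(float(mask.sum()) * res * res)
        taken |= ndimage.binary_dilation(
            mask, structure=np.ones((3, 3), dtype=bool)
        )

    if spec.background == "solid":
        truth_areas = sorted(pore_areas, reverse=True)
    else:
        # fibrous background: pores merge with background void; report
        # the actual connected void components instead
        lab, n = ndimage.label(~solid, structure=np.ones((3, 3), dtype=int))
        counts = np.bincount(lab.ravel())[1:]
        truth_areas = sorted((counts * res * res).tolist(), reverse=True)

    porosity = float((~solid).sum()) / solid.size
    return (
        BinaryImage(solid, res),
        GroundTruth(true_porosity=porosity, true_pore_areas_um2=truth_areas),
    )


def render_sem_like(
    binary: BinaryImage,
    blur_sigma_px: float,
    noise_sd: float,
    seed: int = 0,
) -> GrayImage:
    """Grayscale stand-in for an SEM micrograph: solid bright, optional
    Gaussian blur then additive Gaussian noise, clipped to [0, 1].

    With blur 0 and noise 0 the result equals the binary image cast to
    {0, 1} exactly.
    """
    if blur_sigma_px < 0:
        raise ValueError(f"blur_sigma_px must be >= 0, got {blur_sigma_px}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    gray = binary.pixels.astype(float)
    if blur_sigma_px > 0:
        gray = ndimage.gaussian_filter(gray, blur_sigma_px, mode="reflect")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        gray = gray + rng.normal(0.0, noise_sd, size=gray.shape)
    return GrayImage(np.clip(gray, 0.0, 1.0), binary.resolution_um_per_px)
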