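"""Sequential voxel deposition of fibers onto a 3D discrete grid.

Each fiber is a straight ribbon of voxels (length x width footprint,
vertical solid thickness from the wall/lumen geometry).  A depositing
fiber drapes onto the structure under a flexibility constraint: its
bottom surface must clear the current height map and may change by at
most F voxels per lateral step inside the footprint, and it takes the
minimal such surface (rigid bridging at F = 0, full conformation as
F grows).  Fibers stack without interpenetrating, so solid volume is
conserved exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .population import FiberPopulationSpec, sample_widths

_NEIGHBOR_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]

_MAX_DRAPE_ITER = 100_000


class SimulationError(RuntimeError):
    pass


@dataclass
class FiberMorphology:
    """Dimensional parameters of a single fiber.

    ``flexibility`` is the maximum vertical drop in voxels per lateral
    voxel step during draping.  The vertical extent of the deposited
    fiber is 2*wall + lumen when the lumen is open, 2*wall when
    collapsed; an open lumen stays void (counted as pore space).
    """

    width_um: float
    length_um: float
    wall_thickness_um: float
    lumen_um: float = 0.0
    flexibility: int = 0
    lumen_open: bool = False

    def __post_init__(self) -> None:
        if not self.width_um > 0:
            raise ValueError(f"width_um must be > 0, got {self.width_um}")
        if not self.length_um > 0:
            raise ValueError(f"length_um must be > 0, got {self.length_um}")
        if not self.wall_thickness_um > 0:
            raise ValueError(
                f"wall_thickness_um must be > 0, got {self.wall_thickness_um}"
            )
        if self.lumen_um < 0:
            raise ValueError(f"lumen_um must be >= 0, got {self.lumen_um}")
        if self.flexibility < 0:
            raise ValueError(
                f"flexibility must be >= 0, got {self.flexibility}"
            )

    @property
    def vertical_extent_um(self) -> float:
        if self.lumen_open and self.lumen_um > 0:
            return 2 * self.wall_thickness_um + self.lumen_um
        return 2 * self.wall_thickness_um


@dataclass
class FiberRecord:
    placed: bool
    voxels: int
    footprint_px: int
    center: tuple[float, float]
    angle_rad: float
    t_vox: int
    bottom_min: int
    bottom_max: int
    reason: str | None = None


@dataclass
class SimConfig:
    domain_px: tuple[int, int]
    resolution_um_per_voxel: float
    target_layers: float
    population: FiberPopulationSpec
    seed: int = 0
    boundary: str = "periodic"
    open_lumen: bool = False
    max_fibers: int = 200_000
    top_view_depth_voxels: int | None = None

    def __post_init__(self) -> None:
        nx, ny = self.domain_px
        if nx < 16 or ny < 16:
            raise ValueError(f"domain_px must be >= 16 per side, got {nx}x{ny}")
        if not self.resolution_um_per_voxel > 0:
            raise ValueError("resolution_um_per_voxel must be > 0")
        if not self.target_layers > 0:
            raise ValueError("target_layers must be > 0")
        if self.boundary not in ("periodic", "clipped"):
            raise ValueError(f"boundary must be periodic|clipped, got {self.boundary}")

    def to_dict(self) -> dict:
        return {
            "domain_px": list(self.domain_px),
            "resolution_um_per_voxel": self.resolution_um_per_voxel,
            "target_layers": self.target_layers,
            "population": self.population.to_dict(),
            "seed": self.seed,
            "boundary": self.boundary,
            "open_lumen": self.open_lumen,
            "max_fibers": self.max_fibers,
            "top_view_depth_voxels": self.top_view_depth_voxels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["domain_px"] = tuple(d["domain_px"])
        d["population"] = FiberPopulationSpec.from_dict(d["population"])
        return cls(**d)


class Structure3D:
    """Voxel occupancy grid (x, y, z), z = thickness direction, z=0 substrate.

    ``height_map[i, j]`` is 1 + the top occupied z for non-empty columns,
    0 for empty columns.  ``fiber_log`` records every placement attempt.
    """

    def __init__(
        self, nx: int, ny: int, resolution_um_per_voxel: float, nz: int = 8
    ) -> None:
        self.occupancy = np.zeros((nx, ny, nz), dtype=bool)
        self.height_map = np.zeros((nx, ny), dtype=np.int64)
        self.fiber_log: list[FiberRecord] = []
        self.resolution_um_per_voxel = float(resolution_um_per_voxel)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def solid_voxel_count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def placed_fiber_count(self) -> int:
        return sum(1 for r in self.fiber_log if r.placed)

    def _ensure_z(self, z_needed: int) -> None:
        nz = self.occupancy.shape[2]
        if z_needed > nz:
            new_nz = max(z_needed, 2 * nz)
            pad = np.zeros(
                (self.occupancy.shape[0], self.occupancy.shape[1], new_nz - nz),
                dtype=bool,
            )
            self.occupancy = np.concatenate([self.occupancy, pad], axis=2)

    def median_fiber_thickness_vox(self) -> int:
        ts = [r.t_vox for r in self.fiber_log if r.placed]
        if not ts:
            return 1
        return int(np.median(ts))


def _ribbon_pixels(
    l_vox: int, w_vox: int, center: tuple[float, float], angle: float
) -> np.ndarray:
    """Integer lattice footprint of an l x w ribbon centred at ``center``.

    Sampled at half-pixel pitch so rotated ribbons have no holes; exact
    l x w rectangle for axis-aligned placements at integer centres.
    Returns unique (n, 2) int coordinates, unwrapped (may be negative).
    """
    us = np.linspace(-(l_vox - 1) / 2.0, (l_vox - 1) / 2.0, 2 * l_vox - 1)
    vs = np.linspace(-(w_vox - 1) / 2.0, (w_vox - 1) / 2.0, 2 * w_vox - 1)
    uu, vv = np.meshgrid(us, vs, indexing="ij")
    c, s = math.cos(angle), math.sin(angle)
    xs = center[0] + uu * c - vv * s
    ys = center[1] + uu * s + vv * c
    # half-up rounding (np.round would round ties to even)
    x = np.floor(xs + 0.5).astype(np.int64).ravel()
    y = np.floor(ys + 0.5).astype(np.int64).ravel()
    # bitmap dedupe over the bounding box: much faster than a row sort
    xmin, ymin = x.min(), y.min()
    grid = np.zeros((x.max() - xmin + 1, y.max() - ymin + 1), dtype=bool)
    grid[x - xmin, y - ymin] = True
    gx, gy = np.nonzero(grid)
    return np.stack([gx + xmin, gy + ymin], axis=1)


def _footprint_edges(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Directed 8-neighbour adjacency among footprint pixels (by index)."""
    xmin = pts[:, 0].min()
    ymin = pts[:, 1].min()
    w = pts[:, 0].max() - xmin + 1
    h = pts[:, 1].max() - ymin + 1
    grid = np.full((w + 2, h + 2), -1, dtype=np.int64)
    gx = pts[:, 0] - xmin + 1
    gy = pts[:, 1] - ymin + 1
    grid[gx, gy] = np.arange(len(pts))
    src_list, dst_list = [], []
    for dx, dy in _NEIGHBOR_OFFSETS:
        nb = grid[gx + dx, gy + dy]
        ok = nb >= 0
        src_list.append(nb[ok])
        dst_list.append(np.arange(len(pts))[ok])
    return np.concatenate(src_list), np.concatenate(dst_list)


def _drape_surface(
    pts: np.ndarray, heights: np.ndarray, flexibility: int
) -> np.ndarray:
    """Minimal bottom surface b >= heights with |b(p) - b(q)| <= F for
    8-adjacent footprint pixels p, q.

    Computed by monotone fixed-point relaxation upward from ``heights``;
    the limit is b(p) = max_q (heights(q) - F * d(p, q)) with d the
    footprint graph distance, i.e. the least admissible surface.
    """
    if flexibility <= 0 or len(pts) == 1:
        return np.full(len(pts), heights.max(), dtype=np.int64)
    src, dst = _footprint_edges(pts)
    b = heights.astype(np.int64).copy()
    for _ in range(_MAX_DRAPE_ITER):
        nb = b.copy()
        np.maximum.at(nb, dst, b[src] - flexibility)
        if np.array_equal(nb, b):
            return b
        b = nb
    raise SimulationError("drape relaxation failed to converge")


def place_fiber(
    structure: Structure3D,
    fiber: FiberMorphology,
    center: tuple[float, float],
    angle: float,
    boundary: str = "periodic",
) -> Structure3D:
    """Deposit one fiber; mutates and returns ``structure``.

    A rejected placement (empty footprint after clipping) is recorded in
    ``fiber_log`` with ``placed=False`` and a reason.
    """
    res = structure.resolution_um_per_voxel
    nx, ny = structure.height_map.shape
    l_vox = max(1, round(fiber.length_um / res))
    w_vox = max(1, round(fiber.width_um / res))
    wall_vox = max(1, round(fiber.wall_thickness_um / res))

    pts = _ribbon_pixels(l_vox, w_vox, center, angle)
    if boundary == "periodic":
        ix = np.mod(pts[:, 0], nx)
        iy = np.mod(pts[:, 1], ny)
        # drop pixels wrapping onto an already-used column of this fiber
        keys = ix * ny + iy
        _, first = np.unique(keys, return_index=True)
        if len(first) < len(pts):
            first.sort()
            pts, ix, iy = pts[first], ix[first], iy[first]
    else:
        inside = (
            (pts[:, 0] >= 0) & (pts[:, 0] < nx)
            & (pts[:, 1] >= 0) & (pts[:, 1] < ny)
        )
        pts = pts[inside]
        if len(pts) == 0:
            structure.fiber_log.append(
                FiberRecord(
                    placed=False, voxels=0, footprint_px=0, center=center,
                    angle_rad=angle, t_vox=0, bottom_min=0, bottom_max=0,
                    reason="footprint empty after clipping",
                )
            )
            return structure
        ix, iy = pts[:, 0], pts[:, 1]

    heights = structure.height_map[ix, iy]
    b = _drape_surface(pts, heights, int(fiber.flexibility))

    open_lumen = fiber.lumen_open and fiber.lumen_um > 0
    lumen_vox = round(fiber.lumen_um / res) if open_lumen else 0
    if open_lumen and lumen_vox > 0:
        slabs = [(0, wall_vox), (wall_vox + lumen_vox, 2 * wall_vox + lumen_vox)]
        extent = 2 * wall_vox + lumen_vox
    else:
        extent = max(1, round(fiber.vertical_extent_um / res))
        slabs = [(0, extent)]

    top = int(b.max()) + extent
    structure._ensure_z(top)
    solid_per_column = 0
    for z0, z1 in slabs:
        solid_per_column += z1 - z0
        for k in range(z0, z1):
            structure.occupancy[ix, iy, b + k] = True
    structure.height_map[ix, iy] = b + extent
    structure.fiber_log.append(
        FiberRecord(
            placed=True,
            voxels=int(len(pts) * solid_per_column),
            footprint_px=int(len(pts)),
            center=tuple(center),
            angle_rad=float(angle),
            t_vox=int(extent),
            bottom_min=int(b.min()),
            bottom_max=int(b.max()),
        )
    )
    return structure


def simulate_structure(config: SimConfig) -> Structure3D:
    """Deposit fibers sampled from the population until the mean areal
    coverage (sum of footprint areas / domain area) reaches
    ``target_layers``.  Deterministic for a fixed config seed."""
    rng = np.random.default_rng(config.seed)
    nx, ny = config.domain_px
    st = Structure3D(nx, ny, config.resolution_um_per_voxel)
    pop = config.population
    domain_area = nx * ny
    coverage = 0.0
    attempts = 0
    while coverage < config.target_layers:
        if attempts >= config.max_fibers:
            raise SimulationError(
                f"fiber cap {config.max_fibers} reached at coverage "
                f"{coverage:.3f} < target {config.target_layers} "
                f"({st.placed_fiber_count} placed)"
            )
        width = float(sample_widths(rng, pop, 1)[0])
        fiber = FiberMorphology(
            width_um=width,
            length_um=pop.aspect_ratio * width,
            wall_thickness_um=pop.wall_thickness_um,
            lumen_um=pop.lumen_um,
            flexibility=int(pop.flexibility),
            lumen_open=config.open_lumen,
        )
        center = (rng.uniform(0, nx), rng.uniform(0, ny))
        angle = rng.uniform(0, math.pi)
        place_fiber(st, fiber, center, angle, boundary=config.boundary)
        rec = st.fiber_log[-1]
        if rec.placed:
            coverage += rec.footprint_px / domain_area
        attempts += 1
    return st


def top_height_map(structure: Structure3D) -> np.ndarray:
    """Recompute per-column top heights from the occupancy grid.

    Must equal the incrementally maintained ``height_map`` exactly.
    """
    occ = structure.occupancy
    nz = occ.shape[2]
    any_solid = occ.any(axis=2)
    top = nz - np.argmax(occ[:, :, ::-1], axis=2)
    return np.where(any_solid, top, 0).astype(np.int64)
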