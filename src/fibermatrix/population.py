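"""Fiber population parameterisation and width-law sampling.

A :class:`FiberPopulationSpec` describes one statistical class of fibers:
the lateral width range and its distribution law, the length/width aspect
ratio, the wall thickness and lumen, and an integer flexibility bounding
vertical deflection per lateral voxel step during deposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

WIDTH_LAWS = ("log-uniform", "log-normal", "two-mode")


class SpecValidationError(ValueError):
    """Invalid population / phantom specification; names the offending field."""


@dataclass
class FiberPopulationSpec:
    width_range_um: tuple[float, float]
    width_law: str = "log-uniform"
    aspect_ratio: float = 50.0
    wall_thickness_um: float = 0.2
    lumen_um: float = 0.0
    flexibility: int = 0
    mixture_weight: float = 0.5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        lo, hi = self.width_range_um
        if not (lo > 0 and lo <= hi):
            raise SpecValidationError(
                f"width_range_um: need 0 < min <= max, got ({lo}, {hi})"
            )
        if self.width_law not in WIDTH_LAWS:
            raise SpecValidationError(
                f"width_law: {self.width_law!r} not in {WIDTH_LAWS}"
            )
        if self.aspect_ratio < 1:
            raise SpecValidationError(
                f"aspect_ratio: must be >= 1, got {self.aspect_ratio}"
            )
        if not self.wall_thickness_um > 0:
            raise SpecValidationError(
                f"wall_thickness_um: must be > 0, got {self.wall_thickness_um}"
            )
        if self.lumen_um < 0:
            raise SpecValidationError(
                f"lumen_um: must be >= 0, got {self.lumen_um}"
            )
        if self.flexibility < 0 or int(self.flexibility) != self.flexibility:
            raise SpecValidationError(
                f"flexibility: must be a non-negative integer, got {self.flexibility}"
            )
        if not 0 <= self.mixture_weight <= 1:
            raise SpecValidationError(
                f"mixture_weight: must be in [0, 1], got {self.mixture_weight}"
            )

    def to_dict(self) -> dict:
        return {
            "width_range_um": list(self.width_range_um),
            "width_law": self.width_law,
            "aspect_ratio": self.aspect_ratio,
            "wall_thickness_um": self.wall_thickness_um,
            "lumen_um": self.lumen_um,
            "flexibility": int(self.flexibility),
            "mixture_weight": self.mixture_weight,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FiberPopulationSpec":
        d = dict(d)
        d["width_range_um"] = tuple(d["width_range_um"])
        return cls(**d)


def sample_widths(
    rng: np.random.Generator, spec: FiberPopulationSpec, n: int
) -> np.ndarray:
    """Draw ``n`` fiber widths (µm) from the spec's width law.

    All laws are supported on exactly [min, max]:

    * ``log-uniform`` — uniform in log-width over the range.
    * ``log-normal`` — normal in log-width centred on the geometric mean
      with sigma = span/4, truncated to the range by clipping.
    * ``two-mode`` — mixture of two log-uniform modes split at the
      geometric mean of the range; ``mixture_weight`` is the fraction of
      draws from the nano (lower) mode.
    """
    lo, hi = spec.width_range_um
    if lo == hi:
        return np.full(n, float(lo))
    llo, lhi = math.log(lo), math.log(hi)
    if spec.width_law == "log-uniform":
        logw = rng.uniform(llo, lhi, size=n)
    elif spec.width_law == "log-normal":
        mu = 0.5 * (llo + lhi)
        sigma = (lhi - llo) / 4.0
        logw = np.clip(rng.normal(mu, sigma, size=n), llo, lhi)
    else:  # two-mode
        lsplit = 0.5 * (llo + lhi)
        nano = rng.random(n) < spec.mixture_weight
        logw = np.where(
            nano,
            rng.uniform(llo, lsplit, size=n),
            rng.uniform(lsplit, lhi, size=n),
        )
    # exp(log(lo)) can undershoot lo by one ulp: clip to the exact bounds
    return np.clip(np.exp(logw), lo, hi)
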