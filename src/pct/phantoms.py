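"""Analytic RSP phantoms voxelized onto a grid.

A phantom is a background RSP plus a list of solid elements (cylinders with
axis along the vertical ``y`` axis, or axis-aligned boxes).  Later elements
override earlier ones where they overlap, so an insert phantom is written as
a large cylinder followed by small insert cylinders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import RSPVolume, VoxelGrid

__all__ = ["PhantomElement", "PhantomSpec", "make_phantom", "water_cylinder"]


@dataclass(frozen=True)
class PhantomElement:
    """One solid of uniform RSP.

    ``shape`` is ``"cylinder"`` (axis along y; dimensions = (diameter, height))
    or ``"box"`` (dimensions = full edge lengths (dx, dy, dz)).  ``center`` is
    the element center in object-frame mm.
    """

    shape: str
    center: tuple[float, float, float]
    dimensions: tuple[float, ...]
    rsp: float

    def __post_init__(self) -> None:
        if self.shape not in ("cylinder", "box"):
            raise ValueError(f"unknown phantom shape {self.shape!r}")
        n_expected = 2 if self.shape == "cylinder" else 3
        if len(self.dimensions) != n_expected:
            raise ValueError(
                f"{self.shape} needs {n_expected} dimensions, got {self.dimensions}"
            )
        if any(not d > 0 for d in self.dimensions):
            raise ValueError(f"dimensions must be > 0, got {self.dimensions}")
        if self.rsp < 0:
            raise ValueError(f"rsp must be >= 0, got {self.rsp}")


@dataclass(frozen=True)
class PhantomSpec:
    """Background RSP plus overriding elements (later wins on overlap)."""

    elements: tuple[PhantomElement, ...] = ()
    background_rsp: float = 0.0

    def __post_init__(self) -> None:
        if self.background_rsp < 0:
            raise ValueError("background_rsp must be >= 0")
        object.__setattr__(self, "elements", tuple(self.elements))

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray] | None:
        """Axis-aligned bounding box over all elements, or None if empty."""
        if not self.elements:
            return None
        lows, highs = [], []
        for el in self.elements:
            c = np.asarray(el.center, dtype=float)
            if el.shape == "cylinder":
                d, h = el.dimensions
                half = np.array([d / 2, h / 2, d / 2])
            else:
                half = np.asarray(el.dimensions, dtype=float) / 2
            lows.append(c - half)
            highs.append(c + half)
        return np.min(lows, axis=0), np.max(highs, axis=0)


def make_phantom(spec: PhantomSpec, grid: VoxelGrid) -> RSPVolume:
    """Voxelize a phantom: each voxel takes the spec RSP at its center.

    The grid must cover the bounding box of the phantom elements (otherwise
    part of the object would be silently cut off and line integrals through
    the volume would be wrong).
    """
    if not isinstance(spec, PhantomSpec):
        raise TypeError("spec must be a PhantomSpec")
    bbox = spec.bounding_box()
    if bbox is not None and not grid.contains_box(*bbox):
        raise ValueError(
            "grid does not cover the phantom bounding box "
            f"{bbox[0]}..{bbox[1]} (grid extent {grid.extent[0]}..{grid.extent[1]})"
        )
    x, y, z = grid.center_mesh()
    data = np.full(grid.shape, float(spec.background_rsp))
    for el in spec.elements:
        cx, cy, cz = el.center
        if el.shape == "cylinder":
            diameter, height = el.dimensions
            inside = ((x - cx) ** 2 + (z - cz) ** 2 <= (diameter / 2) ** 2) & (
                np.abs(y - cy) <= height / 2
            )
        else:
            dx, dy, dz = el.dimensions
            inside = (
                (np.abs(x - cx) <= dx / 2)
                & (np.abs(y - cy) <= dy / 2)
                & (np.abs(z - cz) <= dz / 2)
            )
        data = np.where(inside, el.rsp, data)
    return RSPVolume(grid=grid, data=data)


def water_cylinder(diameter_mm: float = 180.0, height_mm: float = 16.0,
                   rsp: float = 1.0) -> PhantomSpec:
    """A uniform water cylinder centered at the isocenter, axis along y."""
    return PhantomSpec(
        elements=(PhantomElement("cylinder", (0.0, 0.0, 0.0),
                                 (diameter_mm, height_mm), rsp),),
        background_rsp=0.0,
    )
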