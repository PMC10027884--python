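"""Dose/density grid container and the flat binary + JSON-header file format.

A volume ``name`` is stored as two files: ``name.f64`` (the voxel values as
a flat little-endian array, C order, axis order x, y, z) and ``name.json``
(shape, spacing_mm, origin_mm, dtype).  The format is bit-exact and
deliberately trivial so any tool can read it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .geometry import GridSpec

__all__ = ["DoseGrid", "write_volume", "read_volume", "sample_trilinear"]


@dataclass
class DoseGrid:
    """A 3D scalar dose field (Gy) on a regular voxel lattice."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    def sample(self, points, clamp: bool = False) -> np.ndarray:
        """Trilinear interpolation of the field at world points (mm)."""
        return sample_trilinear(self.grid, self.values, points, clamp=clamp)

    @property
    def max(self) -> float:
        return float(self.values.max())


def sample_trilinear(grid: GridSpec, values: np.ndarray, points, clamp: bool = False) -> np.ndarray:
    """Trilinear lookup of gridded values at world points.

    With ``clamp=True`` queries outside the grid are clamped to the nearest
    voxel centre; otherwise they raise.
    """
    axes = tuple(grid.axis(d) for d in range(3))
    interp = RegularGridInterpolator(axes, values, method="linear", bounds_error=not clamp, fill_value=None)
    p = np.asarray(points, dtype=float)
    if clamp:
        lo = np.array([a[0] for a in axes])
        hi = np.array([a[-1] for a in axes])
        p = np.clip(p, lo, hi)
    return interp(p)


def write_volume(basepath, grid: GridSpec, values: np.ndarray) -> None:
    """Write a volume as ``<basepath>.f64`` + ``<basepath>.json``."""
    base = Path(basepath)
    arr = np.ascontiguousarray(np.asarray(values, dtype="<f8"))
    if arr.shape != grid.shape:
        raise ValueError("values shape does not match grid")
    base.with_suffix(".f64").write_bytes(arr.tobytes())
    header = {
        "shape": list(grid.shape),
        "spacing_mm": list(grid.spacing_mm),
        "origin_mm": list(grid.origin_mm),
        "dtype": "<f8",
        "order": "C",
        "axes": "xyz",
    }
    base.with_suffix(".json").write_text(json.dumps(header, indent=2))


def read_volume(basepath):
    """Read a volume written by :func:`write_volume`; returns (GridSpec, ndarray)."""
    base = Path(basepath)
    header = json.loads(base.with_suffix(".json").read_text())
    grid = GridSpec(tuple(header["shape"]), tuple(header["spacing_mm"]), tuple(header["origin_mm"]))
    raw = np.frombuffer(base.with_suffix(".f64").read_bytes(), dtype=header["dtype"])
    return grid, raw.reshape(grid.shape).astype(float)
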