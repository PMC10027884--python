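"""Coordinate systems, detector-array lattices, and gantry rotation.

World frame conventions
-----------------------
* Lengths are millimetres, angles radians, isocenter at the origin.
* The gantry (and the measuring plane of a phantom-mounted array) rotates
  about the ``z`` axis, which coincides with the long axis of the
  cylindrical phantom.  A gantry angle ``theta`` of zero puts the beam
  along ``-y`` (source on ``+y``); positive angles are counter-clockwise
  when viewed from ``+z``.  The sign convention can be flipped via the
  ``sign`` argument of :func:`rotate_plane` / :func:`plane_axes`.
* The detector plane at angle ``theta`` contains the rotation axis and the
  in-plane transverse direction ``e_u(theta)``; a chamber at in-plane
  coordinates ``(u, v)`` sits at the world point ``u * e_u + v * e_z``.

Cylindrical coordinates ``(r, phi, z)`` share the ``z`` axis with the world
frame; ``phi`` is measured counter-clockwise from ``+x`` and reduced to
``[0, 2*pi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "CylindricalPoint",
    "DetectorArraySpec",
    "GridSpec",
    "cart_to_cyl",
    "cyl_to_cart",
    "detector_positions",
    "rotate_plane",
    "beam_direction",
    "plane_axes",
    "get_array",
    "array_to_config",
    "array_from_config",
    "OCTAVIUS_729",
    "OCTAVIUS_1500",
    "MATRIXX",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class CylindricalPoint:
    """A point in cylindrical coordinates (r in mm, phi in [0, 2*pi), z in mm)."""

    r: float
    phi: float
    z: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.r, self.phi, self.z])):
            raise ValueError("cylindrical coordinates must be finite")
        if self.r < 0:
            raise ValueError(f"radial coordinate must be non-negative, got {self.r}")
        if not (0.0 <= self.phi < TWO_PI):
            raise ValueError(f"phi must lie in [0, 2*pi), got {self.phi}")

    def to_cartesian(self) -> np.ndarray:
        return cyl_to_cart(np.array([self.r, self.phi, self.z]))


def cart_to_cyl(points) -> np.ndarray:
    """Convert cartesian ``(x, y, z)`` to cylindrical ``(r, phi, z)``.

    ``phi`` follows the three-branch arcsine rule: 0 on the axis,
    ``arcsin(y/r)`` for ``x >= 0`` and ``pi - arcsin(y/r)`` for ``x < 0``,
    reduced modulo ``2*pi`` so the output is single valued.

    Parameters
    ----------
    points : array_like, shape (..., 3)

    Returns
    -------
    ndarray, shape (..., 3) with columns ``(r, phi, z)``.
    """
    p = np.asarray(points, dtype=float)
    if p.shape[-1] != 3:
        raise ValueError("expected points with final axis of length 3")
    if not np.all(np.isfinite(p)):
        raise ValueError("cartesian coordinates must be finite")
    x, y, z = p[..., 0], p[..., 1], p[..., 2]
    r = np.hypot(x, y)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(r > 0, np.clip(np.divide(y, np.where(r > 0, r, 1.0)), -1, 1), 0.0)
    asin = np.arcsin(ratio)
    phi = np.where(x >= 0, asin, np.pi - asin)
    phi = np.where(r == 0, 0.0, phi)
    phi = np.mod(phi, TWO_PI)
    return np.stack([r, phi, z], axis=-1)


def cyl_to_cart(points) -> np.ndarray:
    """Convert cylindrical ``(r, phi, z)`` back to cartesian ``(x, y, z)``."""
    c = np.asarray(points, dtype=float)
    if c.shape[-1] != 3:
        raise ValueError("expected points with final axis of length 3")
    r, phi, z = c[..., 0], c[..., 1], c[..., 2]
    if np.any(r < 0):
        raise ValueError("radial coordinate must be non-negative")
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=-1)


# ---------------------------------------------------------------------------
# Detector arrays
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DetectorArraySpec:
    """Lattice geometry and chamber properties of one ion-chamber array.

    ``lattice_kind`` is one of ``square`` (n x n grid), ``checkerboard``
    (two interleaved square grids, ``m**2 + (m-1)**2`` chambers with
    nearest neighbours on the diagonal) or ``square_minus_corners``
    (n x n grid with the four corner chambers absent).
    """

    name: str
    lattice_kind: str
    pitch_mm: float          # nearest-neighbour centre spacing
    n_detectors: int
    chamber_size_mm: float   # lateral extent
    chamber_height_mm: float
    chamber_volume_cm3: float
    max_area_cm: tuple = (27.0, 27.0)

    def __post_init__(self) -> None:
        if self.lattice_kind not in ("square", "checkerboard", "square_minus_corners"):
            raise ValueError(f"unknown lattice_kind {self.lattice_kind!r}")
        if self.pitch_mm <= 0:
            raise ValueError("pitch must be positive")
        _lattice_side(self)  # validates (lattice_kind, n_detectors) consistency

    @property
    def positions(self) -> np.ndarray:
        return detector_positions(self)


def _lattice_side(spec: DetectorArraySpec) -> int:
    """Side count of the primary square grid; raises on inconsistent specs."""
    n = spec.n_detectors
    if spec.lattice_kind == "square":
        m = int(round(np.sqrt(n)))
        if m * m != n:
            raise ValueError(f"square lattice needs a square count, got {n}")
    elif spec.lattice_kind == "checkerboard":
        # n = m^2 + (m-1)^2  =>  2m^2 - 2m + 1 - n = 0
        m = int(round((2 + np.sqrt(4 - 8 * (1 - n))) / 4))
        if m * m + (m - 1) * (m - 1) != n:
            raise ValueError(f"checkerboard lattice cannot hold {n} chambers")
    else:  # square_minus_corners
        m = int(round(np.sqrt(n + 4)))
        if m * m - 4 != n:
            raise ValueError(f"square-minus-corners lattice cannot hold {n} chambers")
    return m


def detector_positions(spec: DetectorArraySpec) -> np.ndarray:
    """In-plane chamber centre positions (mm), shape ``(n_detectors, 2)``.

    The lattice is centred on the array origin and deterministic: positions
    are ordered row-major by (v, u); for the checkerboard the offset grid
    follows the primary grid.
    """
    m = _lattice_side(spec)
    if spec.lattice_kind == "checkerboard":
        step = spec.pitch_mm / np.sqrt(2.0)  # axis-aligned half-step
        coarse = 2.0 * step
        ax1 = (np.arange(m) - (m - 1) / 2.0) * coarse
        g1 = np.stack(np.meshgrid(ax1, ax1, indexing="ij"), axis=-1).reshape(-1, 2)
        ax2 = (np.arange(m - 1) - (m - 2) / 2.0) * coarse
        g2 = np.stack(np.meshgrid(ax2, ax2, indexing="ij"), axis=-1).reshape(-1, 2)
        pos = np.concatenate([g1, g2], axis=0)
    else:
        ax = (np.arange(m) - (m - 1) / 2.0) * spec.pitch_mm
        pos = np.stack(np.meshgrid(ax, ax, indexing="ij"), axis=-1).reshape(-1, 2)
        if spec.lattice_kind == "square_minus_corners":
            half = (m - 1) / 2.0 * spec.pitch_mm
            corner = (np.abs(np.abs(pos[:, 0]) - half) < 1e-9) & (
                np.abs(np.abs(pos[:, 1]) - half) < 1e-9
            )
            pos = pos[~corner]
    half_x = spec.max_area_cm[0] * 10.0 / 2.0
    half_y = spec.max_area_cm[1] * 10.0 / 2.0
    if np.any(np.abs(pos[:, 0]) > half_x + 1e-9) or np.any(np.abs(pos[:, 1]) > half_y + 1e-9):
        raise ValueError(f"{spec.name}: lattice exceeds the maximum measuring area")
    return pos


OCTAVIUS_729 = DetectorArraySpec(
    name="octavius729",
    lattice_kind="square",
    pitch_mm=10.0,
    n_detectors=729,
    chamber_size_mm=5.0,
    chamber_height_mm=5.0,
    chamber_volume_cm3=0.125,
    max_area_cm=(27.0, 27.0),
)

OCTAVIUS_1500 = DetectorArraySpec(
    name="octavius1500",
    lattice_kind="checkerboard",
    pitch_mm=5.0 * np.sqrt(2.0),  # 7.07 mm diagonal nearest-neighbour spacing
    n_detectors=1405,
    chamber_size_mm=4.4,
    chamber_height_mm=3.0,
    chamber_volume_cm3=0.058,
    max_area_cm=(27.0, 27.0),
)

MATRIXX = DetectorArraySpec(
    name="matrixx",
    lattice_kind="square_minus_corners",
    pitch_mm=7.62,
    n_detectors=1020,
    chamber_size_mm=4.4,
    chamber_height_mm=5.5,
    chamber_volume_cm3=0.07,
    max_area_cm=(24.0, 24.0),
)

_BUILTINS = {a.name: a for a in (OCTAVIUS_729, OCTAVIUS_1500, MATRIXX)}


def get_array(name: str) -> DetectorArraySpec:
    """Look up a built-in array spec by name."""
    try:
        return _BUILTINS[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown array {name!r}; built-ins: {sorted(_BUILTINS)}"
        ) from None


def array_to_config(spec: DetectorArraySpec) -> dict:
    return {
        "name": spec.name,
        "lattice_kind": spec.lattice_kind,
        "pitch_mm": float(spec.pitch_mm),
        "n_detectors": int(spec.n_detectors),
        "chamber_size_mm": float(spec.chamber_size_mm),
        "chamber_height_mm": float(spec.chamber_height_mm),
        "chamber_volume_cm3": float(spec.chamber_volume_cm3),
        "max_area_cm": list(spec.max_area_cm),
    }


def array_from_config(cfg: dict) -> DetectorArraySpec:
    cfg = dict(cfg)
    cfg["max_area_cm"] = tuple(cfg.get("max_area_cm", (27.0, 27.0)))
    return DetectorArraySpec(**cfg)


# ---------------------------------------------------------------------------
# Gantry rotation
# ---------------------------------------------------------------------------


def rotate_plane(points, theta: float, sign: int = 1) -> np.ndarray:
    """Rigidly rotate points about the phantom long axis (world ``z``).

    ``theta = 0`` is the reference orientation; ``sign=-1`` selects the
    clockwise-positive convention.
    """
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    p = np.asarray(points, dtype=float)
    c, s = np.cos(sign * theta), np.sin(sign * theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return p @ rot.T


def beam_direction(theta: float, sign: int = 1) -> np.ndarray:
    """Unit propagation direction of the (parallel) beam at gantry angle theta."""
    t = sign * theta
    return np.array([np.sin(t), -np.cos(t), 0.0])


def plane_axes(theta: float, sign: int = 1):
    """Orthonormal in-plane axes (e_u, e_v) of the detector plane at theta.

    ``e_u`` is the transverse in-plane direction, ``e_v`` the rotation axis.
    """
    t = sign * theta
    e_u = np.array([np.cos(t), np.sin(t), 0.0])
    e_v = np.array([0.0, 0.0, 1.0])
    return e_u, e_v


def chambers_world(spec: DetectorArraySpec, theta: float, sign: int = 1) -> np.ndarray:
    """World coordinates (mm) of all chamber centres at gantry angle theta."""
    pos = detector_positions(spec)
    ref = np.column_stack([pos[:, 0], np.zeros(len(pos)), pos[:, 1]])
    return rotate_plane(ref, theta, sign=sign)


# ---------------------------------------------------------------------------
# Voxel grids
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Regular voxel lattice: 0-based indices, voxel-centre convention.

    ``origin_mm`` is the world coordinate of the centre of voxel (0, 0, 0).
    """

    shape: tuple
    spacing_mm: tuple
    origin_mm: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))
        if len(self.shape) != 3 or len(self.spacing_mm) != 3 or len(self.origin_mm) != 3:
            raise ValueError("shape, spacing_mm and origin_mm must have length 3")
        if any(s <= 0 for s in self.shape):
            raise ValueError("voxel counts must be positive")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacings must be positive")

    @classmethod
    def centred_cube(cls, extent_mm: float, spacing_mm: float) -> "GridSpec":
        """Cube of side ``extent_mm`` centred on the isocenter."""
        n = int(round(extent_mm / spacing_mm)) + 1
        origin = -(n - 1) / 2.0 * spacing_mm
        return cls((n, n, n), (spacing_mm,) * 3, (origin,) * 3)

    def axis(self, dim: int) -> np.ndarray:
        return self.origin_mm[dim] + self.spacing_mm[dim] * np.arange(self.shape[dim])

    def voxel_centres(self) -> np.ndarray:
        """All voxel-centre world coordinates, shape ``(nx*ny*nz, 3)``."""
        xs, ys, zs = (self.axis(d) for d in range(3))
        g = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
        return g.reshape(-1, 3)

    def world_to_index(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return (p - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    def index_to_world(self, indices) -> np.ndarray:
        i = np.asarray(indices, dtype=float)
        return np.asarray(self.origin_mm) + i * np.asarray(self.spacing_mm)

    @property
    def voxel_volume_cm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz / 1000.0

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))
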