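"""Linear, bilinear and angular interpolation of planar measurements and
assembly into a volumetric dose.

The pipeline mirrors how phantom-based QA systems rebuild a 3D dose from
rotational planar measurements:

1. per control point, the chamber readings are completed to a full
   axis-aligned lattice (checkerboard arrays: missing sites from their
   diagonal neighbours; dropout: policy-dependent) and interpolated
   bilinearly (:class:`PlanarInterpolant` / :func:`densify_plane`);
2. each in-plane value is carried along its parallel ray by the PDD depth
   factor (:func:`extend_depth`);
3. the per-control-point contributions are accumulated into the target
   voxel grid in world coordinates (:func:`reconstruct_volume`).

Everything is piecewise linear in each interpolated coordinate, so values
never overshoot the contributing nodes and measured positions are
reproduced exactly ("the interpolation error on nodes is 0").
Extrapolation beyond the outermost chambers is clamped to the nearest
measured node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import DetectorArraySpec, GridSpec, _lattice_side
from .gridio import DoseGrid
from .measurement import PlanarMeasurement
from .synthetic import ArcPlan, PDDTable, Phantom

__all__ = [
    "InterpolationNode",
    "interp_linear",
    "BilinearCell",
    "interp_bilinear",
    "PlanarInterpolant",
    "DensePlane",
    "densify_plane",
    "interp_angular",
    "extend_depth",
    "ReconstructedDose",
    "reconstruct_volume",
]


# ---------------------------------------------------------------------------
# Two-point and four-point primitives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InterpolationNode:
    """One (position, value) sample; positions in mm or radians."""

    x: float
    y: float


def interp_linear(n0: InterpolationNode, n1: InterpolationNode, x) -> np.ndarray:
    """Two-point linear interpolation through ``(x0, y0)`` and ``(x1, y1)``:

    ``phi(x) = (x - x1)/(x0 - x1) * y0 + (x - x0)/(x1 - x0) * y1``

    Exact at the nodes; raises on coincident node positions.
    """
    if n0.x == n1.x:
        raise ValueError("interpolation nodes must have distinct positions")
    x = np.asarray(x, dtype=float)
    return (x - n1.x) / (n0.x - n1.x) * n0.y + (x - n0.x) / (n1.x - n0.x) * n1.y


@dataclass(frozen=True)
class BilinearCell:
    """One rectangular cell with corner values f11=(x1,y1) ... f22=(x2,y2)."""

    x1: float
    x2: float
    y1: float
    y2: float
    f11: float
    f21: float
    f12: float
    f22: float

    def __post_init__(self) -> None:
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError("cell requires x1 < x2 and y1 < y2")


def interp_bilinear(cell: BilinearCell, q) -> np.ndarray:
    """Bilinear interpolation: linear in x to get R1, R2, then linear in y.

    Equals the weighted average of the four corner values with the areas of
    the diagonally opposite sub-rectangles as weights.
    """
    q = np.asarray(q, dtype=float)
    x, y = q[..., 0], q[..., 1]
    r1 = interp_linear(
        InterpolationNode(cell.x1, cell.f11), InterpolationNode(cell.x2, cell.f21), x
    )
    r2 = interp_linear(
        InterpolationNode(cell.x1, cell.f12), InterpolationNode(cell.x2, cell.f22), x
    )
    w = (y - cell.y1) / (cell.y2 - cell.y1)
    return (1.0 - w) * r1 + w * r2


# ---------------------------------------------------------------------------
# Planar interpolant over one measurement
# ---------------------------------------------------------------------------


def _fill_lattice(V: np.ndarray) -> np.ndarray:
    """Fill NaN lattice sites in place-preserving priority order.

    Priority per site: mean of the four diagonal neighbours; else the
    opposite horizontal pair; else the opposite vertical pair.  All three
    rules reproduce fields affine in the lattice coordinates exactly.
    Repeats until stable, then falls back to one-dimensional interpolation
    along rows/columns with edge clamping for anything left (wide dropout
    regions).
    """
    V = V.copy()
    n_i, n_j = V.shape
    for _ in range(n_i * n_j):
        nan = ~np.isfinite(V)
        if not nan.any():
            return V
        P = np.pad(V, 1, constant_values=np.nan)
        diag = np.stack(
            [P[:-2, :-2], P[:-2, 2:], P[2:, :-2], P[2:, 2:]]
        )
        horiz = np.stack([P[1:-1, :-2], P[1:-1, 2:]])
        vert = np.stack([P[:-2, 1:-1], P[2:, 1:-1]])
        cand = np.where(
            np.isfinite(diag).all(axis=0),
            diag.mean(axis=0),
            np.where(
                np.isfinite(horiz).all(axis=0),
                horiz.mean(axis=0),
                np.where(np.isfinite(vert).all(axis=0), vert.mean(axis=0), np.nan),
            ),
        )
        fill = nan & np.isfinite(cand)
        if not fill.any():
            break
        V[fill] = cand[fill]
    # fallback: 1D interpolation with clamping, rows then columns
    for axis_vals in (V, V.T):
        for row in axis_vals:
            good = np.isfinite(row)
            if good.any() and not good.all():
                idx = np.arange(len(row))
                row[~good] = np.interp(idx[~good], idx[good], row[good])
    if not np.isfinite(V).all():
        raise ValueError("lattice cannot be completed; too few responding chambers")
    return V


@dataclass
class PlanarInterpolant:
    """Piecewise-bilinear interpolant of one planar measurement.

    ``values[i, j]`` lives at ``(x_axis[i], y_axis[j])`` on a completed
    uniform axis-aligned lattice.  Queries outside the lattice are clamped
    to the nearest node (no extrapolation).
    """

    x_axis: np.ndarray
    y_axis: np.ndarray
    values: np.ndarray

    @classmethod
    def from_measurement(
        cls, m: PlanarMeasurement, policy: str = "interpolate_over"
    ) -> "PlanarInterpolant":
        if policy not in ("interpolate_over", "zero_fill"):
            raise ValueError(f"unknown dropout policy {policy!r}")
        spec = m.array
        vals = m.values.copy()
        if not np.isfinite(vals).any():
            raise ValueError(
                f"control point {m.control_point_index}: no responding chambers"
            )
        if policy == "zero_fill":
            vals = np.where(np.isfinite(vals), vals, 0.0)
        side = _lattice_side(spec)
        if spec.lattice_kind == "checkerboard":
            step = spec.pitch_mm / np.sqrt(2.0)
            n = 2 * side - 1
            axis = (np.arange(n) - (n - 1) / 2.0) * step
            V = np.full((n, n), np.nan)
            g1 = vals[: side * side].reshape(side, side)
            g2 = vals[side * side :].reshape(side - 1, side - 1)
            V[0::2, 0::2] = g1
            V[1::2, 1::2] = g2
        else:
            axis = (np.arange(side) - (side - 1) / 2.0) * spec.pitch_mm
            V = np.full((side, side), np.nan)
            if spec.lattice_kind == "square":
                V[:, :] = vals.reshape(side, side)
            else:  # square_minus_corners
                half = (side - 1) / 2.0 * spec.pitch_mm
                pos = spec.positions
                ii = np.rint((pos[:, 0] + half) / spec.pitch_mm).astype(int)
                jj = np.rint((pos[:, 1] + half) / spec.pitch_mm).astype(int)
                V[ii, jj] = vals
        V = _fill_lattice(V)
        return cls(axis.copy(), axis.copy(), V)

    def __call__(self, u, v) -> np.ndarray:
        """Bilinear evaluation at in-plane coordinates (mm), edge-clamped."""
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        nx, ny = self.values.shape
        dx = self.x_axis[1] - self.x_axis[0]
        dy = self.y_axis[1] - self.y_axis[0]
        fx = np.clip((u - self.x_axis[0]) / dx, 0.0, nx - 1.0)
        fy = np.clip((v - self.y_axis[0]) / dy, 0.0, ny - 1.0)
        i0 = np.minimum(fx.astype(int), nx - 2)
        j0 = np.minimum(fy.astype(int), ny - 2)
        tx = fx - i0
        ty = fy - j0
        V = self.values
        return (
            V[i0, j0] * (1 - tx) * (1 - ty)
            + V[i0 + 1, j0] * tx * (1 - ty)
            + V[i0, j0 + 1] * (1 - tx) * ty
            + V[i0 + 1, j0 + 1] * tx * ty
        )


@dataclass
class DensePlane:
    """A densified 2D dose map at one gantry angle."""

    theta: float
    u_axis: np.ndarray
    v_axis: np.ndarray
    values: np.ndarray
    control_point_index: int = 0


def densify_plane(
    m: PlanarMeasurement,
    target_pitch_mm: float,
    policy: str = "interpolate_over",
) -> DensePlane:
    """Resample one planar measurement onto a fine square lattice.

    Measured chamber positions that coincide with target nodes retain their
    measured values exactly.  The target lattice spans the chamber hull; no
    extrapolation is performed.
    """
    if target_pitch_mm > m.array.pitch_mm + 1e-12:
        raise ValueError("target pitch must not exceed the array pitch")
    interp = PlanarInterpolant.from_measurement(m, policy=policy)
    span_x = interp.x_axis[-1] - interp.x_axis[0]
    span_y = interp.y_axis[-1] - interp.y_axis[0]
    nu = int(np.floor(span_x / target_pitch_mm + 1e-9)) + 1
    nv = int(np.floor(span_y / target_pitch_mm + 1e-9)) + 1
    u_axis = interp.x_axis[0] + target_pitch_mm * np.arange(nu)
    v_axis = interp.y_axis[0] + target_pitch_mm * np.arange(nv)
    uu, vv = np.meshgrid(u_axis, v_axis, indexing="ij")
    return DensePlane(m.theta, u_axis, v_axis, interp(uu, vv), m.control_point_index)


# ---------------------------------------------------------------------------
# Angular interpolation
# ---------------------------------------------------------------------------


def interp_angular(planes: Sequence, phi: float, full_arc: bool = True) -> np.ndarray:
    """Per-pixel linear interpolation in gantry angle.

    ``planes`` is a sequence of :class:`DensePlane` (or ``(theta, array)``
    pairs) with strictly increasing angles.  For a full arc the
    interpolation wraps periodically across the closure; for a partial arc
    a query outside the covered range raises.
    """
    items = [
        (p.theta, p.values) if isinstance(p, DensePlane) else (float(p[0]), np.asarray(p[1]))
        for p in planes
    ]
    if len(items) < 2:
        raise ValueError("angular interpolation needs at least two planes")
    thetas = np.array([t for t, _ in items])
    if np.any(np.diff(thetas) <= 0):
        raise ValueError("plane angles must be strictly increasing")
    if full_arc:
        period = 2.0 * np.pi
        phi_red = thetas[0] + np.mod(phi - thetas[0], period)
        if phi_red >= thetas[-1]:
            lo, hi = len(items) - 1, 0
            span = (thetas[0] + period) - thetas[-1]
            w = (phi_red - thetas[-1]) / span
        else:
            hi = int(np.searchsorted(thetas, phi_red, side="right"))
            lo = hi - 1
            w = (phi_red - thetas[lo]) / (thetas[hi] - thetas[lo])
    else:
        if phi < thetas[0] - 1e-12 or phi > thetas[-1] + 1e-12:
            raise ValueError(
                f"angle {phi} outside the partial arc [{thetas[0]}, {thetas[-1]}]"
            )
        phi_red = np.clip(phi, thetas[0], thetas[-1])
        hi = min(int(np.searchsorted(thetas, phi_red, side="right")), len(items) - 1)
        lo = hi - 1
        w = (phi_red - thetas[lo]) / (thetas[hi] - thetas[lo])
    return (1.0 - w) * items[lo][1] + w * items[hi][1]


# ---------------------------------------------------------------------------
# Depth extension and volumetric assembly
# ---------------------------------------------------------------------------


def extend_depth(
    plane_values: np.ndarray,
    pdd: PDDTable,
    field_cm: float,
    depths_mm,
    ref_depth_mm,
) -> np.ndarray:
    """Carry in-plane values along their rays with the PDD depth factor:

    ``dose(d) = plane * PDD(field, d) / PDD(field, d_ref)``.

    If ``depths_mm`` is one-dimensional while the plane is 2D the result
    gains a trailing depth axis; otherwise shapes broadcast elementwise.
    Depths outside the table raise a range error.
    """
    plane_values = np.asarray(plane_values, dtype=float)
    depths = np.asarray(depths_mm, dtype=float)
    num = pdd.evaluate(field_cm, depths)
    den = pdd.evaluate(field_cm, ref_depth_mm)
    if np.any(np.asarray(den) <= 0):
        raise ValueError("reference depth has zero PDD; cannot normalise")
    ratio = num / den
    if plane_values.ndim == 2 and depths.ndim == 1:
        return plane_values[:, :, None] * ratio[None, None, :]
    return plane_values * ratio


@dataclass
class ReconstructedDose(DoseGrid):
    """A reconstructed volumetric dose with its provenance settings."""

    provenance: dict = field(default_factory=dict)


def reconstruct_volume(
    measurements: Sequence[PlanarMeasurement],
    array: DetectorArraySpec,
    pdd: PDDTable,
    plan: ArcPlan,
    target: GridSpec,
    geometry: str | None = None,
    phantom: Phantom | None = None,
    policy: str = "interpolate_over",
    sign: int = 1,
) -> ReconstructedDose:
    """Assemble the volumetric dose from all per-control-point measurements.

    For every control point the chamber readings are interpolated in-plane,
    extended along the (parallel) rays by the water-PDD depth factor — the
    phantom is assumed homogeneous water, which is exactly the modelling
    limitation heterogeneous media expose — and summed into the target
    grid.  ``geometry`` selects the cylindrical (phantom-mounted Octavius
    style) or rectangular (gantry-mounted slab) depth model; by default it
    is inferred from the array.
    """
    if len(measurements) != plan.n_control_points:
        raise ValueError(
            f"{len(measurements)} measurements for {plan.n_control_points} control points"
        )
    if geometry is None:
        geometry = "rectangular" if array.lattice_kind == "square_minus_corners" else "cylindrical"
    if geometry not in ("cylindrical", "rectangular"):
        raise ValueError(f"unknown geometry {geometry!r}")
    if phantom is None:
        phantom = Phantom(kind="cylinder") if geometry == "cylindrical" else Phantom(kind="slab")

    pts = target.voxel_centres()
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    out = np.zeros(len(pts), dtype=float)
    for i, m in enumerate(measurements):
        if abs(m.theta - plan.theta[i]) > 1e-9:
            raise ValueError(
                f"control point {i}: measurement angle {m.theta} != plan angle {plan.theta[i]}"
            )
        try:
            interp = PlanarInterpolant.from_measurement(m, policy=policy)
        except ValueError as err:
            raise ValueError(f"control point {i}: {err}") from None
        t = sign * m.theta
        u = x * np.cos(t) + y * np.sin(t)
        s = x * np.sin(t) - y * np.cos(t)
        depth, inside = phantom.geometric_depth(u, s, z)
        ref = phantom.plane_ref_depth(u)
        den = pdd.evaluate(plan.field_cm[i], np.where(inside, ref, 1.0))
        ok = inside & (den > 1e-9)
        if not np.any(ok):
            continue
        plane_vals = interp(u[ok], z[ok])
        num = pdd.evaluate(plan.field_cm[i], depth[ok])
        out[ok] += plane_vals * num / den[ok]
    return ReconstructedDose(
        grid=target,
        values=out.reshape(target.shape),
        provenance={
            "array": array.name,
            "geometry": geometry,
            "policy": policy,
            "n_control_points": plan.n_control_points,
            "target_spacing_mm": list(target.spacing_mm),
        },
    )
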