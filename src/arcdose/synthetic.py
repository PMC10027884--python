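"""Synthetic ground truth: phantoms, PDD tables, arc plans, beams and ROIs.

This module generates every input the reconstruction study needs without any
external data:

* analytic phantoms (water cylinder or slab, optional spherical inserts of
  configurable mass density) rasterisable to a :class:`DensityVolume`;
* percent-depth-dose (PDD) tables from a buildup-then-exponential family,
  one curve per square field size;
* VMAT-like arc plans: evenly spaced gantry control points with seeded
  per-point field-size and weight modulation and a dose-rate surrogate;
* a parallel-beam dose model — flat in-field profile, logistic penumbra,
  depth factor given by the PDD evaluated at radiological depth — that is
  superposed over control points into a ground-truth :class:`DoseGrid`;
* voxelised ROI masks (spheres, ellipsoids, shells) spanning lens-scale
  (~0.2 cm^3) to organ-scale structures.

The beam is parallel (no source divergence) and heterogeneity acts only
through radiological depth; both choices keep the ground truth analytic
while preserving the sampling/interpolation structure under study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .geometry import GridSpec
from .gridio import DoseGrid

__all__ = [
    "PDDTable",
    "make_pdd_table",
    "Insert",
    "Phantom",
    "DensityVolume",
    "make_density_phantom",
    "ArcPlan",
    "make_plan",
    "beam_dose",
    "ground_truth_dose",
    "per_control_point_doses",
    "ROI",
    "ROISet",
    "make_roi_set",
    "sphere_radius_for_volume_mm",
    "prescription_scale",
]

DENSITY_RANGE = (0.0, 3.0)  # g/cm^3, span of modelled tissue types
LN4 = np.log(4.0)


# ---------------------------------------------------------------------------
# Percent depth dose
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PDDTable:
    """Percent depth dose per (field size, depth), max-normalised to 100.

    ``values[i, j]`` is the PDD of square field ``field_sizes_cm[i]`` at
    ``depths_mm[j]``.  Depths are uniformly spaced.  Field sizes not
    tabulated are evaluated by linear interpolation between the bracketing
    tabulated fields.
    """

    field_sizes_cm: tuple
    depths_mm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        fs = tuple(float(f) for f in self.field_sizes_cm)
        object.__setattr__(self, "field_sizes_cm", fs)
        object.__setattr__(self, "depths_mm", np.asarray(self.depths_mm, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if any(np.diff(fs) <= 0):
            raise ValueError("field sizes must be strictly increasing")
        if self.values.shape != (len(fs), len(self.depths_mm)):
            raise ValueError("values shape must be (n_fields, n_depths)")
        steps = np.diff(self.depths_mm)
        if not np.allclose(steps, steps[0]):
            raise ValueError("depths must be uniformly spaced")

    @property
    def max_depth_mm(self) -> float:
        return float(self.depths_mm[-1])

    def _field_weights(self, field_cm: float):
        fs = self.field_sizes_cm
        if not (fs[0] <= field_cm <= fs[-1]):
            raise ValueError(
                f"field size {field_cm} cm outside tabulated range [{fs[0]}, {fs[-1]}]"
            )
        hi = int(np.searchsorted(fs, field_cm, side="left"))
        if hi == 0 or fs[hi] == field_cm:
            return hi, hi, 1.0
        lo = hi - 1
        w_hi = (field_cm - fs[lo]) / (fs[hi] - fs[lo])
        return lo, hi, 1.0 - w_hi

    def curve(self, field_cm: float) -> np.ndarray:
        """The PDD curve at an arbitrary field size (linear mix in field)."""
        lo, hi, w_lo = self._field_weights(float(field_cm))
        return w_lo * self.values[lo] + (1.0 - w_lo) * self.values[hi]

    def evaluate(self, field_cm: float, depth_mm) -> np.ndarray:
        """PDD (percent) at given depths for one field size; linear in depth."""
        d = np.asarray(depth_mm, dtype=float)
        if np.any(d < -1e-9) or np.any(d > self.max_depth_mm + 1e-9):
            raise ValueError(
                f"depth outside table range [0, {self.max_depth_mm}] mm"
            )
        d = np.clip(d, 0.0, self.max_depth_mm)
        c = self.curve(field_cm)
        step = self.depths_mm[1] - self.depths_mm[0]
        f = (d - self.depths_mm[0]) / step
        i0 = np.clip(np.floor(f).astype(int), 0, len(c) - 2)
        t = f - i0
        return c[i0] * (1.0 - t) + c[i0 + 1] * t


def make_pdd_table(
    field_sizes_cm: Sequence[float] = (4.0, 10.0, 26.0),
    depths_mm: np.ndarray | None = None,
    buildup_mu_per_mm: float = 0.35,
    atten_mu0_per_mm: float = 0.0060,
    atten_field_slope_per_mm_cm: float = 6.0e-5,
) -> PDDTable:
    """Analytic PDD family: buildup ``(1 - exp(-b d))`` times ``exp(-mu(F) d)``.

    ``mu(F) = mu0 - slope * F`` decreases with field size so larger fields
    fall off more slowly (a phantom-scatter surrogate).  Each curve is
    normalised to 100 at its depth of maximum.  The mandatory 4, 10 and
    26 cm fields must be present.
    """
    fs = tuple(sorted(float(f) for f in field_sizes_cm))
    for mandatory in (4.0, 10.0, 26.0):
        if mandatory not in fs:
            raise ValueError(f"field size list must include {mandatory} cm")
    if depths_mm is None:
        depths_mm = np.arange(0.0, 281.0, 1.0)
    depths_mm = np.asarray(depths_mm, dtype=float)
    b = float(buildup_mu_per_mm)
    rows = []
    for f in fs:
        mu = atten_mu0_per_mm - atten_field_slope_per_mm_cm * f
        if b <= 0 or mu <= 0:
            raise ValueError("attenuation coefficients must be positive")
        raw = (1.0 - np.exp(-b * depths_mm)) * np.exp(-mu * depths_mm)
        rows.append(100.0 * raw / raw.max())
    return PDDTable(fs, depths_mm, np.array(rows))


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Insert:
    """A spherical insert of uniform mass density inside the phantom."""

    centre_mm: tuple
    radius_mm: float
    rho: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "centre_mm", tuple(float(c) for c in self.centre_mm))
        if self.radius_mm <= 0:
            raise ValueError("insert radius must be positive")
        if not (DENSITY_RANGE[0] <= self.rho <= DENSITY_RANGE[1]):
            raise ValueError(
                f"insert density {self.rho} outside {DENSITY_RANGE} g/cm^3"
            )


@dataclass(frozen=True)
class Phantom:
    """Analytic phantom geometry used by the parallel-beam dose model.

    ``kind='cylinder'``: water cylinder of ``radius_mm`` about the rotation
    axis, length ``length_mm``; the beam enters through the curved surface
    so the reference (detector-plane) depth is ``sqrt(R^2 - u^2)``.

    ``kind='slab'``: gantry-mounted buildup — the beam always enters a flat
    water surface at distance ``ref_depth_mm`` upstream of the isocenter
    plane; lateral extent ``half_width_mm``.
    """

    kind: str = "cylinder"
    radius_mm: float = 135.0
    length_mm: float = 270.0
    ref_depth_mm: float = 120.0
    half_width_mm: float = 120.0
    inserts: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in ("cylinder", "slab"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        object.__setattr__(self, "inserts", tuple(self.inserts))

    # -- geometry in beam coordinates -------------------------------------
    # u: transverse in-plane, v: axial (z), s: along-beam, all mm.

    def geometric_depth(self, u, s, v):
        """(depth_mm, inside_mask) for points in beam coordinates."""
        u = np.asarray(u, dtype=float)
        s = np.asarray(s, dtype=float)
        v = np.asarray(v, dtype=float)
        if self.kind == "cylinder":
            r2 = self.radius_mm**2
            arg = r2 - u * u
            inside = (u * u + s * s <= r2) & (np.abs(v) <= self.length_mm / 2.0)
            depth = s + np.sqrt(np.clip(arg, 0.0, None))
        else:
            inside = (
                (np.abs(u) <= self.half_width_mm)
                & (np.abs(v) <= self.half_width_mm)
                & (s >= -self.ref_depth_mm)
                & (s <= self.ref_depth_mm)
            )
            depth = s + self.ref_depth_mm
        return np.where(inside, depth, 0.0), inside

    def plane_ref_depth(self, u):
        """Depth of the detector plane (s = 0) as a function of u."""
        u = np.asarray(u, dtype=float)
        if self.kind == "cylinder":
            return np.sqrt(np.clip(self.radius_mm**2 - u * u, 0.0, None))
        return np.full(u.shape, self.ref_depth_mm)

    def radiological_depth(self, points, theta: float, sign: int = 1):
        """(radiological depth mm, inside mask) for world points at angle theta.

        Radiological depth is the geometric depth corrected by the
        water-equivalent deficit/excess of every insert crossed upstream of
        the point: ``d_rad = d_geom - sum_i (1 - rho_i) * chord_i``.
        """
        p = np.asarray(points, dtype=float)
        t = sign * theta
        x, y, z = p[..., 0], p[..., 1], p[..., 2]
        u = x * np.cos(t) + y * np.sin(t)
        s = x * np.sin(t) - y * np.cos(t)
        d_geom, inside = self.geometric_depth(u, s, z)
        d_rad = d_geom.copy()
        if self.inserts:
            b = np.array([np.sin(t), -np.cos(t), 0.0])
            s_in = s - d_geom  # beam coordinate of the entry point
            for ins in self.inserts:
                m = p - np.asarray(ins.centre_mm)
                m_par = m @ b
                h2 = np.einsum("...i,...i->...", m, m) - m_par * m_par
                delta2 = ins.radius_mm**2 - h2
                hit = delta2 > 0
                delta = np.sqrt(np.clip(delta2, 0.0, None))
                s_c = s - m_par
                chord = np.clip(
                    np.minimum(s, s_c + delta) - np.maximum(s_in, s_c - delta),
                    0.0,
                    None,
                )
                d_rad = d_rad - np.where(hit, (1.0 - ins.rho) * chord, 0.0)
        return np.where(inside, np.clip(d_rad, 0.0, None), 0.0), inside

    def density_at(self, points) -> np.ndarray:
        """Mass density (g/cm^3) at world points; 0 outside the phantom."""
        p = np.asarray(points, dtype=float)
        x, y, z = p[..., 0], p[..., 1], p[..., 2]
        if self.kind == "cylinder":
            inside = (x * x + y * y <= self.radius_mm**2) & (
                np.abs(z) <= self.length_mm / 2.0
            )
        else:
            inside = (
                (np.abs(x) <= self.half_width_mm)
                & (np.abs(z) <= self.half_width_mm)
                & (np.abs(y) <= self.ref_depth_mm)
            )
        rho = np.where(inside, 1.0, 0.0)
        for ins in self.inserts:
            d2 = np.einsum("...i,...i->...", p - np.asarray(ins.centre_mm), p - np.asarray(ins.centre_mm))
            rho = np.where(inside & (d2 <= ins.radius_mm**2), ins.rho, rho)
        return rho


@dataclass
class DensityVolume:
    """Voxelised mass density (g/cm^3) with an optional analytic phantom."""

    grid: GridSpec
    rho: np.ndarray
    phantom: Phantom | None = None

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.shape != self.grid.shape:
            raise ValueError("rho shape must match grid shape")
        if self.rho.min() < DENSITY_RANGE[0] or self.rho.max() > DENSITY_RANGE[1]:
            raise ValueError(f"densities must lie in {DENSITY_RANGE} g/cm^3")


def make_density_phantom(
    kind: str = "cylindrical",
    heterogeneity: str = "homogeneous",
    grid: GridSpec | None = None,
    params: dict | None = None,
) -> DensityVolume:
    """Build a density phantom and rasterise it onto ``grid``.

    ``kind`` is ``cylindrical`` (water cylinder, default radius 135 mm and
    length 270 mm) or ``cuboid`` (gantry-mounted slab).  ``heterogeneity``
    is ``homogeneous``, ``lung_insert`` (one spherical low-density insert;
    ``params``: ``insert_centre_mm``, ``insert_radius_mm``, ``insert_rho``)
    or ``custom`` (``params['inserts']`` is a list of ``(centre, radius,
    rho)`` tuples or :class:`Insert`).
    """
    params = dict(params or {})
    if kind == "cylindrical":
        base = dict(
            kind="cylinder",
            radius_mm=params.pop("radius_mm", 135.0),
            length_mm=params.pop("length_mm", 270.0),
        )
    elif kind == "cuboid":
        base = dict(
            kind="slab",
            ref_depth_mm=params.pop("ref_depth_mm", 120.0),
            half_width_mm=params.pop("half_width_mm", 120.0),
        )
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")

    if heterogeneity == "homogeneous":
        inserts: tuple = ()
    elif heterogeneity == "lung_insert":
        inserts = (
            Insert(
                centre_mm=tuple(params.pop("insert_centre_mm", (-40.0, 0.0, 0.0))),
                radius_mm=params.pop("insert_radius_mm", 30.0),
                rho=params.pop("insert_rho", 0.21),
            ),
        )
    elif heterogeneity == "custom":
        raw = params.pop("inserts", ())
        inserts = tuple(
            ins if isinstance(ins, Insert) else Insert(tuple(ins[0]), float(ins[1]), float(ins[2]))
            for ins in raw
        )
    else:
        raise ValueError(f"unknown heterogeneity {heterogeneity!r}")

    phantom = Phantom(inserts=inserts, **base)
    if grid is None:
        grid = GridSpec.centred_cube(270.0, 5.0)
    rho = phantom.density_at(grid.voxel_centres()).reshape(grid.shape)
    return DensityVolume(grid, rho, phantom)


# ---------------------------------------------------------------------------
# Arc plans
# ---------------------------------------------------------------------------


@dataclass
class ArcPlan:
    """A rotational delivery: one beam state per gantry control point.

    ``weight`` is a monitor-unit surrogate (the in-field dose in Gy each
    control point contributes at the reference depth before prescription
    scaling); ``dose_rate_cgy_min`` is a delivery-rate surrogate used by
    the low-signal dropout model.
    """

    theta: np.ndarray
    field_cm: np.ndarray
    weight: np.ndarray
    dose_rate_cgy_min: np.ndarray
    prescription_gy: float = 60.0
    seed: int | None = None
    arc: tuple = (0.0, 2.0 * np.pi)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.field_cm = np.asarray(self.field_cm, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        self.dose_rate_cgy_min = np.asarray(self.dose_rate_cgy_min, dtype=float)
        n = len(self.theta)
        if n < 2:
            raise ValueError("a plan needs at least two control points")
        for name in ("field_cm", "weight", "dose_rate_cgy_min"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length must equal the control-point count")
        if np.any(np.diff(self.theta) <= 0):
            raise ValueError("control-point angles must be strictly ordered")
        if np.any(self.weight < 0):
            raise ValueError("weights must be non-negative")
        self.arc = (float(self.arc[0]), float(self.arc[1]))

    @property
    def n_control_points(self) -> int:
        return len(self.theta)

    @property
    def full_arc(self) -> bool:
        return abs((self.arc[1] - self.arc[0]) - 2.0 * np.pi) < 1e-9

    def scaled(self, factor: float) -> "ArcPlan":
        return ArcPlan(
            self.theta.copy(),
            self.field_cm.copy(),
            self.weight * factor,
            self.dose_rate_cgy_min.copy(),
            self.prescription_gy,
            self.seed,
            self.arc,
        )


def make_plan(
    n_control_points: int = 178,
    arc: tuple = (0.0, 2.0 * np.pi),
    field_range_cm: tuple = (4.5, 7.0),
    weight_jitter: float = 0.5,
    dose_rate_range: tuple = (100.0, 600.0),
    prescription_gy: float = 60.0,
    seed: int | None = 0,
) -> ArcPlan:
    """Seeded arc plan with evenly spaced control points.

    A full 360-degree arc omits the duplicate closing angle (178 points at
    360/178-degree steps).  Per-point field sizes are uniform in
    ``field_range_cm`` and weights are jittered by ``weight_jitter``
    around equal weighting; with ``weight_jitter=0`` and a degenerate
    field range the plan is an unmodulated arc.
    """
    if n_control_points < 2:
        raise ValueError("need at least two control points")
    start, stop = float(arc[0]), float(arc[1])
    span = stop - start
    if span <= 0:
        raise ValueError("arc span must be positive")
    full = abs(span - 2.0 * np.pi) < 1e-9
    theta = np.linspace(start, stop, n_control_points, endpoint=not full)
    rng = np.random.default_rng(seed)
    lo, hi = field_range_cm
    fields = rng.uniform(lo, hi, n_control_points) if hi > lo else np.full(n_control_points, lo)
    jit = np.clip(weight_jitter, 0.0, 1.0)
    weights = rng.uniform(1.0 - jit, 1.0 + jit, n_control_points) / n_control_points
    rates = rng.uniform(*dose_rate_range, n_control_points)
    return ArcPlan(theta, fields, weights, rates, prescription_gy, seed, (start, stop))


# ---------------------------------------------------------------------------
# Parallel-beam dose model
# ---------------------------------------------------------------------------


def _aperture(t, field_mm: float, k_mm: float):
    """Flat-top profile with logistic penumbra (80-20 width = 2*ln4*k)."""
    half = field_mm / 2.0
    a = 1.0 / (1.0 + np.exp(-(t + half) / k_mm))
    b = 1.0 / (1.0 + np.exp(-(half - t) / k_mm))
    return a * b


def _beam_dose_points(
    points,
    theta: float,
    field_cm: float,
    weight: float,
    pdd: PDDTable,
    phantom: Phantom,
    penumbra_mm: float,
    sign: int,
) -> np.ndarray:
    p = np.asarray(points, dtype=float)
    t = sign * theta
    x, y, z = p[..., 0], p[..., 1], p[..., 2]
    u = x * np.cos(t) + y * np.sin(t)
    d_rad, inside = phantom.radiological_depth(p, theta, sign=sign)
    k = penumbra_mm / (2.0 * LN4)
    prof = _aperture(u, field_cm * 10.0, k) * _aperture(z, field_cm * 10.0, k)
    dose = np.zeros(p.shape[:-1], dtype=float)
    if np.any(inside):
        dose[inside] = (
            weight * prof[inside] * pdd.evaluate(field_cm, d_rad[inside]) / 100.0
        )
    return dose


def beam_dose(
    points,
    theta: float,
    field_cm: float,
    weight: float,
    pdd: PDDTable,
    phantom: Phantom,
    penumbra_mm: float = 6.0,
    sign: int = 1,
) -> np.ndarray:
    """Dose (Gy) of one parallel beam at arbitrary world points (mm).

    The beam propagates along ``beam_direction(theta)``; the in-field dose
    at water-equivalent depth ``d`` is ``weight * PDD(field, d) / 100``
    shaped laterally by a logistic-penumbra flat-top profile in both the
    transverse (``u``) and axial (``z``) directions.  Points outside the
    phantom receive zero.
    """
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    return _beam_dose_points(points, theta, field_cm, weight, pdd, phantom, penumbra_mm, sign)


def ground_truth_dose(
    plan: ArcPlan,
    density: DensityVolume | Phantom,
    pdd: PDDTable,
    grid: GridSpec,
    penumbra_mm: float = 6.0,
    sign: int = 1,
) -> DoseGrid:
    """Superpose the per-control-point parallel beams onto ``grid``."""
    phantom = density.phantom if isinstance(density, DensityVolume) else density
    if phantom is None:
        raise ValueError("density volume carries no analytic phantom")
    pts = grid.voxel_centres()
    total = np.zeros(len(pts), dtype=float)
    for i in range(plan.n_control_points):
        total += _beam_dose_points(
            pts, plan.theta[i], plan.field_cm[i], plan.weight[i], pdd, phantom, penumbra_mm, sign
        )
    return DoseGrid(grid, total.reshape(grid.shape))


def per_control_point_doses(
    plan: ArcPlan,
    density: DensityVolume | Phantom,
    pdd: PDDTable,
    grid: GridSpec,
    penumbra_mm: float = 6.0,
    sign: int = 1,
):
    """Yield one :class:`DoseGrid` contribution per control point (lazily)."""
    phantom = density.phantom if isinstance(density, DensityVolume) else density
    if phantom is None:
        raise ValueError("density volume carries no analytic phantom")
    pts = grid.voxel_centres()
    for i in range(plan.n_control_points):
        vals = _beam_dose_points(
            pts, plan.theta[i], plan.field_cm[i], plan.weight[i], pdd, phantom, penumbra_mm, sign
        )
        yield DoseGrid(grid, vals.reshape(grid.shape))


def prescription_scale(truth: DoseGrid, ptv_mask: np.ndarray, prescription_gy: float, coverage_pct: float = 95.0) -> float:
    """Scale factor making the PTV D(coverage) equal the prescription.

    Mirrors the clinical acceptability rule that the prescribed dose cover
    at least 95% of the PTV.
    """
    doses = truth.values[ptv_mask]
    if doses.size == 0:
        raise ValueError("PTV mask is empty")
    d_cov = np.quantile(doses, 1.0 - coverage_pct / 100.0)
    if d_cov <= 0:
        raise ValueError("PTV coverage dose is zero; cannot normalise")
    return prescription_gy / d_cov


# ---------------------------------------------------------------------------
# Regions of interest
# ---------------------------------------------------------------------------


@dataclass
class ROI:
    name: str
    role: str  # "PTV" or "OAR"
    mask: np.ndarray
    nominal_volume_cm3: float

    def __post_init__(self) -> None:
        if self.role not in ("PTV", "OAR"):
            raise ValueError("ROI role must be 'PTV' or 'OAR'")
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"ROI {self.name!r} has an empty mask")


@dataclass
class ROISet:
    """Named boolean masks over one grid."""

    grid: GridSpec
    rois: list

    def __post_init__(self) -> None:
        for roi in self.rois:
            if roi.mask.shape != self.grid.shape:
                raise ValueError(f"ROI {roi.name!r} mask does not match the grid")

    def __getitem__(self, name: str) -> ROI:
        for roi in self.rois:
            if roi.name == name:
                return roi
        raise KeyError(name)

    def __iter__(self):
        return iter(self.rois)

    def names(self) -> list:
        return [r.name for r in self.rois]


def sphere_radius_for_volume_mm(volume_cm3: float) -> float:
    """Radius (mm) of a sphere with the given volume (cm^3)."""
    return (3.0 * volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


def make_roi_set(grid: GridSpec, config: Iterable) -> ROISet:
    """Voxelise ROI shapes onto ``grid``.

    Each config entry is a mapping with keys ``name``, ``role`` (PTV/OAR),
    ``shape`` (sphere/ellipsoid/shell), ``centre_mm`` and ``size_mm``:
    sphere -> radius; ellipsoid -> (a, b, c) semi-axes; shell ->
    (inner_radius, outer_radius).  A voxel belongs to the mask when its
    centre lies inside the shape.
    """
    pts = grid.voxel_centres()
    rois = []
    for entry in config:
        name = entry["name"]
        centre = np.asarray(entry["centre_mm"], dtype=float)
        shape = entry["shape"]
        size = entry["size_mm"]
        d = pts - centre
        if shape == "sphere":
            r = float(size)
            if r <= 0:
                raise ValueError(f"ROI {name!r}: radius must be positive")
            inside = np.einsum("ij,ij->i", d, d) <= r * r
            vol = 4.0 / 3.0 * np.pi * r**3 / 1000.0
        elif shape == "ellipsoid":
            a, b, c = (float(s) for s in size)
            if min(a, b, c) <= 0:
                raise ValueError(f"ROI {name!r}: semi-axes must be positive")
            inside = (d[:, 0] / a) ** 2 + (d[:, 1] / b) ** 2 + (d[:, 2] / c) ** 2 <= 1.0
            vol = 4.0 / 3.0 * np.pi * a * b * c / 1000.0
        elif shape == "shell":
            r_in, r_out = (float(s) for s in size)
            if not (0 <= r_in < r_out):
                raise ValueError(f"ROI {name!r}: need 0 <= inner < outer radius")
            r2 = np.einsum("ij,ij->i", d, d)
            inside = (r2 >= r_in * r_in) & (r2 <= r_out * r_out)
            vol = 4.0 / 3.0 * np.pi * (r_out**3 - r_in**3) / 1000.0
        else:
            raise ValueError(f"ROI {name!r}: unknown shape {shape!r}")
        mask = inside.reshape(grid.shape)
        if not mask.any():
            raise ValueError(f"ROI {name!r} lies entirely outside the grid")
        rois.append(ROI(name, entry["role"], mask, vol))
    return ROISet(grid, rois)
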