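"""Simulated detector-array readout during arc delivery.

One :class:`PlanarMeasurement` holds the per-chamber doses recorded at a
single gantry control point.  A chamber that did not respond (low-signal
dropout) carries the explicit ``NO_RESPONSE`` marker (NaN) rather than
0 Gy, so downstream interpolation must choose a policy for it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import DetectorArraySpec, beam_direction, detector_positions, plane_axes
from .gridio import DoseGrid
from .synthetic import ArcPlan, PDDTable, Phantom, _beam_dose_points

__all__ = [
    "NO_RESPONSE",
    "PlanarMeasurement",
    "sample_planar",
    "deliver_plan",
    "measure_arc",
    "apply_noise_and_dropout",
    "write_measurement_csv",
    "read_measurement_csv",
]

NO_RESPONSE = np.nan


@dataclass
class PlanarMeasurement:
    """Chamber doses for one control point.

    ``values`` has one entry per chamber of ``array`` (ordering of
    :func:`arcdose.geometry.detector_positions`); no-response chambers are
    NaN.  ``rate_surrogate_cgy_min`` is the per-chamber delivery-rate
    surrogate used by the dropout model.
    """

    theta: float
    values: np.ndarray
    array: DetectorArraySpec
    control_point_index: int = 0
    rate_surrogate_cgy_min: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.array.n_detectors,):
            raise ValueError(
                f"expected {self.array.n_detectors} readings, got {self.values.shape}"
            )
        finite = np.isfinite(self.values)
        if np.any(self.values[finite] < 0):
            raise ValueError("chamber readings must be non-negative")
        if self.rate_surrogate_cgy_min is not None:
            self.rate_surrogate_cgy_min = np.asarray(self.rate_surrogate_cgy_min, dtype=float)
            if self.rate_surrogate_cgy_min.shape != self.values.shape:
                raise ValueError("rate surrogate must match the reading count")

    @property
    def responding(self) -> np.ndarray:
        return np.isfinite(self.values)

    def replace_values(self, values: np.ndarray) -> "PlanarMeasurement":
        return PlanarMeasurement(
            self.theta, values, self.array, self.control_point_index, self.rate_surrogate_cgy_min
        )


# 3x3x3 midpoint-symmetric quadrature offsets on [-1/2, 1/2] per axis.
_QUAD = (np.arange(3) - 1.0) / 3.0


def sample_planar(
    dose: DoseGrid,
    array: DetectorArraySpec,
    theta: float,
    mode: str = "point",
    sign: int = 1,
) -> PlanarMeasurement:
    """Sample a gridded dose at the rotated chamber positions.

    ``point`` mode is a trilinear lookup at each chamber centre; the
    ``volume_averaged`` mode averages a fixed 3x3x3 quadrature over the
    chamber box (``chamber_size`` laterally, ``chamber_height`` along the
    beam axis).
    """
    if mode not in ("point", "volume_averaged"):
        raise ValueError(f"unknown sampling mode {mode!r}")
    pos = detector_positions(array)
    e_u, e_v = plane_axes(theta, sign=sign)
    centres = pos[:, 0:1] * e_u + pos[:, 1:2] * e_v

    lo = np.array([dose.grid.axis(d)[0] for d in range(3)])
    hi = np.array([dose.grid.axis(d)[-1] for d in range(3)])

    def _lookup(points: np.ndarray) -> np.ndarray:
        out = (points < lo - 1e-9) | (points > hi + 1e-9)
        if np.any(out):
            bad = int(np.nonzero(out.any(axis=1))[0][0])
            raise ValueError(
                f"chamber {bad} at {points[bad]} mm falls outside the dose grid"
            )
        return dose.sample(np.clip(points, lo, hi))

    if mode == "point":
        values = _lookup(centres)
    else:
        b = beam_direction(theta, sign=sign)
        acc = np.zeros(len(centres))
        for du in _QUAD:
            for dv in _QUAD:
                for db in _QUAD:
                    off = (
                        du * array.chamber_size_mm * e_u
                        + dv * array.chamber_size_mm * e_v
                        + db * array.chamber_height_mm * b
                    )
                    acc += _lookup(centres + off)
        values = acc / 27.0
    return PlanarMeasurement(theta, values, array)


def _attach_rate(plan: ArcPlan, index: int, values: np.ndarray) -> np.ndarray:
    """Per-chamber dose-rate surrogate: the control point's nominal rate
    scaled by each chamber's reading relative to the plane maximum."""
    peak = np.nanmax(values) if np.any(np.isfinite(values)) else 0.0
    if peak <= 0:
        return np.zeros_like(values)
    return plan.dose_rate_cgy_min[index] * np.clip(values, 0.0, None) / peak


def deliver_plan(
    plan: ArcPlan,
    dose_per_cp,
    array: DetectorArraySpec,
    mode: str = "point",
    sign: int = 1,
) -> list:
    """Measure each per-control-point dose contribution in delivery order.

    ``dose_per_cp`` is an iterable of :class:`DoseGrid`, one per control
    point (it may be a lazy generator).
    """
    measurements = []
    for i, dose in enumerate(dose_per_cp):
        if i >= plan.n_control_points:
            raise ValueError("more dose contributions than control points")
        m = sample_planar(dose, array, plan.theta[i], mode=mode, sign=sign)
        m.control_point_index = i
        m.rate_surrogate_cgy_min = _attach_rate(plan, i, m.values)
        measurements.append(m)
    if len(measurements) != plan.n_control_points:
        raise ValueError(
            f"plan has {plan.n_control_points} control points but only "
            f"{len(measurements)} dose contributions were supplied"
        )
    return measurements


def measure_arc(
    plan: ArcPlan,
    phantom: Phantom,
    pdd: PDDTable,
    array: DetectorArraySpec,
    penumbra_mm: float = 6.0,
    sign: int = 1,
) -> list:
    """Exact per-control-point chamber readings from the analytic beam model.

    Equivalent to :func:`deliver_plan` on analytically evaluated
    contributions, without the intermediate voxel grids (and therefore
    without trilinear lookup error).
    """
    pos = detector_positions(array)
    out = []
    for i in range(plan.n_control_points):
        e_u, e_v = plane_axes(plan.theta[i], sign=sign)
        centres = pos[:, 0:1] * e_u + pos[:, 1:2] * e_v
        values = _beam_dose_points(
            centres, plan.theta[i], plan.field_cm[i], plan.weight[i], pdd, phantom, penumbra_mm, sign
        )
        m = PlanarMeasurement(plan.theta[i], values, array, i)
        m.rate_surrogate_cgy_min = _attach_rate(plan, i, values)
        out.append(m)
    return out


def apply_noise_and_dropout(
    measurements,
    sigma_rel: float = 0.0,
    dropout_rate_threshold_cgy_min: float = 0.0,
    seed: int | None = 0,
) -> list:
    """Multiplicative Gaussian noise plus low-rate dropout.

    Readings whose dose-rate surrogate falls below the threshold (the
    classic 5 cGy/min low-signal cutoff) become no-response markers.
    Seeded and reproducible; ``sigma_rel=0`` with threshold 0 is the
    identity.
    """
    if sigma_rel < 0:
        raise ValueError("sigma_rel must be non-negative")
    if dropout_rate_threshold_cgy_min < 0:
        raise ValueError("dropout threshold must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for m in measurements:
        values = m.values.copy()
        if sigma_rel > 0:
            noise = rng.normal(1.0, sigma_rel, values.shape)
            values = np.clip(values * noise, 0.0, None)
        if dropout_rate_threshold_cgy_min > 0:
            if m.rate_surrogate_cgy_min is None:
                raise ValueError("measurements carry no dose-rate surrogate")
            drop = m.rate_surrogate_cgy_min < dropout_rate_threshold_cgy_min
            values = np.where(drop, NO_RESPONSE, values)
        out.append(m.replace_values(values))
    return out


def write_measurement_csv(path, m: PlanarMeasurement) -> None:
    """Export one control point as CSV (the analogue of a vendor planar export)."""
    pos = detector_positions(m.array)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["chamber_index", "x_mm", "y_mm", "theta_rad", "dose_Gy", "flag"])
        for i, ((x, y), v) in enumerate(zip(pos, m.values)):
            flag = "ok" if np.isfinite(v) else "no_response"
            w.writerow([i, f"{x:.4f}", f"{y:.4f}", f"{m.theta:.17g}", "" if not np.isfinite(v) else f"{v:.8e}", flag])


def read_measurement_csv(path, array: DetectorArraySpec, control_point_index: int = 0) -> PlanarMeasurement:
    rows = list(csv.DictReader(open(path)))
    if len(rows) != array.n_detectors:
        raise ValueError("row count does not match the array spec")
    values = np.array(
        [float(r["dose_Gy"]) if r["flag"] == "ok" else NO_RESPONSE for r in rows]
    )
    theta = float(rows[0]["theta_rad"])
    return PlanarMeasurement(theta, values, array, control_point_index)
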