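import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arcdose.geometry import GridSpec, detector_positions, get_array
from arcdose.measurement import NO_RESPONSE, PlanarMeasurement, measure_arc
from arcdose.reconstruction import (
    BilinearCell,
    DensePlane,
    InterpolationNode,
    PlanarInterpolant,
    densify_plane,
    extend_depth,
    interp_angular,
    interp_bilinear,
    interp_linear,
    reconstruct_volume,
)
from arcdose.synthetic import ArcPlan, make_plan


def _measurement(array_name, fn, theta=0.0):
    arr = get_array(array_name)
    pos = detector_positions(arr)
    return PlanarMeasurement(theta, fn(pos[:, 0], pos[:, 1]), arr)


class TestLinear:
    def test_exact_at_nodes(self):
        n0, n1 = InterpolationNode(0.3, 2.5), InterpolationNode(1.7, -0.5)
        assert interp_linear(n0, n1, 0.3) == 2.5
        assert interp_linear(n0, n1, 1.7) == -0.5

    @pytest.mark.parametrize(
        "nodes,x,expected",
        [(((0, 0), (1, 1)), 0.5, 0.5), (((0, 2), (4, 10)), 1.0, 4.0)],
    )
    def test_examples(self, nodes, x, expected):
        (x0, y0), (x1, y1) = nodes
        out = interp_linear(InterpolationNode(x0, y0), InterpolationNode(x1, y1), x)
        assert out == pytest.approx(expected, abs=1e-14)

    def test_coincident_nodes_rejected(self):
        with pytest.raises(ValueError):
            interp_linear(InterpolationNode(1, 0), InterpolationNode(1, 5), 0.5)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0, 1))
    def test_monotone_between_nodes(self, t):
        n0, n1 = InterpolationNode(0.0, 1.0), InterpolationNode(2.0, 5.0)
        v = interp_linear(n0, n1, 2.0 * t)
        assert 1.0 - 1e-12 <= v <= 5.0 + 1e-12


class TestBilinear:
    def _cell(self):
        return BilinearCell(0, 1, 0, 1, f11=1, f21=3, f12=5, f22=7)

    def test_constant_cell(self):
        c = BilinearCell(0, 2, -1, 1, 4, 4, 4, 4)
        assert interp_bilinear(c, (0.3, 0.3)) == pytest.approx(4.0, abs=1e-14)

    def test_centre_is_corner_mean(self):
        assert interp_bilinear(self._cell(), (0.5, 0.5)) == pytest.approx(4.0, abs=1e-14)

    def test_weighted_area_example(self):
        assert interp_bilinear(self._cell(), (0.25, 0.75)) == pytest.approx(4.5, abs=1e-14)

    def test_degenerate_cell_rejected(self):
        with pytest.raises(ValueError):
            BilinearCell(0, 0, 0, 1, 1, 1, 1, 1)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 10_000))
    def test_matches_weighted_area_oracle_and_order_swap(self, seed):
        rng = np.random.default_rng(seed)
        x1, y1 = rng.uniform(-50, 50, 2)
        dx, dy = rng.uniform(0.1, 30, 2)
        f = rng.uniform(-10, 10, 4)
        cell = BilinearCell(x1, x1 + dx, y1, y1 + dy, *f)
        qx = x1 + rng.uniform(0, 1) * dx
        qy = y1 + rng.uniform(0, 1) * dy
        # oracle: areas of the diagonally opposite sub-rectangles
        area = dx * dy
        oracle = (
            cell.f11 * (cell.x2 - qx) * (cell.y2 - qy)
            + cell.f21 * (qx - cell.x1) * (cell.y2 - qy)
            + cell.f12 * (cell.x2 - qx) * (qy - cell.y1)
            + cell.f22 * (qx - cell.x1) * (qy - cell.y1)
        ) / area
        v = interp_bilinear(cell, (qx, qy))
        assert v == pytest.approx(oracle, abs=1e-12)
        # y-then-x evaluation order gives the same result
        s1 = interp_linear(InterpolationNode(y1, cell.f11), InterpolationNode(cell.y2, cell.f12), qy)
        s2 = interp_linear(InterpolationNode(y1, cell.f21), InterpolationNode(cell.y2, cell.f22), qy)
        swapped = interp_linear(InterpolationNode(x1, s1), InterpolationNode(cell.x2, s2), qx)
        assert v == pytest.approx(swapped, abs=1e-12)


class TestDensifyPlane:
    @pytest.mark.parametrize("array_name", ["octavius729", "octavius1500"])
    def test_affine_fields_reproduced(self, array_name):
        f = lambda x, y: 10.0 + 0.02 * x - 0.01 * y
        m = _measurement(array_name, f)
        dp = densify_plane(m, 2.5)
        uu, vv = np.meshgrid(dp.u_axis, dp.v_axis, indexing="ij")
        assert np.abs(dp.values - f(uu, vv)).max() < 1e-10

    def test_chamber_values_unchanged_at_original_positions(self, rng):
        arr = get_array("octavius729")
        vals = rng.uniform(0.5, 2.0, arr.n_detectors)
        m = PlanarMeasurement(0.0, vals, arr)
        dp = densify_plane(m, 2.5)
        # chambers sit on every 4th dense node
        assert np.array_equal(dp.values[::4, ::4].ravel(), vals)

    def test_checkerboard_diagonal_fill_exact_for_linear_field(self):
        f = lambda x, y: 30.0 + 0.05 * (x + y)
        m = _measurement("octavius1500", f)
        itp = PlanarInterpolant.from_measurement(m)
        xx, yy = np.meshgrid(itp.x_axis, itp.y_axis, indexing="ij")
        assert np.abs(itp.values - f(xx, yy)).max() < 1e-10

    def test_monotone_no_overshoot(self, rng):
        arr = get_array("octavius729")
        vals = rng.uniform(0.0, 1.0, arr.n_detectors)
        m = PlanarMeasurement(0.0, vals, arr)
        dp = densify_plane(m, 2.5)
        assert dp.values.min() >= vals.min() - 1e-12
        assert dp.values.max() <= vals.max() + 1e-12

    def test_target_pitch_coarser_than_array_rejected(self):
        m = _measurement("octavius729", lambda x, y: np.ones_like(x))
        with pytest.raises(ValueError):
            densify_plane(m, 11.0)

    def test_all_no_response_rejected(self):
        arr = get_array("octavius729")
        m = PlanarMeasurement(0.0, np.full(arr.n_detectors, NO_RESPONSE), arr)
        with pytest.raises(ValueError, match="respond"):
            densify_plane(m, 2.5)

    def test_dropout_policies(self, rng):
        arr = get_array("octavius729")
        vals = rng.uniform(1.0, 2.0, arr.n_detectors)
        drop = rng.random(arr.n_detectors) < 0.05
        vals_d = np.where(drop, NO_RESPONSE, vals)
        m = PlanarMeasurement(0.0, vals_d, arr)
        zero = PlanarInterpolant.from_measurement(m, policy="zero_fill")
        over = PlanarInterpolant.from_measurement(m, policy="interpolate_over")
        grid_idx = np.unravel_index(np.nonzero(drop)[0], (27, 27))
        assert np.all(zero.values[grid_idx] == 0.0)
        assert np.all(over.values[grid_idx] >= 1.0 - 1e-9)  # filled from neighbours

    def test_clamped_beyond_hull(self):
        f = lambda x, y: 10.0 + 0.01 * x
        m = _measurement("octavius729", f)
        itp = PlanarInterpolant.from_measurement(m)
        assert itp(200.0, 0.0) == pytest.approx(f(130.0, 0.0), abs=1e-12)


class TestAngular:
    def test_node_exactness_and_identical_planes(self, rng):
        shapes = (5, 5)
        planes = [(0.1 * k, rng.uniform(0, 1, shapes)) for k in range(4)]
        out = interp_angular(planes, 0.2, full_arc=False)
        assert np.array_equal(out, planes[2][1])
        same = [(0.0, planes[0][1]), (1.0, planes[0][1])]
        mid = interp_angular(same, 0.7, full_arc=False)
        assert np.allclose(mid, planes[0][1], atol=1e-15)

    def test_full_arc_wraparound_matches_unwrapped_oracle(self, rng):
        thetas = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        maps = [rng.uniform(0, 1, (4, 4)) for _ in thetas]
        planes = list(zip(thetas, maps))
        q = 2 * np.pi - 0.1  # between the last plane and the wrapped first one
        out = interp_angular(planes, q, full_arc=True)
        # oracle: unwrap by appending the first plane at theta0 + 2*pi
        ext = planes + [(2 * np.pi, maps[0])]
        oracle = interp_angular(ext, q, full_arc=False)
        assert np.abs(out - oracle).max() < 1e-12
        # queries are periodic
        assert np.allclose(interp_angular(planes, q - 2 * np.pi, full_arc=True), out)

    def test_partial_arc_range_error(self, rng):
        planes = [(0.0, np.zeros((2, 2))), (1.0, np.ones((2, 2)))]
        with pytest.raises(ValueError, match="arc"):
            interp_angular(planes, 1.5, full_arc=False)

    def test_needs_two_planes(self):
        with pytest.raises(ValueError):
            interp_angular([(0.0, np.zeros((2, 2)))], 0.0)


class TestExtendDepth:
    def test_reference_depth_is_identity(self, pdd):
        plane = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = extend_depth(plane, pdd, 10.0, 50.0, 50.0)
        assert np.allclose(out, plane, atol=1e-14)

    def test_tabulated_field_uses_stored_curve(self, pdd):
        plane = np.ones((2, 2))
        depths = np.array([20.0, 100.0, 200.0])
        out = extend_depth(plane, pdd, 10.0, depths, 100.0)
        expect = pdd.evaluate(10.0, depths) / pdd.evaluate(10.0, 100.0)
        assert np.allclose(out[0, 0, :], expect, atol=1e-14)

    def test_intermediate_field_is_curve_mix(self, pdd):
        depths = np.linspace(20, 250, 24)
        out7 = extend_depth(np.ones((1, 1)), pdd, 7.0, depths, 100.0)[0, 0]
        mix = 0.5 * pdd.evaluate(4.0, depths) + 0.5 * pdd.evaluate(10.0, depths)
        ref = 0.5 * pdd.evaluate(4.0, 100.0) + 0.5 * pdd.evaluate(10.0, 100.0)
        assert np.allclose(out7, mix / ref, atol=1e-12)

    def test_depth_outside_table_rejected(self, pdd):
        with pytest.raises(ValueError):
            extend_depth(np.ones((1, 1)), pdd, 10.0, 5000.0, 100.0)


class TestReconstructVolume:
    def test_single_beam_matches_truth_in_field(self, pdd, water_cylinder):
        from arcdose.synthetic import ground_truth_dose

        plan = ArcPlan(
            np.array([0.0, np.pi / 2]), np.array([10.0, 10.0]), np.array([1.0, 0.0]),
            np.array([300.0, 300.0]), 60.0, 0, (0.0, np.pi / 2),
        )
        grid = GridSpec.centred_cube(100.0, 2.5)
        truth = ground_truth_dose(plan, water_cylinder, pdd, grid)
        arr = get_array("octavius729")
        ms = measure_arc(plan, water_cylinder, pdd, arr)
        recon = reconstruct_volume(ms, arr, pdd, plan, grid)
        pts = grid.voxel_centres()
        infield = (np.abs(pts[:, 0]) < 30) & (np.abs(pts[:, 2]) < 30)  # >=20 mm from edges
        err = np.abs(recon.values.ravel() - truth.values.ravel())
        assert err[infield].max() < 0.005 * truth.values.max()

    def test_linearity(self, pdd, water_cylinder, small_grid):
        plan = make_plan(n_control_points=6, seed=4)
        arr = get_array("octavius729")
        ms = measure_arc(plan, water_cylinder, pdd, arr)
        r1 = reconstruct_volume(ms, arr, pdd, plan, small_grid)
        ms2 = [m.replace_values(2.0 * m.values) for m in ms]
        r2 = reconstruct_volume(ms2, arr, pdd, plan, small_grid)
        assert np.allclose(r2.values, 2.0 * r1.values, rtol=0, atol=1e-12)

    def test_rectangular_geometry_runs(self, pdd, small_grid):
        from arcdose.synthetic import Phantom, ground_truth_dose

        slab = Phantom(kind="slab")
        plan = make_plan(n_control_points=6, seed=4, field_range_cm=(6.0, 6.0))
        arr = get_array("matrixx")
        ms = measure_arc(plan, slab, pdd, arr)
        recon = reconstruct_volume(ms, arr, pdd, plan, small_grid, phantom=slab)
        assert recon.provenance["geometry"] == "rectangular"
        truth = ground_truth_dose(plan, slab, pdd, small_grid)
        centre = tuple(s // 2 for s in small_grid.shape)
        assert recon.values[centre] == pytest.approx(truth.values[centre], rel=0.01)

    def test_count_and_angle_mismatch_rejected(self, pdd, water_cylinder, small_grid):
        plan = make_plan(n_control_points=4, seed=0)
        arr = get_array("octavius729")
        ms = measure_arc(plan, water_cylinder, pdd, arr)
        with pytest.raises(ValueError, match="measurements"):
            reconstruct_volume(ms[:-1], arr, pdd, plan, small_grid)
        bad = list(ms)
        bad[1] = PlanarMeasurement(bad[1].theta + 0.1, bad[1].values, arr, 1)
        with pytest.raises(ValueError, match="angle"):
            reconstruct_volume(bad, arr, pdd, plan, small_grid)

    def test_node_exactness_through_densify(self, rng):
        # reconstruction reproduces measured chamber values on the plane
        arr = get_array("octavius1500")
        pos = detector_positions(arr)
        vals = rng.uniform(0.5, 1.5, arr.n_detectors)
        m = PlanarMeasurement(0.0, vals, arr)
        itp = PlanarInterpolant.from_measurement(m)
        rec = itp(pos[:, 0], pos[:, 1])
        assert np.abs((rec - vals) / vals).max() < 1e-12
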