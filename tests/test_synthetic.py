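import numpy as np
import pytest

from arcdose.geometry import GridSpec
from arcdose.synthetic import (
    DensityVolume,
    Insert,
    Phantom,
    ground_truth_dose,
    make_density_phantom,
    make_pdd_table,
    make_plan,
    make_roi_set,
    prescription_scale,
    sphere_radius_for_volume_mm,
)


class TestPDDTable:
    def test_normalised_to_100_at_maximum(self, pdd):
        assert np.allclose(pdd.values.max(axis=1), 100.0)

    def test_monotone_beyond_buildup(self, pdd):
        for row in pdd.values:
            i = row.argmax()
            assert np.all(np.diff(row[i:]) <= 0)

    def test_larger_field_larger_dose_beyond_buildup(self, pdd):
        i = max(row.argmax() for row in pdd.values)
        tail = pdd.values[:, i:]
        assert np.all(np.diff(tail, axis=0) >= -1e-12)

    def test_intermediate_field_is_linear_mix(self, pdd):
        # 7 cm sits midway between the 4 and 10 cm tabulated fields
        mix = 0.5 * pdd.values[0] + 0.5 * pdd.values[1]
        assert np.allclose(pdd.curve(7.0), mix, atol=1e-12)

    def test_mandatory_fields_enforced(self):
        with pytest.raises(ValueError):
            make_pdd_table(field_sizes_cm=(4.0, 26.0))

    def test_nonpositive_attenuation_rejected(self):
        with pytest.raises(ValueError):
            make_pdd_table(atten_mu0_per_mm=-0.001, atten_field_slope_per_mm_cm=0.0)

    def test_depth_and_field_range_errors(self, pdd):
        with pytest.raises(ValueError):
            pdd.evaluate(10.0, 1e4)
        with pytest.raises(ValueError):
            pdd.evaluate(30.0, 50.0)


class TestDensityPhantom:
    def test_homogeneous_interior_is_exactly_water(self):
        grid = GridSpec.centred_cube(80.0, 4.0)
        dv = make_density_phantom("cylindrical", "homogeneous", grid)
        assert np.all(dv.rho == 1.0)  # 80 mm cube is entirely inside the cylinder

    def test_lung_insert_density(self):
        grid = GridSpec.centred_cube(120.0, 4.0)
        dv = make_density_phantom(
            "cylindrical",
            "lung_insert",
            grid,
            {"insert_centre_mm": (0, 0, 0), "insert_radius_mm": 20.0, "insert_rho": 0.01},
        )
        centre = dv.rho[tuple(s // 2 for s in grid.shape)]
        assert centre == 0.01
        assert dv.rho.max() == 1.0

    def test_custom_inserts_histogram_levels(self):
        grid = GridSpec.centred_cube(120.0, 4.0)
        dv = make_density_phantom(
            "cylindrical",
            "custom",
            grid,
            {"inserts": [((-30, 0, 0), 15.0, 0.3), ((30, 0, 0), 15.0, 2.0)]},
        )
        levels = np.unique(dv.rho)
        assert set(np.round(levels, 6)) == {0.3, 1.0, 2.0}
        # voxel counts per level track the configured insert volumes
        v_ins = 4 / 3 * np.pi * 15.0**3
        for level in (0.3, 2.0):
            n = (dv.rho == level).sum()
            assert abs(n * 64.0 - v_ins) / v_ins < 0.1

    def test_density_range_enforced(self):
        grid = GridSpec.centred_cube(40.0, 4.0)
        with pytest.raises(ValueError):
            make_density_phantom(
                "cylindrical", "custom", grid, {"inserts": [((0, 0, 0), 10.0, 5.0)]}
            )
        with pytest.raises(ValueError):
            DensityVolume(grid, np.full(grid.shape, 4.0))


class TestArcPlans:
    @pytest.mark.parametrize("n", [178, 120])
    def test_full_arc_counts_and_span(self, n):
        plan = make_plan(n_control_points=n, seed=3)
        assert plan.n_control_points == n
        assert plan.full_arc
        assert plan.theta[0] == 0.0
        assert np.isclose(plan.theta[-1], 2 * np.pi * (n - 1) / n)
        assert np.all(np.diff(plan.theta) > 0)

    def test_same_seed_identical_plans(self):
        a, b = make_plan(seed=11), make_plan(seed=11)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.field_cm, b.field_cm)
        assert np.array_equal(a.weight, b.weight)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            make_plan(arc=(1.0, 1.0))
        with pytest.raises(ValueError):
            make_plan(n_control_points=1)


class TestGroundTruthDose:
    def _static_plan(self, field=10.0, thetas=(0.0, np.pi / 2), weights=(1.0, 0.0)):
        from arcdose.synthetic import ArcPlan

        n = len(thetas)
        return ArcPlan(
            np.array(thetas),
            np.full(n, field),
            np.array(weights),
            np.full(n, 300.0),
            60.0,
            0,
            (float(thetas[0]), float(thetas[-1])),
        )

    def test_on_axis_depth_ratio_equals_pdd_ratio(self, pdd, water_cylinder):
        plan = self._static_plan()
        grid = GridSpec((1, 41, 1), (1.0, 5.0, 1.0), (0.0, -100.0, 0.0))
        dose = ground_truth_dose(plan, water_cylinder, pdd, grid)
        y = grid.axis(1)
        d = 135.0 - y  # beam from +y
        prof = dose.values[0, :, 0]
        ratio = prof[5] / prof[30]
        expect = pdd.evaluate(10.0, d[5]) / pdd.evaluate(10.0, d[30])
        assert np.isclose(ratio, expect, rtol=1e-12)

    def test_opposed_beams_half_turn_symmetry(self, pdd, water_cylinder):
        plan = self._static_plan(thetas=(0.0, np.pi), weights=(1.0, 1.0))
        grid = GridSpec.centred_cube(80.0, 8.0)
        dose = ground_truth_dose(plan, water_cylinder, pdd, grid)
        flipped = dose.values[::-1, ::-1, :]
        assert np.abs(dose.values - flipped).max() < 1e-10

    def test_linearity_in_weights(self, pdd, water_cylinder, small_grid):
        plan = make_plan(n_control_points=12, seed=5)
        dose1 = ground_truth_dose(plan, water_cylinder, pdd, small_grid)
        dose2 = ground_truth_dose(plan.scaled(2.0), water_cylinder, pdd, small_grid)
        assert np.allclose(dose2.values, 2.0 * dose1.values, rtol=0, atol=1e-12)

    def test_zero_outside_aperture_union(self, pdd, water_cylinder):
        plan = self._static_plan(field=4.0)
        grid = GridSpec((3, 3, 3), (10.0, 10.0, 10.0), (80.0, -10.0, 60.0))
        dose = ground_truth_dose(plan, water_cylinder, pdd, grid)
        assert dose.values.max() < 1e-6  # > 3 penumbra widths outside the field

    def test_low_density_insert_raises_downstream_dose(self, pdd):
        plan = self._static_plan()
        het = Phantom(kind="cylinder", inserts=(Insert((0.0, 60.0, 0.0), 25.0, 0.2),))
        hom = Phantom(kind="cylinder")
        grid = GridSpec((1, 11, 1), (1.0, 5.0, 1.0), (0.0, -25.0, 0.0))  # downstream of insert
        d_het = ground_truth_dose(plan, het, pdd, grid).values
        d_hom = ground_truth_dose(plan, hom, pdd, grid).values
        assert np.all(d_het > d_hom)

    def test_uniform_full_arc_rotationally_invariant(self, pdd, water_cylinder):
        plan = make_plan(
            n_control_points=178, field_range_cm=(6.0, 6.0), weight_jitter=0.0, seed=0
        )
        phi = np.linspace(0, 2 * np.pi, 73)
        ring = np.column_stack([20 * np.cos(phi), 20 * np.sin(phi), np.zeros_like(phi)])
        grid = GridSpec.centred_cube(60.0, 2.0)
        dose = ground_truth_dose(plan, water_cylinder, pdd, grid)
        vals = dose.sample(ring)
        assert vals.std() / vals.mean() < 0.01


class TestROIs:
    def test_sphere_volume_close_to_analytic(self):
        grid = GridSpec.centred_cube(30.0, 1.0)
        rs = make_roi_set(
            grid, [{"name": "s", "role": "OAR", "shape": "sphere", "centre_mm": (0, 0, 0), "size_mm": 10.0}]
        )
        vol = rs["s"].mask.sum() * grid.voxel_volume_cm3
        assert abs(vol - 4 / 3 * np.pi) / (4 / 3 * np.pi) < 0.02

    def test_lens_scale_roi_nonempty_on_clinical_grid(self):
        grid = GridSpec.centred_cube(100.0, 2.5)
        r = sphere_radius_for_volume_mm(0.2)
        assert 3.0 < r < 4.0
        rs = make_roi_set(
            grid, [{"name": "lens", "role": "OAR", "shape": "sphere", "centre_mm": (30, 0, 0), "size_mm": r}]
        )
        assert rs["lens"].mask.sum() > 0

    def test_disjoint_rois_do_not_intersect(self):
        grid = GridSpec.centred_cube(100.0, 2.5)
        rs = make_roi_set(
            grid,
            [
                {"name": "a", "role": "PTV", "shape": "sphere", "centre_mm": (-25, 0, 0), "size_mm": 10},
                {"name": "b", "role": "OAR", "shape": "ellipsoid", "centre_mm": (25, 0, 0), "size_mm": (10, 8, 6)},
            ],
        )
        assert not np.any(rs["a"].mask & rs["b"].mask)

    def test_roi_outside_grid_rejected(self):
        grid = GridSpec.centred_cube(40.0, 4.0)
        with pytest.raises(ValueError, match="far"):
            make_roi_set(
                grid, [{"name": "far", "role": "OAR", "shape": "sphere", "centre_mm": (500, 0, 0), "size_mm": 5}]
            )

    def test_shell_shape(self):
        grid = GridSpec.centred_cube(60.0, 2.0)
        rs = make_roi_set(
            grid, [{"name": "sh", "role": "OAR", "shape": "shell", "centre_mm": (0, 0, 0), "size_mm": (10, 20)}]
        )
        assert not rs["sh"].mask[tuple(s // 2 for s in grid.shape)]


def test_prescription_scale_sets_coverage(pdd, water_cylinder):
    grid = GridSpec.centred_cube(80.0, 4.0)
    plan = make_plan(n_control_points=24, seed=2)
    truth = ground_truth_dose(plan, water_cylinder, pdd, grid)
    rs = make_roi_set(
        grid, [{"name": "PTV", "role": "PTV", "shape": "sphere", "centre_mm": (0, 0, 0), "size_mm": 15}]
    )
    mask = rs["PTV"].mask
    s = prescription_scale(truth, mask, 60.0)
    scaled = truth.values * s
    assert np.isclose(np.quantile(scaled[mask], 0.05), 60.0, rtol=1e-9)
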