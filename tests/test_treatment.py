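"""Helical path planning and treatment homogenization."""

import numpy as np
import pytest

from histoqa import (
    BubbleCloudSpec,
    CalibrationState,
    TreatmentPlan,
    apply_treatment,
    plan_helical_path,
    rasterize_cloud_union,
)

CENTER = (25.0, 25.0, 25.0)


def _sphere_voxels(vol, center, diameter):
    x, y, z = vol.world_axes()
    d2 = (
        (x - center[0])[:, None, None] ** 2
        + (y - center[1])[None, :, None] ** 2
        + (z - center[2])[None, None, :] ** 2
    )
    return d2 <= (diameter / 2) ** 2


class TestPlanHelicalPath:
    def test_degenerate_small_plan_is_single_center(self):
        path = plan_helical_path(TreatmentPlan(center_mm=CENTER, diameter_mm=2.0))
        assert len(path) == 1
        assert np.allclose(path.centers_mm[0], CENTER)

    def test_smaller_plan_has_fewer_centers(self):
        p20 = plan_helical_path(TreatmentPlan(center_mm=CENTER, diameter_mm=20.0))
        p28 = plan_helical_path(TreatmentPlan(center_mm=CENTER, diameter_mm=28.0))
        assert len(p20) < len(p28)

    @pytest.mark.parametrize("diameter", [20.0, 28.0])
    def test_union_covers_planned_sphere(self, phantom, diameter):
        truth, _ = phantom
        path = plan_helical_path(TreatmentPlan(center_mm=CENTER, diameter_mm=diameter))
        union = rasterize_cloud_union(path, truth)
        sphere = _sphere_voxels(truth, CENTER, diameter)
        coverage = (union.values & sphere).sum() / sphere.sum()
        assert coverage >= 0.99

    def test_union_extent_stays_near_planned_diameter(self, phantom):
        truth, _ = phantom
        cloud = BubbleCloudSpec()
        path = plan_helical_path(TreatmentPlan(center_mm=CENTER, diameter_mm=28.0), cloud)
        idx = np.argwhere(rasterize_cloud_union(path, truth).values)
        w = truth.world_from_index(idx)
        for axis, semi in enumerate(cloud.semi_axes_mm):
            extent = w[:, axis].max() - w[:, axis].min()
            assert 28.0 - 1.0 <= extent <= 28.0 + 2 * semi

    def test_every_center_inside_planned_sphere(self):
        plan = TreatmentPlan(center_mm=CENTER, diameter_mm=28.0)
        path = plan_helical_path(plan)
        d = np.linalg.norm(path.centers_mm - np.asarray(CENTER), axis=1)
        assert np.all(d <= 14.0 + 1e-9)

    def test_cloud_long_axis_must_be_z(self):
        with pytest.raises(ValueError):
            BubbleCloudSpec(semi_axes_mm=(3.0, 1.5, 1.5))


class TestApplyTreatment:
    def test_zero_offset_union_centroid_at_plan_center(self, phantom):
        truth, _ = phantom
        path = plan_helical_path(TreatmentPlan(center_mm=CENTER, diameter_mm=28.0))
        _, treated = apply_treatment(truth, path, CalibrationState(), seed=0)
        c = treated.world_coords_of_true().mean(axis=0)
        assert np.all(np.abs(c - np.asarray(CENTER)) <= truth.spacing_mm / 2)

    def test_offset_displaces_treated_mask_exactly(self, phantom):
        # a whole-voxel offset translates the rasterized mask voxel-for-voxel
        truth, _ = phantom
        path = plan_helical_path(TreatmentPlan(center_mm=CENTER, diameter_mm=20.0))
        _, base = apply_treatment(truth, path, CalibrationState(), seed=0)
        v = (1.0, -1.5, 2.0)  # multiples of the 0.5 mm spacing
        _, moved = apply_treatment(truth, path, CalibrationState(v), seed=0)
        shift = tuple(int(round(x / truth.spacing_mm)) for x in v)
        rolled = np.roll(base.values, shift, axis=(0, 1, 2))
        assert np.array_equal(moved.values, rolled)

    def test_offset_displaces_centroid(self, phantom, shifted_treatment):
        truth, _ = phantom
        _, _, treated = shifted_treatment
        c = treated.world_coords_of_true().mean(axis=0)
        expected = np.asarray(CENTER) + np.array([0.0, 0.0, -2.4])
        assert np.all(np.abs(c - expected) <= truth.spacing_mm / 2)

    def test_conservation_outside_treated_region(self, phantom):
        truth, _ = phantom
        path = plan_helical_path(TreatmentPlan(center_mm=CENTER, diameter_mm=20.0))
        post, treated = apply_treatment(truth, path, CalibrationState(), seed=0)
        assert np.array_equal(post.values[~treated.values], truth.values[~treated.values])

    def test_homogenization_kills_variance(self, phantom):
        truth, _ = phantom
        path = plan_helical_path(TreatmentPlan(center_mm=CENTER, diameter_mm=20.0))
        post, treated = apply_treatment(truth, path, CalibrationState(), seed=0)
        treated_var = post.values[treated.values].var()
        # equal-size untreated layered reference region in a corner
        ref = _sphere_voxels(truth, (12.0, 12.0, 25.0), 20.0)
        assert treated_var < 0.1 * truth.values[ref].var()

    def test_second_pass_idempotent(self, phantom):
        truth, _ = phantom
        path = plan_helical_path(TreatmentPlan(center_mm=CENTER, diameter_mm=20.0))
        once, treated = apply_treatment(truth, path, CalibrationState(), seed=0)
        twice, _ = apply_treatment(once, path, CalibrationState(), seed=0)
        assert np.array_equal(once.values, twice.values)

    def test_windowed_mixing_mode_matches_layer_mean(self, phantom, default_spec):
        truth, _ = phantom
        path = plan_helical_path(TreatmentPlan(center_mm=CENTER, diameter_mm=20.0))
        post, treated = apply_treatment(
            truth, path, CalibrationState(), seed=0, full_homogenization=False
        )
        s = default_spec
        expected = (
            s.low_layer_thickness_mm * s.intensity_low
            + s.high_layer_thickness_mm * s.intensity_high
        ) / s.layer_period_mm
        # away from boundaries the window mean equals the weighted layer mean
        center_val = post.values[50, 50, 50]
        assert center_val == pytest.approx(expected, abs=1e-9)

    def test_path_outside_bounds_rejected(self, phantom):
        truth, _ = phantom
        path = plan_helical_path(TreatmentPlan(center_mm=CENTER, diameter_mm=20.0))
        with pytest.raises(ValueError):
            apply_treatment(truth, path, CalibrationState((0.0, 0.0, 40.0)), seed=0)

    def test_empty_path_rejected(self, phantom):
        truth, _ = phantom
        from histoqa import CloudPath

        with pytest.raises(ValueError):
            apply_treatment(truth, CloudPath(np.empty((0, 3))), seed=0)
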