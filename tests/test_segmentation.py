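"""Segmentation primitives and the two scene recipes on labeled constructions."""

import numpy as np
import pytest

from weightsense.cloud import PointCloud
from weightsense.segmentation import (
    EmptySegmentationError,
    SegmentationConfig,
    crop_roi,
    fit_plane_ransac,
    largest_component,
    morphological_clean,
    remove_plane_ransac,
    segment_lying,
    segment_standing,
    statistical_outlier_filter,
    subtract_background,
    thermal_segment,
)
from weightsense.synthetic import SceneSpec, render_reference, render_scene


class TestCropRoi:
    def test_inside_unchanged(self, rng):
        cloud = PointCloud(rng.uniform(0.2, 0.8, size=(30, 3)))
        assert len(crop_roi(cloud, ((0, 0, 0), (1, 1, 1)))) == 30

    def test_outside_empty(self, rng):
        cloud = PointCloud(rng.uniform(2, 3, size=(30, 3)))
        assert len(crop_roi(cloud, ((0, 0, 0), (1, 1, 1)))) == 0

    def test_partial_count(self):
        xyz = np.full((10, 3), 5.0)
        xyz[:4] = [[0.5, 0.5, 0.5]] * 4
        assert len(crop_roi(PointCloud(xyz), ((0, 0, 0), (1, 1, 1)))) == 4

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            crop_roi(PointCloud(np.zeros((1, 3))), ((0, 0, 0), (0, 1, 1)))


class TestPlaneRansac:
    def _plane_scene(self, rng):
        u = rng.uniform(-1, 1, size=(1000, 2))
        plane = np.column_stack([u[:, 0], u[:, 1], np.zeros(1000)])
        box = rng.uniform(0.2, 0.5, size=(100, 3)) + [0, 0, 0.3]
        return PointCloud(np.vstack([plane, box]))

    def test_plane_removed_box_remains(self, rng):
        cloud = self._plane_scene(rng)
        remainder, plane = remove_plane_ransac(cloud, tol=0.01, iters=300, seed=1)
        assert len(remainder) == 100
        assert abs(abs(plane.normal[2]) - 1.0) < 1e-6

    def test_normal_recovered_within_half_degree(self, rng):
        cloud = self._plane_scene(rng)
        _, plane = remove_plane_ransac(cloud, tol=0.01, iters=300, seed=1)
        angle = np.degrees(np.arccos(min(abs(plane.normal[2]), 1.0)))
        assert angle < 0.5

    def test_all_coplanar_empty_remainder(self, rng):
        u = rng.uniform(-1, 1, size=(200, 2))
        cloud = PointCloud(np.column_stack([u, np.zeros(200)]))
        remainder, _ = remove_plane_ransac(cloud, tol=0.01, iters=100, seed=0)
        assert len(remainder) == 0

    def test_seed_reproducible_bit_exact(self, rng):
        cloud = self._plane_scene(rng)
        p1 = fit_plane_ransac(cloud.xyz, 0.01, 200, seed=7)
        p2 = fit_plane_ransac(cloud.xyz, 0.01, 200, seed=7)
        assert np.array_equal(p1.normal, p2.normal) and p1.offset == p2.offset

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_plane_ransac(np.zeros((2, 3)), 0.01)


class TestThermalSegment:
    def test_all_warm_kept(self):
        cloud = PointCloud(np.zeros((5, 3)), temperature=np.full(5, 36.0))
        assert len(thermal_segment(cloud, 30.0)) == 5

    def test_half_warm(self):
        t = np.array([36.0] * 5 + [22.0] * 5)
        cloud = PointCloud(np.zeros((10, 3)), temperature=t)
        assert len(thermal_segment(cloud, 30.0)) == 5

    def test_threshold_above_all_empty(self):
        cloud = PointCloud(np.zeros((5, 3)), temperature=np.full(5, 36.0))
        assert len(thermal_segment(cloud, 40.0)) == 0

    def test_missing_channel_is_config_error(self):
        with pytest.raises(ValueError):
            thermal_segment(PointCloud(np.zeros((5, 3))), 30.0)


class TestBackgroundSubtraction:
    def test_identical_scene_empty(self, rng):
        xyz = rng.normal(size=(50, 3))
        scene = PointCloud(xyz.copy())
        ref = PointCloud(xyz.copy())
        assert len(subtract_background(scene, ref, 0.05)) == 0

    def test_organized_person_pixels_survive(self):
        h, w = 10, 10
        ref_z = np.full((h, w), 3.0)
        scene_z = ref_z.copy()
        scene_z[3:7, 4:8] = 1.5  # person surface
        grid = np.stack(np.meshgrid(np.arange(w), np.arange(h)), -1).reshape(-1, 2) * 0.01
        ref = PointCloud(np.column_stack([grid, ref_z.ravel()]), organized=(h, w))
        scene = PointCloud(np.column_stack([grid, scene_z.ravel()]), organized=(h, w))
        out = subtract_background(scene, ref, 0.1)
        assert len(out) == 16
        np.testing.assert_allclose(out.xyz[:, 2], 1.5)

    def test_large_threshold_empty(self, rng):
        scene = PointCloud(rng.normal(size=(50, 3)))
        ref = PointCloud(rng.normal(size=(50, 3)))
        assert len(subtract_background(scene, ref, 1e6)) == 0

    def test_mismatched_grids_rejected(self):
        a = PointCloud(np.zeros((4, 3)), organized=(2, 2))
        b = PointCloud(np.zeros((6, 3)), organized=(2, 3))
        with pytest.raises(ValueError):
            subtract_background(a, b, 0.05)


class TestLargestComponent:
    def test_single_blob_identity(self, rng):
        cloud = PointCloud(rng.normal(scale=0.01, size=(100, 3)))
        assert len(largest_component(cloud, 0.05)) == 100

    def test_two_blobs(self, rng):
        big = rng.normal(scale=0.01, size=(500, 3))
        small = rng.normal(scale=0.01, size=(50, 3)) + [1, 0, 0]
        out = largest_component(PointCloud(np.vstack([big, small])), 0.05)
        assert len(out) == 500
        assert np.all(out.xyz[:, 0] < 0.5)

    def test_empty_input_empty_output(self):
        assert len(largest_component(PointCloud(np.empty((0, 3))), 0.05)) == 0

    def test_tie_broken_by_sensor_distance(self):
        near = np.array([[0, 0, 1.0], [0, 0.01, 1.0]])
        far = np.array([[0, 0, 3.0], [0, 0.01, 3.0]])
        out = largest_component(PointCloud(np.vstack([far, near])), 0.05)
        np.testing.assert_allclose(out.xyz[:, 2], 1.0)


class TestMorphology:
    def test_large_square_nearly_preserved(self):
        # a disc element rounds the 4 sharp corners, nothing else
        mask = np.zeros((60, 60), bool)
        mask[5:55, 5:55] = True
        cleaned = morphological_clean(mask, 2)
        assert cleaned.sum() >= 0.99 * mask.sum()
        assert not np.any(cleaned & ~mask)

    def test_isolated_pixel_removed(self):
        mask = np.zeros((20, 20), bool)
        mask[10, 10] = True
        assert morphological_clean(mask, 1).sum() == 0

    def test_speckles_removed_square_kept(self):
        mask = np.zeros((40, 40), bool)
        mask[5:25, 5:25] = True
        mask[30, 30] = mask[35, 2] = mask[2, 35] = True
        cleaned = morphological_clean(mask, 1)
        assert not cleaned[30, 30] and not cleaned[35, 2] and not cleaned[2, 35]
        assert cleaned.sum() >= 396  # square minus at most the 4 corners
        assert not np.any(cleaned & ~mask)

    def test_result_subset_of_input(self, rng):
        mask = rng.random((30, 30)) > 0.5
        cleaned = morphological_clean(mask, 1)
        assert not np.any(cleaned & ~mask)


class TestOutlierFilter:
    def _grid(self):
        g = np.stack(np.meshgrid(np.arange(10), np.arange(10)), -1).reshape(-1, 2) * 0.01
        return np.column_stack([g, np.zeros(100)])

    def test_symmetric_cloud_unchanged(self):
        # every point of a regular ring has the identical neighbor statistic
        theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        ring = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(100)])
        assert len(statistical_outlier_filter(PointCloud(ring), 8, 2.0)) == 100

    def test_displaced_point_removed(self):
        pts = self._grid()
        pts[50] += [0, 0, 1.0]
        out = statistical_outlier_filter(PointCloud(pts), 8, 2.0)
        assert len(out) == 99
        assert np.all(out.xyz[:, 2] < 0.5)

    def test_infinite_sigma_keeps_all(self):
        pts = self._grid()
        pts[50] += [0, 0, 1.0]
        assert len(statistical_outlier_filter(PointCloud(pts), 8, np.inf)) == 100

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            statistical_outlier_filter(PointCloud(np.zeros((5, 3))), 8, 2.0)


class TestLyingRecipe:
    def test_person_recovered_with_thermal(self, subject):
        spec = SceneSpec(mode="lying", bystander=True)
        cloud, labels = render_scene(subject, spec, seed=21)
        seg = segment_lying(cloud, SegmentationConfig(roi=spec.lying_roi()))
        person = np.zeros(len(cloud), bool)
        person[seg.person_indices] = True
        truth = labels == 1
        assert (person & truth).sum() / truth.sum() >= 0.99
        assert (person & (labels == 0)).sum() / (labels == 0).sum() <= 0.01

    def test_partition_invariant(self, lying_frame, seg_cfg):
        spec, cloud, _ = lying_frame
        seg_cfg.roi = spec.lying_roi()
        seg = segment_lying(cloud, seg_cfg)
        assert seg.person.n_valid + seg.environment.n_valid == cloud.n_valid
        assert seg.support_plane is not None

    def test_empty_scene_raises(self, seg_cfg):
        spec = SceneSpec(mode="lying")
        ref = render_reference(spec, seed=3)  # stretcher and floor, no person
        seg_cfg.roi = spec.lying_roi()
        with pytest.raises(EmptySegmentationError):
            segment_lying(ref, seg_cfg)

    def test_geometric_fallback_without_thermal(self, subject, seg_cfg):
        spec = SceneSpec(mode="lying", thermal=False)
        cloud, labels = render_scene(subject, spec, seed=22)
        seg_cfg.roi = spec.lying_roi()
        seg = segment_lying(cloud, seg_cfg)
        person = np.zeros(len(cloud), bool)
        person[seg.person_indices] = True
        truth = labels == 1
        assert (person & truth).sum() / truth.sum() >= 0.99


class TestStandingRecipe:
    def test_person_recovered(self, standing_frame, seg_cfg):
        spec, cloud, labels, ref = standing_frame
        seg = segment_standing(cloud, ref, seg_cfg)
        person = np.zeros(len(cloud), bool)
        person[seg.person_indices] = True
        truth = labels == 1
        assert (person & truth).sum() / truth.sum() >= 0.99
        assert (person & (labels == 0)).sum() / (labels == 0).sum() <= 0.01

    def test_partition_invariant(self, standing_frame, seg_cfg):
        _, cloud, _, ref = standing_frame
        seg = segment_standing(cloud, ref, seg_cfg)
        assert seg.person.n_valid + seg.environment.n_valid == cloud.n_valid

    def test_person_absent_raises(self, standing_frame, seg_cfg):
        spec, _, _, ref = standing_frame
        other = render_reference(spec, seed=77)
        with pytest.raises(EmptySegmentationError):
            segment_standing(other, ref, seg_cfg)

    def test_clutter_rejected_by_largest_component(self, subject, seg_cfg):
        spec = SceneSpec(mode="standing", thermal=False, bystander=True)
        cloud, labels = render_scene(subject, spec, seed=23)
        ref = render_reference(spec, seed=24)
        seg = segment_standing(cloud, ref, seg_cfg)
        person = np.zeros(len(cloud), bool)
        person[seg.person_indices] = True
        truth = labels == 1
        assert (person & truth).sum() / truth.sum() >= 0.99
        assert (person & (labels == 0)).sum() / (labels == 0).sum() <= 0.01
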