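"""Synthetic phantom: poses, tracking noise, rendering, dataset assembly."""

import numpy as np
import pytest
from scipy import stats

from usncal import (
    PhantomConfig,
    PixelPoint,
    add_tracking_noise,
    generate_dataset,
    intersect_line_with_image_plane,
    make_ground_truth_calibration,
    render_reflection_image,
    sample_needle_pose,
)
from usncal.errors import InvalidCount
from usncal.phantom import (
    blob_semi_axes,
    insertion_angle_deg,
    intensity_weighted_centroid,
    sample_calibration_observations,
    _GRID,
)


class TestGroundTruthCalibration:
    def test_deterministic_under_seed(self, native_config):
        a = make_ground_truth_calibration(native_config, np.random.default_rng(5))
        b = make_ground_truth_calibration(native_config, np.random.default_rng(5))
        assert np.array_equal(a.matrix, b.matrix)

    def test_column_norms_are_pixel_spacings(self, native_config):
        T = make_ground_truth_calibration(native_config, np.random.default_rng(1))
        norms = np.linalg.norm(T.matrix[:3, :3], axis=0)
        assert norms == pytest.approx([0.097, 0.102, 0.0995])

    def test_block_determinant_positive(self, native_config):
        T = make_ground_truth_calibration(native_config, np.random.default_rng(2))
        assert np.linalg.det(T.matrix[:3, :3]) == pytest.approx(
            0.097 * 0.102 * 0.0995
        )

    def test_translation_within_tracker_volume(self, native_config):
        for seed in range(10):
            T = make_ground_truth_calibration(native_config, np.random.default_rng(seed))
            assert np.linalg.norm(T.translation) <= 500.0


class TestNeedlePose:
    def test_line_pierces_plane_at_target(self, native_config, ground_truth):
        rng = np.random.default_rng(0)
        for _ in range(20):
            target = PixelPoint(rng.uniform(0, 355), rng.uniform(0, 588))
            line = sample_needle_pose(ground_truth, target, native_config, rng)
            hit = intersect_line_with_image_plane(ground_truth, line)
            assert np.allclose([hit.u, hit.v], [target.u, target.v], atol=1e-6)

    def test_insertion_angle_within_configured_range(self, native_config, ground_truth):
        rng = np.random.default_rng(1)
        lo, hi = native_config.insertion_angle_range
        for _ in range(50):
            line = sample_needle_pose(
                ground_truth, PixelPoint(100, 200), native_config, rng
            )
            assert lo - 1e-9 <= insertion_angle_deg(ground_truth, line) <= hi + 1e-9

    def test_angle_distribution_uniform_by_ks(self, native_config, ground_truth):
        rng = np.random.default_rng(2)
        angles = np.array([
            insertion_angle_deg(
                ground_truth,
                sample_needle_pose(ground_truth, PixelPoint(150, 300), native_config, rng),
            )
            for _ in range(1000)
        ])
        lo, hi = native_config.insertion_angle_range
        res = stats.kstest(angles, stats.uniform(loc=lo, scale=hi - lo).cdf)
        assert res.pvalue > 0.01

    def test_tip_distance_from_plane_in_range(self, native_config, ground_truth):
        rng = np.random.default_rng(3)
        normal = ground_truth.plane_normal
        for _ in range(20):
            target = PixelPoint(50, 400)
            line = sample_needle_pose(ground_truth, target, native_config, rng)
            from usncal import lift_pixel_to_tracker

            pierce = lift_pixel_to_tracker(ground_truth, target)
            h = abs(float(np.dot(line.tip - pierce, normal)))
            lo, hi = native_config.tip_distance_range_mm
            assert lo - 1e-6 <= h <= hi + 1e-6


class TestTrackingNoise:
    def test_zero_noise_returns_input_unchanged(self, quiet_config):
        from usncal import NeedleLine

        line = NeedleLine((1, 2, 3), (0, 0.6, 0.8))
        out = add_tracking_noise(line, quiet_config, np.random.default_rng(0))
        assert out is line

    def test_rms_tip_displacement_matches_spec(self, native_config):
        from usncal import NeedleLine

        rng = np.random.default_rng(4)
        line = NeedleLine((0, 0, 0), (1, 0, 0))
        disp = np.array([
            np.linalg.norm(add_tracking_noise(line, native_config, rng).tip)
            for _ in range(10_000)
        ])
        rms = np.sqrt(np.mean(disp**2))
        assert rms == pytest.approx(1.2, rel=0.05)

    def test_rms_direction_rotation_matches_spec(self, native_config):
        from usncal import NeedleLine

        rng = np.random.default_rng(5)
        line = NeedleLine((0, 0, 0), (1, 0, 0))
        ang = np.array([
            np.degrees(
                np.arccos(
                    np.clip(add_tracking_noise(line, native_config, rng).direction @ line.direction, -1, 1)
                )
            )
            for _ in range(10_000)
        ])
        # the angle between old and new direction is |gaussian| scaled by the
        # random axis' component perpendicular to the direction
        assert np.sqrt(np.mean(ang**2)) < 0.5 + 0.05
        assert np.sqrt(np.mean(ang**2)) > 0.2

    def test_noisy_direction_stays_unit(self, native_config):
        from usncal import NeedleLine

        rng = np.random.default_rng(6)
        line = NeedleLine((0, 0, 0), (0.48, -0.6, 0.64))
        for _ in range(100):
            out = add_tracking_noise(line, native_config, rng)
            assert np.linalg.norm(out.direction) == pytest.approx(1.0, abs=1e-9)


class TestRendering:
    def test_deterministic_under_seed(self, native_config):
        a = render_reflection_image(PixelPoint(100, 300), 45.0, native_config, 9)
        b = render_reflection_image(PixelPoint(100, 300), 45.0, native_config, 9)
        assert np.array_equal(a, b)

    def test_background_is_dim(self, native_config):
        img = render_reflection_image(PixelPoint(30, 30), 45.0, native_config, 0)
        assert img.mean() < 15.0
        assert img.dtype == np.uint8

    def test_farfield_blob_is_larger(self, native_config):
        H = native_config.image_height
        near = render_reflection_image(
            PixelPoint(178, 0.1 * H), 45.0, native_config, 1, heading=0.0
        )
        far = render_reflection_image(
            PixelPoint(178, 0.9 * H), 45.0, native_config, 1, heading=0.0
        )
        thresh = 60
        assert (far > thresh).sum() > (near > thresh).sum()

    def test_oblique_insertions_elongate_the_blob(self, native_config):
        steep = render_reflection_image(
            PixelPoint(178, 300), 70.0, native_config, 1, heading=0.0
        )
        shallow = render_reflection_image(
            PixelPoint(178, 300), 25.0, native_config, 1, heading=0.0
        )
        assert (shallow > 60).sum() > (steep > 60).sum()

    @pytest.mark.parametrize("u,v,angle", [(100, 150, 40.0), (250, 450, 65.0), (178, 294, 25.0)])
    def test_intensity_weighted_centroid_near_request(self, native_config, u, v, angle):
        img = render_reflection_image(PixelPoint(u, v), angle, native_config, 3)
        c = intensity_weighted_centroid(img)
        assert np.hypot(c.u - u, c.v - v) < 1.5

    def test_semi_axes_follow_size_law(self, native_config):
        a1, b1 = blob_semi_axes(0.0, 30.0, native_config)
        a2, b2 = blob_semi_axes(native_config.image_height, 30.0, native_config)
        assert b2 == pytest.approx(b1 * (1 + native_config.farfield_gain))
        assert a1 == pytest.approx(b1 / np.sin(np.radians(30.0)))


class TestGenerateDataset:
    def test_labels_come_from_inverse_calibration(self, native_config):
        frames, T_gt = generate_dataset(10, native_config, np.random.default_rng(1))
        for f in frames:
            hit = intersect_line_with_image_plane(T_gt, f.pose)
            assert np.allclose([hit.u, hit.v], [f.label.u, f.label.v], atol=1e-9)

    def test_requested_count_is_exact_and_in_bounds(self, native_config):
        frames, _ = generate_dataset(50, native_config, np.random.default_rng(2))
        assert len(frames) == 50
        for f in frames:
            assert f.label.in_bounds(native_config.image_width, native_config.image_height)

    def test_stratification_covers_all_grid_cells(self, native_config):
        frames, _ = generate_dataset(64, native_config, np.random.default_rng(3))
        W, H = native_config.image_width, native_config.image_height
        cells = set()
        for f in frames:
            cu = min(int(f.label.u / ((W - 1) / _GRID)), _GRID - 1)
            cv = min(int(f.label.v / ((H - 1) / _GRID)), _GRID - 1)
            cells.add((cu, cv))
        assert len(cells) == _GRID * _GRID

    def test_bitwise_reproducible_under_seed(self, native_config):
        fa, Ta = generate_dataset(4, native_config, np.random.default_rng(7))
        fb, Tb = generate_dataset(4, native_config, np.random.default_rng(7))
        assert np.array_equal(Ta.matrix, Tb.matrix)
        for a, b in zip(fa, fb):
            assert np.array_equal(a.image, b.image)
            assert (a.label.u, a.label.v) == (b.label.u, b.label.v)
            assert np.array_equal(a.pose.tip, b.pose.tip)

    def test_labels_are_independent_of_rendering(self, native_config):
        """Label provenance is geometric: skipping rendering changes nothing."""
        fa, Ta = generate_dataset(6, native_config, np.random.default_rng(11))
        fb, Tb = generate_dataset(6, native_config, np.random.default_rng(11), render=False)
        assert np.array_equal(Ta.matrix, Tb.matrix)
        for a, b in zip(fa, fb):
            assert (a.label.u, a.label.v) == (b.label.u, b.label.v)

    def test_invalid_count_rejected(self, native_config):
        with pytest.raises(InvalidCount):
            generate_dataset(0, native_config, np.random.default_rng(0))

    def test_calibration_observations_respect_geometry(self, native_config, ground_truth):
        obs = sample_calibration_observations(
            ground_truth, 8, native_config, np.random.default_rng(1)
        )
        assert len(obs) == 8
        for label, pose, noisy in obs:
            hit = intersect_line_with_image_plane(ground_truth, pose)
            assert np.allclose([hit.u, hit.v], [label.u, label.v], atol=1e-9)
            assert np.linalg.norm(noisy.direction) == pytest.approx(1.0, abs=1e-9)
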