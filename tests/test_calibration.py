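"""Anisotropic Procrustes, the ICP point-to-line fit, TRE and spacings."""

import numpy as np
import pytest
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from usncal import (
    NeedleLine,
    PhantomConfig,
    PixelPoint,
    PointLineCalibration,
    PointLinePair,
    RigidScaledTransform,
    calibrate,
    compute_tre,
    extract_pixel_spacings,
    make_ground_truth_calibration,
    point_to_line_distance,
    solve_anisotropic_procrustes,
    tre_vs_n_pairs,
)
from usncal.errors import (
    DegenerateConfiguration,
    DegenerateLines,
    EmptyPairs,
    InsufficientPairs,
    NonDecomposable,
)
from usncal.phantom import sample_calibration_observations


def random_rotation(seed):
    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()


def noiseless_pairs(T_gt, n, config, seed):
    obs = sample_calibration_observations(T_gt, n, config, np.random.default_rng(seed))
    return [PointLinePair(label, pose) for label, pose, _ in obs]


class TestAnisotropicProcrustes:
    def test_identity_when_targets_equal_sources(self):
        P = np.random.default_rng(0).uniform(-10, 10, (8, 3))
        T = solve_anisotropic_procrustes(P, P)
        assert np.allclose(T.matrix, np.eye(4), atol=1e-9)

    def test_pure_translation_recovered(self):
        P = np.random.default_rng(1).uniform(-10, 10, (8, 3))
        T = solve_anisotropic_procrustes(P, P + np.array([3.0, -2.0, 5.0]))
        assert np.allclose(T.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(T.scales, 1.0, atol=1e-9)
        assert np.allclose(T.translation, [3, -2, 5], atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_constructed_transform(self, seed):
        rng = np.random.default_rng(seed)
        R0 = random_rotation(seed)
        S0 = np.array([0.1, 0.2, 0.15])
        t0 = rng.uniform(-50, 50, 3)
        P = rng.uniform(-50, 50, (20, 3))
        Q = (P * S0) @ R0.T + t0
        T = solve_anisotropic_procrustes(P, Q)
        assert np.allclose(T.scales, S0, rtol=1e-9)
        assert np.allclose(T.rotation, R0, atol=1e-9)
        assert np.allclose(T.translation, t0, atol=1e-7)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_nonlinear_least_squares_oracle(self, seed):
        """Alternating solve agrees with a generic NLS fit of the same objective."""
        rng = np.random.default_rng(100 + seed)
        P = rng.uniform(-30, 30, (20, 3))
        Q = (P * [0.12, 0.21, 0.16]) @ random_rotation(seed).T + rng.uniform(-20, 20, 3)
        Q = Q + rng.normal(0, 0.05, Q.shape)  # noise so the optimum is interior
        T = solve_anisotropic_procrustes(P, Q)

        def resid(x):
            R = Rotation.from_rotvec(x[:3]).as_matrix()
            return (((P * x[3:6]) @ R.T + x[6:]) - Q).ravel()

        x0 = np.concatenate([
            Rotation.from_matrix(T.rotation).as_rotvec(),
            T.scales, T.translation,
        ])
        # perturb so the oracle does its own work
        sol = least_squares(resid, x0 + 1e-3, method="lm", xtol=1e-15, ftol=1e-15)
        obj_alt = float(np.sum(resid(x0) ** 2))
        obj_nls = float(np.sum(sol.fun**2))
        assert obj_alt == pytest.approx(obj_nls, rel=1e-6)

    def test_planar_sources_fix_elevation_scale(self):
        rng = np.random.default_rng(3)
        R0 = random_rotation(33)
        P = np.column_stack([rng.uniform(0, 355, 12), rng.uniform(0, 588, 12), np.zeros(12)])
        Q = (P * [0.097, 0.102, 0.5]) @ R0.T
        T = solve_anisotropic_procrustes(P, Q)
        assert T.scales[0] == pytest.approx(0.097, rel=1e-9)
        assert T.scales[1] == pytest.approx(0.102, rel=1e-9)
        assert T.scales[2] == pytest.approx(0.5 * (0.097 + 0.102), rel=1e-12)

    def test_collinear_sources_rejected(self):
        t = np.linspace(0, 1, 8)
        P = np.column_stack([t, 2 * t, 3 * t])
        with pytest.raises(DegenerateConfiguration):
            solve_anisotropic_procrustes(P, P)

    def test_too_few_points_rejected(self):
        P = np.random.default_rng(0).uniform(0, 1, (3, 3))
        with pytest.raises(DegenerateConfiguration):
            solve_anisotropic_procrustes(P, P)


class TestCalibrationFit:
    def test_noiseless_recovery(self, native_config, ground_truth):
        pairs = noiseless_pairs(ground_truth, 12, native_config, seed=1)
        res = PointLineCalibration(pairs).fit()
        c = res.compare_to(ground_truth)
        assert c["rotation_error_deg"] < 0.01
        assert c["translation_error_mm"] < 0.01
        assert c["scale_error_pct_lateral"] < 0.1
        assert c["scale_error_pct_axial"] < 0.1
        assert res.tre_mm < 1e-6
        assert res.converged

    @pytest.mark.parametrize("seed", range(12))
    def test_noiseless_recovery_across_seeds(self, native_config, seed):
        T_gt = make_ground_truth_calibration(native_config, np.random.default_rng(seed))
        pairs = noiseless_pairs(T_gt, 10, native_config, seed=1000 + seed)
        res = PointLineCalibration(pairs).fit()
        assert res.tre_mm < 1e-6
        assert res.compare_to(T_gt)["rotation_error_deg"] < 0.01

    def test_equivariance_under_rigid_motion(self, native_config, ground_truth):
        pairs = noiseless_pairs(ground_truth, 10, native_config, seed=2)
        G = np.eye(4)
        G[:3, :3] = random_rotation(9)
        G[:3, 3] = [40.0, -25.0, 60.0]
        moved = [
            PointLinePair(p.point, p.line.transformed(G)) for p in pairs
        ]
        res = PointLineCalibration(moved).fit()
        expected = ground_truth.compose_left(G)
        c = res.compare_to(expected)
        assert c["rotation_error_deg"] < 0.01
        assert c["translation_error_mm"] < 0.01
        assert c["scale_error_pct_lateral"] < 0.1

    def test_identity_preserving_configuration(self):
        rng = np.random.default_rng(5)
        pts = [PixelPoint(u, v) for u, v in rng.uniform(10, 300, (8, 2))]
        # lines passing exactly through the identity-mapped pixel points
        pairs = []
        for p in pts:
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            pairs.append(PointLinePair(p, NeedleLine(np.array([p.u, p.v, 0.0]) - 7 * d, d)))
        init = RigidScaledTransform.identity()
        res = PointLineCalibration(pairs).fit(init=init)
        assert res.tre_mm < 1e-9

    def test_insufficient_pairs_raises(self, native_config, ground_truth):
        pairs = noiseless_pairs(ground_truth, 5, native_config, seed=3)
        with pytest.raises(InsufficientPairs):
            calibrate(pairs)

    def test_parallel_lines_rejected(self):
        d = np.array([0.0, 0.6, 0.8])
        pairs = [
            PointLinePair(PixelPoint(10 * i, 20 * i), NeedleLine((i, 0, 0), d))
            for i in range(1, 8)
        ]
        with pytest.raises(DegenerateLines):
            PointLineCalibration(pairs)

    def test_tre_history_non_increasing(self, native_config, ground_truth):
        obs = sample_calibration_observations(
            ground_truth, 12, native_config, np.random.default_rng(4)
        )
        pairs = [PointLinePair(label, noisy) for label, _, noisy in obs]
        res = PointLineCalibration(pairs).fit()
        h = np.array(res.tre_history)
        assert np.all(np.diff(h) <= 1e-9)

    def test_summary_mentions_key_quantities(self, native_config, ground_truth):
        pairs = noiseless_pairs(ground_truth, 8, native_config, seed=6)
        res = PointLineCalibration(pairs).fit()
        text = res.summary()
        assert "TRE" in text and "spacing" in text


class TestTre:
    def test_perfect_calibration_gives_zero(self, native_config, ground_truth):
        pairs = noiseless_pairs(ground_truth, 8, native_config, seed=7)
        assert compute_tre(ground_truth, pairs) < 1e-9

    def test_unit_perpendicular_displacement(self):
        line = NeedleLine((1.0, 0.0, 0.0), (0, 0, 1))
        pair = PointLinePair(PixelPoint(0, 0), line)
        assert compute_tre(RigidScaledTransform.identity(), [pair]) == pytest.approx(1.0)

    def test_matches_distance_oracle(self, native_config, ground_truth):
        rng = np.random.default_rng(8)
        obs = sample_calibration_observations(ground_truth, 10, native_config, rng)
        pairs = [PointLinePair(label, noisy) for label, _, noisy in obs]
        T = make_ground_truth_calibration(native_config, rng)
        M, t = T.matrix[:3, :3], T.translation
        d2 = [
            point_to_line_distance(M @ [p.point.u, p.point.v, 0] + t, p.line) ** 2
            for p in pairs
        ]
        assert compute_tre(T, pairs) == pytest.approx(float(np.sqrt(np.mean(d2))), rel=1e-9)

    def test_empty_pairs_rejected(self, ground_truth):
        with pytest.raises(EmptyPairs):
            compute_tre(ground_truth, [])


class TestPixelSpacings:
    def test_identity(self):
        assert extract_pixel_spacings(RigidScaledTransform.identity()) == (1.0, 1.0)

    def test_axis_aligned_scales(self):
        T = RigidScaledTransform.from_parts(np.eye(3), (0.097, 0.102, 0.1), (0, 0, 0))
        assert extract_pixel_spacings(T) == pytest.approx((0.097, 0.102))

    @pytest.mark.parametrize("seed", range(5))
    def test_invariant_to_rotation_and_translation(self, seed):
        T = RigidScaledTransform.from_parts(
            random_rotation(seed), (0.097, 0.102, 0.1),
            np.random.default_rng(seed).uniform(-100, 100, 3),
        )
        lat, axi = extract_pixel_spacings(T)
        assert lat == pytest.approx(0.097, abs=1e-12)
        assert axi == pytest.approx(0.102, abs=1e-12)

    def test_shear_detected(self):
        from usncal.geometry import require_rotation_times_diag

        block = np.eye(3)
        block[0, 1] = 0.3
        with pytest.raises(NonDecomposable):
            require_rotation_times_diag(block)


class TestTreVsNPairs:
    def test_zero_noise_gives_zero_everywhere(self, quiet_config, ground_truth):
        curve = tre_vs_n_pairs(
            ground_truth, quiet_config, np.random.default_rng(0),
            ns=(6, 9), n_trials=3, n_holdout=8,
        )
        assert all(v < 1e-6 for v in curve.values())

    def test_smallest_n_below_minimum_rejected(self, native_config, ground_truth):
        with pytest.raises(InsufficientPairs):
            tre_vs_n_pairs(ground_truth, native_config, ns=(4, 9), n_trials=1)
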