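"""Registration solvers: Kabsch, ICP, CPD, GMM-L2, FPFH+RANSAC, overlap head."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import multivariate_normal

from c2pbench.geometry import (
    GeometryError,
    PointCloud,
    RigidTransform,
    apply_rigid,
)
from c2pbench.registration import (
    CorrespondenceSet,
    OverlapHeadParams,
    compute_fpfh,
    compute_losses,
    cpd_rigid_register,
    descriptor_correspondences,
    gmm_l2_distance,
    gmmreg_register,
    icp_register,
    overlap_head,
    ransac_pose,
    weighted_kabsch_umeyama,
)


def _random_transform(rng, angle_scale=1.0, trans_scale=1.0) -> RigidTransform:
    rotvec = rng.normal(size=3)
    rotvec *= angle_scale / max(np.linalg.norm(rotvec), 1e-12)
    return RigidTransform(
        Rotation.from_rotvec(rotvec).as_matrix(), trans_scale * rng.normal(size=3)
    )


def _unweighted_umeyama_oracle(src: np.ndarray, tgt: np.ndarray) -> RigidTransform:
    """Independent oracle: rotation via scipy's Wahba solver on centered sets."""
    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    rot, _ = Rotation.align_vectors(tgt - mu_t, src - mu_s)
    R = rot.as_matrix()
    return RigidTransform(R, mu_t - R @ mu_s)


class TestWeightedKabsch:
    @pytest.mark.parametrize("seed", range(5))
    def test_exact_recovery_uniform_weights(self, seed):
        rng = np.random.default_rng(seed)
        src = rng.normal(size=(30, 3))
        T = _random_transform(rng)
        tgt = T.apply(src)
        est = weighted_kabsch_umeyama(src, tgt)
        np.testing.assert_allclose(est.as_matrix(), T.as_matrix(), atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_unweighted_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        src = rng.normal(size=(25, 3))
        tgt = _random_transform(rng).apply(src) + 0.01 * rng.normal(size=(25, 3))
        est = weighted_kabsch_umeyama(src, tgt)
        oracle = _unweighted_umeyama_oracle(src, tgt)
        np.testing.assert_allclose(est.as_matrix(), oracle.as_matrix(), atol=1e-10)

    def test_zero_weight_equals_exclusion(self):
        rng = np.random.default_rng(2)
        src = rng.normal(size=(20, 3))
        T = _random_transform(rng)
        tgt = T.apply(src)
        # corrupt the last five points, then weight them out
        tgt_bad = tgt.copy()
        tgt_bad[15:] += rng.normal(size=(5, 3))
        w = np.ones(20)
        w[15:] = 0.0
        with_weights = weighted_kabsch_umeyama(src, tgt_bad, w)
        without = weighted_kabsch_umeyama(src[:15], tgt[:15])
        np.testing.assert_allclose(
            with_weights.as_matrix(), without.as_matrix(), atol=1e-10
        )

    def test_identity_for_equal_sets(self):
        src = np.random.default_rng(3).normal(size=(10, 3))
        est = weighted_kabsch_umeyama(src, src)
        np.testing.assert_allclose(est.as_matrix(), np.eye(4), atol=1e-12)

    def test_collinear_support_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(GeometryError, match="collinear"):
            weighted_kabsch_umeyama(line, line + [1.0, 0, 0])


class TestICP:
    def test_self_registration_identity(self):
        cloud = PointCloud(np.random.default_rng(0).normal(size=(200, 3)))
        res = icp_register(cloud, cloud)
        np.testing.assert_allclose(res.transform.as_matrix(), np.eye(4), atol=1e-9)
        assert res.final_residual < 1e-12

    def test_small_motion_full_overlap_recovery(self):
        rng = np.random.default_rng(1)
        src = PointCloud(rng.uniform(-1, 1, (800, 3)), frame="normalized")
        T = RigidTransform(
            Rotation.from_euler("z", 5, degrees=True).as_matrix(), [0.05, 0.0, 0.0]
        )
        res = icp_register(src, apply_rigid(src, T))
        rel = res.transform.inverse() @ T
        assert rel.rotation_angle_deg() < 0.1
        assert np.linalg.norm(res.transform.translation - T.translation) < 0.001

    def test_zero_iterations_returns_identity(self):
        cloud = PointCloud(np.random.default_rng(2).normal(size=(50, 3)))
        res = icp_register(cloud, cloud, max_iter=0)
        np.testing.assert_array_equal(res.transform.as_matrix(), np.eye(4))
        assert res.n_iterations == 0

    def test_residual_monotone(self, recovery_pair):
        res = icp_register(recovery_pair.source, recovery_pair.target, threshold=0.0)
        assert np.all(np.diff(res.history) <= 1e-12)


class TestCPD:
    def test_identical_clouds_identity(self):
        cloud = PointCloud(np.random.default_rng(0).normal(size=(150, 3)))
        res = cpd_rigid_register(cloud, cloud)
        np.testing.assert_allclose(res.transform.as_matrix(), np.eye(4), atol=1e-6)

    def test_small_rotation_recovery(self):
        rng = np.random.default_rng(1)
        src = PointCloud(rng.uniform(-1, 1, (400, 3)), frame="normalized")
        T = RigidTransform(
            Rotation.from_euler("y", 8, degrees=True).as_matrix(), [0.03, -0.02, 0.01]
        )
        res = cpd_rigid_register(src, apply_rigid(src, T))
        rel = res.transform.inverse() @ T
        assert rel.rotation_angle_deg() < 0.5
        assert np.linalg.norm(res.transform.translation - T.translation) < 0.005

    def test_nll_monotone(self, recovery_pair):
        res = cpd_rigid_register(recovery_pair.source, recovery_pair.target)
        assert np.all(np.diff(res.history) <= 1e-6 * max(1.0, abs(res.history[0])))

    def test_variance_collapse_flagged_on_exact_data(self):
        cloud = PointCloud(np.random.default_rng(3).normal(size=(100, 3)))
        res = cpd_rigid_register(cloud, cloud)
        assert "variance_collapse" in res.flags


class TestGMMReg:
    def test_self_distance_minimal_at_identity(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-1, 1, (80, 3))
        d_self = gmm_l2_distance(pts, pts, h=0.2)
        for seed in range(100):
            T = _random_transform(np.random.default_rng(seed), 0.5, 0.3)
            assert gmm_l2_distance(T.apply(pts), pts, h=0.2) >= d_self - 1e-12

    def test_closed_form_matches_monte_carlo(self):
        h = 0.3
        mu = np.array([[0.1, 0.2, -0.1]])
        nu = np.array([[0.3, -0.1, 0.2]])
        closed = gmm_l2_distance(mu, nu, h)
        rng = np.random.default_rng(1)
        n = 10**6
        comp = rng.random(n) < 0.5
        x = np.where(comp[:, None], mu, nu) + rng.normal(0, h, (n, 3))
        f = multivariate_normal.pdf(x, mu[0], h**2 * np.eye(3))
        g = multivariate_normal.pdf(x, nu[0], h**2 * np.eye(3))
        mc = np.mean((f - g) ** 2 / (0.5 * (f + g)))
        assert closed == pytest.approx(mc, rel=0.01)

    def test_small_rotation_recovery(self):
        rng = np.random.default_rng(2)
        src = PointCloud(rng.uniform(-1, 1, (300, 3)), frame="normalized")
        T = RigidTransform(
            Rotation.from_euler("x", 6, degrees=True).as_matrix(), [0.02, 0.01, -0.03]
        )
        res = gmmreg_register(src, apply_rigid(src, T))
        rel = res.transform.inverse() @ T
        assert rel.rotation_angle_deg() < 1.0
        assert np.linalg.norm(res.transform.translation - T.translation) < 0.01


def _surface_cloud(seed: int, n: int = 800) -> PointCloud:
    """Jittered sphere-surface cloud (dense enough for radius queries)."""
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return PointCloud(u * (1.0 + 0.05 * rng.normal(size=(n, 1))))


class TestDescriptorMatching:
    def test_descriptor_rigid_invariance(self):
        rng = np.random.default_rng(0)
        from c2pbench.geometry import estimate_normals

        cloud = estimate_normals(_surface_cloud(0), k=10)
        T = _random_transform(rng)
        moved = apply_rigid(cloud, T)
        d0 = compute_fpfh(cloud, radius=0.3)
        d1 = compute_fpfh(moved, radius=0.3)
        assert np.abs(d0 - d1).max() < 1e-6

    def test_self_matching_identity(self):
        cloud = _surface_cloud(1)
        corrs = descriptor_correspondences(cloud, cloud, radius=0.3)
        assert len(corrs) == len(cloud)
        np.testing.assert_array_equal(corrs.source_indices, corrs.target_indices)

    def test_partial_pair_match_quality(self, phantom):
        # exact-index correctness varies with patch shape; assert the mean
        # over pairs (boundary truncation and descriptor collisions cap it
        # well below 1 on a smooth organ surface)
        from c2pbench.synthesis import GenerationConfig, generate_pair

        cfg = GenerationConfig(deform_max=0.0, noise_sigma=0.0)
        fracs = []
        for seed in (7, 200, 201):
            rec = generate_pair(phantom, cfg, seed=seed)
            corrs = descriptor_correspondences(rec.source, rec.target, 0.08)
            fracs.append(
                (rec.correspondence[corrs.target_indices] == corrs.source_indices).mean()
            )
        assert np.mean(fracs) >= 0.4
        assert min(fracs) >= 0.2

    def test_radius_too_small_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_fpfh(_surface_cloud(2, n=100), radius=1e-4)


class TestRansac:
    def test_outlier_rejection_recovery(self):
        rng = np.random.default_rng(0)
        src_pts = rng.uniform(-1, 1, (150, 3))
        T = _random_transform(rng, angle_scale=0.5)
        tgt_pts = T.apply(src_pts)
        tgt_pts[100:] = rng.uniform(-1, 1, (50, 3))  # 50 random outliers
        corrs = CorrespondenceSet(np.column_stack([np.arange(150)] * 2))
        res = ransac_pose(
            PointCloud(src_pts), PointCloud(tgt_pts), corrs, refine=False
        )
        rel = res.transform.inverse() @ T
        assert rel.rotation_angle_deg() < 0.5
        assert np.linalg.norm(res.transform.translation - T.translation) < 0.005
        assert len(res.correspondences) >= 100

    def test_all_exact_correspondences(self):
        rng = np.random.default_rng(1)
        src_pts = rng.uniform(-1, 1, (60, 3))
        T = _random_transform(rng)
        corrs = CorrespondenceSet(np.column_stack([np.arange(60)] * 2))
        res = ransac_pose(
            PointCloud(src_pts), PointCloud(T.apply(src_pts)), corrs, refine=False
        )
        assert len(res.correspondences) == 60
        assert res.final_residual < 1e-9

    def test_minimal_three_point_case(self):
        src_pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0.5]])
        T = _random_transform(np.random.default_rng(2))
        corrs = CorrespondenceSet(np.column_stack([np.arange(3)] * 2))
        res = ransac_pose(
            PointCloud(src_pts), PointCloud(T.apply(src_pts)), corrs, refine=False
        )
        np.testing.assert_allclose(res.transform.as_matrix(), T.as_matrix(), atol=1e-9)

    def test_no_consensus_flagged(self):
        rng = np.random.default_rng(3)
        src_pts = rng.uniform(-1, 1, (30, 3))
        tgt_pts = rng.uniform(10, 11, (30, 3))  # unrelated clouds
        corrs = CorrespondenceSet(np.column_stack([np.arange(30)] * 2))
        res = ransac_pose(
            PointCloud(src_pts),
            PointCloud(tgt_pts),
            corrs,
            max_corr_dist=1e-9,
            n_iters=200,
            refine=False,
        )
        assert not res.converged
        assert "ransac_no_consensus" in res.flags
        np.testing.assert_array_equal(res.transform.as_matrix(), np.eye(4))

    def test_full_perturbation_pair_recovery(self, clean_pair):
        corrs = descriptor_correspondences(clean_pair.source, clean_pair.target, 0.08)
        res = ransac_pose(clean_pair.source, clean_pair.target, corrs)
        rel = res.transform.inverse() @ clean_pair.gt_transform
        assert rel.rotation_angle_deg() < 0.5
        t_mm = (
            np.linalg.norm(res.transform.translation - clean_pair.gt_transform.translation)
            * clean_pair.norm_map.scale
        )
        assert t_mm < 0.5


class TestEquivariance:
    def test_prerotation_conjugates_solution(self, recovery_pair):
        # registering (Q src, Q tgt) must give Q T Q^-1
        Q = RigidTransform(
            Rotation.from_euler("zx", [30, 20], degrees=True).as_matrix(), np.zeros(3)
        )
        src_q = apply_rigid(recovery_pair.source, Q)
        tgt_q = apply_rigid(recovery_pair.target, Q)
        base = icp_register(recovery_pair.source, recovery_pair.target).transform
        conj = icp_register(src_q, tgt_q).transform
        expected = Q @ base @ Q.inverse()
        np.testing.assert_allclose(conj.as_matrix(), expected.as_matrix(), atol=1e-6)


class TestOverlapHead:
    def test_zero_features_give_half(self):
        params = OverlapHeadParams(np.zeros(8), 0.0)
        scores, _ = overlap_head(np.zeros((5, 8)), params, n_partial=3)
        np.testing.assert_array_equal(scores, 0.5)

    def test_partial_scores_exactly_one(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            params = OverlapHeadParams(rng.normal(size=16), float(rng.normal()))
            feats = rng.normal(size=(rng.integers(1, 50), 16)) * 10
            _, partial = overlap_head(feats, params, n_partial=int(rng.integers(1, 600)))
            assert np.all(partial == 1.0)

    def test_sigmoid_monotone_in_logit(self):
        # grid stops short of float64 saturation so strict growth is testable
        params = OverlapHeadParams(np.array([1.0]), 0.0)
        grid = np.linspace(-30, 30, 101).reshape(-1, 1)
        scores, _ = overlap_head(grid, params, n_partial=0)
        assert np.all(np.diff(scores) > 0)
        assert np.all((scores > 0) & (scores < 1))
        assert scores[-1] > 1 - 1e-12  # approaches 1 in the large-logit limit

    def test_nonfinite_features_rejected(self):
        params = OverlapHeadParams(np.ones(2), 0.0)
        with pytest.raises(ValueError, match="finite"):
            overlap_head(np.array([[np.nan, 1.0]]), params, n_partial=1)


class TestLosses:
    def _perfect_inputs(self):
        rng = np.random.default_rng(0)
        pred = rng.normal(size=(10, 3))
        scores = np.array([1.0] * 5 + [0.0] * 5)
        # matched feature pairs identical; non-matches far apart
        fa = np.vstack([np.eye(5) * 10, np.zeros((0, 5))])
        fb = np.eye(5) * 10
        matches = np.column_stack([np.arange(5), np.arange(5)])
        labels = scores.copy()
        return pred, scores, fa[:5], fb, matches, labels

    def test_all_zero_at_perfect_prediction(self):
        pred, scores, fa, fb, matches, labels = self._perfect_inputs()
        eps = np.finfo(float).tiny
        total, reg, feat, ov = compute_losses(
            pred, pred, np.clip(scores, eps, 1 - 1e-16), fa, fb, matches, labels
        )
        assert reg == 0.0
        assert feat == 0.0
        assert ov == pytest.approx(0.0, abs=1e-12)
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_registration_loss_linear_in_error(self):
        pred, scores, fa, fb, matches, labels = self._perfect_inputs()
        offset = np.random.default_rng(1).normal(size=pred.shape)
        conf = np.full(10, 0.7)
        _, reg1, _, _ = compute_losses(
            pred + offset, pred, conf, fa, fb, matches, labels
        )
        _, reg2, _, _ = compute_losses(
            pred + 2 * offset, pred, conf, fa, fb, matches, labels
        )
        assert reg2 == pytest.approx(2 * reg1, rel=1e-12)

    def test_overlap_bce_half_scores(self):
        pred, _, fa, fb, matches, _ = self._perfect_inputs()
        labels = np.array([0, 1] * 5, dtype=float)
        scores = np.full(10, 0.5)
        _, _, _, ov = compute_losses(pred, pred, scores, fa, fb, matches, labels)
        assert ov == pytest.approx(np.log(2.0), rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            compute_losses(
                np.zeros((3, 3)),
                np.zeros((4, 3)),
                np.ones(3),
                np.zeros((2, 2)),
                np.zeros((2, 2)),
                np.zeros((0, 2)),
                np.ones(3),
            )
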