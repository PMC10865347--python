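import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fespath.consensus import (PoseEnsemble, RMSDMatrix, kabsch_superpose,
                               pairwise_rmsd, hierarchical_levels,
                               kelley_optimal_k, consensus_model,
                               cluster_ensemble, pool_ensembles)
from fespath.synthetic import planted_pose_ensemble, PlantedEnsembleSpec


def random_cloud(rng, n=12):
    return rng.standard_normal((n, 3)) * 2.0


class TestKabsch:
    def test_identical_sets_zero_rmsd(self, rng):
        pts = random_cloud(rng)
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-8)

    def test_rigid_copy_recovered_exactly(self, rng):
        pts = random_cloud(rng)
        true_rot = Rotation.random(random_state=3).as_matrix()
        moved = pts @ true_rot.T + np.array([1.0, -2.0, 3.0])
        rot, trans, rmsd = kabsch_superpose(pts, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(moved @ rot.T + trans, pts, atol=1e-8)

    def test_mirror_image_not_matched(self, rng):
        pts = random_cloud(rng, n=8)
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        rot, _, rmsd = kabsch_superpose(pts, mirrored)
        assert np.linalg.det(rot) == pytest.approx(1.0)
        assert rmsd > 0.1
        # brute force over proper rotations: no det=+1 rotation does better
        best = np.inf
        a = pts - pts.mean(axis=0)
        b = mirrored - mirrored.mean(axis=0)
        for trial in Rotation.random(2000, random_state=0):
            r = np.sqrt(np.mean(np.sum((b @ trial.as_matrix().T - a) ** 2, axis=1)))
            best = min(best, r)
        assert rmsd <= best + 1e-9
        assert best > 0.1

    @pytest.mark.parametrize("points", [
        np.zeros((2, 3)),
        np.outer(np.arange(5.0), [1.0, 0.0, 0.0]),  # collinear
    ])
    def test_degenerate_inputs_rejected(self, points):
        with pytest.raises(ValueError):
            kabsch_superpose(points, points)


class TestPairwiseRMSD:
    def test_identical_poses_zero_matrix(self, rng):
        spec = PlantedEnsembleSpec(cluster_sizes=(4,), sigma=0.0, seed=5)
        ensemble, _ = planted_pose_ensemble(spec)
        matrix = pairwise_rmsd(ensemble)
        np.testing.assert_allclose(matrix.values, 0.0, atol=1e-8)

    def test_zero_sigma_block_structure(self):
        spec = PlantedEnsembleSpec(cluster_sizes=(3, 3), sigma=0.0, seed=5)
        ensemble, labels = planted_pose_ensemble(spec)
        matrix = pairwise_rmsd(ensemble).values
        same = labels[:, None] == labels[None, :]
        assert np.max(matrix[same]) < 1e-8
        assert np.min(matrix[~same]) > 1.0

    def test_symmetry_and_diagonal(self, planted_default):
        _, ensemble, _ = planted_default
        small = PoseEnsemble(ensemble.poses[:10], ensemble.receptor_selection,
                             ensemble.mobile_selection)
        matrix = pairwise_rmsd(small)
        np.testing.assert_allclose(matrix.values, matrix.values.T, atol=1e-10)
        np.testing.assert_allclose(np.diag(matrix.values), 0.0)


class TestHierarchicalLevels:
    def two_block_matrix(self):
        # 4 + 3 members, tight blocks far apart
        d = np.zeros((7, 7))
        d[:4, :4] = 1.0
        d[4:, 4:] = 1.0
        d[:4, 4:] = 20.0
        d[4:, :4] = 20.0
        np.fill_diagonal(d, 0.0)
        return RMSDMatrix(values=d)

    def test_two_blocks_recovered_at_k2(self):
        levels = hierarchical_levels(self.two_block_matrix())
        labels = levels[2]
        assert len(set(labels[:4])) == 1
        assert len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_extreme_levels(self):
        levels = hierarchical_levels(self.two_block_matrix())
        assert len(set(levels[7])) == 7
        assert len(set(levels[1])) == 1

    def test_sizes_sum_to_n_at_every_level(self):
        levels = hierarchical_levels(self.two_block_matrix())
        for k, labels in levels.items():
            assert np.bincount(labels).sum() == 7
            assert len(np.unique(labels)) == k


def brute_force_kelley(levels, matrix):
    """Direct evaluation of the penalty from its definition, over all levels."""
    n = len(matrix)
    ks, spreads = [], []
    for k in range(2, n):
        labels = levels[k]
        per_cluster = []
        for lab in np.unique(labels):
            idx = np.nonzero(labels == lab)[0]
            if len(idx) < 2:
                continue
            vals = [matrix.values[i, j] for i in idx for j in idx if i < j]
            per_cluster.append(np.mean(vals))
        ks.append(k)
        spreads.append(np.mean(per_cluster) if per_cluster else np.nan)
    spreads = np.array(spreads, dtype=float)
    valid = ~np.isnan(spreads)
    smin, smax = np.nanmin(spreads), np.nanmax(spreads)
    norm = 1 + (spreads - smin) * (n - 3) / (smax - smin) if smax > smin \
        else np.ones_like(spreads)
    pen = np.where(valid, norm + np.array(ks), np.inf)
    return ks[int(np.argmin(pen))]


class TestKelley:
    def test_three_blobs_of_ten(self, rng):
        centers = np.array([[0.0, 0, 0], [30.0, 0, 0], [0, 30.0, 0]])
        cloud = rng.standard_normal((8, 3))
        poses = []
        from fespath.synthetic import _pose_structure
        receptor = rng.standard_normal((5, 3)) * 3
        for c in centers:
            for _ in range(10):
                poses.append(_pose_structure(
                    receptor, cloud + c + 0.3 * rng.standard_normal((8, 3))))
        ensemble = PoseEnsemble(poses, receptor_selection=np.arange(5))
        matrix = pairwise_rmsd(ensemble)
        levels = hierarchical_levels(matrix)
        k_star, curve = kelley_optimal_k(levels, matrix)
        assert k_star == 3
        assert k_star == brute_force_kelley(levels, matrix)

    def test_scaling_invariance(self, rng):
        d = np.abs(rng.standard_normal((12, 12)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        matrix = RMSDMatrix(values=d)
        levels = hierarchical_levels(matrix)
        k1, c1 = kelley_optimal_k(levels, matrix)
        scaled = RMSDMatrix(values=5.0 * d)
        levels2 = hierarchical_levels(scaled)
        k2, c2 = kelley_optimal_k(levels2, scaled)
        assert k1 == k2
        np.testing.assert_allclose(c1, c2, atol=1e-9)

    def test_identical_members_undefined(self):
        matrix = RMSDMatrix(values=np.zeros((5, 5)))
        levels = hierarchical_levels(matrix)
        with pytest.raises(ValueError, match="identical|undefined"):
            kelley_optimal_k(levels, matrix)


class TestConsensusModel:
    def test_identical_poses_tie_breaks_to_first(self):
        spec = PlantedEnsembleSpec(cluster_sizes=(5,), sigma=0.0, seed=2)
        ensemble, _ = planted_pose_ensemble(spec)
        matrix = pairwise_rmsd(ensemble)
        assert consensus_model(ensemble, np.zeros(5, dtype=int), matrix) == 0

    def test_largest_cluster_wins(self):
        spec = PlantedEnsembleSpec(cluster_sizes=(95, 80), sigma=0.5, seed=3)
        ensemble, labels = planted_pose_ensemble(spec)
        matrix = pairwise_rmsd(ensemble)
        member = consensus_model(ensemble, labels, matrix)
        assert labels[member] == 0

    def test_brute_force_equivalence_small_ensembles(self, rng):
        spec = PlantedEnsembleSpec(cluster_sizes=(30, 15), sigma=0.5,
                                   seed=4)
        ensemble, labels = planted_pose_ensemble(spec)
        matrix = pairwise_rmsd(ensemble)
        member = consensus_model(ensemble, labels, matrix)
        idx = np.nonzero(labels == 0)[0]
        means = [np.mean([matrix.values[i, j] for j in idx if j != i])
                 for i in idx]
        assert member == idx[int(np.argmin(means))]

    def test_centroid_displacement_below_cluster_median(self, planted_default,
                                                        planted_clustering):
        _, ensemble, labels = planted_default
        result = planted_clustering
        member = result.centroid_member
        lab = labels[member]
        idx = np.nonzero(labels == lab)[0]
        # displacement of each member from the planted rigid reference is
        # estimated by its mean RMSD to the rest of the cluster
        matrix = pairwise_rmsd(
            PoseEnsemble([ensemble.poses[i] for i in idx],
                         ensemble.receptor_selection,
                         ensemble.mobile_selection))
        means = matrix.values.sum(axis=1) / (len(idx) - 1)
        member_pos = int(np.nonzero(idx == member)[0][0])
        assert means[member_pos] <= np.median(means)


class TestFullConsensusStage:
    def test_planted_default_recovery(self, planted_default, planted_clustering):
        _, _, labels = planted_default
        result = planted_clustering
        assert result.chosen_k == 10
        assert result.cluster_sizes[0] == 95
        got = result.labels()
        for lab in np.unique(labels):
            assert len(np.unique(got[labels == lab])) == 1
        assert len(np.unique(got)) == 10

    def test_sizes_sum_to_ensemble(self, planted_clustering):
        assert planted_clustering.cluster_sizes.sum() == 500

    def test_pool_ensembles_concatenates(self):
        spec = PlantedEnsembleSpec(cluster_sizes=(3,), sigma=0.0, seed=1)
        e1, _ = planted_pose_ensemble(spec)
        e2, _ = planted_pose_ensemble(spec)
        pooled = pool_ensembles([e1, e2])
        assert len(pooled) == 6
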