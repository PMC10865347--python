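"""Consensus stage of docking-pose aggregation.

Pooled candidate complexes are compared by heavy-atom RMSD after optimal
superposition on a shared (receptor) selection, clustered by average-linkage
agglomeration of the RMSD matrix, the number of clusters is selected by the
Kelley–Gardner–Sutcliffe penalty, and the consensus model is the member of
the most populated cluster nearest its centroid (minimum mean RMSD to the
other members).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_formats import Structure

__all__ = [
    "PoseEnsemble",
    "RMSDMatrix",
    "ClusteringResult",
    "kabsch_superpose",
    "pairwise_rmsd",
    "hierarchical_levels",
    "kelley_optimal_k",
    "consensus_model",
    "cluster_ensemble",
    "pool_ensembles",
]

logger = logging.getLogger(__name__)


@dataclass
class PoseEnsemble:
    """Candidate complex poses sharing one atom ordering.

    ``receptor_selection``/``mobile_selection`` are index arrays into the
    shared atom list marking the fixed and docked components.
    """

    poses: list
    receptor_selection: np.ndarray = None
    mobile_selection: np.ndarray = None

    def __post_init__(self):
        if not self.poses:
            raise ValueError("ensemble must contain at least one pose")
        n = len(self.poses[0])
        for i, pose in enumerate(self.poses):
            if len(pose) != n:
                raise ValueError(f"pose {i} has {len(pose)} atoms, expected {n}")
            if not (np.array_equal(pose.name, self.poses[0].name)
                    and np.array_equal(pose.chain, self.poses[0].chain)):
                raise ValueError(f"pose {i} atom ordering differs from pose 0")
        if self.receptor_selection is None:
            self.receptor_selection = np.arange(n)
        if self.mobile_selection is None:
            self.mobile_selection = np.arange(n)
        self.receptor_selection = np.asarray(self.receptor_selection, dtype=int)
        self.mobile_selection = np.asarray(self.mobile_selection, dtype=int)

    def __len__(self) -> int:
        return len(self.poses)

    def coords(self) -> np.ndarray:
        return np.stack([p.coord for p in self.poses])


@dataclass
class RMSDMatrix:
    """Symmetric pairwise dissimilarity matrix in Å."""

    values: np.ndarray
    member_ids: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("RMSD matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("RMSD matrix must be symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-10):
            raise ValueError("RMSD matrix diagonal must be zero")
        if np.any(self.values < -1e-12):
            raise ValueError("RMSD entries must be non-negative")
        if self.member_ids is None:
            self.member_ids = np.arange(n)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ClusteringResult:
    """Assignments at every level plus the Kelley-selected level."""

    assignments: dict            # k -> label array (labels 0..k-1)
    chosen_k: int
    penalty_curve: np.ndarray    # shape (n_levels, 2): k, penalty
    cluster_sizes: np.ndarray    # sizes at chosen_k, descending
    centroid_member: int

    def labels(self, k: int | None = None) -> np.ndarray:
        return self.assignments[self.chosen_k if k is None else k]


# ---------------------------------------------------------------------------
# Superposition


def kabsch_superpose(reference: np.ndarray, mobile: np.ndarray, weights=None):
    """Optimal proper superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD to
    ``reference`` over proper rotations (det +1; mirror images are not
    matched).
    """
    reference = np.asarray(reference, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if reference.shape != mobile.shape or reference.ndim != 2 or reference.shape[1] != 3:
        raise ValueError("point sets must both have shape (n, 3)")
    n = len(reference)
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    ref_c = reference.mean(axis=0)
    mob_c = mobile.mean(axis=0)
    a = reference - ref_c
    b = mobile - mob_c
    # collinearity check: rank of the centered reference
    if np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    h = b.T @ a
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.array([1.0, 1.0, d])
    rotation = vt.T @ np.diag(diag) @ u.T
    translation = ref_c - rotation @ mob_c
    moved = b @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return rotation, translation, rmsd


def pairwise_rmsd(ensemble: PoseEnsemble, fit_selection=None, rmsd_selection=None) -> RMSDMatrix:
    """All-vs-all RMSD: superpose each pair on ``fit_selection``, measure the
    RMSD over ``rmsd_selection`` (defaults: receptor selection / all atoms)."""
    fit = np.asarray(fit_selection if fit_selection is not None
                     else ensemble.receptor_selection, dtype=int)
    meas = np.asarray(rmsd_selection if rmsd_selection is not None
                      else np.arange(len(ensemble.poses[0])), dtype=int)
    if len(fit) < 3:
        raise ValueError("fit selection needs at least 3 atoms")
    if len(meas) == 0:
        raise ValueError("rmsd selection is empty")
    coords = ensemble.coords()
    n = len(ensemble)
    # precenter fit coordinates once per pose
    fit_xyz = coords[:, fit, :]
    fit_centers = fit_xyz.mean(axis=1)
    fit_centered = fit_xyz - fit_centers[:, None, :]
    meas_xyz = coords[:, meas, :]
    out = np.zeros((n, n))
    for i in range(n):
        ai = fit_centered[i]
        for j in range(i + 1, n):
            h = fit_centered[j].T @ ai
            u, s, vt = np.linalg.svd(h)
            d = np.sign(np.linalg.det(vt.T @ u.T))
            rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
            trans = fit_centers[i] - rot @ fit_centers[j]
            moved = meas_xyz[j] @ rot.T + trans
            out[i, j] = out[j, i] = np.sqrt(
                np.mean(np.sum((moved - meas_xyz[i]) ** 2, axis=1)))
    return RMSDMatrix(values=out)


# ---------------------------------------------------------------------------
# Clustering


def hierarchical_levels(matrix: RMSDMatrix, linkage: str = "average") -> dict:
    """Agglomerative merge tree; returns ``{k: labels}`` for k = 1..n.

    Labels at each level are renumbered 0..k−1 in order of first appearance.
    """
    n = len(matrix)
    if n == 1:
        return {1: np.zeros(1, dtype=int)}
    condensed = squareform(matrix.values, checks=False)
    z = hierarchy.linkage(condensed, method=linkage)
    cuts = hierarchy.cut_tree(z)  # shape (n, n): column c has n - c clusters
    levels = {}
    for c in range(n):
        k = n - c
        raw = cuts[:, c]
        _, labels = np.unique(raw, return_inverse=True)
        levels[k] = labels.astype(int)
    return levels


def _average_spread(matrix: np.ndarray, labels: np.ndarray) -> float:
    """Mean over clusters (with >= 2 members) of their mean pairwise RMSD."""
    spreads = []
    for lab in np.unique(labels):
        idx = np.nonzero(labels == lab)[0]
        if len(idx) < 2:
            continue
        sub = matrix[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        spreads.append(float(np.mean(sub[iu])))
    return float(np.mean(spreads)) if spreads else np.nan


def kelley_optimal_k(levels: dict, matrix: RMSDMatrix):
    """Kelley–Gardner–Sutcliffe selection of the cluster count.

    Average spreads over levels k = 2..n−1 are linearly rescaled onto
    [1, n−2]; penalty(k) = rescaled spread + k; the optimum k* is the
    argmin, ties broken toward smaller k.  Returns ``(k_star, curve)``
    where ``curve`` has rows ``(k, penalty)``.
    """
    n = len(matrix)
    if n < 3:
        raise ValueError("Kelley criterion needs at least 3 members")
    ks = np.array(sorted(k for k in levels if 2 <= k <= n - 1))
    spreads = np.array([_average_spread(matrix.values, levels[k]) for k in ks])
    valid = ~np.isnan(spreads)
    if not valid.any():
        raise ValueError("criterion undefined: no level has a multi-member cluster")
    smin = np.nanmin(spreads)
    smax = np.nanmax(spreads)
    if smax - smin < 1e-12:
        if smax < 1e-12:
            raise ValueError("criterion undefined: all members identical (zero spread)")
        rescaled = np.ones_like(spreads)
    else:
        rescaled = 1.0 + (spreads - smin) * (n - 3) / (smax - smin)
    penalty = np.where(valid, rescaled + ks, np.inf)
    k_star = int(ks[np.argmin(penalty)])  # argmin returns first (smallest k) on ties
    curve = np.column_stack([ks.astype(float), penalty])
    return k_star, curve


def consensus_model(ensemble: PoseEnsemble, labels: np.ndarray,
                    matrix: RMSDMatrix | None = None) -> int:
    """Member of the most populated cluster nearest its centroid.

    The centroid member minimizes the mean RMSD to all other members of
    the largest cluster; ties break toward the lowest member index, and a
    tie in largest-cluster size is resolved toward the more compact
    cluster (smaller internal mean RMSD).
    """
    labels = np.asarray(labels)
    if matrix is None:
        matrix = pairwise_rmsd(ensemble)
    uniq, counts = np.unique(labels, return_counts=True)
    top = counts.max()
    tied = uniq[counts == top]
    if len(tied) > 1:
        logger.info("largest-cluster tie between labels %s (size %d); "
                    "choosing the more compact one", tied.tolist(), top)
        spreads = []
        for lab in tied:
            members = np.nonzero(labels == lab)[0]
            spreads.append(np.mean(matrix.values[np.ix_(members, members)]))
        chosen = tied[int(np.argmin(spreads))]
    else:
        chosen = tied[0]
    idx = np.nonzero(labels == chosen)[0]
    if len(idx) == 1:
        return int(idx[0])
    sub = matrix.values[np.ix_(idx, idx)]
    mean_to_others = sub.sum(axis=1) / (len(idx) - 1)
    return int(idx[int(np.argmin(mean_to_others))])


def cluster_ensemble(ensemble: PoseEnsemble, fit_selection=None,
                     rmsd_selection=None, linkage: str = "average") -> ClusteringResult:
    """Full consensus stage: RMSD matrix → levels → Kelley k* → centroid."""
    matrix = pairwise_rmsd(ensemble, fit_selection, rmsd_selection)
    levels = hierarchical_levels(matrix, linkage=linkage)
    k_star, curve = kelley_optimal_k(levels, matrix)
    labels = levels[k_star]
    sizes = np.sort(np.bincount(labels))[::-1]
    centroid = consensus_model(ensemble, labels, matrix)
    logger.info("Kelley-selected k=%d; largest cluster %d members; consensus model %d",
                k_star, sizes[0], centroid)
    return ClusteringResult(assignments=levels, chosen_k=k_star,
                            penalty_curve=curve, cluster_sizes=sizes,
                            centroid_member=centroid)


def pool_ensembles(ensembles: list) -> PoseEnsemble:
    """Concatenate per-engine pose ensembles sharing one atom ordering."""
    poses = [p for ens in ensembles for p in ens.poses]
    first = ensembles[0]
    return PoseEnsemble(poses=poses,
                        receptor_selection=first.receptor_selection,
                        mobile_selection=first.mobile_selection)
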