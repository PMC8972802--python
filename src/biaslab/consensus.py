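"""Multi-run consensus over per-particle pose estimates.

Several independent assignment runs (different algorithms, metrics or seeds)
produce one pose estimate per particle each.  Per particle, the estimates
are clustered by single linkage under the SO(3) geodesic distance at a
threshold theta; if the most-populated cluster holds a strict majority of
the runs the particle "agrees", and its consensus pose is the quaternion
(chordal) mean of that cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .align import AssignmentRun
from .geometry import Pose, angular_distance, mean_pose

DEFAULT_THETA = 10.0


@dataclass
class ParticleConsensus:
    clusters: list[list[int]]        # run indices per cluster, largest first
    cluster_radii: list[float]       # max pairwise distance within each cluster
    agrees: bool
    consensus_pose: Pose


@dataclass
class ConsensusReport:
    particles: list[ParticleConsensus]
    agreement_fraction: float
    threshold: float
    n_runs: int

    def agreeing_indices(self) -> np.ndarray:
        return np.array([i for i, p in enumerate(self.particles) if p.agrees], dtype=int)


def consensus(runs: list[AssignmentRun], threshold: float = DEFAULT_THETA) -> ConsensusReport:
    """Cluster per-particle pose estimates across runs and report agreement.

    agreement flag: the most-populated cluster contains a strict majority of
    the runs (always true for a single run).  Ties between equally populated
    clusters break on the smallest contained run index.
    """
    if len(runs) < 1:
        raise ValueError("need at least one assignment run")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = len(runs[0])
    if any(len(r) != n for r in runs):
        raise ValueError("all runs must cover the same particles")

    particles: list[ParticleConsensus] = []
    n_agree = 0
    for i in range(n):
        poses = [r.poses[i] for r in runs]
        clusters = _cluster_poses(poses, threshold)
        clusters.sort(key=lambda c: (-len(c), min(c)))
        radii = [_cluster_radius(poses, c) for c in clusters]
        agrees = len(clusters[0]) * 2 > len(runs)
        cpose = mean_pose([poses[j] for j in clusters[0]])
        n_agree += agrees
        particles.append(ParticleConsensus(clusters=clusters, cluster_radii=radii,
                                           agrees=agrees, consensus_pose=cpose))
    return ConsensusReport(particles=particles, agreement_fraction=n_agree / n,
                           threshold=threshold, n_runs=len(runs))


def _cluster_poses(poses: list[Pose], threshold: float) -> list[list[int]]:
    r = len(poses)
    if r == 1:
        return [[0]]
    d = np.zeros((r, r))
    for a in range(r):
        for b in range(a + 1, r):
            d[a, b] = d[b, a] = angular_distance(poses[a], poses[b])
    z = linkage(squareform(d, checks=False), method="single")
    flat = fcluster(z, t=threshold, criterion="distance")
    return [list(np.flatnonzero(flat == k)) for k in np.unique(flat)]


def _cluster_radius(poses: list[Pose], members: list[int]) -> float:
    if len(members) < 2:
        return 0.0
    return max(angular_distance(poses[a], poses[b])
               for i, a in enumerate(members) for b in members[i + 1:])
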