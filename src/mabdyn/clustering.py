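"""Pairwise CA RMSD matrix and GROMOS (Daura) clustering.

The RMSD between two frames is the least-squares value after optimal rigid
superposition (Kabsch) on the analysis selection itself.  Clustering picks
the frame with the most neighbors within the cutoff as a medoid, removes it
and its neighbors, and repeats until frames run out or the cluster cap is
hit; leftover frames are reported unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mabdyn.core_io import TrajectorySlice

__all__ = ["ClusterResult", "kabsch_rmsd", "rmsd_matrix", "gromos_cluster"]

UNASSIGNED = -1


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD of coordinate sets a, b (n, 3) over rigid superposition."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must share shape (n, 3)")
    if a.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    return _rotated_rmsd(ac, bc)


def _rotated_rmsd(ac: np.ndarray, bc: np.ndarray) -> float:
    """RMSD after applying the optimal rotation explicitly (centered inputs).

    Applying the rotation and measuring the residual avoids the catastrophic
    cancellation of the singular-value shortcut for near-identical frames.
    """
    u, _, vt = np.linalg.svd(bc.T @ ac)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    diff = bc @ rot - ac
    return float(np.sqrt((diff**2).sum() / ac.shape[0]))


def rmsd_matrix(traj: TrajectorySlice, selection: np.ndarray | None = None) -> np.ndarray:
    """Symmetric all-pairs superposed-RMSD matrix in Angstrom.

    ``selection`` holds atom indices; default is all CA atoms of the slice.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if selection is None:
        selection = np.flatnonzero(traj.topology.atom_names == "CA")
    selection = np.asarray(selection, dtype=np.intp)
    if selection.size < 3:
        raise ValueError("selection must contain at least 3 atoms")
    xyz = traj.coordinates[:, selection, :]
    n = traj.n_frames
    centered = xyz - xyz.mean(axis=1, keepdims=True)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = _rotated_rmsd(centered[i], centered[j])
    return mat


@dataclass
class ClusterResult:
    """Assignment of frames to GROMOS clusters.

    ``labels[f]`` is the cluster id of frame f (ids ordered by decreasing
    size, ties by discovery order) or -1 for unassigned frames.
    """

    labels: np.ndarray
    medoids: np.ndarray  # frame index per cluster id
    sizes: np.ndarray
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.medoids)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)

    def to_frame(self) -> pd.DataFrame:
        medoid_set = set(int(m) for m in self.medoids)
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.labels)),
                "cluster": self.labels,
                "is_medoid": [int(f) in medoid_set for f in range(len(self.labels))],
            }
        )


def gromos_cluster(matrix: np.ndarray, cutoff: float, max_clusters: int = 10) -> ClusterResult:
    """Greedy neighbor-count clustering on a distance matrix.

    Ties on neighbor count break toward the lowest frame index.  At most
    ``max_clusters`` clusters are formed; frames left over are unassigned.
    Cluster ids are re-ordered by decreasing size after the greedy pass.
    """
    mat = np.asarray(matrix, dtype=np.float64)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = mat.shape[0]
    labels = np.full(n, UNASSIGNED, dtype=np.int64)
    remaining = np.ones(n, dtype=bool)
    medoids: list[int] = []
    members_per_cluster: list[np.ndarray] = []
    while remaining.any() and len(medoids) < max_clusters:
        idx = np.flatnonzero(remaining)
        neigh = (mat[np.ix_(idx, idx)] <= cutoff).sum(axis=1)  # includes self
        medoid = int(idx[int(np.argmax(neigh))])  # argmax takes lowest index on ties
        cluster = idx[mat[medoid, idx] <= cutoff]
        medoids.append(medoid)
        members_per_cluster.append(cluster)
        remaining[cluster] = False
    order = sorted(
        range(len(medoids)), key=lambda k: (-len(members_per_cluster[k]), k)
    )
    final_medoids = []
    sizes = []
    for new_id, k in enumerate(order):
        labels[members_per_cluster[k]] = new_id
        final_medoids.append(medoids[k])
        sizes.append(len(members_per_cluster[k]))
    return ClusterResult(
        labels=labels,
        medoids=np.asarray(final_medoids, dtype=np.int64),
        sizes=np.asarray(sizes, dtype=np.int64),
        cutoff=float(cutoff),
    )
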