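"""Kabsch superposition CA-RMSD and gromos (Daura) conformational clustering.

The clustering is the greedy neighbour-count algorithm of Daura et al.: find
the frame with the most neighbours within the RMSD cutoff (ties go to the
lowest frame index), pull it out together with its neighbours as one cluster,
and repeat on the remainder.  The conventional cutoff for peptide oligomer
ensembles is 0.4 nm on CA atoms of all residues, which is this package's
default (``AnalysisParameters.cluster_cutoff`` = 4 A).

Identical peptide copies are interchangeable physically; by default the fixed
chain order of the file is used (the standard gromos behaviour), with an
optional mode minimizing the RMSD over all chain relabelings.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .model_io import SystemModel, Trajectory, select

__all__ = ["RMSDMatrix", "ClusterResult", "kabsch_rmsd", "rmsd_matrix", "daura_cluster"]


@dataclass(frozen=True)
class RMSDMatrix:
    """Symmetric frame-by-frame CA-RMSD matrix (A) with the selection used."""

    values: np.ndarray
    selection: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if not np.allclose(np.diag(v), 0, atol=1e-9) or not np.allclose(v, v.T):
            raise ValueError("RMSD matrix must be symmetric with zero diagonal")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class Cluster:
    center: int
    members: tuple[int, ...]
    population: float


@dataclass(frozen=True)
class ClusterResult:
    """Ordered clusters (non-increasing size); members partition all frames."""

    clusters: tuple[Cluster, ...]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self, n_frames: int) -> np.ndarray:
        lab = np.full(n_frames, -1, dtype=int)
        for k, c in enumerate(self.clusters):
            for m in c.members:
                lab[m] = k
        return lab


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimum RMSD over proper rotations + translations (Kabsch superposition).

    Inputs are matched (n, 3) point sets, n >= 3 and non-collinear.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point sets must have matching (n, 3) shapes")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    if np.linalg.matrix_rank(np.vstack([a, b])) < 2:
        raise ValueError("degenerate (collinear) geometry")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    r = vt.T @ diag @ u.T
    diff = a @ r.T - b
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def _chain_permuted_rmsd(
    coords_a: np.ndarray, coords_b: np.ndarray, chain_blocks: list[np.ndarray]
) -> float:
    """Minimum Kabsch RMSD over relabelings of identical chains."""
    best = np.inf
    base = np.concatenate(chain_blocks)
    for perm in permutations(range(len(chain_blocks))):
        order = np.concatenate([chain_blocks[p] for p in perm])
        # permute B's chains against A's fixed order
        r = kabsch_rmsd(coords_a[base], coords_b[order])
        best = min(best, r)
    return best


def rmsd_matrix(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    permute_chains: bool = False,
) -> RMSDMatrix:
    """All-pairs CA-RMSD matrix for a trajectory (CA of all residues by default)."""
    model = traj.model
    if selection is None:
        selection = select(model, "calpha")
    selection = np.asarray(selection, dtype=int)
    coords = traj.coordinates_array()

    chain_blocks = None
    if permute_chains:
        chain_blocks = [
            np.array([i for i in selection if model.atoms[i].chain_id == c])
            for c in model.chains
        ]

    n = traj.n_frames
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if permute_chains:
                r = _chain_permuted_rmsd(coords[i], coords[j], chain_blocks)
            else:
                r = kabsch_rmsd(coords[i][selection], coords[j][selection])
            mat[i, j] = mat[j, i] = r
    return RMSDMatrix(mat, selection)


def daura_cluster(rmsd: RMSDMatrix | np.ndarray, cutoff: float = 4.0) -> ClusterResult:
    """gromos/Daura greedy clustering with a strict < cutoff neighbour relation."""
    values = rmsd.values if isinstance(rmsd, RMSDMatrix) else np.asarray(rmsd, dtype=float)
    n = values.shape[0]
    remaining = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while remaining.any():
        idx = np.where(remaining)[0]
        sub = values[np.ix_(idx, idx)]
        neighbour_counts = np.sum(sub < cutoff, axis=1) - 1  # exclude self
        best = int(idx[np.argmax(neighbour_counts)])  # argmax ties -> lowest index
        members = idx[values[best, idx] < cutoff]
        members = np.union1d(members, [best])
        clusters.append(Cluster(best, tuple(int(m) for m in members), len(members) / n))
        remaining[members] = False
    # discovery order is already non-increasing in size (greedy max-neighbour)
    return ClusterResult(tuple(clusters))
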