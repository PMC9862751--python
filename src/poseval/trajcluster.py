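"""Trajectory-frame clustering and representative-conformation selection.

Frames are subsampled, pairwise-superposed on a backbone selection, and
clustered on the resulting RMSD matrix with a deterministic leader
algorithm: the frame with the most neighbors within the cutoff seeds the
first cluster together with those neighbors, the process repeats on the
remainder, and the top cluster's seed is the representative conformation.
Ties always resolve to the lowest original frame index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import (
    BACKBONE_NAMES,
    MolecularStructure,
    Trajectory,
    TrajectoryEnsemble,
    kabsch_superpose,
    rmsd_fixed,
)

__all__ = [
    "ClusterResult",
    "rmsd_matrix",
    "subsample",
    "neighbor_cluster",
    "representative_conformation",
]

DEFAULT_CUTOFF = 2.0  # Angstrom backbone RMSD


@dataclass
class ClusterResult:
    """Leader-clustering outcome over a set of frames.

    ``labels[i]`` is the cluster id of frame i (0 = most populated, -1 =
    overflow past ``max_clusters``); ``representative_frame`` indexes the
    top cluster's seed; ``neighbor_counts`` are the within-cutoff neighbor
    counts computed on the full matrix before any removal.
    """

    labels: np.ndarray
    representative_frame: int
    neighbor_counts: np.ndarray
    cutoff: float
    seeds: list[int]


def subsample(frames: np.ndarray, interval: int = 10,
              max_frames: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Every ``interval``-th frame, capped at ``max_frames``.

    Returns (subset coords, original frame indices).
    """
    if interval < 1:
        raise ValueError("interval must be >= 1")
    frames = np.asarray(frames)
    idx = np.arange(0, frames.shape[0], interval)[:max_frames]
    return frames[idx], idx


def rmsd_matrix(frames: np.ndarray, selection: np.ndarray) -> np.ndarray:
    """Pairwise RMSD over ``selection`` after optimal superposition per pair.

    Symmetric with a zero diagonal; rigid-body differences between frames do
    not contribute.
    """
    frames = np.asarray(frames, dtype=float)
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty atom selection")
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    sel = frames[:, selection, :]
    n = sel.shape[0]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sup = kabsch_superpose(sel[j], sel[i])
            mat[i, j] = mat[j, i] = rmsd_fixed(sup.apply(sel[j]), sel[i])
    return mat


def neighbor_cluster(matrix: np.ndarray, cutoff: float = DEFAULT_CUTOFF,
                     max_clusters: int = 10) -> ClusterResult:
    """Iterative most-neighbors (leader) clustering of an RMSD matrix.

    At each round the unassigned frame with the most unassigned neighbors
    within ``cutoff`` (ties: lowest index) seeds a cluster containing itself
    and those neighbors.  After ``max_clusters`` rounds any remainder is
    labelled -1 (overflow).  The seed of each cluster is its representative.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("RMSD matrix must be square and symmetric")
    adjacency = (matrix <= cutoff)
    np.fill_diagonal(adjacency, False)
    full_counts = adjacency.sum(axis=1).astype(int)

    labels = np.full(n, -1, dtype=int)
    remaining = np.ones(n, dtype=bool)
    seeds: list[int] = []
    for cluster_id in range(max_clusters):
        if not remaining.any():
            break
        counts = np.where(remaining, (adjacency & remaining).sum(axis=1), -1)
        seed = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(adjacency[seed] & remaining)
        labels[seed] = cluster_id
        labels[members] = cluster_id
        remaining[seed] = False
        remaining[members] = False
        seeds.append(seed)
    return ClusterResult(
        labels=labels,
        representative_frame=seeds[0],
        neighbor_counts=full_counts,
        cutoff=float(cutoff),
        seeds=seeds,
    )


def _backbone_selection(template: MolecularStructure) -> np.ndarray:
    sel = [i for i in template.indices(role="receptor")
           if template.atoms[i].name in BACKBONE_NAMES]
    if not sel:  # structures without roles: any backbone-named atom
        sel = [i for i, a in enumerate(template.atoms) if a.name in BACKBONE_NAMES]
    if len(sel) < 3:
        raise ValueError("no receptor backbone selection available")
    return np.array(sel, dtype=int)


def representative_conformation(traj: Trajectory | TrajectoryEnsemble,
                                template: MolecularStructure | None = None,
                                selection: np.ndarray | None = None,
                                cutoff: float = DEFAULT_CUTOFF,
                                interval: int = 10, max_frames: int = 1000,
                                max_clusters: int = 10,
                                ) -> tuple[MolecularStructure, int]:
    """Most-populated-cluster seed frame of a trajectory, as a structure.

    Runs subsample -> pairwise RMSD -> leader clustering on the (receptor)
    backbone and materializes the representative frame.  Returns the
    structure and the original frame index.
    """
    if isinstance(traj, TrajectoryEnsemble):
        template = traj.atom_template
        traj = traj.trials[0]
    if template is None:
        raise ValueError("template required for a bare Trajectory")
    if selection is None:
        selection = _backbone_selection(template)
    frames, orig_idx = subsample(traj.coords, interval=interval, max_frames=max_frames)
    if frames.shape[0] == 1:
        return template.with_coords(frames[0]), int(orig_idx[0])
    mat = rmsd_matrix(frames, selection)
    result = neighbor_cluster(mat, cutoff=cutoff, max_clusters=max_clusters)
    rep = int(orig_idx[result.representative_frame])
    return template.with_coords(traj.coords[rep]), rep
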