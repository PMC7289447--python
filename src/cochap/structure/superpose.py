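"""Rigid-body superposition and conformational clustering.

Kabsch superposition (SVD with a determinant correction, so the rotation
is always proper) and single-linkage clustering of frames by pairwise
RMSD, the classic way conformational ensembles are condensed into a few
representative structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import Structure
from .geometry import Selection, selection_mask

__all__ = ["kabsch_superpose", "pairwise_rmsd_matrix", "cluster_frames_single_linkage", "FrameCluster"]


def kabsch_superpose(
    X: np.ndarray, Y: np.ndarray, selection: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation R and translation t minimizing RMSD(R X + t, Y).

    ``selection`` (boolean or index array) restricts the fit to a subset of
    the matched points; the returned RMSD is over that subset.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X and Y must be matched (n, 3) coordinate sets")
    if selection is not None:
        X, Y = X[selection], Y[selection]
    if len(X) < 3:
        raise ValueError("need at least 3 points")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    H = (X - xc).T @ (Y - yc)
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    diff = (X @ R.T + t) - Y
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return R, t, rmsd


def _frame_coords(frames: Sequence[Structure], selection: Optional[Selection]):
    if selection is None:
        return [f.coords for f in frames]
    masks = [selection_mask(f, selection) for f in frames]
    n = {int(m.sum()) for m in masks}
    if len(n) != 1:
        raise ValueError("selection yields different atom counts across frames")
    return [f.coords[m] for f, m in zip(frames, masks)]


def pairwise_rmsd_matrix(
    frames: Sequence[Structure],
    selection: Optional[Selection] = None,
    fit_selection: Optional[Selection] = None,
) -> np.ndarray:
    """All-pairs RMSD after Kabsch superposition.

    ``fit_selection`` names the atoms used to superpose (a stated reference
    selection, e.g. a rigid domain); ``selection`` the atoms the RMSD is
    evaluated on.  Defaults: fit and evaluate on all atoms.
    """
    coords = _frame_coords(frames, selection)
    fit_coords = coords if fit_selection is None else _frame_coords(frames, fit_selection)
    n = len(frames)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            R, t, _ = kabsch_superpose(fit_coords[i], fit_coords[j])
            diff = coords[i] @ R.T + t - coords[j]
            out[i, j] = out[j, i] = float(
                np.sqrt(np.mean(np.sum(diff**2, axis=1)))
            )
    return out


@dataclass
class FrameCluster:
    members: list[int]
    centroid: int  # frame index minimizing summed within-cluster RMSD


def cluster_frames_single_linkage(
    frames: Sequence[Structure],
    selection: Optional[Selection] = None,
    cutoff: float = 0.18,
    fit_selection: Optional[Selection] = None,
) -> list[FrameCluster]:
    """Single-linkage clusters: connected components of the RMSD < cutoff graph.

    Returns clusters sorted by decreasing size; each carries the centroid
    frame (minimum summed RMSD to its cluster mates, ties to the lowest
    frame index).
    """
    frames = list(frames)
    if not frames:
        return []
    rmsd = pairwise_rmsd_matrix(frames, selection, fit_selection)
    adj = csr_matrix(rmsd < cutoff)
    n_comp, labels = connected_components(adj, directed=False)
    clusters = []
    for comp in range(n_comp):
        members = sorted(np.where(labels == comp)[0].tolist())
        sub = rmsd[np.ix_(members, members)]
        centroid = members[int(np.argmin(sub.sum(axis=1)))]
        clusters.append(FrameCluster(members=members, centroid=centroid))
    clusters.sort(key=lambda c: (-len(c.members), c.members[0]))
    return clusters
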