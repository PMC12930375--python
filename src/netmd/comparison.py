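"""Pairwise replica distances, hierarchical clustering and the RMSD baseline.

Replicas of every system are compared by their normalized DTW distances;
Ward's hierarchical clustering on that matrix discriminates systems or
conditions by their time-resolved dynamic signatures, with the number of
clusters chosen by the largest-gap or elbow criterion on merge heights.
A descriptor-based baseline is provided: a pairwise Cα-RMSD frame cost
matrix fed through dependent DTW, clustered by PAM k-medoids with
silhouette selection of k.

Ward linkage on a DTW distance matrix is formally a heuristic (DTW is not
Euclidean); the Lance-Williams Ward update is applied to squared distances
(the "ward.D2" convention), via scipy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .alignment import Normalization, dtw

__all__ = [
    "DistanceMatrix",
    "LinkageTree",
    "ClusterSolution",
    "pairwise_dtw_matrix",
    "ward_linkage",
    "select_k",
    "cut_tree",
    "linkage_to_newick",
    "rmsd_cost_matrix",
    "kabsch_rmsd",
    "kmedoids_with_silhouette",
]


@dataclass
class DistanceMatrix:
    """Symmetric replica x replica distance matrix with labels."""

    labels: list[str]
    matrix: np.ndarray
    systems: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.matrix < 0).any() or not np.allclose(np.diag(self.matrix), 0):
            raise ValueError("distance matrix must be non-negative with zero diagonal")


@dataclass
class LinkageTree:
    """Agglomerative merge list in scipy linkage format, plus labels."""

    linkage: np.ndarray  # (n-1, 4): cluster_a, cluster_b, height, size
    labels: list[str]
    method: str = "ward"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass
class ClusterSolution:
    k: int
    assignment: dict[str, int]
    criterion: str


def pairwise_dtw_matrix(
    series_list: Sequence[np.ndarray],
    labels: Sequence[str] | None = None,
    systems: Sequence[str] | None = None,
    normalization: Normalization = "path",
) -> DistanceMatrix:
    """Normalized DTW cost between every unordered pair of series."""
    n = len(series_list)
    if n < 2:
        raise ValueError("need at least two series")
    lab = list(labels) if labels is not None else [f"r{i}" for i in range(n)]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            c = dtw(series_list[i], series_list[j], normalization=normalization).normalized_cost
            mat[i, j] = mat[j, i] = c
    return DistanceMatrix(labels=lab, matrix=mat, systems=list(systems) if systems else None)


def ward_linkage(dist: DistanceMatrix) -> LinkageTree:
    """Ward's hierarchical clustering of a precomputed distance matrix."""
    condensed = squareform(dist.matrix, checks=True)
    link = hierarchy.linkage(condensed, method="ward")
    return LinkageTree(linkage=link, labels=list(dist.labels), method="ward")


def select_k(
    tree: LinkageTree, method: Literal["largest-gap", "elbow"] = "largest-gap"
) -> ClusterSolution:
    """Data-driven cluster count from the merge-height profile.

    largest-gap: cut just below the largest difference between consecutive
    merge heights.  elbow: cut at the maximum curvature (second difference)
    of the height profile, ties resolved toward smaller k.
    """
    heights = tree.heights
    n_merges = len(heights)
    n_leaves = n_merges + 1
    if method == "largest-gap":
        if n_merges < 2:
            raise ValueError("largest-gap needs at least two merges")
        gaps = np.diff(heights)
        if gaps.max() <= 1e-12:
            warnings.warn("degenerate (equal) merge heights; falling back to k=1")
            return _cut(tree, 1, "largest-gap")
        m = int(np.argmax(gaps)) + 1  # gap between merge m and m+1 (1-based)
        k = n_leaves - m
    elif method == "elbow":
        if n_merges < 3:
            raise ValueError("elbow needs at least three merges")
        d2 = heights[2:] - 2 * heights[1:-1] + heights[:-2]
        if np.abs(d2).max() <= 1e-12:
            warnings.warn("degenerate (equal) merge heights; falling back to k=1")
            return _cut(tree, 1, "elbow")
        # ties toward smaller k = larger merge index
        m = int(len(d2) - 1 - np.argmax(d2[::-1])) + 2  # 1-based merge index
        k = n_leaves - m
    else:
        raise ValueError(f"unknown method {method!r}")
    return _cut(tree, max(k, 1), method)


def _cut(tree: LinkageTree, k: int, criterion: str) -> ClusterSolution:
    flat = hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")
    return ClusterSolution(
        k=int(len(set(flat))),
        assignment={lab: int(c) for lab, c in zip(tree.labels, flat)},
        criterion=criterion,
    )


def cut_tree(tree: LinkageTree, k: int) -> ClusterSolution:
    """Cut the dendrogram into a fixed number of clusters."""
    return _cut(tree, k, "fixed")


def linkage_to_newick(tree: LinkageTree) -> str:
    """Export the dendrogram as a Newick string with branch lengths."""
    link = tree.linkage
    n = len(tree.labels)
    heights = {i: 0.0 for i in range(n)}

    def render(node: int) -> str:
        if node < n:
            return tree.labels[node].replace(" ", "_")
        row = link[node - n]
        a, b, h = int(row[0]), int(row[1]), float(row[2])
        heights[node] = h
        left = render(a)
        right = render(b)
        bl_a = h - heights[a]
        bl_b = h - heights[b]
        return f"({left}:{bl_a:.10g},{right}:{bl_b:.10g})"

    return render(2 * n - 2) + ";"


# ---------------------------------------------------------------------------
# Descriptor-based baseline: Cα-RMSD cost matrix + k-medoids
# ---------------------------------------------------------------------------

def kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Least RMSD between two frames after optimal rigid superposition."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("frames must be matching (n_atoms, 3) arrays")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    cov = xc.T @ yc
    u, s, vt = np.linalg.svd(cov)
    sign = np.sign(np.linalg.det(u @ vt))
    s[-1] *= sign
    # RMSD^2 = (|x|^2 + |y|^2 - 2 tr(S)) / n
    msd = (np.sum(xc * xc) + np.sum(yc * yc) - 2.0 * s.sum()) / x.shape[0]
    return float(np.sqrt(max(msd, 0.0)))


def rmsd_cost_matrix(coords_a: np.ndarray, coords_b: np.ndarray) -> np.ndarray:
    """Pairwise Cα-RMSD between every frame of A and every frame of B.

    Each entry is the least RMSD after Kabsch superposition; the matrix is
    the local-cost input of the dependent-DTW descriptor baseline.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.ndim != 3 or b.ndim != 3 or a.shape[2] != 3 or b.shape[2] != 3:
        raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
    if a.shape[1] != b.shape[1]:
        raise ValueError("atom-count mismatch between trajectories")
    if a.shape[1] < 3:
        raise ValueError("need at least three atoms per frame")
    out = np.empty((a.shape[0], b.shape[0]))
    for i in range(a.shape[0]):
        for j in range(b.shape[0]):
            out[i, j] = kabsch_rmsd(a[i], b[j])
    return out


def _pam(dist: np.ndarray, k: int, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic PAM (BUILD + SWAP) k-medoids on a precomputed matrix."""
    n = dist.shape[0]
    # BUILD: greedy medoid selection
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.array(
            [np.maximum(current - dist[:, c], 0).sum() if c not in medoids else -1.0 for c in range(n)]
        )
        medoids.append(int(np.argmax(gains)))
    medoids_arr = np.array(sorted(medoids))
    # SWAP until no improvement
    for _ in range(max_iter):
        assign = medoids_arr[np.argmin(dist[:, medoids_arr], axis=1)]
        best_cost = dist[np.arange(n), assign].sum()
        improved = False
        for mi in range(k):
            for h in range(n):
                if h in medoids_arr:
                    continue
                trial = medoids_arr.copy()
                trial[mi] = h
                t_assign = trial[np.argmin(dist[:, trial], axis=1)]
                t_cost = dist[np.arange(n), t_assign].sum()
                if t_cost < best_cost - 1e-12:
                    medoids_arr = np.array(sorted(trial))
                    best_cost = t_cost
                    improved = True
        if not improved:
            break
    assign = medoids_arr[np.argmin(dist[:, medoids_arr], axis=1)]
    return medoids_arr, assign


def kmedoids_with_silhouette(
    dist: DistanceMatrix, k_range: Sequence[int] = range(2, 6), seed: int = 0
) -> ClusterSolution:
    """PAM k-medoids per candidate k; keep the k maximizing mean silhouette.

    The PAM initialization is the deterministic greedy BUILD step, so the
    result does not depend on ``seed``; the argument is kept for interface
    stability.  Ties resolve toward smaller k.
    """
    from sklearn.metrics import silhouette_score

    n = len(dist.labels)
    best: tuple[float, int, np.ndarray] | None = None
    for k in k_range:
        if not 2 <= k <= n - 1:
            continue
        _, assign = _pam(dist.matrix, k)
        if len(set(assign.tolist())) < 2:
            continue
        score = silhouette_score(dist.matrix, assign, metric="precomputed")
        if best is None or score > best[0] + 1e-12:
            best = (float(score), k, assign)
    if best is None:
        raise ValueError("no valid k in k_range")
    _, k, assign = best
    # relabel clusters to consecutive ids
    remap = {c: i + 1 for i, c in enumerate(dict.fromkeys(assign.tolist()))}
    return ClusterSolution(
        k=k,
        assignment={lab: remap[c] for lab, c in zip(dist.labels, assign.tolist())},
        criterion="silhouette",
    )
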