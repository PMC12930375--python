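"""Dependent DTW, barycenter averaging and iterative outlier pruning.

MD replicas evolve asynchronously, so frame-to-frame comparison is
unreliable; dynamic time warping aligns two embedding series with a
monotone warp path minimizing the summed local cost.  "Dependent" DTW uses
one Euclidean local cost over all embedding dimensions.  DTW Barycenter
Averaging (DBA) iteratively builds a consensus series minimizing the
average alignment cost to all replicas of an ensemble, and replicas whose
normalized DTW distance to that consensus stands out are pruned so the
final consensus reflects only reproducible behavior.

Inside DBA the alignment and the objective use the squared-Euclidean local
cost: with that cost the barycenter mean-update provably never increases
the objective, which is the classic DBA guarantee.  Reported replica
*scores* use the plain Euclidean-cost DTW normalized by warp-path length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from numba import njit

__all__ = [
    "WarpPath",
    "DTWResult",
    "BarycenterResult",
    "PruningReport",
    "dtw",
    "dtw_from_cost",
    "dba_barycenter",
    "prune_outliers",
]

Normalization = Literal["path", "max", "sum"]


@dataclass
class DTWResult:
    """Optimal alignment of two series: total cost, normalized cost, path."""

    cost: float
    normalized_cost: float
    path: list[tuple[int, int]]


@njit(cache=False)
def _local_cost_matrix(a, b, squared):  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    d = a.shape[1]
    out = np.empty((n, m), dtype=np.float64)
    for i in range(n):
        for j in range(m):
            s = 0.0
            for k in range(d):
                diff = a[i, k] - b[j, k]
                s += diff * diff
            out[i, j] = s if squared else np.sqrt(s)
    return out


@njit(cache=False)
def _accumulate(local):  # pragma: no cover
    n, m = local.shape
    acc = np.empty((n, m), dtype=np.float64)
    acc[0, 0] = local[0, 0]
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + local[0, j]
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + local[i, 0]
        for j in range(1, m):
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = local[i, j] + best
    return acc


def _backtrace(acc: np.ndarray) -> list[tuple[int, int]]:
    """Optimal path by backtracking; ties prefer diagonal, then vertical
    (advance the first series), then horizontal."""
    i, j = acc.shape[0] - 1, acc.shape[1] - 1
    path = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag, vert, horz = acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1]
            best = min(diag, vert, horz)
            if diag == best:
                i, j = i - 1, j - 1
            elif vert == best:
                i -= 1
            else:
                j -= 1
        path.append((i, j))
    path.reverse()
    return path


def _normalizer(path_len: int, n: int, m: int, normalization: Normalization) -> int:
    if normalization == "path":
        return path_len
    if normalization == "max":
        return max(n, m)
    if normalization == "sum":
        return n + m
    raise ValueError(f"unknown normalization {normalization!r}")


def _result_from_local(local: np.ndarray, normalization: Normalization) -> DTWResult:
    acc = _accumulate(local)
    path = _backtrace(acc)
    cost = float(acc[-1, -1])
    div = _normalizer(len(path), local.shape[0], local.shape[1], normalization)
    return DTWResult(cost=cost, normalized_cost=cost / div, path=path)


def _as_2d(a: np.ndarray) -> np.ndarray:
    a = np.ascontiguousarray(np.asarray(a, dtype=np.float64))
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2 or a.shape[0] < 1:
        raise ValueError("series must be a non-empty 1-d or 2-d array")
    return a


def dtw(
    a: np.ndarray,
    b: np.ndarray,
    normalization: Normalization = "path",
    squared: bool = False,
) -> DTWResult:
    """Classic dependent DTW with Euclidean local cost over all dimensions.

    ``cost`` is the sum of local distances along the optimal path and
    ``normalized_cost`` divides by the warp-path length (configurable to
    max(n, m) or n + m).  ``squared=True`` switches the local cost to
    squared Euclidean (used internally by DBA).
    """
    a, b = _as_2d(a), _as_2d(b)
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"dimension mismatch: {a.shape[1]} vs {b.shape[1]}")
    local = _local_cost_matrix(a, b, squared)
    return _result_from_local(local, normalization)


def dtw_from_cost(cost_matrix: np.ndarray, normalization: Normalization = "path") -> DTWResult:
    """Run the DTW recurrence on a precomputed local-cost matrix.

    Supports descriptor-based baselines where the local cost is, e.g., a
    pairwise Cα-RMSD matrix between the frames of two trajectories.
    """
    local = np.ascontiguousarray(np.asarray(cost_matrix, dtype=np.float64))
    if local.ndim != 2 or local.shape[0] < 1 or local.shape[1] < 1:
        raise ValueError("cost matrix must be a non-empty 2-d array")
    if (local < 0).any():
        raise ValueError("cost matrix entries must be non-negative")
    return _result_from_local(local, normalization)


@dataclass
class BarycenterResult:
    """DBA consensus: barycenter matrix, per-replica scores and associations.

    ``associations[r][t]`` lists the frames of replica r matched to
    barycenter index t by the final warp path (never empty, since a warp
    path covers every index of both series).  ``objective_trace`` is the
    mean per-replica squared-cost alignment objective per iteration and is
    non-increasing.
    """

    barycenter: np.ndarray
    replica_ids: list[str]
    results: list[DTWResult]
    associations: list[list[list[int]]]
    iterations_run: int
    objective_trace: list[float]

    @property
    def normalized_costs(self) -> np.ndarray:
        return np.array([r.normalized_cost for r in self.results])


def _resample(series: np.ndarray, length: int) -> np.ndarray:
    """Linear resampling of an (n, D) series to the requested length."""
    n = series.shape[0]
    if n == length:
        return series.copy()
    x_old = np.linspace(0.0, 1.0, n)
    x_new = np.linspace(0.0, 1.0, length)
    return np.column_stack([np.interp(x_new, x_old, series[:, k]) for k in range(series.shape[1])])


def dba_barycenter(
    series_list: Sequence[np.ndarray],
    replica_ids: Sequence[str] | None = None,
    init: Literal["medoid", "mean"] = "medoid",
    max_iter: int = 30,
    tol: float = 1e-5,
    length: int | None = None,
    normalization: Normalization = "path",
) -> BarycenterResult:
    """DTW Barycenter Averaging over replicas of possibly different lengths.

    Starts from the medoid replica (minimum summed DTW cost to the others)
    resampled to the median replica length, then alternates aligning every
    replica to the barycenter and replacing each barycenter point by the
    mean of all frames associated to it.  Stops when the relative objective
    decrease falls below ``tol`` or after ``max_iter`` iterations.
    """
    if not series_list:
        raise ValueError("need at least one series")
    arrs = [_as_2d(s) for s in series_list]
    d = arrs[0].shape[1]
    for s in arrs[1:]:
        if s.shape[1] != d:
            raise ValueError("all series must share the same dimensionality")
    ids = list(replica_ids) if replica_ids is not None else [f"r{i}" for i in range(len(arrs))]
    L = length if length is not None else int(np.median([s.shape[0] for s in arrs]))

    if init == "medoid" and len(arrs) > 1:
        sums = np.zeros(len(arrs))
        for i in range(len(arrs)):
            for j in range(i + 1, len(arrs)):
                c = dtw(arrs[i], arrs[j], squared=True).cost
                sums[i] += c
                sums[j] += c
        bary = _resample(arrs[int(np.argmin(sums))], L)
    elif init == "mean":
        bary = np.mean([_resample(s, L) for s in arrs], axis=0)
    else:
        bary = _resample(arrs[0], L)

    trace: list[float] = []
    associations: list[list[list[int]]] = []
    iterations = 0
    for it in range(max_iter):
        iterations = it + 1
        sums = np.zeros_like(bary)
        counts = np.zeros(L)
        associations = []
        objective = 0.0
        for s in arrs:
            res = dtw(bary, s, squared=True)
            objective += res.cost
            assoc: list[list[int]] = [[] for _ in range(L)]
            for t, f in res.path:
                assoc[t].append(f)
                sums[t] += s[f]
                counts[t] += 1
            associations.append(assoc)
        objective /= len(arrs)
        trace.append(objective)
        new_bary = sums / counts[:, None]
        if trace[-1] == 0.0 or (
            len(trace) >= 2 and (trace[-2] - trace[-1]) < tol * max(trace[-2], 1e-30)
        ):
            bary = new_bary if trace[-1] > 0 else bary
            break
        bary = new_bary

    # final scores and associations against the final barycenter
    results = [dtw(bary, s, normalization=normalization) for s in arrs]
    associations = []
    for s, res in zip(arrs, results):
        assoc = [[] for _ in range(bary.shape[0])]
        for t, f in res.path:
            assoc[t].append(f)
        associations.append(assoc)
    return BarycenterResult(
        barycenter=bary,
        replica_ids=ids,
        results=results,
        associations=associations,
        iterations_run=iterations,
        objective_trace=trace,
    )


def write_warp_path(path: Sequence[tuple[int, int]], stream) -> None:
    """Dump a warp path as a two-column (index_a, index_b) text file."""
    stream.write("index_a\tindex_b\n")
    for i, j in path:
        stream.write(f"{i}\t{j}\n")


@dataclass
class PruningReport:
    """Which replicas survived consensus building, and removal order."""

    kept: list[str]
    removed: list[tuple[str, float]] = field(default_factory=list)


def prune_outliers(
    series_list: Sequence[np.ndarray],
    replica_ids: Sequence[str] | None = None,
    rule: Literal["gap", "count", "threshold"] = "gap",
    count: int = 1,
    threshold: float = 1.0,
    max_removals: int | None = None,
    **dba_kwargs,
) -> tuple[PruningReport, BarycenterResult]:
    """Iteratively remove the replica farthest from the DBA consensus.

    The default "gap" rule removes the worst replica while its normalized
    DTW cost exceeds the next-worst by more than the mean adjacent gap of
    the sorted costs -- a data-driven criterion that fires only when one
    replica clearly stands apart.  "count" removes a fixed number of worst
    replicas; "threshold" removes while the worst cost exceeds a fixed
    value.  At least two replicas are always kept.
    """
    arrs = [_as_2d(s) for s in series_list]
    ids = list(replica_ids) if replica_ids is not None else [f"r{i}" for i in range(len(arrs))]
    if len(arrs) < 2:
        raise ValueError("need at least two replicas")
    limit = max_removals if max_removals is not None else len(arrs) - 2
    limit = min(limit, len(arrs) - 2)

    removed: list[tuple[str, float]] = []
    while True:
        bary = dba_barycenter(arrs, replica_ids=ids, **dba_kwargs)
        costs = bary.normalized_costs
        if len(removed) >= limit or len(arrs) <= 2:
            break
        order = np.argsort(costs)[::-1]
        worst = int(order[0])
        fire = False
        if rule == "count":
            fire = len(removed) < count
        elif rule == "threshold":
            fire = costs[worst] > threshold
        elif rule == "gap":
            sorted_costs = costs[order]
            gaps = -np.diff(sorted_costs)
            if len(gaps) and gaps.max() > 0:
                fire = gaps[0] > gaps.mean()
        else:
            raise ValueError(f"unknown pruning rule {rule!r}")
        if not fire:
            break
        removed.append((ids[worst], float(costs[worst])))
        del arrs[worst]
        del ids[worst]

    return PruningReport(kept=ids, removed=removed), bary
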