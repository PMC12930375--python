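"""Deviation profiles, moving-average smoothing and PELT change points.

Frame-wise Euclidean distances between an aligned replica and its
consensus trajectory (or between the best replicas of two systems) form a
deviation profile over the aligned time axis.  After moving-average
smoothing to suppress thermal noise, the Pruned Exact Linear Time (PELT)
algorithm segments the profile under a penalty linear in the number of
change points, localizing the windows where the dynamics diverge.  Contact
frequencies inside a window can then be pulled back to raw frames per
replica and contrasted between two groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import BarycenterResult, dtw
from .contacts import OccupancySeries
from .embedding import EmbeddingSeries

__all__ = [
    "DeviationProfile",
    "ChangePointSet",
    "deviation_profile",
    "pair_deviation_profile",
    "smooth",
    "default_penalty",
    "pelt_segment",
    "optimal_partition",
    "contact_shift_table",
]


@dataclass
class DeviationProfile:
    """Non-negative distance values along an aligned time axis."""

    source: tuple[str, str]
    values: np.ndarray
    smoothing_window: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("deviation values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ChangePointSet:
    """Ordered interior change-point indices with the penalty used.

    ``indices`` are segment starts in (0, L); ``segment_means`` has one
    entry per segment (len(indices) + 1).
    """

    indices: list[int]
    penalty: float
    segment_means: list[float]


def deviation_profile(
    replica: EmbeddingSeries, consensus: BarycenterResult
) -> DeviationProfile:
    """Distance of a replica to the consensus at every barycenter index.

    Value at index t is the Euclidean distance between barycenter[t] and
    the mean of the replica frames associated to t by the warp path.  If
    the replica did not participate in the consensus it is aligned to the
    barycenter first.
    """
    if replica.replica_id in consensus.replica_ids:
        r = consensus.replica_ids.index(replica.replica_id)
        assoc = consensus.associations[r]
    else:
        res = dtw(consensus.barycenter, replica.matrix)
        assoc = [[] for _ in range(consensus.barycenter.shape[0])]
        for t, f in res.path:
            assoc[t].append(f)
    values = np.empty(consensus.barycenter.shape[0])
    for t, frames in enumerate(assoc):
        if not frames:
            raise ValueError(f"no frames associated to barycenter index {t}")
        mean_frame = replica.matrix[frames].mean(axis=0)
        values[t] = np.linalg.norm(consensus.barycenter[t] - mean_frame)
    return DeviationProfile(source=(replica.replica_id, "consensus"), values=values)


def pair_deviation_profile(
    a: EmbeddingSeries | np.ndarray,
    b: EmbeddingSeries | np.ndarray,
    ids: tuple[str, str] | None = None,
) -> DeviationProfile:
    """Cross-system divergence profile between two aligned series.

    The two series (replica embeddings or consensus barycenters) are
    aligned by DTW and, for every frame of the first series, the mean
    local distance over the warp-path steps visiting that frame is
    reported, giving a profile on the first series' time axis.  Comparing
    the consensus barycenters of two systems gives the least noisy
    profile, since each barycenter point already averages several frames
    per replica.
    """
    mat_a = a.matrix if isinstance(a, EmbeddingSeries) else np.asarray(a, dtype=float)
    mat_b = b.matrix if isinstance(b, EmbeddingSeries) else np.asarray(b, dtype=float)
    if ids is None:
        ids = (
            a.replica_id if isinstance(a, EmbeddingSeries) else "a",
            b.replica_id if isinstance(b, EmbeddingSeries) else "b",
        )
    res = dtw(mat_a, mat_b)
    sums = np.zeros(mat_a.shape[0])
    counts = np.zeros(mat_a.shape[0])
    for i, j in res.path:
        d = np.linalg.norm(mat_a[i] - mat_b[j])
        sums[i] += d
        counts[i] += 1
    return DeviationProfile(source=ids, values=sums / counts)


def smooth(profile: DeviationProfile, window: int) -> DeviationProfile:
    """Centered moving average with a shrinking window at the boundaries."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    v = profile.values
    half = window // 2
    c = np.concatenate([[0.0], np.cumsum(v)])
    n = len(v)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    out = (c[hi + 1] - c[lo]) / (hi - lo + 1)
    return DeviationProfile(source=profile.source, values=out, smoothing_window=window)


def default_penalty(values: np.ndarray) -> float:
    """BIC-like linear penalty 2 sigma^2 log L, sigma from first differences."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2:
        return 1.0
    sigma2 = float(np.sum(np.diff(v) ** 2) / (2 * (n - 1)))
    return max(2.0 * sigma2 * np.log(n), 1e-12)


def _prefix_sums(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.concatenate([[0.0], np.cumsum(v)]),
        np.concatenate([[0.0], np.cumsum(v * v)]),
    )


def _segment_cost(s1: np.ndarray, s2: np.ndarray, a: int, b: int) -> float:
    """Sum of squared deviations from the mean of values[a:b]."""
    n = b - a
    tot = s1[b] - s1[a]
    return float(s2[b] - s2[a] - tot * tot / n)


def pelt_segment(values: np.ndarray, penalty: float | None = None) -> ChangePointSet:
    """Exact penalized least-squares segmentation via PELT.

    Minimizes sum of within-segment squared deviations plus
    ``penalty`` x (number of change points); the pruning step only discards
    candidates that provably cannot be optimal, so the result equals the
    unpruned optimal-partitioning dynamic program.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2:
        raise ValueError("series must have length >= 2")
    beta = default_penalty(v) if penalty is None else float(penalty)
    if beta <= 0:
        raise ValueError("penalty must be positive")
    s1, s2 = _prefix_sums(v)

    f = np.full(n + 1, np.inf)
    f[0] = -beta
    prev = np.zeros(n + 1, dtype=int)
    candidates = [0]
    for t in range(1, n + 1):
        best = np.inf
        best_tau = 0
        for tau in candidates:
            c = f[tau] + _segment_cost(s1, s2, tau, t) + beta
            if c < best:
                best = c
                best_tau = tau
        f[t] = best
        prev[t] = best_tau
        # PELT pruning: tau cannot be optimal for any t' > t if
        # f(tau) + C(tau, t) > f(t)
        candidates = [
            tau for tau in candidates if f[tau] + _segment_cost(s1, s2, tau, t) <= f[t]
        ]
        candidates.append(t)

    cps: list[int] = []
    t = n
    while t > 0:
        tau = int(prev[t])
        if tau > 0:
            cps.append(tau)
        t = tau
    cps.reverse()
    bounds = [0] + cps + [n]
    means = [float(v[a:b].mean()) for a, b in zip(bounds[:-1], bounds[1:])]
    return ChangePointSet(indices=cps, penalty=beta, segment_means=means)


def optimal_partition(values: np.ndarray, penalty: float) -> ChangePointSet:
    """Unpruned O(n^2) optimal-partitioning dynamic program (reference)."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    s1, s2 = _prefix_sums(v)
    f = np.full(n + 1, np.inf)
    f[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    for t in range(1, n + 1):
        costs = [f[tau] + _segment_cost(s1, s2, tau, t) + penalty for tau in range(t)]
        best_tau = int(np.argmin(costs))
        f[t] = costs[best_tau]
        prev[t] = best_tau
    cps: list[int] = []
    t = n
    while t > 0:
        tau = int(prev[t])
        if tau > 0:
            cps.append(tau)
        t = tau
    cps.reverse()
    bounds = [0] + cps + [n]
    means = [float(v[a:b].mean()) for a, b in zip(bounds[:-1], bounds[1:])]
    return ChangePointSet(indices=cps, penalty=penalty, segment_means=means)


def contact_shift_table(
    group_a: Sequence[OccupancySeries],
    group_b: Sequence[OccupancySeries],
    window: tuple[int, int],
    warp_maps_a: Sequence[Sequence[Sequence[int]]],
    warp_maps_b: Sequence[Sequence[Sequence[int]]],
    restrict_to_residue: str | None = None,
) -> pd.DataFrame:
    """Per-edge occupancy difference between two groups within a window.

    ``window`` is a half-open [start, end) range on the aligned axis; the
    warp maps (aligned index -> raw frame indices, one per replica) pull
    the window back to each replica's own frames.  Rows are ranked by
    absolute occupancy difference; ``restrict_to_residue`` keeps only edges
    touching the named residue (``chain:resname:resid``).
    """
    start, end = window
    axis_len = len(warp_maps_a[0])
    if not (0 <= start < end <= axis_len):
        raise ValueError(f"window {window} outside aligned axis of length {axis_len}")
    vocab = group_a[0].vocabulary
    for s in list(group_a) + list(group_b):
        if s.vocabulary != vocab:
            raise ValueError("all series must share one vocabulary")

    def group_occupancy(group, maps):
        rows = []
        for s, amap in zip(group, maps):
            frames = sorted({f for t in range(start, end) for f in amap[t]})
            rows.append(s.matrix[frames].mean(axis=0))
        return np.mean(rows, axis=0)

    occ_a = group_occupancy(group_a, warp_maps_a)
    occ_b = group_occupancy(group_b, warp_maps_b)
    diff = occ_a - occ_b
    df = pd.DataFrame(
        {
            "residue_a": [str(e[0]) for e in vocab.edges],
            "residue_b": [str(e[1]) for e in vocab.edges],
            "occupancy_a": occ_a,
            "occupancy_b": occ_b,
            "difference": diff,
            "favors": np.where(diff > 0, "A", np.where(diff < 0, "B", "-")),
        }
    )
    if restrict_to_residue is not None:
        mask = (df["residue_a"] == restrict_to_residue) | (
            df["residue_b"] == restrict_to_residue
        )
        df = df[mask]
    df = df.reindex(df["difference"].abs().sort_values(ascending=False, kind="stable").index)
    return df.reset_index(drop=True)
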