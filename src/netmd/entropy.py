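"""Shannon-entropy scoring and pruning of contact edges.

Each contact is a presence/absence variable across all frames and replicas
of an ensemble; its binary Shannon entropy (in bits, max 1.0) measures how
variable the contact is.  Contacts that are effectively invariant carry no
dynamic signal and are pruned; an optional upper cutoff can additionally
discard near-random, high-entropy contacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TextIO

import numpy as np
from scipy.optimize import brentq

from .contacts import EdgeVocabulary, OccupancySeries

__all__ = [
    "binary_entropy",
    "occupancy_interval",
    "EdgeEntropyTable",
    "EntropyFilterSpec",
    "edge_entropy",
    "filter_edges",
    "write_entropy_report",
]


def binary_entropy(p: np.ndarray | float) -> np.ndarray | float:
    """H(p) = -p log2 p - (1-p) log2(1-p), with 0 log 0 := 0."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    interior = (p > 0) & (p < 1)
    q = p[interior]
    out[interior] = -q * np.log2(q) - (1 - q) * np.log2(1 - q)
    return out if out.ndim else float(out)


def occupancy_interval(cutoff: float) -> tuple[float, float]:
    """Occupancy interval [p*, 1-p*] retained by an entropy cutoff.

    Solves H(p*) = cutoff on (0, 1/2) by root finding; cutoff 0 retains
    everything except exact 0/1 occupancy.
    """
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must lie in [0, 1]")
    if cutoff == 0:
        return (0.0, 1.0)
    if cutoff == 1:
        return (0.5, 0.5)
    p_star = brentq(lambda p: binary_entropy(p) - cutoff, 1e-12, 0.5, xtol=1e-14)
    return (p_star, 1.0 - p_star)


@dataclass
class EdgeEntropyTable:
    """Per-edge occupancy and entropy pooled over an ensemble's replicas."""

    vocabulary: EdgeVocabulary
    occupancy: np.ndarray  # fraction in [0,1] per edge
    entropy: np.ndarray  # bits per edge
    n_frames_total: int


@dataclass
class EntropyFilterSpec:
    """Retention band in bits: keep edges with lower <= H (<= upper if set)."""

    lower_cutoff: float = 0.1
    upper_cutoff: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.lower_cutoff <= 1:
            raise ValueError("lower_cutoff must lie in [0, 1]")
        if self.upper_cutoff is not None and not self.lower_cutoff <= self.upper_cutoff <= 1:
            raise ValueError("upper_cutoff must lie in [lower_cutoff, 1]")


def edge_entropy(ensembles: Sequence[OccupancySeries]) -> EdgeEntropyTable:
    """Pool active-frame counts over all series and score each edge.

    All series must share one vocabulary; occupancy p is total active frames
    over total frames, and entropy is the binary entropy of p.
    """
    if not ensembles:
        raise ValueError("need at least one occupancy series")
    vocab = ensembles[0].vocabulary
    for s in ensembles[1:]:
        if s.vocabulary != vocab:
            raise ValueError("all series must share one vocabulary")
    counts = np.zeros(len(vocab), dtype=np.int64)
    total = 0
    for s in ensembles:
        counts += s.matrix.sum(axis=0, dtype=np.int64)
        total += s.n_frames
    p = counts / total
    return EdgeEntropyTable(
        vocabulary=vocab, occupancy=p, entropy=binary_entropy(p), n_frames_total=total
    )


def filter_edges(
    series_list: Sequence[OccupancySeries],
    table: EdgeEntropyTable,
    spec: EntropyFilterSpec = EntropyFilterSpec(),
) -> tuple[list[OccupancySeries], EdgeVocabulary]:
    """Column-subset every series to the edges inside the entropy band.

    Raising the lower cutoff can only shrink the retained set; an empty
    retained set is an error (the cutoff is too aggressive for the data).
    """
    if table.vocabulary != series_list[0].vocabulary:
        raise ValueError("entropy table vocabulary does not match the series")
    keep = table.entropy >= spec.lower_cutoff
    if spec.upper_cutoff is not None:
        keep &= table.entropy <= spec.upper_cutoff
    if not keep.any():
        raise ValueError(
            "no edges retained; lower the entropy cutoff "
            f"(lower_cutoff={spec.lower_cutoff})"
        )
    retained = table.vocabulary.subset(keep)
    filtered = [
        OccupancySeries(
            replica_id=s.replica_id,
            vocabulary=retained,
            matrix=s.matrix[:, keep],
            system_id=s.system_id,
        )
        for s in series_list
    ]
    return filtered, retained


def write_entropy_report(
    table: EdgeEntropyTable, spec: EntropyFilterSpec, stream: TextIO
) -> None:
    """TSV report: residue pair, occupancy, entropy in bits, retained flag."""
    keep = table.entropy >= spec.lower_cutoff
    if spec.upper_cutoff is not None:
        keep &= table.entropy <= spec.upper_cutoff
    stream.write("residue_a\tresidue_b\toccupancy\tentropy_bits\tretained\n")
    for (a, b), p, h, k in zip(table.vocabulary.edges, table.occupancy, table.entropy, keep):
        stream.write(f"{a}\t{b}\t{float(p)!r}\t{float(h)!r}\t{int(k)}\n")
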