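"""Weisfeiler-Lehman graph documents and Graph2Vec-style frame embeddings.

Every frame graph is flattened into a "document" of WL subtree tokens:
iteration 0 emits each node's residue label, and iteration i emits a stable
digest of the node's previous label together with the sorted multiset of
its neighbors' previous labels.  Tokens from all iterations 0..k coexist so
the document captures both coarse (residue identity) and finer (local
connectivity) structure.  A distributed bag-of-tokens model with negative
sampling (the PV-DBOW objective Graph2Vec builds on) then maps every frame
to one D-dimensional vector; all replicas and systems under comparison are
trained jointly in a single model so their coordinates are commensurable.

Training is single-threaded and fully seeded: identical inputs and seed
give bitwise-identical embedding matrices.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .contacts import FrameGraph

__all__ = [
    "WLDocument",
    "EmbeddingConfig",
    "EmbeddingSeries",
    "wl_relabel",
    "train_embeddings",
    "embed_frame_graphs",
    "reduce_pca",
]


@dataclass
class WLDocument:
    """Multiset of WL subtree tokens for one graph (one trajectory frame)."""

    graph_index: int
    tokens: list[str]


@dataclass
class EmbeddingConfig:
    """Hyper-parameters of the WL + document-embedding step.

    ``wl_iterations`` (default 3) controls how far neighborhood information
    propagates; ``dimensions`` (default 16) is the latent space size.  The
    remaining knobs belong to the PV-DBOW optimizer.
    """

    wl_iterations: int = 3
    dimensions: int = 16
    epochs: int = 100
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    negative: int = 5
    min_token_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wl_iterations < 1:
            raise ValueError("wl_iterations must be >= 1")
        if self.dimensions < 2:
            raise ValueError("dimensions must be >= 2")


@dataclass
class EmbeddingSeries:
    """Frames x D embedding matrix for one replica."""

    replica_id: str
    system_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if not np.isfinite(self.matrix).all():
            raise ValueError("embedding matrix contains non-finite entries")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]


def _digest(text: str) -> str:
    return hashlib.blake2b(text.encode("utf-8"), digest_size=8).hexdigest()


def wl_relabel(graph: FrameGraph, k: int, graph_index: int = 0) -> WLDocument:
    """Run k WL relabeling iterations and emit tokens from iterations 0..k.

    The digest of a node at iteration i is a 16-hex-character hash of
    ``prev_label|sorted neighbor prev_labels`` -- stable across runs and
    platforms, and invariant under node and edge-list reordering.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    adj = graph.adjacency()
    labels = list(graph.nodes)
    tokens: list[str] = list(labels)
    for _ in range(k):
        new_labels = []
        for v, neigh in enumerate(adj):
            neighborhood = ",".join(sorted(labels[u] for u in neigh))
            new_labels.append(_digest(f"{labels[v]}|{neighborhood}"))
        labels = new_labels
        tokens.extend(labels)
    return WLDocument(graph_index=graph_index, tokens=tokens)


# ---------------------------------------------------------------------------
# PV-DBOW with negative sampling (numba kernel)
# ---------------------------------------------------------------------------

_NEG_TABLE_SIZE = 1 << 20


@njit(cache=False)
def _sgd_pvdbow(
    doc_ids, token_ids, doc_vecs, ctx_vecs, neg_table, epochs, lr0, lr_min, negative, seed
):  # pragma: no cover - exercised through train_embeddings
    n_examples = token_ids.shape[0]
    dim = doc_vecs.shape[1]
    total = epochs * n_examples
    state = np.uint64(seed * np.uint64(2654435761) + np.uint64(1))
    table_size = np.uint64(neg_table.shape[0])
    grad = np.empty(dim, dtype=np.float64)
    step = 0
    for _ in range(epochs):
        for i in range(n_examples):
            lr = lr0 - (lr0 - lr_min) * (step / total)
            step += 1
            d = doc_ids[i]
            target = token_ids[i]
            for j in range(dim):
                grad[j] = 0.0
            for k in range(negative + 1):
                if k == 0:
                    t = target
                    label = 1.0
                else:
                    state ^= state << np.uint64(13)
                    state ^= state >> np.uint64(7)
                    state ^= state << np.uint64(17)
                    t = neg_table[state % table_size]
                    if t == target:
                        continue
                    label = 0.0
                f = 0.0
                for j in range(dim):
                    f += doc_vecs[d, j] * ctx_vecs[t, j]
                if f > 8.0:
                    s = 1.0
                elif f < -8.0:
                    s = 0.0
                else:
                    s = 1.0 / (1.0 + np.exp(-f))
                g = (label - s) * lr
                for j in range(dim):
                    grad[j] += g * ctx_vecs[t, j]
                    ctx_vecs[t, j] += g * doc_vecs[d, j]
            for j in range(dim):
                doc_vecs[d, j] += grad[j]


def train_embeddings(
    documents: Sequence[WLDocument], config: EmbeddingConfig = EmbeddingConfig()
) -> np.ndarray:
    """Train one joint PV-DBOW model; returns the (n_docs, D) matrix.

    Token vocabulary order is the sorted token set (deterministic); the
    negative-sampling table follows the usual unigram^0.75 distribution.
    """
    if not documents:
        raise ValueError("no documents to embed")
    counts: Counter[str] = Counter()
    for doc in documents:
        counts.update(doc.tokens)
    vocab = sorted(t for t, c in counts.items() if c >= config.min_token_count)
    if not vocab:
        raise ValueError("empty token vocabulary: all graphs are edgeless and label-free")
    token_index = {t: i for i, t in enumerate(vocab)}

    doc_ids: list[int] = []
    token_ids: list[int] = []
    for d, doc in enumerate(documents):
        for t in doc.tokens:
            idx = token_index.get(t)
            if idx is not None:
                doc_ids.append(d)
                token_ids.append(idx)
    doc_ids_arr = np.asarray(doc_ids, dtype=np.int64)
    token_ids_arr = np.asarray(token_ids, dtype=np.int64)

    freq = np.array([counts[t] for t in vocab], dtype=np.float64) ** 0.75
    cum = np.cumsum(freq / freq.sum())
    positions = (np.arange(_NEG_TABLE_SIZE) + 0.5) / _NEG_TABLE_SIZE
    neg_table = np.searchsorted(cum, positions).astype(np.int64)

    rng = np.random.RandomState(config.seed)
    dim = config.dimensions
    doc_vecs = (rng.rand(len(documents), dim) - 0.5) / dim
    ctx_vecs = np.zeros((len(vocab), dim), dtype=np.float64)

    _sgd_pvdbow(
        doc_ids_arr,
        token_ids_arr,
        doc_vecs,
        ctx_vecs,
        neg_table,
        config.epochs,
        config.learning_rate,
        config.min_learning_rate,
        config.negative,
        np.uint64(config.seed + 1),
    )
    return doc_vecs


def embed_frame_graphs(
    graphs_per_series: Sequence[Sequence[FrameGraph]],
    ids: Sequence[tuple[str, str]],
    config: EmbeddingConfig = EmbeddingConfig(),
) -> list[EmbeddingSeries]:
    """WL-relabel and jointly embed the frames of several replicas.

    ``ids`` gives ``(system_id, replica_id)`` per series.  All frames of all
    series share one model so the resulting coordinates are comparable
    across replicas and systems.
    """
    if len(graphs_per_series) != len(ids):
        raise ValueError("ids must match graphs_per_series")
    documents: list[WLDocument] = []
    offsets = [0]
    for graphs in graphs_per_series:
        for g in graphs:
            documents.append(wl_relabel(g, config.wl_iterations, graph_index=len(documents)))
        offsets.append(len(documents))
    matrix = train_embeddings(documents, config)
    out = []
    for (system_id, replica_id), start, stop in zip(ids, offsets[:-1], offsets[1:]):
        out.append(
            EmbeddingSeries(replica_id=replica_id, system_id=system_id, matrix=matrix[start:stop])
        )
    return out


def reduce_pca(
    series_list: Sequence[EmbeddingSeries], variance_kept: float = 0.90
) -> list[EmbeddingSeries]:
    """Joint PCA reduction keeping the stated cumulative explained variance.

    Intended for visualization and clustering diagnostics only: trajectory
    alignment always consumes the raw D-dimensional series.
    """
    if not 0 < variance_kept <= 1:
        raise ValueError("variance_kept must lie in (0, 1]")
    from sklearn.decomposition import PCA

    stacked = np.vstack([s.matrix for s in series_list])
    if stacked.shape[0] < 2:
        raise ValueError("need at least two frames in total")
    pca = PCA(svd_solver="full")
    pca.fit(stacked)
    evr = pca.explained_variance_ratio_
    if variance_kept == 1.0:
        n_comp = int((pca.explained_variance_ > 1e-12).sum())
    else:
        n_comp = int(np.searchsorted(np.cumsum(evr), variance_kept) + 1)
    n_comp = max(n_comp, 1)
    out = []
    for s in series_list:
        reduced = pca.transform(s.matrix)[:, :n_comp]
        out.append(EmbeddingSeries(replica_id=s.replica_id, system_id=s.system_id, matrix=reduced))
    return out
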