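"""Residue-contact tables, shared edge vocabularies and per-frame graphs.

Trajectory frames are represented as undirected residue-contact graphs: one
node per residue, one edge per observed residue-residue interaction.  Input
is a GetContacts-style tab-separated table (one row per atom-level contact
per frame); atom-level records are collapsed to residue pairs, so a frame
graph is a simple unlabeled graph over the residues of the system.

All replicas and systems under comparison are mapped onto one shared
:class:`EdgeVocabulary` so their occupancy matrices live in the same column
space and their graphs share a common node set.
"""

from __future__ import annotations

import functools
import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd

__all__ = [
    "ResidueId",
    "ContactEventTable",
    "EdgeVocabulary",
    "OccupancySeries",
    "FrameGraph",
    "parse_contact_table",
    "write_contact_table",
    "build_vocabulary",
    "to_occupancy",
    "build_cg_contacts",
    "to_frame_graphs",
]


@functools.total_ordering
@dataclass(frozen=True)
class ResidueId:
    """A residue identified by chain, 3-letter name and sequence number.

    Ordering is total and lexicographic on ``(chain, residue_number)`` so
    that edge endpoints can be canonically sorted independently of the
    residue name.
    """

    chain: str
    residue_name: str
    residue_number: int

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise ValueError(f"residue_number must be >= 1, got {self.residue_number}")

    @property
    def sort_key(self) -> tuple[str, int]:
        return (self.chain, self.residue_number)

    def __lt__(self, other: "ResidueId") -> bool:
        return self.sort_key < other.sort_key

    def __str__(self) -> str:
        return f"{self.chain}:{self.residue_name}:{self.residue_number}"

    @classmethod
    def from_string(cls, text: str) -> "ResidueId":
        """Parse ``chain:resname:resid`` (an optional trailing atom field is ignored)."""
        parts = text.split(":")
        if len(parts) < 3:
            raise ValueError(f"cannot parse residue identifier {text!r}")
        chain, resname, resid = parts[0], parts[1], parts[2]
        return cls(chain=chain, residue_name=resname, residue_number=int(resid))


Edge = tuple[ResidueId, ResidueId]


def canonical_edge(a: ResidueId, b: ResidueId) -> Edge:
    """Order the endpoints of an undirected contact; self-contacts are rejected."""
    if a.sort_key == b.sort_key:
        raise ValueError(f"self-contact on residue {a}")
    return (a, b) if a < b else (b, a)


@dataclass
class ContactEventTable:
    """Long-format record of every residue-pair contact per frame of one replica.

    ``frames`` spans the contiguous range ``0..n_frames-1``; frames without
    any contact simply contribute no rows but remain part of the range.
    """

    replica_id: str
    events: pd.DataFrame  # columns: frame, interaction_type, residue_a, residue_b
    n_frames: int
    system_id: str = ""

    REQUIRED_COLUMNS = ("frame", "interaction_type", "residue_a", "residue_b")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"events table missing columns {missing}")
        if len(self.events) and int(self.events["frame"].max()) >= self.n_frames:
            raise ValueError("frame index exceeds declared n_frames")

    def edge_set(self) -> set[Edge]:
        return set(zip(self.events["residue_a"], self.events["residue_b"]))

    def __len__(self) -> int:
        return len(self.events)


class EdgeVocabulary:
    """Deterministically ordered set of canonical residue pairs.

    Columns of every :class:`OccupancySeries` are indexed by this shared
    vocabulary so that replicas and systems are directly comparable.
    """

    def __init__(self, edges: Iterable[Edge]):
        ordered = sorted(set(edges), key=lambda e: (e[0].sort_key, e[1].sort_key))
        self._edges: tuple[Edge, ...] = tuple(ordered)
        self._index = {e: i for i, e in enumerate(self._edges)}
        if len(self._index) != len(self._edges):
            raise ValueError("duplicate edges in vocabulary")

    @property
    def edges(self) -> tuple[Edge, ...]:
        return self._edges

    def index_of(self, edge: Edge) -> int:
        return self._index[edge]

    def __contains__(self, edge: Edge) -> bool:
        return edge in self._index

    def __len__(self) -> int:
        return len(self._edges)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, EdgeVocabulary) and self._edges == other._edges

    def __hash__(self) -> int:
        return hash(self._edges)

    def subset(self, keep: np.ndarray) -> "EdgeVocabulary":
        """New vocabulary from a boolean column mask, preserving order."""
        keep = np.asarray(keep, dtype=bool)
        if keep.shape != (len(self),):
            raise ValueError("mask length does not match vocabulary size")
        return EdgeVocabulary(e for e, k in zip(self._edges, keep) if k)

    def node_set(self) -> list[ResidueId]:
        """Sorted union of all edge endpoints (the shared node set)."""
        nodes = {r for e in self._edges for r in e}
        return sorted(nodes, key=lambda r: r.sort_key)


@dataclass
class OccupancySeries:
    """Binary frames x edges matrix for one replica over a shared vocabulary."""

    replica_id: str
    vocabulary: EdgeVocabulary
    matrix: np.ndarray  # uint8, shape (n_frames, len(vocabulary))
    system_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.vocabulary):
            raise ValueError("matrix shape does not match vocabulary size")
        if self.matrix.size and self.matrix.max() > 1:
            raise ValueError("occupancy entries must be 0/1")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]


@dataclass
class FrameGraph:
    """One frame's residue-contact graph over the constant shared node set.

    ``nodes`` are label strings (``chain:resname:resid``); ``edges`` are
    index pairs into ``nodes``.  Isolated nodes are kept so that graphs of
    different frames (and systems) remain comparable.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    edge_labels: tuple[str, ...] = ()

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.nodes]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for i, label in enumerate(self.nodes):
            g.add_node(i, label=label)
        g.add_edges_from(self.edges)
        return g


# ---------------------------------------------------------------------------
# GetContacts-style TSV dialect
# ---------------------------------------------------------------------------

def parse_contact_table(
    stream: TextIO | Iterable[str], replica_id: str, n_frames: int | None = None
) -> ContactEventTable:
    """Parse a GetContacts-style TSV into a residue-level contact table.

    Data lines are TAB-separated ``frame, interaction_type, atom_1, atom_2``
    with ``atom = chain:resname:resid:atomname``; comment lines start with
    ``#`` and extra trailing columns are ignored.  Atom-level records are
    collapsed to residue pairs, duplicates within a frame are merged, and
    endpoints are canonically ordered.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    frames: list[int] = []
    itypes: list[str] = []
    res_a: list[ResidueId] = []
    res_b: list[ResidueId] = []
    saw_data = False
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 4:
            raise ValueError(
                f"line {lineno}: expected >=4 tab-separated columns, got {len(cols)}"
            )
        try:
            frame = int(cols[0])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-integer frame index {cols[0]!r}") from exc
        if frame < 0:
            raise ValueError(f"line {lineno}: negative frame index {frame}")
        try:
            a = ResidueId.from_string(cols[2])
            b = ResidueId.from_string(cols[3])
            a, b = canonical_edge(a, b)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
        saw_data = True
        frames.append(frame)
        itypes.append(cols[1])
        res_a.append(a)
        res_b.append(b)

    if not saw_data:
        raise ValueError(f"no contact records found for replica {replica_id!r}")

    df = pd.DataFrame(
        {"frame": frames, "interaction_type": itypes, "residue_a": res_a, "residue_b": res_b}
    )
    # multiple interaction types / atom pairs between the same residues in a
    # frame count as a single unlabeled edge
    df = df.drop_duplicates(subset=["frame", "residue_a", "residue_b"], keep="first")
    df = df.sort_values(["frame"], kind="stable").reset_index(drop=True)
    total = n_frames if n_frames is not None else int(df["frame"].max()) + 1
    return ContactEventTable(replica_id=replica_id, events=df, n_frames=total)


def write_contact_table(table: ContactEventTable, stream: TextIO) -> None:
    """Emit the same TSV dialect that :func:`parse_contact_table` reads.

    Residue endpoints are written with a placeholder atom field (``CA``)
    since atom identity is not retained at residue level.
    """
    stream.write(f"# replica: {table.replica_id}\n")
    stream.write(f"# n_frames: {table.n_frames}\n")
    stream.write("# frame\tinteraction_type\tatom_1\tatom_2\n")
    for frame, itype, a, b in table.events[
        ["frame", "interaction_type", "residue_a", "residue_b"]
    ].itertuples(index=False):
        stream.write(f"{frame}\t{itype}\t{a}:CA\t{b}:CA\n")


def build_vocabulary(tables: Sequence[ContactEventTable]) -> EdgeVocabulary:
    """Sorted union of all residue pairs across all tables (deterministic)."""
    if not tables:
        raise ValueError("need at least one contact table")
    edges: set[Edge] = set()
    for t in tables:
        edges.update(t.edge_set())
    return EdgeVocabulary(edges)


def to_occupancy(
    table: ContactEventTable, vocab: EdgeVocabulary, n_frames: int | None = None
) -> OccupancySeries:
    """Rasterize a contact table into a binary frames x edges matrix."""
    total = table.n_frames if n_frames is None else n_frames
    if len(table.events) and int(table.events["frame"].max()) >= total:
        raise ValueError("table contains frames beyond n_frames")
    mat = np.zeros((total, len(vocab)), dtype=np.uint8)
    for frame, a, b in table.events[["frame", "residue_a", "residue_b"]].itertuples(index=False):
        edge = (a, b)
        if edge not in vocab:
            raise KeyError(
                f"edge {a}--{b} not in vocabulary; build the vocabulary over all inputs first"
            )
        mat[frame, vocab.index_of(edge)] = 1
    return OccupancySeries(
        replica_id=table.replica_id,
        vocabulary=vocab,
        matrix=mat,
        system_id=table.system_id,
    )


def build_cg_contacts(
    coords: np.ndarray,
    bead_residues: Sequence[ResidueId],
    mutation_sites: Sequence[ResidueId],
    replica_id: str = "cg",
    node_radius: float = 15.0,
    edge_cutoff: float = 6.0,
    node_reference: str = "first",
) -> ContactEventTable:
    """Coarse-grained contact construction from per-frame bead coordinates.

    Nodes are the beads within ``node_radius`` (inclusive, Angstrom) of any
    mutation-site bead; edges connect node pairs strictly closer than
    ``edge_cutoff`` in a frame.  ``node_reference`` selects which frames
    define the node set: ``"first"`` uses frame 0, ``"any"`` admits a bead
    if it is within the radius in any frame.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError("coords must have shape (n_frames, n_beads, 3)")
    n_frames, n_beads, _ = coords.shape
    if n_frames < 1:
        raise ValueError("need at least one frame")
    if len(bead_residues) != n_beads:
        raise ValueError("bead_residues length must equal the bead count")
    if node_reference not in ("first", "any"):
        raise ValueError("node_reference must be 'first' or 'any'")

    index_of = {r: i for i, r in enumerate(bead_residues)}
    site_idx = []
    for site in mutation_sites:
        if site not in index_of:
            raise KeyError(f"mutation site {site} not present among beads")
        site_idx.append(index_of[site])

    ref = coords[:1] if node_reference == "first" else coords
    # distance of every bead to every mutation site over the reference frames
    d = np.linalg.norm(ref[:, :, None, :] - ref[:, None, site_idx, :], axis=-1)
    node_mask = (d.min(axis=2) <= node_radius).any(axis=0)
    nodes = np.flatnonzero(node_mask)

    frames: list[int] = []
    res_a: list[ResidueId] = []
    res_b: list[ResidueId] = []
    iu, ju = np.triu_indices(len(nodes), k=1)
    for f in range(n_frames):
        pos = coords[f, nodes]
        dist = np.linalg.norm(pos[iu] - pos[ju], axis=1)
        for a_i, b_i in zip(nodes[iu[dist < edge_cutoff]], nodes[ju[dist < edge_cutoff]]):
            a, b = canonical_edge(bead_residues[a_i], bead_residues[b_i])
            frames.append(f)
            res_a.append(a)
            res_b.append(b)

    df = pd.DataFrame(
        {
            "frame": pd.Series(frames, dtype=int),
            "interaction_type": ["cg"] * len(frames),
            "residue_a": res_a,
            "residue_b": res_b,
        }
    )
    return ContactEventTable(replica_id=replica_id, events=df, n_frames=n_frames)


def read_bead_table(stream: TextIO | Iterable[str]) -> tuple[np.ndarray, list[ResidueId]]:
    """Read coarse-grained bead coordinates from a plain whitespace table.

    Columns: frame, chain, resname, resid, x, y, z (Angstrom); comment
    lines start with '#'.  Every frame must list the same beads in the
    same order.  Returns coordinates of shape (n_frames, n_beads, 3) and
    the per-bead residue identities.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    frames: dict[int, list[tuple[ResidueId, tuple[float, float, float]]]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 7:
            raise ValueError(f"line {lineno}: expected 7 columns, got {len(cols)}")
        try:
            f = int(cols[0])
            r = ResidueId(chain=cols[1], residue_name=cols[2], residue_number=int(cols[3]))
            xyz = (float(cols[4]), float(cols[5]), float(cols[6]))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
        frames.setdefault(f, []).append((r, xyz))
    if not frames:
        raise ValueError("no bead records found")
    order = sorted(frames)
    if order != list(range(len(order))):
        raise ValueError("frame indices must form a contiguous range starting at 0")
    residues = [r for r, _ in frames[0]]
    coords = np.empty((len(order), len(residues), 3))
    for f in order:
        if [r for r, _ in frames[f]] != residues:
            raise ValueError(f"frame {f}: bead list differs from frame 0")
        coords[f] = [xyz for _, xyz in frames[f]]
    return coords, residues


def to_frame_graphs(
    series: OccupancySeries, node_set: Sequence[ResidueId] | None = None
) -> list[FrameGraph]:
    """One graph per frame over the constant shared node set.

    The node set defaults to the union of the vocabulary's endpoints and is
    identical for every frame (isolated nodes kept), so WL documents built
    from these graphs are comparable across frames, replicas and systems.
    """
    nodes = list(node_set) if node_set is not None else series.vocabulary.node_set()
    labels = tuple(str(r) for r in nodes)
    node_index = {r: i for i, r in enumerate(nodes)}
    edge_cols = []
    for e in series.vocabulary.edges:
        edge_cols.append((node_index[e[0]], node_index[e[1]]))
    edge_cols_arr = np.array(edge_cols, dtype=np.int64).reshape(-1, 2)

    graphs: list[FrameGraph] = []
    for f in range(series.n_frames):
        active = np.flatnonzero(series.matrix[f])
        pairs = tuple(map(tuple, edge_cols_arr[active]))
        graphs.append(FrameGraph(nodes=labels, edges=pairs))
    return graphs
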