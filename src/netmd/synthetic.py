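"""Synthetic multi-replica contact ensembles with known ground truth.

The generator emulates the structure of multi-system, multi-replica MD
contact data: a shared latent state sequence on a canonical time axis
(conformational regimes separated by change points), per-replica monotone
time warps (asynchronous sampling), per-edge Bernoulli occupancy profiles
with i.i.d. bit-flip noise (thermal fluctuation), system-specific contact
differences (mutation effects) and one optional outlier replica.  Every
hidden quantity is returned alongside the tables, so each pipeline stage
can be validated against ground truth without any external download.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .contacts import ContactEventTable, EdgeVocabulary, ResidueId

__all__ = ["GeneratorSpec", "GroundTruth", "generate_ensemble", "default_benchmark_spec"]

_AA = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]


@dataclass
class GeneratorSpec:
    """Full description of a synthetic contact ensemble.

    ``canonical_boundaries`` split the canonical axis of ``n_frames`` into
    latent states; each variant system owns a disjoint set of
    ``condition_edges`` whose occupancy flips from ``p_on`` to ``p_off``
    in states >= ``condition_onset_state``.  ``outlier`` plants one replica
    whose profile is inverted on ``outlier_edge_fraction`` of all edges.
    """

    n_systems: int = 3
    replicas_per_system: int = 5
    n_frames: int = 500
    length_jitter: int = 20
    n_residues: int = 60
    vocabulary_size: int = 450
    n_states: int = 3
    canonical_boundaries: tuple[int, ...] = (165, 335)
    frac_invariant_edges: float = 0.40
    frac_dynamic_edges: float = 0.25
    frac_intermediate_edges: float = 0.05
    p_on: float = 0.95
    p_off: float = 0.05
    condition_edges: int = 25
    condition_onset_state: int = 1
    warp_knots: int = 8
    warp_roughness: float = 0.3
    flip_noise: float = 0.005
    outlier: tuple[int, int] | None = (0, 4)  # (system index, replica index)
    outlier_edge_fraction: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.flip_noise <= 1 or not 0 <= self.p_off <= 1 or not 0 <= self.p_on <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if len(self.canonical_boundaries) != self.n_states - 1:
            raise ValueError("need n_states - 1 canonical boundaries")
        if list(self.canonical_boundaries) != sorted(set(self.canonical_boundaries)):
            raise ValueError("boundaries must be strictly increasing")
        if self.canonical_boundaries and not (
            0 < self.canonical_boundaries[0] and self.canonical_boundaries[-1] < self.n_frames
        ):
            raise ValueError("boundaries must lie inside the canonical axis")
        fracs = (
            self.frac_invariant_edges + self.frac_dynamic_edges + self.frac_intermediate_edges
        )
        if not 0 <= fracs <= 1:
            raise ValueError("edge-class fractions must sum to at most 1")
        n_pairs = self.n_residues * (self.n_residues - 1) // 2
        if self.vocabulary_size > n_pairs:
            raise ValueError("vocabulary_size exceeds available residue pairs")
        if self.condition_edges * max(self.n_systems - 1, 0) > self.vocabulary_size:
            raise ValueError("vocabulary smaller than the requested condition effects")
        if self.outlier is not None:
            s, r = self.outlier
            if not (0 <= s < self.n_systems and 0 <= r < self.replicas_per_system):
                raise ValueError("outlier (system, replica) out of range")


@dataclass
class GroundTruth:
    """Hidden state of a generated ensemble.

    ``warps[replica]`` maps each replica frame to its canonical index;
    ``replica_boundaries`` are the canonical change points pulled into each
    replica's frame axis.
    """

    warps: dict[str, np.ndarray]
    canonical_boundaries: tuple[int, ...]
    replica_boundaries: dict[str, list[int]]
    condition_edge_sets: dict[str, list[tuple[str, str]]]
    outlier_replica: str | None
    system_of: dict[str, str]

    def to_json(self) -> str:
        payload = {
            "warps": {k: v.tolist() for k, v in self.warps.items()},
            "canonical_boundaries": list(self.canonical_boundaries),
            "replica_boundaries": self.replica_boundaries,
            "condition_edge_sets": self.condition_edge_sets,
            "outlier_replica": self.outlier_replica,
            "system_of": self.system_of,
        }
        return json.dumps(payload, indent=1)


def _monotone_warp(rng: np.random.Generator, length: int, canonical: int, knots: int, roughness: float) -> np.ndarray:
    """Piecewise-linear monotone map from replica frames onto the canonical axis."""
    x = np.linspace(0, length - 1, knots)
    y = np.linspace(0, canonical - 1, knots)
    jitter = rng.normal(0.0, roughness * canonical / knots, size=knots)
    jitter[0] = jitter[-1] = 0.0
    y = np.maximum.accumulate(np.clip(y + jitter, 0, canonical - 1))
    y[-1] = canonical - 1
    warp = np.interp(np.arange(length), x, y)
    return np.round(warp).astype(np.int64)


def generate_ensemble(spec: GeneratorSpec) -> tuple[list[ContactEventTable], GroundTruth]:
    """Sample contact tables for every replica of every system.

    Per replica: draw a monotone warp of the canonical axis, read the
    latent state at each warped time, emit each edge from its state's
    Bernoulli occupancy, then flip every bit independently with
    ``flip_noise``.  Deterministic for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    residues = [
        ResidueId(chain="A", residue_name=_AA[i % len(_AA)], residue_number=i + 1)
        for i in range(spec.n_residues)
    ]
    all_pairs = list(itertools.combinations(range(spec.n_residues), 2))
    chosen = rng.choice(len(all_pairs), size=spec.vocabulary_size, replace=False)
    chosen.sort()
    edge_pairs = [(residues[all_pairs[c][0]], residues[all_pairs[c][1]]) for c in chosen]
    n_edges = spec.vocabulary_size

    # Edge classes mirror empirical contact-occupancy distributions, which
    # are strongly bimodal: most contacts are (nearly) always formed or
    # never formed, a minority rearranges between conformational states.
    #   invariant      p in {0, 1} in every state (pruned by the filter)
    #   dynamic        p in {p_on, p_off}, switching across latent states
    #   intermediate   constant p ~ U(0.25, 0.75) (noisy, uninformative)
    #   static-extreme constant p in {p_on, p_off} (formed/unformed, stable)
    classes = rng.choice(
        4,
        size=n_edges,
        p=[
            spec.frac_invariant_edges,
            spec.frac_dynamic_edges,
            spec.frac_intermediate_edges,
            1.0 - spec.frac_invariant_edges - spec.frac_dynamic_edges - spec.frac_intermediate_edges,
        ],
    )
    profiles = np.empty((spec.n_states, n_edges))
    for e in range(n_edges):
        if classes[e] == 0:
            profiles[:, e] = float(rng.random() < 0.5)
        elif classes[e] == 1:
            choices = rng.random(spec.n_states) < 0.5
            if choices.all() or not choices.any():
                choices[rng.integers(spec.n_states)] = not choices[0]
            profiles[:, e] = np.where(choices, spec.p_on, spec.p_off)
        elif classes[e] == 2:
            profiles[:, e] = rng.uniform(0.25, 0.75)
        else:
            profiles[:, e] = spec.p_on if rng.random() < 0.5 else spec.p_off

    # disjoint condition-edge sets for the variant systems (systems 1..S-1)
    pool = rng.permutation(n_edges)
    condition_sets: dict[int, np.ndarray] = {}
    cursor = 0
    for s in range(1, spec.n_systems):
        condition_sets[s] = np.sort(pool[cursor : cursor + spec.condition_edges])
        cursor += spec.condition_edges
    # condition edges are persistently present in the reference profile
    for edges in condition_sets.values():
        profiles[:, edges] = spec.p_on

    boundaries = np.array(spec.canonical_boundaries, dtype=int)

    tables: list[ContactEventTable] = []
    warps: dict[str, np.ndarray] = {}
    replica_boundaries: dict[str, list[int]] = {}
    system_of: dict[str, str] = {}
    outlier_replica: str | None = None

    for s in range(spec.n_systems):
        system_id = f"S{s}"
        sys_profiles = profiles.copy()
        if s in condition_sets:
            for state in range(spec.condition_onset_state, spec.n_states):
                sys_profiles[state, condition_sets[s]] = spec.p_off
        for r in range(spec.replicas_per_system):
            replica_id = f"S{s}-r{r}"
            system_of[replica_id] = system_id
            rep_profiles = sys_profiles
            if spec.outlier == (s, r):
                outlier_replica = replica_id
                n_flip = int(round(spec.outlier_edge_fraction * n_edges))
                flip_idx = rng.choice(n_edges, size=n_flip, replace=False)
                rep_profiles = sys_profiles.copy()
                rep_profiles[:, flip_idx] = 1.0 - rep_profiles[:, flip_idx]

            length = spec.n_frames - int(rng.integers(0, spec.length_jitter + 1))
            warp = _monotone_warp(
                rng, length, spec.n_frames, spec.warp_knots, spec.warp_roughness
            )
            warps[replica_id] = warp
            states = np.searchsorted(boundaries, warp, side="right")
            replica_boundaries[replica_id] = [
                int(np.searchsorted(warp, b, side="left")) for b in boundaries
            ]

            p = rep_profiles[states]  # (length, n_edges)
            active = rng.random((length, n_edges)) < p
            noise = rng.random((length, n_edges)) < spec.flip_noise
            active ^= noise

            fr, ed = np.nonzero(active)
            events = pd.DataFrame(
                {
                    "frame": fr.astype(int),
                    "interaction_type": np.full(len(fr), "syn", dtype=object),
                    "residue_a": [edge_pairs[e][0] for e in ed],
                    "residue_b": [edge_pairs[e][1] for e in ed],
                }
            )
            tables.append(
                ContactEventTable(
                    replica_id=replica_id,
                    events=events,
                    n_frames=length,
                    system_id=system_id,
                )
            )

    condition_edge_sets = {
        f"S{s}": [(str(edge_pairs[e][0]), str(edge_pairs[e][1])) for e in edges]
        for s, edges in condition_sets.items()
    }
    truth = GroundTruth(
        warps=warps,
        canonical_boundaries=spec.canonical_boundaries,
        replica_boundaries=replica_boundaries,
        condition_edge_sets=condition_edge_sets,
        outlier_replica=outlier_replica,
        system_of=system_of,
    )
    return tables, truth


def toy_bead_trajectory(
    n_frames: int = 5, n_beads: int = 12, drift: float = 0.5, seed: int = 0
) -> tuple[np.ndarray, list[ResidueId]]:
    """Small coarse-grained bead layout for exercising geometric builders.

    Beads sit on a jittered line with 4 Angstrom spacing and drift slowly
    over frames; returns coordinates (n_frames, n_beads, 3) and residue
    identities, matching the coarse-grained contact builder's inputs.
    """
    rng = np.random.default_rng(seed)
    residues = [
        ResidueId(chain="A", residue_name=_AA[i % len(_AA)], residue_number=i + 1)
        for i in range(n_beads)
    ]
    base = np.zeros((n_beads, 3))
    base[:, 0] = 4.0 * np.arange(n_beads)
    base += rng.normal(0, 0.5, size=base.shape)
    coords = np.array(
        [base + drift * f * rng.normal(0, 0.2, size=base.shape) for f in range(n_frames)]
    )
    return coords, residues


def default_benchmark_spec(seed: int = 42) -> GeneratorSpec:
    """The documented benchmark: 3 systems x 5 replicas x ~500 frames.

    450-edge vocabulary over 60 residues, three latent states, 25-edge
    condition effects per variant system expressed from the second state
    onward, and one planted outlier replica in the reference system.
    """
    return GeneratorSpec(seed=seed)
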