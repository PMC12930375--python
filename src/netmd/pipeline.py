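"""End-to-end orchestration: parse -> filter -> embed -> align -> compare.

The pipeline wires the library stages together behind one config object,
writes every artifact into a run directory, and records a manifest
(config, seed, package versions, per-stage output files).  Runs are
deterministic for a fixed config and seed; the expensive embedding stage
is cached on disk keyed by a hash of the inputs and the relevant config,
so reruns and downstream-only parameter changes resume cheaply.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import BarycenterResult, PruningReport, dtw, prune_outliers
from .comparison import (
    ClusterSolution,
    linkage_to_newick,
    pairwise_dtw_matrix,
    select_k,
    ward_linkage,
)
from .contacts import (
    ContactEventTable,
    EdgeVocabulary,
    OccupancySeries,
    build_vocabulary,
    parse_contact_table,
    to_frame_graphs,
    to_occupancy,
)
from .divergence import (
    contact_shift_table,
    default_penalty,
    deviation_profile,
    pair_deviation_profile,
    pelt_segment,
    smooth,
)
from .embedding import EmbeddingConfig, EmbeddingSeries, embed_frame_graphs
from .entropy import EntropyFilterSpec, edge_entropy, write_entropy_report

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]

STAGES = (
    "parse",
    "vocabulary",
    "entropy_filter",
    "embed",
    "align",
    "compare",
    "changepoints",
    "contact_shifts",
)


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Every knob of the end-to-end run, with documented defaults.

    ``inputs`` maps system id -> list of contact TSV paths (one per
    replica).  Entropy filtering is applied per system by default, and the
    union of the per-system retained vocabularies defines the common edge
    space for the joint embedding.
    """

    inputs: dict[str, list[str]] = field(default_factory=dict)
    out_dir: str = "netmd_run"
    seed: int = 0
    # entropy filter
    entropy_lower: float = 0.1
    entropy_upper: float | None = None
    entropy_mode: str = "per-system"  # or "pooled"
    # embedding
    wl_iterations: int = 3
    dimensions: int = 16
    epochs: int = 100
    learning_rate: float = 0.025
    min_token_count: int = 1
    # alignment
    normalization: str = "path"
    dba_max_iter: int = 30
    dba_tol: float = 1e-5
    pruning_rule: str = "gap"
    pruning_count: int = 1
    pruning_threshold: float = 1.0
    # clustering
    k_criterion: str = "largest-gap"
    cluster_on: str = "kept"  # final dendrogram on pruned replicas; or "all"
    # change points
    cp_penalty: float | None = None
    cp_window: int = 25
    # "consensus-pair": align the two systems' barycenters (least noisy);
    # "pair": align the best replica of each system; "consensus": each
    # replica against its own system consensus
    cp_mode: str = "consensus-pair"
    top_shift_edges: int = 50

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def embedding_config(self) -> EmbeddingConfig:
        return EmbeddingConfig(
            wl_iterations=self.wl_iterations,
            dimensions=self.dimensions,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            min_token_count=self.min_token_count,
            seed=self.seed,
        )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return PipelineConfig.from_dict(data)


@dataclass
class PipelineResult:
    """In-memory view of a completed run."""

    config: PipelineConfig
    occupancies: dict[str, list[OccupancySeries]]
    vocabulary: EdgeVocabulary
    embeddings: dict[str, list[EmbeddingSeries]]
    consensus: dict[str, BarycenterResult]
    pruning: dict[str, PruningReport]
    cluster_solution: ClusterSolution
    changepoints: dict[str, list[int]]
    manifest: dict


class _Manifest:
    def __init__(self, out_dir: Path, config: PipelineConfig):
        self.out_dir = out_dir
        self.data = {
            "netmd_version": __version__,
            "numpy_version": np.__version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "stages": [],
            "files": [],
        }

    def stage(self, name: str, files: Sequence[str]) -> None:
        self.data["stages"].append({"name": name, "files": list(files)})
        self.data["files"].extend(files)

    def write(self) -> None:
        with open(self.out_dir / "manifest.json", "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)


def _embed_cache_key(config: PipelineConfig, occ: dict[str, list[OccupancySeries]]) -> str:
    h = hashlib.sha256()
    payload = {
        k: v
        for k, v in config.to_dict().items()
        if k
        in (
            "entropy_lower",
            "entropy_upper",
            "entropy_mode",
            "wl_iterations",
            "dimensions",
            "epochs",
            "learning_rate",
            "min_token_count",
            "seed",
        )
    }
    h.update(json.dumps(payload, sort_keys=True).encode())
    for system_id in sorted(occ):
        for s in occ[system_id]:
            h.update(s.replica_id.encode())
            h.update(s.matrix.tobytes())
    return h.hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    tables: Sequence[ContactEventTable] | None = None,
) -> PipelineResult:
    """Execute all stages and write artifacts plus a manifest.

    ``tables`` may be supplied directly (e.g. from the synthetic
    generator); otherwise ``config.inputs`` is read from disk.  Any stage
    failure aborts with the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out_dir, config)

    # ---- parse -----------------------------------------------------------
    try:
        if tables is None:
            tables = []
            for system_id, paths in config.inputs.items():
                for path in paths:
                    with open(path) as fh:
                        t = parse_contact_table(fh, replica_id=Path(path).stem)
                    t.system_id = system_id
                    tables.append(t)
        if not tables:
            raise ValueError("no input tables")
        systems = sorted({t.system_id for t in tables})
        if sum(1 for _ in tables) < 2:
            raise ValueError("need at least two replicas in total")
        manifest.stage("parse", [])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("parse", str(exc)) from exc

    # ---- vocabulary ------------------------------------------------------
    try:
        vocab = build_vocabulary(list(tables))
        occ_all = {
            sys_id: [to_occupancy(t, vocab) for t in tables if t.system_id == sys_id]
            for sys_id in systems
        }
        manifest.stage("vocabulary", [])
    except Exception as exc:
        raise PipelineError("vocabulary", str(exc)) from exc

    # ---- entropy filter --------------------------------------------------
    try:
        spec = EntropyFilterSpec(config.entropy_lower, config.entropy_upper)
        files = []
        if config.entropy_mode == "pooled":
            groups = {"all": [s for sys_id in systems for s in occ_all[sys_id]]}
        else:
            groups = occ_all
        keep_union = np.zeros(len(vocab), dtype=bool)
        for gid, series in groups.items():
            table = edge_entropy(series)
            fname = f"entropy_{gid}.tsv"
            with open(out_dir / fname, "w") as fh:
                write_entropy_report(table, spec, fh)
            files.append(fname)
            keep = table.entropy >= spec.lower_cutoff
            if spec.upper_cutoff is not None:
                keep &= table.entropy <= spec.upper_cutoff
            keep_union |= keep
        if not keep_union.any():
            raise ValueError("no edges retained by the entropy filter")
        retained = vocab.subset(keep_union)
        occ = {
            sys_id: [
                OccupancySeries(
                    replica_id=s.replica_id,
                    vocabulary=retained,
                    matrix=s.matrix[:, keep_union],
                    system_id=s.system_id,
                )
                for s in occ_all[sys_id]
            ]
            for sys_id in systems
        }
        manifest.stage("entropy_filter", files)
    except Exception as exc:
        raise PipelineError("entropy_filter", str(exc)) from exc

    # ---- embed (joint across all systems and replicas) -------------------
    try:
        cache_dir = out_dir / "cache"
        cache_dir.mkdir(exist_ok=True)
        key = _embed_cache_key(config, occ)
        cache_file = cache_dir / f"embeddings-{key}.tsv"
        ids = [(s.system_id, s.replica_id) for sys_id in systems for s in occ[sys_id]]
        if cache_file.exists():
            emb_df = pd.read_csv(cache_file, sep="\t", float_precision="round_trip")
            embeddings = {}
            for system_id, replica_id in ids:
                sub = emb_df[emb_df["replica_id"] == replica_id]
                mat = sub[[c for c in emb_df.columns if c.startswith("e")]].to_numpy()
                embeddings.setdefault(system_id, []).append(
                    EmbeddingSeries(replica_id=replica_id, system_id=system_id, matrix=mat)
                )
        else:
            node_set = retained.node_set()
            graphs = [
                to_frame_graphs(s, node_set=node_set)
                for sys_id in systems
                for s in occ[sys_id]
            ]
            flat = embed_frame_graphs(graphs, ids, config.embedding_config())
            embeddings = {}
            rows = []
            for es in flat:
                embeddings.setdefault(es.system_id, []).append(es)
                for f in range(es.n_frames):
                    rows.append(
                        [es.system_id, es.replica_id, f]
                        + [repr(float(v)) for v in es.matrix[f]]
                    )
            emb_df = pd.DataFrame(
                rows,
                columns=["system_id", "replica_id", "frame"]
                + [f"e{k}" for k in range(config.dimensions)],
            )
            emb_df.to_csv(cache_file, sep="\t", index=False)
        emb_df.to_csv(out_dir / "embeddings.tsv", sep="\t", index=False)
        manifest.stage("embed", ["embeddings.tsv", f"cache/embeddings-{key}.tsv"])
    except Exception as exc:
        raise PipelineError("embed", str(exc)) from exc

    # ---- align: per-system DBA + pruning ---------------------------------
    try:
        consensus: dict[str, BarycenterResult] = {}
        pruning: dict[str, PruningReport] = {}
        files = []
        score_rows = []
        for sys_id in systems:
            series = embeddings[sys_id]
            report, bary = prune_outliers(
                [s.matrix for s in series],
                replica_ids=[s.replica_id for s in series],
                rule=config.pruning_rule,
                count=config.pruning_count,
                threshold=config.pruning_threshold,
                max_iter=config.dba_max_iter,
                tol=config.dba_tol,
                normalization=config.normalization,
            )
            consensus[sys_id] = bary
            pruning[sys_id] = report
            fname = f"barycenter_{sys_id}.tsv"
            pd.DataFrame(bary.barycenter).to_csv(out_dir / fname, sep="\t", index=False)
            files.append(fname)
            for rid, cost in zip(bary.replica_ids, bary.normalized_costs):
                score_rows.append([sys_id, rid, "kept", repr(float(cost))])
            for rid, cost in report.removed:
                score_rows.append([sys_id, rid, "pruned", repr(float(cost))])
        pd.DataFrame(
            score_rows, columns=["system_id", "replica_id", "status", "normalized_dtw"]
        ).to_csv(out_dir / "replica_scores.tsv", sep="\t", index=False)
        files.append("replica_scores.tsv")
        manifest.stage("align", files)
    except Exception as exc:
        raise PipelineError("align", str(exc)) from exc

    # ---- compare: pairwise matrix, Ward, k selection ---------------------
    try:
        flat_series = [s for sys_id in systems for s in embeddings[sys_id]]
        dist = pairwise_dtw_matrix(
            [s.matrix for s in flat_series],
            labels=[s.replica_id for s in flat_series],
            systems=[s.system_id for s in flat_series],
            normalization=config.normalization,
        )
        pd.DataFrame(dist.matrix, index=dist.labels, columns=dist.labels).to_csv(
            out_dir / "distance_matrix.tsv", sep="\t"
        )
        if config.cluster_on == "kept":
            kept_ids = {rid for sys_id in systems for rid in pruning[sys_id].kept}
            keep_mask = np.array([lab in kept_ids for lab in dist.labels])
            from .comparison import DistanceMatrix

            dist_clust = DistanceMatrix(
                labels=[lab for lab, k in zip(dist.labels, keep_mask) if k],
                matrix=dist.matrix[np.ix_(keep_mask, keep_mask)],
            )
        else:
            dist_clust = dist
        tree = ward_linkage(dist_clust)
        with open(out_dir / "dendrogram.nwk", "w") as fh:
            fh.write(linkage_to_newick(tree) + "\n")
        solution = select_k(tree, method=config.k_criterion)
        pd.DataFrame(
            sorted(solution.assignment.items()), columns=["replica_id", "cluster"]
        ).to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
        manifest.stage(
            "compare", ["distance_matrix.tsv", "dendrogram.nwk", "clusters.tsv"]
        )
    except Exception as exc:
        raise PipelineError("compare", str(exc)) from exc

    # ---- change points ---------------------------------------------------
    try:
        changepoints: dict[str, list[int]] = {}
        rows = []
        best_of: dict[str, EmbeddingSeries] = {}
        for sys_id in systems:
            bary = consensus[sys_id]
            costs = bary.normalized_costs
            best_id = bary.replica_ids[int(np.argmin(costs))]
            best_of[sys_id] = next(
                s for s in embeddings[sys_id] if s.replica_id == best_id
            )
        if config.cp_mode in ("consensus-pair", "pair") and len(systems) > 1:
            ref = systems[0]
            for sys_id in systems[1:]:
                if config.cp_mode == "consensus-pair":
                    prof = pair_deviation_profile(
                        consensus[ref].barycenter,
                        consensus[sys_id].barycenter,
                        ids=(f"{ref}-consensus", f"{sys_id}-consensus"),
                    )
                else:
                    prof = pair_deviation_profile(best_of[ref], best_of[sys_id])
                sm = smooth(prof, config.cp_window)
                # penalty from the unsmoothed profile: smoothing shrinks the
                # first differences and would otherwise understate the noise
                beta = config.cp_penalty if config.cp_penalty is not None else default_penalty(prof.values)
                cps = pelt_segment(sm.values, beta)
                label = f"{ref}|{sys_id}"
                changepoints[label] = cps.indices
                for idx, (a, b) in enumerate(
                    zip([0] + cps.indices, cps.indices + [len(sm.values)])
                ):
                    rows.append([label, a, b, repr(cps.segment_means[idx]), repr(cps.penalty)])
        else:
            for sys_id in systems:
                for s in embeddings[sys_id]:
                    prof = deviation_profile(s, consensus[sys_id])
                    sm = smooth(prof, config.cp_window)
                    beta = config.cp_penalty if config.cp_penalty is not None else default_penalty(prof.values)
                    cps = pelt_segment(sm.values, beta)
                    changepoints[s.replica_id] = cps.indices
                    for idx, (a, b) in enumerate(
                        zip([0] + cps.indices, cps.indices + [len(sm.values)])
                    ):
                        rows.append(
                            [s.replica_id, a, b, repr(cps.segment_means[idx]), repr(cps.penalty)]
                        )
        pd.DataFrame(
            rows, columns=["profile", "segment_start", "segment_end", "segment_mean", "penalty"]
        ).to_csv(out_dir / "changepoints.tsv", sep="\t", index=False)
        manifest.stage("changepoints", ["changepoints.tsv"])
    except Exception as exc:
        raise PipelineError("changepoints", str(exc)) from exc

    # ---- contact shift tables (reference vs each other system) -----------
    try:
        files = []
        if len(systems) > 1:
            ref = systems[0]
            occ_by_id = {s.replica_id: s for sys_id in systems for s in occ[sys_id]}
            b_ref = consensus[ref]
            axis_len = b_ref.barycenter.shape[0]
            for sys_id in systems[1:]:
                b_other = consensus[sys_id]
                # window axis = reference barycenter; pull the window back to
                # raw frames of every kept replica on both sides
                res = dtw(b_ref.barycenter, b_other.barycenter)
                pair_map: list[list[int]] = [[] for _ in range(axis_len)]
                for i, j in res.path:
                    pair_map[i].append(j)
                group_a = [occ_by_id[rid] for rid in b_ref.replica_ids]
                maps_a = b_ref.associations
                group_b = [occ_by_id[rid] for rid in b_other.replica_ids]
                maps_b = []
                for assoc in b_other.associations:
                    composed = [
                        sorted({f for j in pair_map[t] for f in assoc[j]})
                        for t in range(axis_len)
                    ]
                    maps_b.append(composed)
                label = f"{ref}|{sys_id}"
                cps = changepoints.get(label, [])
                if cps and config.cp_mode == "consensus-pair":
                    start = cps[0]
                    end = cps[1] if len(cps) > 1 else axis_len
                else:
                    start, end = 0, axis_len
                table = contact_shift_table(
                    group_a, group_b, (start, end), maps_a, maps_b
                )
                fname = f"contact_shifts_{ref}_vs_{sys_id}.tsv"
                table.head(config.top_shift_edges).to_csv(
                    out_dir / fname, sep="\t", index=False
                )
                files.append(fname)
        manifest.stage("contact_shifts", files)
    except Exception as exc:
        raise PipelineError("contact_shifts", str(exc)) from exc

    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    manifest.data["files"].append("config.yaml")
    manifest.data["files"].append("manifest.json")
    manifest.write()

    return PipelineResult(
        config=config,
        occupancies=occ,
        vocabulary=retained,
        embeddings=embeddings,
        consensus=consensus,
        pruning=pruning,
        cluster_solution=solution,
        changepoints=changepoints,
        manifest=manifest.data,
    )
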