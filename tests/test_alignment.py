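"""DTW against a brute-force path oracle, DBA fixed points, pruning."""

import itertools

import numpy as np
import pytest

from netmd.alignment import dba_barycenter, dtw, dtw_from_cost, prune_outliers
from netmd.synthetic import GeneratorSpec, generate_ensemble


def enumerate_paths(n, m):
    """All admissible warp paths from (0,0) to (n-1,m-1)."""

    def extend(path):
        i, j = path[-1]
        if (i, j) == (n - 1, m - 1):
            yield path
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            if i + di < n and j + dj < m:
                yield from extend(path + [(i + di, j + dj)])

    yield from extend([(0, 0)])


def brute_force_cost(a, b):
    a = np.atleast_2d(a.T).T if a.ndim == 1 else a
    best = np.inf
    for path in enumerate_paths(len(a), len(b)):
        cost = sum(np.linalg.norm(np.atleast_1d(a[i] - b[j])) for i, j in path)
        best = min(best, cost)
    return best


class TestDTW:
    def test_identical_series_cost_zero_diagonal_path(self):
        a = np.arange(12.0).reshape(4, 3)
        r = dtw(a, a)
        assert r.cost == 0
        assert r.path == [(i, i) for i in range(4)]

    def test_stated_onedimensional_example(self):
        r = dtw(np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0]))
        assert r.cost == 0
        assert r.path == [(0, 0), (1, 0), (2, 1)]

    @pytest.mark.parametrize("dim", [1, 2])
    def test_matches_brute_force_enumeration(self, dim):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n, m = rng.integers(1, 7, size=2)
            a = rng.normal(size=(n, dim))
            b = rng.normal(size=(m, dim))
            assert dtw(a, b).cost == pytest.approx(brute_force_cost(a, b), abs=1e-10)

    def test_cost_symmetry(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            a = rng.normal(size=(rng.integers(2, 9), 3))
            b = rng.normal(size=(rng.integers(2, 9), 3))
            assert dtw(a, b).cost == pytest.approx(dtw(b, a).cost, rel=1e-12)

    def test_normalized_cost_divides_by_path_length(self):
        a = np.zeros((4, 2))
        b = np.ones((3, 2))
        r = dtw(a, b)
        assert r.normalized_cost == pytest.approx(r.cost / len(r.path))
        assert r.normalized_cost <= r.cost

    def test_time_dilated_copy_costs_zero_with_stretched_path(self):
        """The shorter series is adaptively stretched over a frame-duplicated copy."""
        rng = np.random.default_rng(29)
        a = rng.normal(size=(6, 2))
        dilated = np.repeat(a, 2, axis=0)
        r = dtw(a, dilated)
        assert r.cost == pytest.approx(0, abs=1e-12)
        assert len(r.path) == len(dilated)  # every duplicated frame visited

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            dtw(np.zeros((3, 2)), np.zeros((3, 3)))


class TestDTWFromCost:
    def test_zero_matrix_costs_zero(self):
        assert dtw_from_cost(np.zeros((4, 5))).cost == 0

    def test_equivalent_to_dtw_on_local_distances(self):
        rng = np.random.default_rng(31)
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(7, 3))
        local = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
        assert dtw_from_cost(local).cost == pytest.approx(dtw(a, b).cost, rel=1e-12)

    def test_antidiagonal_matrix_prefers_diagonal(self):
        r = dtw_from_cost(np.array([[0.0, 5.0], [5.0, 0.0]]))
        assert r.cost == 0
        assert r.path == [(0, 0), (1, 1)]

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            dtw_from_cost(np.array([[0.0, -1.0]]))


class TestDBA:
    def test_single_series_is_a_fixed_point(self):
        a = np.random.default_rng(0).normal(size=(10, 2))
        r = dba_barycenter([a])
        np.testing.assert_allclose(r.barycenter, a)
        assert r.objective_trace[-1] == 0

    def test_identical_series_return_the_input(self):
        a = np.random.default_rng(1).normal(size=(8, 3))
        r = dba_barycenter([a, a.copy(), a.copy()])
        np.testing.assert_allclose(r.barycenter, a)
        assert r.objective_trace[-1] == pytest.approx(0, abs=1e-20)

    def test_two_constant_series_average_to_midpoint(self):
        a = np.zeros((5, 1))
        b = np.full((5, 1), 2.0)
        r = dba_barycenter([a, b])
        np.testing.assert_allclose(r.barycenter, np.ones((5, 1)))

    def test_objective_trace_monotone_on_random_ensembles(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            series = [rng.normal(size=(int(rng.integers(5, 15)), 4)) for _ in range(4)]
            r = dba_barycenter(series, max_iter=15)
            trace = np.array(r.objective_trace)
            assert (np.diff(trace) <= 1e-9 * np.maximum(trace[:-1], 1)).all()

    def test_every_barycenter_index_has_associations_from_each_replica(self):
        rng = np.random.default_rng(3)
        series = [rng.normal(size=(10, 2)) for _ in range(3)]
        r = dba_barycenter(series)
        for assoc in r.associations:
            assert all(len(frames) >= 1 for frames in assoc)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dba_barycenter([])


class TestPruning:
    def test_identical_replicas_prune_nothing(self):
        a = np.random.default_rng(4).normal(size=(10, 2))
        report, _ = prune_outliers([a.copy() for _ in range(4)])
        assert report.removed == []
        assert len(report.kept) == 4

    def test_fixed_count_removes_exactly_the_worst(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(12, 2))
        series = [base + 0.01 * rng.normal(size=base.shape) for _ in range(4)]
        series.append(base + 5.0)  # constant offset outlier
        ids = [f"r{i}" for i in range(5)]
        report, _ = prune_outliers(series, replica_ids=ids, rule="count", count=1)
        assert [r[0] for r in report.removed] == ["r4"]
        assert report.kept == ["r0", "r1", "r2", "r3"]

    def test_gap_rule_removes_planted_outlier_first(self, tiny_spec):
        """A replica drawn from a shifted contact regime is pruned first."""
        spec = GeneratorSpec(
            **{
                **tiny_spec.__dict__,
                "outlier": (0, 2),
                "outlier_edge_fraction": 0.3,
                "seed": 13,
            }
        )
        tables, truth = generate_ensemble(spec)
        from netmd.contacts import build_vocabulary, to_frame_graphs, to_occupancy
        from netmd.embedding import EmbeddingConfig, embed_frame_graphs

        sys0 = [t for t in tables if t.system_id == "S0"]
        vocab = build_vocabulary(sys0)
        occ = [to_occupancy(t, vocab) for t in sys0]
        emb = embed_frame_graphs(
            [to_frame_graphs(s) for s in occ],
            [(t.system_id, t.replica_id) for t in sys0],
            EmbeddingConfig(epochs=30, seed=9),
        )
        report, _ = prune_outliers(
            [e.matrix for e in emb], replica_ids=[e.replica_id for e in emb]
        )
        assert report.removed, "planted outlier was not pruned"
        assert report.removed[0][0] == truth.outlier_replica

    def test_removal_order_is_descending_cost(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(10, 2))
        series = [base + 0.01 * rng.normal(size=base.shape) for _ in range(3)]
        series += [base + 3.0, base + 6.0]
        report, _ = prune_outliers(series, rule="count", count=2)
        costs = [c for _, c in report.removed]
        assert costs == sorted(costs, reverse=True)


def test_warp_path_writer_round_trip(tmp_path):
    import io

    from netmd.alignment import write_warp_path

    r = dtw(np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0]))
    buf = io.StringIO()
    write_warp_path(r.path, buf)
    lines = buf.getvalue().strip().splitlines()
    assert lines[0] == "index_a\tindex_b"
    parsed = [tuple(map(int, l.split("\t"))) for l in lines[1:]]
    assert parsed == r.path
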