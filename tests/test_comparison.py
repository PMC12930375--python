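"""Distance matrices, Ward linkage, k selection, and the RMSD baseline."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from netmd.alignment import dtw
from netmd.comparison import (
    DistanceMatrix,
    LinkageTree,
    cut_tree,
    kabsch_rmsd,
    kmedoids_with_silhouette,
    linkage_to_newick,
    pairwise_dtw_matrix,
    rmsd_cost_matrix,
    select_k,
    ward_linkage,
)


def _dm(matrix, labels=None):
    labels = labels or [f"r{i}" for i in range(len(matrix))]
    return DistanceMatrix(labels=labels, matrix=np.asarray(matrix, dtype=float))


class TestPairwiseMatrix:
    def test_entries_match_per_pair_dtw(self):
        rng = np.random.default_rng(0)
        series = [rng.normal(size=(rng.integers(5, 10), 3)) for _ in range(4)]
        dm = pairwise_dtw_matrix(series)
        for i in range(4):
            for j in range(4):
                if i != j:
                    expected = dtw(series[i], series[j]).normalized_cost
                    assert dm.matrix[i, j] == pytest.approx(expected, rel=1e-12)
        np.testing.assert_array_equal(dm.matrix, dm.matrix.T)

    def test_duplicated_series_have_zero_distance(self):
        a = np.random.default_rng(1).normal(size=(6, 2))
        dm = pairwise_dtw_matrix([a, a.copy(), a + 1])
        assert dm.matrix[0, 1] == 0
        assert dm.matrix[0, 2] > 0


def _ward_oracle(dist):
    """Textbook Lance-Williams agglomeration for Ward's criterion.

    Operates on squared distances; returns merge heights (sorted) for
    comparison with the production linkage.
    """
    d2 = dist**2
    active = {i: 1 for i in range(len(dist))}  # cluster -> size
    d2 = {(i, j): d2[i, j] for i in range(len(dist)) for j in range(i + 1, len(dist))}
    heights = []
    next_id = len(dist)
    sizes = dict(active)
    while len(active) > 1:
        (a, b), val = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(np.sqrt(val))
        na, nb = sizes[a], sizes[b]
        merged = {}
        for (i, j), v in d2.items():
            if a in (i, j) or b in (i, j):
                continue
            merged[(i, j)] = v
        for c in list(active):
            if c in (a, b):
                continue
            nc = sizes[c]
            dac = d2[tuple(sorted((a, c)))]
            dbc = d2[tuple(sorted((b, c)))]
            dab = d2[tuple(sorted((a, b)))]
            t = na + nb + nc
            new = ((na + nc) * dac + (nb + nc) * dbc - nc * dab) / t
            merged[tuple(sorted((c, next_id)))] = new
        del active[a], active[b]
        active[next_id] = 1
        sizes[next_id] = na + nb
        d2 = merged
        next_id += 1
    return heights


class TestWardLinkage:
    def test_two_points_merge_at_their_distance(self):
        tree = ward_linkage(_dm([[0, 3.0], [3.0, 0]]))
        assert tree.linkage.shape == (1, 4)
        assert tree.heights[0] == pytest.approx(3.0)

    def test_two_tight_triplets_split_at_the_top(self):
        d = np.full((6, 6), 10.0)
        np.fill_diagonal(d, 0)
        for grp in ([0, 1, 2], [3, 4, 5]):
            for i in grp:
                for j in grp:
                    if i != j:
                        d[i, j] = 1.0
        tree = ward_linkage(_dm(d))
        sol = cut_tree(tree, 2)
        groups = {}
        for lab, c in sol.assignment.items():
            groups.setdefault(c, set()).add(lab)
        assert {frozenset(g) for g in groups.values()} == {
            frozenset({"r0", "r1", "r2"}),
            frozenset({"r3", "r4", "r5"}),
        }

    def test_heights_match_lance_williams_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pts = rng.normal(size=(8, 3))
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            tree = ward_linkage(_dm(d))
            np.testing.assert_allclose(
                np.sort(tree.heights), np.sort(_ward_oracle(d)), rtol=1e-8
            )

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            _dm([[0, 1.0], [2.0, 0]])


class TestSelectK:
    def _tree(self, heights):
        n = len(heights) + 1
        link = np.zeros((len(heights), 4))
        # chain merges: leaves joined one at a time
        link[0] = [0, 1, heights[0], 2]
        for i in range(1, len(heights)):
            link[i] = [i + 1, n + i - 1, heights[i], i + 2]
        return LinkageTree(linkage=link, labels=[f"r{i}" for i in range(n)])

    def test_largest_gap_before_final_merge_gives_two_clusters(self):
        sol = select_k(self._tree([0.1, 0.12, 0.11, 3.0]), "largest-gap")
        assert sol.k == 2

    def test_equal_heights_fall_back_to_one_cluster(self):
        with pytest.warns(UserWarning, match="degenerate"):
            sol = select_k(self._tree([1.0, 1.0, 1.0, 1.0]), "largest-gap")
        assert sol.k == 1

    def test_elbow_finds_the_curvature_maximum(self):
        sol = select_k(self._tree([0.1, 0.12, 0.11, 3.0]), "elbow")
        assert sol.k == 2

    def test_input_order_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(8)
        pts = np.vstack([rng.normal(size=(3, 2)), rng.normal(size=(3, 2)) + 20])
        labels = [f"r{i}" for i in range(6)]
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        sol1 = select_k(ward_linkage(_dm(d, labels)), "largest-gap")
        perm = rng.permutation(6)
        d2 = d[np.ix_(perm, perm)]
        sol2 = select_k(
            ward_linkage(_dm(d2, [labels[p] for p in perm])), "largest-gap"
        )
        assert sol1.k == sol2.k
        part1 = {}
        part2 = {}
        for lab in labels:
            part1.setdefault(sol1.assignment[lab], set()).add(lab)
            part2.setdefault(sol2.assignment[lab], set()).add(lab)
        assert {frozenset(s) for s in part1.values()} == {
            frozenset(s) for s in part2.values()
        }


class TestNewickExport:
    def test_round_trip_through_dendropy(self):
        import dendropy

        rng = np.random.default_rng(9)
        pts = rng.normal(size=(5, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        tree = ward_linkage(_dm(d))
        newick = linkage_to_newick(tree)
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set(tree.labels)


class TestRMSDBaseline:
    def test_frame_against_itself_is_zero(self):
        frame = np.random.default_rng(10).normal(size=(6, 3))
        assert kabsch_rmsd(frame, frame) == pytest.approx(0, abs=1e-12)

    def test_rigid_motion_is_removed(self):
        rng = np.random.default_rng(11)
        frame = rng.normal(size=(8, 3))
        rot = Rotation.from_euler("xyz", [0.3, -1.2, 0.7]).as_matrix()
        moved = frame @ rot.T + np.array([5.0, -3.0, 2.0])
        assert kabsch_rmsd(frame, moved) == pytest.approx(0, abs=1e-9)

    def test_matches_independent_superposition_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a = rng.normal(size=(7, 3))
            b = a + 0.3 * rng.normal(size=(7, 3))
            rot, rssd = Rotation.align_vectors(
                a - a.mean(axis=0), b - b.mean(axis=0)
            )
            oracle = rssd / np.sqrt(len(a))
            assert kabsch_rmsd(a, b) == pytest.approx(oracle, abs=1e-8)

    def test_cost_matrix_shape_and_atom_mismatch(self):
        rng = np.random.default_rng(13)
        ca = rng.normal(size=(3, 5, 3))
        cb = rng.normal(size=(4, 5, 3))
        m = rmsd_cost_matrix(ca, cb)
        assert m.shape == (3, 4)
        assert (m >= 0).all()
        with pytest.raises(ValueError, match="atom-count"):
            rmsd_cost_matrix(ca, rng.normal(size=(4, 6, 3)))


class TestKMedoids:
    def test_two_well_separated_groups(self):
        d = np.full((6, 6), 9.0)
        np.fill_diagonal(d, 0)
        for grp in ([0, 1, 2], [3, 4, 5]):
            for i in grp:
                for j in grp:
                    if i != j:
                        d[i, j] = 0.5
        sol = kmedoids_with_silhouette(_dm(d), k_range=range(2, 5))
        assert sol.k == 2
        clusters = {}
        for lab, c in sol.assignment.items():
            clusters.setdefault(c, set()).add(lab)
        assert {frozenset(c) for c in clusters.values()} == {
            frozenset({"r0", "r1", "r2"}),
            frozenset({"r3", "r4", "r5"}),
        }

    def test_chosen_k_matches_exhaustive_silhouette(self):
        from sklearn.metrics import silhouette_score

        from netmd.comparison import _pam

        rng = np.random.default_rng(14)
        pts = np.vstack(
            [rng.normal(size=(4, 2)), rng.normal(size=(4, 2)) + 8, rng.normal(size=(4, 2)) + 16]
        )
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        sol = kmedoids_with_silhouette(_dm(d), k_range=range(2, 7))
        scores = {}
        for k in range(2, 7):
            _, assign = _pam(d, k)
            scores[k] = silhouette_score(d, assign, metric="precomputed")
        assert sol.k == max(scores, key=lambda k: scores[k])
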