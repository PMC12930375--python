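"""Contact-table parsing, vocabularies, occupancy matrices and CG contacts."""

import io

import numpy as np
import pytest

from netmd.contacts import (
    ContactEventTable,
    ResidueId,
    build_cg_contacts,
    build_vocabulary,
    canonical_edge,
    parse_contact_table,
    to_frame_graphs,
    to_occupancy,
    write_contact_table,
)
from netmd.synthetic import GeneratorSpec, generate_ensemble

from conftest import rid


class TestResidueId:
    def test_ordering_is_on_chain_then_number(self):
        assert rid(5, "A") < rid(3, "B")
        assert rid(3, "A", "GLY") < rid(5, "A", "ALA")

    def test_canonical_edge_sorts_endpoints(self):
        a, b = canonical_edge(rid(333, name="ARG"), rid(329, name="GLU"))
        assert (a.residue_number, b.residue_number) == (329, 333)

    def test_self_contact_rejected(self):
        with pytest.raises(ValueError, match="self-contact"):
            canonical_edge(rid(5), rid(5))


class TestParse:
    def test_single_record_with_canonical_ordering(self):
        t = parse_contact_table(
            "0\thbbb\tA:ARG:333:NH1\tA:GLU:329:OE1\n", replica_id="r0"
        )
        assert len(t) == 1
        row = t.events.iloc[0]
        assert row["frame"] == 0
        assert str(row["residue_a"]) == "A:GLU:329"
        assert str(row["residue_b"]) == "A:ARG:333"

    def test_atom_level_duplicates_collapse_to_one_edge(self):
        lines = (
            "0\thbss\tA:ARG:333:NH1\tA:GLU:329:OE1\n"
            "0\tsaltbr\tA:ARG:333:NH2\tA:GLU:329:OE2\n"
        )
        t = parse_contact_table(lines, replica_id="r0")
        assert len(t) == 1

    def test_comments_and_extra_columns_ignored(self):
        lines = "# a header\n0\thb\tA:ALA:1:CA\tA:GLY:2:CA\textra\tcols\n"
        assert len(parse_contact_table(lines, "r0")) == 1

    @pytest.mark.parametrize(
        "bad, message",
        [
            ("0\thb\tA:ALA:1:CA\n", "columns"),
            ("x\thb\tA:ALA:1:CA\tA:GLY:2:CA\n", "non-integer frame"),
            ("", "no contact records"),
        ],
    )
    def test_malformed_input_raises_with_context(self, bad, message):
        with pytest.raises(ValueError, match=message):
            parse_contact_table(bad, "r0")

    def test_round_trip_write_then_parse_is_exact(self):
        spec = GeneratorSpec(
            n_systems=1, replicas_per_system=1, n_frames=25, length_jitter=0,
            n_residues=10, vocabulary_size=20, n_states=1, canonical_boundaries=(),
            condition_edges=0, outlier=None, seed=3,
        )
        (table,), _ = generate_ensemble(spec)
        buf = io.StringIO()
        write_contact_table(table, buf)
        buf.seek(0)
        again = parse_contact_table(buf, replica_id=table.replica_id)
        assert again.n_frames == table.n_frames
        left = table.events[["frame", "residue_a", "residue_b"]].to_numpy().tolist()
        right = again.events[["frame", "residue_a", "residue_b"]].to_numpy().tolist()
        assert left == right


class TestVocabulary:
    def test_union_is_sorted_and_deduplicated(self, tiny_ensemble):
        tables, _ = tiny_ensemble
        vocab = build_vocabulary(tables)
        keys = [(a.sort_key, b.sort_key) for a, b in vocab.edges]
        assert keys == sorted(keys)
        assert len(set(vocab.edges)) == len(vocab)

    def test_row_order_invariance(self, tiny_ensemble):
        tables, _ = tiny_ensemble
        shuffled = []
        for t in tables:
            ev = t.events.sample(frac=1.0, random_state=1).reset_index(drop=True)
            shuffled.append(
                ContactEventTable(
                    replica_id=t.replica_id, events=ev, n_frames=t.n_frames
                )
            )
        assert build_vocabulary(shuffled) == build_vocabulary(tables)

    def test_vocabulary_of_pair_sets_is_their_union(self):
        t1 = parse_contact_table("0\thb\tA:ALA:1:CA\tA:GLY:2:CA\n", "a")
        t2 = parse_contact_table("0\thb\tA:GLY:2:CA\tA:SER:3:CA\n", "b")
        vocab = build_vocabulary([t1, t2])
        assert len(vocab) == 2
        assert [str(e[0]) for e in vocab.edges] == ["A:ALA:1", "A:GLY:2"]


class TestOccupancy:
    def test_single_contact_layout(self):
        t = parse_contact_table("0\thb\tA:ALA:1:CA\tA:GLY:2:CA\n", "r", n_frames=2)
        occ = to_occupancy(t, build_vocabulary([t]))
        assert occ.matrix.tolist() == [[1], [0]]

    def test_column_sums_match_row_counts(self, tiny_ensemble, tiny_occupancies):
        tables, _ = tiny_ensemble
        occs, vocab = tiny_occupancies
        for table, occ in zip(tables, occs):
            counts = np.zeros(len(vocab), dtype=int)
            for a, b in zip(table.events["residue_a"], table.events["residue_b"]):
                counts[vocab.index_of((a, b))] += 1
            assert (occ.matrix.sum(axis=0) == counts).all()

    def test_unknown_edge_is_an_error(self):
        t1 = parse_contact_table("0\thb\tA:ALA:1:CA\tA:GLY:2:CA\n", "a")
        t2 = parse_contact_table("0\thb\tA:GLY:2:CA\tA:SER:3:CA\n", "b")
        with pytest.raises(KeyError, match="vocabulary"):
            to_occupancy(t2, build_vocabulary([t1]))


class TestCoarseGrained:
    def setup_method(self):
        self.residues = [rid(i + 1) for i in range(4)]

    def test_edge_distance_rule_is_strict(self):
        # beads at 0, 5, 12 on the x axis; site at origin
        coords = np.zeros((1, 3, 3))
        coords[0, 1, 0] = 5.0
        coords[0, 2, 0] = 12.0
        t = build_cg_contacts(coords, self.residues[:3], [self.residues[0]])
        pairs = {(a.residue_number, b.residue_number) for a, b in t.edge_set()}
        assert (1, 2) in pairs  # 5 A < 6 A
        assert (2, 3) not in pairs  # 7 A >= 6 A

    def test_node_radius_excludes_distant_beads(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 16.0
        t = build_cg_contacts(coords, self.residues[:2], [self.residues[0]])
        nodes = {r.residue_number for e in t.edge_set() for r in e}
        assert 2 not in nodes and len(t) == 0

    def test_bead_order_permutation_gives_same_edges(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 10, size=(3, 4, 3))
        t1 = build_cg_contacts(coords, self.residues, [self.residues[0]])
        perm = [2, 0, 3, 1]
        t2 = build_cg_contacts(
            coords[:, perm], [self.residues[i] for i in perm], [self.residues[0]]
        )
        by_frame1 = set(map(tuple, t1.events[["frame", "residue_a", "residue_b"]].to_numpy()))
        by_frame2 = set(map(tuple, t2.events[["frame", "residue_a", "residue_b"]].to_numpy()))
        assert by_frame1 == by_frame2

    def test_unknown_mutation_site_raises(self):
        coords = np.zeros((1, 2, 3))
        with pytest.raises(KeyError, match="mutation site"):
            build_cg_contacts(coords, self.residues[:2], [rid(99)])


class TestFrameGraphs:
    def test_constant_node_set_and_edge_counts(self, tiny_occupancies):
        occs, vocab = tiny_occupancies
        series = occs[0]
        graphs = to_frame_graphs(series)
        assert len(graphs) == series.n_frames
        node_sets = {g.nodes for g in graphs}
        assert len(node_sets) == 1  # constant across frames
        total_edges = sum(len(g.edges) for g in graphs)
        assert total_edges == int(series.matrix.sum())

    def test_empty_frame_keeps_full_node_set(self):
        t = parse_contact_table("0\thb\tA:ALA:1:CA\tA:GLY:2:CA\n", "r", n_frames=2)
        occ = to_occupancy(t, build_vocabulary([t]))
        graphs = to_frame_graphs(occ)
        assert len(graphs[0].edges) == 1 and len(graphs[1].edges) == 0
        assert graphs[1].nodes == graphs[0].nodes


class TestBeadTable:
    def test_round_trip_layout(self):
        from netmd.contacts import read_bead_table
        from netmd.synthetic import toy_bead_trajectory

        coords, residues = toy_bead_trajectory(n_frames=3, n_beads=5, seed=1)
        lines = ["# frame chain resname resid x y z"]
        for f in range(3):
            for b, r in enumerate(residues):
                x, y, z = (float(v) for v in coords[f, b])
                lines.append(
                    f"{f} {r.chain} {r.residue_name} {r.residue_number} {x!r} {y!r} {z!r}"
                )
        got_coords, got_res = read_bead_table("\n".join(lines) + "\n")
        np.testing.assert_allclose(got_coords, coords)
        assert got_res == residues

    def test_cg_contacts_from_toy_layout(self):
        from netmd.synthetic import toy_bead_trajectory

        coords, residues = toy_bead_trajectory(n_frames=2, n_beads=6, seed=2)
        t = build_cg_contacts(coords, residues, [residues[2]])
        assert t.n_frames == 2
        # 4 A spacing: neighbors on the line are within the 6 A edge cutoff
        assert len(t) > 0

    def test_inconsistent_frames_rejected(self):
        from netmd.contacts import read_bead_table

        text = "0 A ALA 1 0 0 0\n1 A GLY 2 0 0 0\n"
        with pytest.raises(ValueError, match="differs"):
            read_bead_table(text)
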