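"""Interface graph construction: parsing, typing, contacts, pruning, components."""

import numpy as np
import pytest

import ifacemine as im
from ifacemine.interface import ContactCriteria, InteractionEdge
from conftest import make_atom

TABLE = im.load_typing_table()
CRITERIA = ContactCriteria()


def _fixture_pdb():
    pdb, _ = im.generate_complex_fixture(im.FixtureSpec(seed=0))
    return pdb


class TestParseStructure:
    def test_atoms_tagged_with_sides(self):
        atoms = im.parse_structure(_fixture_pdb(), ({"A"}, {"B"}), complex_id="fx")
        sides = {a.chain_id: a.side for a in atoms}
        assert sides == {"A": "P", "B": "I"}
        assert all(a.complex_id == "fx" for a in atoms)
        # 3 planted + 4 decoys per chain
        assert sum(a.side == "P" for a in atoms) == 7
        assert sum(a.side == "I" for a in atoms) == 7

    def test_waters_and_hydrogens_excluded(self):
        pdb = _fixture_pdb() + (
            "ATOM    900  O   HOH A 500      99.000  99.000  99.000  1.00  0.00           O\n"
            "ATOM    901  H   GLY A 100       1.000   1.000   1.000  1.00  0.00           H\n"
        )
        atoms = im.parse_structure(pdb, ({"A"}, {"B"}))
        assert not any(a.residue_name == "HOH" for a in atoms)
        assert not any(a.element == "H" for a in atoms)

    def test_overlapping_chain_groups_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            im.parse_structure(_fixture_pdb(), ({"A"}, {"A"}))

    def test_missing_chain_lists_available(self):
        with pytest.raises(ValueError, match="available chains"):
            im.parse_structure(_fixture_pdb(), ({"A"}, {"Z"}))

    def test_malformed_input_raises_parse_error(self):
        from ifacemine.interface import PDBParseError
        bad = "ATOM      1  CA  GLY A   1      xxx.000   0.000   0.000  1.00  0.00           C\n"
        with pytest.raises((PDBParseError, ValueError)):
            atoms = im.parse_structure(bad, ({"A"}, {"B"}))
            if not atoms:  # a silently-empty parse still surfaces as an error
                raise PDBParseError("no atoms parsed")


class TestAtomLabels:
    @pytest.mark.parametrize("residue,atom,expected", [
        ("HIS", "ND1", {"AR", "PS", "DN", "AC"}),
        ("HIS", "NE2", {"AR", "PS", "DN", "AC"}),
        ("ASP", "OD1", {"AC", "NG"}),
        ("ARG", "CZ", {"PS"}),
        ("ARG", "NH1", {"DN", "PS"}),
        ("LYS", "NZ", {"DN", "PS"}),
        ("SER", "OG", {"AC", "DN"}),
        ("GLY", "N", {"DN"}),       # backbone amide nitrogen
        ("GLY", "O", {"AC"}),       # backbone carbonyl oxygen
        ("PRO", "N", set()),        # proline: no amide hydrogen to donate
    ])
    def test_typing_table_examples(self, residue, atom, expected):
        rec = make_atom(atom, residue, 1, "A", "P", (0, 0, 0))
        assert im.assign_atom_labels(rec, TABLE) == frozenset(expected)

    def test_unknown_atom_gets_empty_labels(self):
        rec = make_atom("XX9", "GLY", 1, "A", "P", (0, 0, 0))
        assert im.assign_atom_labels(rec, TABLE) == frozenset()


def _pair(labels_a, labels_b, distance):
    a = make_atom("A1", "GLY", 1, "A", "P", (0.0, 0.0, 0.0))
    b = make_atom("B1", "GLY", 1, "B", "I", (distance, 0.0, 0.0))
    labels = {a.key: frozenset(labels_a), b.key: frozenset(labels_b)}
    return [a, b], labels


class TestComputeContacts:
    @pytest.mark.parametrize("la,lb,distance,expected_types", [
        ({"AC"}, {"DN"}, 2.5, {"hydrogen_bond"}),
        ({"HB"}, {"HB"}, 3.9, set()),                 # above the 3.8 max
        ({"NG"}, {"PS"}, 5.0, {"salt_bridge"}),
        ({"NG"}, {"NG"}, 5.0, {"repulsive"}),
        ({"AR"}, {"AR"}, 3.5, {"aromatic_stacking"}),  # closed upper bound
        ({"AC", "NG"}, {"DN", "PS"}, 2.8, {"hydrogen_bond", "salt_bridge"}),
    ])
    def test_label_and_window_conditions(self, la, lb, distance, expected_types):
        atoms, labels = _pair(la, lb, distance)
        edges = im.compute_contacts(atoms, labels, CRITERIA)
        assert {e.interaction_type for e in edges} == expected_types

    def test_same_side_pairs_never_interact(self):
        a = make_atom("A1", "GLY", 1, "A", "P", (0, 0, 0))
        b = make_atom("A2", "GLY", 2, "A", "P", (2.5, 0, 0))
        labels = {a.key: frozenset({"AC"}), b.key: frozenset({"DN"})}
        assert im.compute_contacts([a, b], labels, CRITERIA) == []

    def test_every_edge_inside_its_window_randomized(self):
        rng = np.random.default_rng(42)
        atoms, labels = [], {}
        for i in range(30):
            side = "P" if i < 15 else "I"
            a = make_atom(f"X{i}", "GLY", i, "A" if side == "P" else "B",
                          side, rng.uniform(0, 10, 3))
            atoms.append(a)
            labels[a.key] = frozenset(
                rng.choice(["AC", "DN", "HB", "NG", "PS", "AR"],
                           size=rng.integers(1, 3), replace=False))
        edges = im.compute_contacts(atoms, labels, CRITERIA)
        assert edges, "fixture should produce some contacts"
        for e in edges:
            w = CRITERIA.windows[e.interaction_type]
            assert w.min_dist <= e.distance <= w.max_dist
            assert e.a.side != e.b.side


class TestMultigraphAndComponents:
    def test_label_pruning_to_exercised_roles(self):
        atoms, labels = _pair({"AC", "NG"}, {"PS"}, 5.0)  # only a salt bridge
        edges = im.compute_contacts(atoms, labels, CRITERIA)
        g = im.build_interface_multigraph(atoms, edges, labels)
        assert g.nodes[atoms[0].key]["labels"] == frozenset({"NG"})

    def test_his_nd1_retains_donor_and_aromatic(self):
        nd1 = make_atom("ND1", "HIS", 1, "A", "P", (0.0, 0.0, 0.0))
        acc = make_atom("O", "GLY", 1, "B", "I", (2.5, 0.0, 0.0))    # acceptor only
        ring = make_atom("CG", "PHE", 2, "B", "I", (0.0, 3.0, 0.0))  # aromatic
        labels = {nd1.key: frozenset({"AR", "PS", "DN", "AC"}),
                  acc.key: frozenset({"AC"}), ring.key: frozenset({"AR"})}
        edges = im.compute_contacts([nd1, acc, ring], labels, CRITERIA)
        g = im.build_interface_multigraph([nd1, acc, ring], edges, labels)
        assert g.nodes[nd1.key]["labels"] == frozenset({"DN", "AR"})

    def test_contactless_atoms_are_not_nodes(self):
        atoms, labels = _pair({"AC"}, {"DN"}, 2.5)
        lonely = make_atom("FAR", "GLY", 9, "A", "P", (50, 50, 50))
        labels[lonely.key] = frozenset({"AC"})
        edges = im.compute_contacts(atoms + [lonely], labels, CRITERIA)
        g = im.build_interface_multigraph(atoms + [lonely], edges, labels)
        assert lonely.key not in g.nodes

    def test_components_partition_nodes_and_edges(self):
        comps = im.build_component_graphs(_fixture_pdb(), ({"A"}, {"B"}),
                                          complex_id="fx")
        assert len(comps) == 3  # three isolated planted pairs
        all_nodes = [n for c in comps for n in c.nodes]
        assert len(all_nodes) == len(set(all_nodes))
        for c in comps:
            assert c.number_of_nodes() == 2 and c.number_of_edges() >= 1

    def test_dataset_serialization_is_deterministic(self, tmp_path):
        import filecmp
        for name in ("a.json", "b.json"):
            comps = im.build_component_graphs(_fixture_pdb(), ({"A"}, {"B"}),
                                              complex_id="fx")
            from ifacemine import io as gio
            gio.write_dataset_json(comps, tmp_path / name)
        assert filecmp.cmp(tmp_path / "a.json", tmp_path / "b.json", shallow=False)
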