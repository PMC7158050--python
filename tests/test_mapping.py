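"""Line graphs, subset-label VF2 mapping, verification, and map_all consistency."""

import networkx as nx
import numpy as np
import pytest

import ifacemine as im
from ifacemine import gspan
from ifacemine.mapping import MappingConsistencyError
from ifacemine.mining import FrequentPattern, derive_display_labels
from conftest import make_graph
from oracles import brute_force_mappings, random_labeled_graph


def _pattern_from_graph(g, occurrences=("g",)):
    p = FrequentPattern(
        graph=g, dfs_code=gspan.min_dfs_code(g), support_count=len(occurrences),
        support_fraction=1.0, occurrence_graph_ids=tuple(occurrences))
    p.display_labels = derive_display_labels(p)
    return p


def _k3(label="HB", t="hydrophobic"):
    return make_graph([(i, {label}) for i in range(3)],
                      [(0, 1, {t}), (1, 2, {t}), (0, 2, {t})])


def _k13(label="HB", t="hydrophobic"):
    return make_graph([("c", {label}), ("l1", {label}),
                       ("l2", {label}), ("l3", {label})],
                      [("c", "l1", {t}), ("c", "l2", {t}), ("c", "l3", {t})])


class TestLineGraph:
    def test_two_edge_path_gives_single_edge(self):
        g = make_graph([("a", {"DN"}), ("b", {"AC"}), ("c", {"DN"})],
                       [("a", "b", {"hydrogen_bond"}), ("b", "c", {"hydrogen_bond"})])
        lg = im.line_graph(g)
        assert lg.number_of_nodes() == 2 and lg.number_of_edges() == 1

    def test_triangle_maps_to_triangle(self):
        lg = im.line_graph(_k3())
        assert lg.number_of_nodes() == 3 and lg.number_of_edges() == 3

    def test_claw_also_maps_to_triangle(self):
        lg = im.line_graph(_k13())
        assert lg.number_of_nodes() == 3 and lg.number_of_edges() == 3

    def test_edgeless_graph_rejected(self):
        g = nx.Graph()
        g.add_node(0, labels=frozenset({"DN"}))
        with pytest.raises(ValueError):
            im.line_graph(g)


class TestLabelsCompatible:
    @pytest.mark.parametrize("a,b,expected", [
        ({"NG"}, {"AC", "NG"}, True),
        ({"NG"}, {"NG"}, True),
        ({"AR"}, {"HB", "DN"}, False),
        ({"AC", "DN"}, {"AC"}, True),
        ({"AC", "NG"}, {"DN", "NG"}, False),
    ])
    def test_subset_rule(self, a, b, expected):
        assert im.labels_compatible(a, b) is expected


class TestMapPattern:
    def test_literal_subgraph_recovers_identity(self):
        target = make_graph(
            [("a", {"DN"}), ("b", {"AC", "NG"}), ("c", {"DN", "PS"})],
            [("a", "b", {"hydrogen_bond"}), ("b", "c", {"salt_bridge"})],
            graph_id="t")
        p = _pattern_from_graph(target.copy())
        maps = [m.as_dict() for m in im.map_pattern(p, target)]
        assert {"a": "a", "b": "b", "c": "c"} in maps

    def test_whitney_pair_yields_no_mapping(self):
        p = _pattern_from_graph(_k3())
        assert im.map_pattern(p, _k13()) == []

    def test_claw_pattern_does_not_map_into_triangle(self):
        p = _pattern_from_graph(_k13())
        assert im.map_pattern(p, _k3()) == []

    def test_subset_labels_allow_display_to_match_richer_atom(self):
        # pattern node displays {NG}; graph node carries {AC, NG}
        target = make_graph([("x", {"AC", "NG"}), ("y", {"PS"})],
                            [("x", "y", {"salt_bridge"})], graph_id="t")
        pattern = make_graph([(0, {"NG"}), (1, {"PS"})],
                             [(0, 1, {"salt_bridge"})])
        p = _pattern_from_graph(pattern)
        maps = im.map_pattern(p, target)
        assert len(maps) == 1 and maps[0].as_dict() == {0: "x", 1: "y"}

    def test_edgeless_pattern_rejected(self):
        g = nx.Graph()
        g.add_node(0, labels=frozenset({"DN"}), label="DN")
        p = FrequentPattern(graph=g, dfs_code=(), support_count=1,
                            support_fraction=1.0, occurrence_graph_ids=())
        with pytest.raises(ValueError):
            im.map_pattern(p, _k3())

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle_on_random_pairs(self, seed):
        rng = np.random.default_rng(1000 + seed)
        node_labels = ["AC", "DN", "HB", "NG"]
        edge_labels = ["hydrogen_bond", "salt_bridge", "hydrophobic"]
        raw_t = random_labeled_graph(rng, int(rng.integers(4, 8)),
                                     int(rng.integers(0, 4)),
                                     node_labels, edge_labels)
        target = nx.Graph(graph_id="t")
        for v, d in raw_t.nodes(data=True):
            target.add_node(v, labels=frozenset({d["label"]}), label=d["label"])
        for u, v, d in raw_t.edges(data=True):
            target.add_edge(u, v, types=frozenset({d["label"]}), label=d["label"])
        # pattern: a random connected edge-subgraph of the target
        edges = list(target.edges())
        rng.shuffle(edges)
        sub = nx.Graph()
        for u, v in edges:
            sub.add_node(u, **target.nodes[u])
            sub.add_node(v, **target.nodes[v])
            sub.add_edge(u, v, **target.edges[u, v])
            if sub.number_of_edges() >= 3 and nx.is_connected(sub):
                break
        if not nx.is_connected(sub):
            sub = sub.subgraph(max(nx.connected_components(sub), key=len)).copy()
        pattern = nx.convert_node_labels_to_integers(sub, label_attribute=None)
        p = _pattern_from_graph(pattern)
        got = {frozenset(m.as_dict().items()) for m in im.map_pattern(p, target)}
        expected = {frozenset(m.items())
                    for m in brute_force_mappings(pattern, p.display_labels, target)}
        assert got == expected and expected  # oracle must find the planted copy

    def test_all_returned_mappings_verify_on_originals(self):
        rng = np.random.default_rng(77)
        target = make_graph(
            [(i, {rng.choice(["AC", "DN", "NG", "PS"])}) for i in range(6)],
            [], graph_id="t")
        for i in range(1, 6):
            target.add_edge(i, int(rng.integers(i)),
                            types=frozenset({"hydrogen_bond"}), label="hydrogen_bond")
        pats = im.gspan_mine([target], 1.0)
        for p in pats:
            for m in im.map_pattern(p, target):
                nm = m.as_dict()
                assert len(set(nm.values())) == len(nm)
                for u, v, d in p.graph.edges(data=True):
                    assert target.has_edge(nm[u], nm[v])
                    assert im.labels_compatible(
                        d["types"], target.edges[nm[u], nm[v]]["types"])


class TestMapAll:
    def test_planted_motif_occurrences_all_mapped(self):
        graphs, manifest = im.generate_graph_dataset(im.GraphFixtureSpec(seed=21))
        patterns = im.filter_maximal(im.gspan_mine(graphs, 0.8))
        by_id = {g.graph["graph_id"]: g for g in graphs}
        mappings = im.map_all(patterns, by_id)
        motif_pats = [i for i, p in enumerate(patterns)
                      if set(p.occurrence_graph_ids) == set(manifest["planted_graph_ids"])]
        assert motif_pats, "the planted motif should be among the maximal patterns"
        mapped_gids = {m.graph_id for m in mappings
                       if m.pattern_id == f"p{motif_pats[0]}"}
        assert mapped_gids == set(manifest["planted_graph_ids"])

    def test_empty_pattern_list_gives_empty_table(self):
        assert im.map_all([], {}) == []

    def test_inconsistent_occurrence_raises(self):
        target = make_graph([("a", {"DN"}), ("b", {"AC"})],
                            [("a", "b", {"hydrogen_bond"})], graph_id="g")
        other = make_graph([("a", {"HB"}), ("b", {"HB"})],
                           [("a", "b", {"hydrophobic"})], graph_id="h")
        p = _pattern_from_graph(target.copy(), occurrences=("h",))
        with pytest.raises(MappingConsistencyError):
            im.map_all([p], {"h": other})

    def test_residue_view_matches_recomputation(self):
        graphs, _ = im.generate_graph_dataset(im.GraphFixtureSpec(seed=22))
        patterns = im.filter_maximal(im.gspan_mine(graphs, 0.8))
        by_id = {g.graph["graph_id"]: g for g in graphs}
        mappings = im.map_all(patterns, by_id)
        touched = im.residues_touched(mappings, by_id)
        for m in mappings:
            g = by_id[m.graph_id]
            for _, node in m.node_map:
                rec = g.nodes[node]["record"]
                assert (rec.complex_id, rec.chain_id, rec.side, rec.residue_name,
                        rec.residue_number, rec.insertion_code) in touched[m.pattern_id]
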