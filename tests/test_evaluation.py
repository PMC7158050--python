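"""Precision/recall evaluation against reference residues and micro-structures."""

import networkx as nx
import pytest

import ifacemine as im
from ifacemine.evaluation import ReferenceItem, ResidueSpec
from ifacemine.mining import FrequentPattern
from conftest import make_graph


def _pattern(nodes, edges):
    g = make_graph(nodes, edges)
    p = FrequentPattern(graph=g, dfs_code=(), support_count=1,
                        support_fraction=1.0, occurrence_graph_ids=("g",))
    p.display_labels = im.derive_display_labels(p)
    return p


def _touch(*residues):
    """Touched-residue tuples: (complex, chain, side, name, number, icode)."""
    return {("cx", "E", "P", name, num, "") for name, num in residues}


SER195 = ReferenceItem("I", residues=(ResidueSpec("SER", 195, side="P"),))
ASP189 = ReferenceItem("II", residues=(ResidueSpec("ASP", 189),))
HIS40 = ReferenceItem("III", residues=(ResidueSpec("HIS", 40),))


def _oxyanion_item():
    s = nx.Graph()
    s.add_node(0, labels=frozenset({"DN"}))
    s.add_node(1, labels=frozenset({"DN"}))
    s.add_node(2, labels=frozenset({"AC"}))
    s.add_edge(0, 2, types=frozenset({"hydrogen_bond"}))
    s.add_edge(1, 2, types=frozenset({"hydrogen_bond"}))
    return ReferenceItem("IV", structure=s)


class TestPatternRelevant:
    def test_residue_rule_matches_touched_aspartate(self):
        p = _pattern([("a", {"NG"}), ("b", {"PS"})], [("a", "b", {"salt_bridge"})])
        matched = im.pattern_relevant(p, _touch(("ASP", 189), ("ARG", 17)),
                                      [SER195, ASP189])
        assert matched == {"II"}

    def test_side_restriction_excludes_wrong_chain_group(self):
        p = _pattern([("a", {"AC"}), ("b", {"DN"})], [("a", "b", {"hydrogen_bond"})])
        touched = {("cx", "I", "I", "SER", 195, "")}  # inhibitor side
        assert im.pattern_relevant(p, touched, [SER195]) == set()

    def test_untouched_reference_gives_empty_set(self):
        p = _pattern([("a", {"AC"}), ("b", {"DN"})], [("a", "b", {"hydrogen_bond"})])
        assert im.pattern_relevant(p, _touch(("GLY", 1)), [SER195, ASP189]) == set()

    def test_oxyanion_microstructure_found_inside_larger_pattern(self):
        # 5-node pattern containing two donors hydrogen-bonded to one acceptor
        p = _pattern(
            [("n1", {"DN"}), ("n2", {"DN"}), ("o", {"AC"}),
             ("x", {"AC", "NG"}), ("y", {"PS"})],
            [("n1", "o", {"hydrogen_bond"}), ("n2", "o", {"hydrogen_bond"}),
             ("n1", "x", {"hydrogen_bond"}), ("x", "y", {"salt_bridge"})])
        assert im.pattern_relevant(p, set(), [_oxyanion_item()]) == {"IV"}

    def test_microstructure_absent_without_second_donor(self):
        p = _pattern([("n1", {"DN"}), ("o1", {"AC"})],
                     [("n1", "o1", {"hydrogen_bond"})])
        assert im.pattern_relevant(p, set(), [_oxyanion_item()]) == set()

    def test_empty_reference_set_rejected(self):
        p = _pattern([("a", {"AC"}), ("b", {"DN"})], [("a", "b", {"hydrogen_bond"})])
        with pytest.raises(ValueError):
            im.pattern_relevant(p, set(), [])


class TestPrecisionRecall:
    def _simple_pattern(self):
        return _pattern([("a", {"AC"}), ("b", {"DN"})],
                        [("a", "b", {"hydrogen_bond"})])

    def test_pooled_nine_of_thirteen_relevant_all_ids_matched(self):
        """11 groups, 13 patterns pooled, 9 relevant, 4 reference ids all matched
        somewhere -> overall precision 0.69, recall 1.00."""
        ref = [SER195, ASP189, HIS40, _oxyanion_item()]
        touch_for = {"I": _touch(("SER", 195)), "II": _touch(("ASP", 189)),
                     "III": _touch(("HIS", 40)), "none": _touch(("ALA", 7))}
        # group -> list of (touched key) per pattern; mirrors a run where 4 of
        # 11 groups contain nothing relevant and group 6 holds 3 patterns
        layout = {
            "1": ["III"], "2": ["none"], "3": ["II"], "4": ["none"],
            "5": ["none"], "6": ["I", "I", "I"], "7": ["IV"], "8": ["I"],
            "9": ["I"], "10": ["II"], "11": ["none"],
        }
        oxy = _pattern(
            [("n1", {"DN"}), ("n2", {"DN"}), ("o", {"AC"})],
            [("n1", "o", {"hydrogen_bond"}), ("n2", "o", {"hydrogen_bond"})])
        groups = {}
        for gid, wants in layout.items():
            pats, touched = [], []
            for w in wants:
                pats.append(oxy if w == "IV" else self._simple_pattern())
                touched.append(set() if w == "IV" else touch_for[w])
            groups[gid] = (pats, touched)
        report = im.precision_recall(groups, ref)
        overall = report[report["group"] == "All"].iloc[0]
        assert overall["patterns"] == 13
        assert overall["precision"] == pytest.approx(0.69)
        assert overall["recall"] == pytest.approx(1.00)
        assert overall["residues"] == "I,II,III,IV"

    def test_all_relevant_gives_perfect_scores(self):
        groups = {"0": ([self._simple_pattern()], [_touch(("SER", 195))])}
        report = im.precision_recall(groups, [SER195])
        assert report.iloc[-1]["precision"] == 1.0
        assert report.iloc[-1]["recall"] == 1.0

    def test_none_relevant_gives_zero_scores(self):
        groups = {"0": ([self._simple_pattern()], [_touch(("ALA", 1))])}
        report = im.precision_recall(groups, [SER195])
        assert report.iloc[-1]["precision"] == 0.0
        assert report.iloc[-1]["recall"] == 0.0

    def test_overall_precision_consistent_with_group_rows(self):
        ref = [SER195, ASP189]
        groups = {
            "0": ([self._simple_pattern()] * 2,
                  [_touch(("SER", 195)), _touch(("ALA", 1))]),
            "1": ([self._simple_pattern()], [_touch(("ASP", 189))]),
        }
        report = im.precision_recall(groups, ref)
        per_group = report[report["group"] != "All"]
        relevant = (per_group["precision"] * per_group["patterns"]).sum()
        overall = report[report["group"] == "All"].iloc[0]
        assert overall["precision"] == pytest.approx(
            round(relevant / per_group["patterns"].sum(), 2))

    def test_recall_monotone_as_patterns_added(self):
        ref = [SER195, ASP189]
        g1 = {"0": ([self._simple_pattern()], [_touch(("SER", 195))])}
        r1 = im.precision_recall(g1, ref).iloc[-1]["recall"]
        g2 = {"0": ([self._simple_pattern(), self._simple_pattern()],
                    [_touch(("SER", 195)), _touch(("ASP", 189))])}
        r2 = im.precision_recall(g2, ref).iloc[-1]["recall"]
        assert r2 >= r1

    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError):
            im.precision_recall({}, [SER195])
        with pytest.raises(ValueError):
            im.precision_recall({"0": ([], [])}, [SER195])


class TestReferenceFile:
    def test_round_trip_yaml(self, tmp_path):
        text = """
items:
  - id: "I"
    residues:
      - {res_name: SER, res_number: 195, side: P}
  - id: "IV"
    structure:
      nodes:
        - {id: 0, labels: [DON]}
        - {id: 1, labels: [DON]}
        - {id: 2, labels: [ACP]}
      edges:
        - {u: 0, v: 2, types: [hydrogen_bond]}
        - {u: 1, v: 2, types: [hydrogen_bond]}
"""
        path = tmp_path / "ref.yaml"
        path.write_text(text)
        items = im.load_reference_items(str(path))
        assert [it.item_id for it in items] == ["I", "IV"]
        assert items[0].residues[0] == ResidueSpec("SER", 195, side="P")
        assert items[1].structure.number_of_nodes() == 3
        assert items[1].structure.nodes[0]["labels"] == {"DN"}
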