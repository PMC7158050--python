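"""Score mined patterns against literature-style reference residues.

Builds two synthetic groups of patterns, one touching a reference serine
and an oxyanion-hole-like micro-structure, the other touching nothing
relevant, and prints the precision/recall table.
"""

import networkx as nx

import ifacemine as im
from ifacemine.evaluation import ReferenceItem, ResidueSpec
from ifacemine.mining import FrequentPattern


def pattern(nodes, edges):
    g = nx.Graph()
    for name, labels in nodes:
        g.add_node(name, labels=frozenset(labels), label="/".join(sorted(labels)))
    for u, v, types in edges:
        g.add_edge(u, v, types=frozenset(types), label="/".join(sorted(types)))
    p = FrequentPattern(graph=g, dfs_code=(), support_count=1,
                        support_fraction=1.0, occurrence_graph_ids=("g",))
    p.display_labels = im.derive_display_labels(p)
    return p


oxyanion = nx.Graph()
for n, l in ((0, "DN"), (1, "DN"), (2, "AC")):
    oxyanion.add_node(n, labels=frozenset({l}))
oxyanion.add_edge(0, 2, types=frozenset({"hydrogen_bond"}))
oxyanion.add_edge(1, 2, types=frozenset({"hydrogen_bond"}))

reference = [
    ReferenceItem("I", residues=(ResidueSpec("SER", 195, side="P"),)),
    ReferenceItem("II", residues=(ResidueSpec("ASP", 189),)),
    ReferenceItem("IV", structure=oxyanion),
]

oxy_pattern = pattern(
    [("n1", {"DN"}), ("n2", {"DN"}), ("o", {"AC"})],
    [("n1", "o", {"hydrogen_bond"}), ("n2", "o", {"hydrogen_bond"})])
plain = pattern([("a", {"HB"}), ("b", {"HB"})], [("a", "b", {"hydrophobic"})])

groups = {
    "0": ([oxy_pattern, plain],
          [{("cx", "E", "P", "SER", 195, "")}, set()]),
    "1": ([plain], [{("cx", "E", "P", "ALA", 7, "")}]),
}
report = im.precision_recall(groups, reference)
print(report.to_string(index=False))

# Group 0's first pattern matches both the serine residue rule (I) and the
# two-donor/one-acceptor micro-structure rule (IV); the hydrophobic patterns
# match nothing, so pooled precision is 1/3 while recall counts the matched
# reference ids (2 of 3).
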