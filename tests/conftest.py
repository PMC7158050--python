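import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ifacemine.interface import AtomRecord


def make_graph(nodes, edges, graph_id="g"):
    """Simple labeled graph from [(name, labels)] and [(u, v, types)]."""
    g = nx.Graph(graph_id=graph_id)
    for name, labels in nodes:
        labs = frozenset(labels)
        g.add_node(name, labels=labs, label="/".join(sorted(labs)))
    for u, v, types in edges:
        ts = frozenset(types)
        g.add_edge(u, v, types=ts, label="/".join(sorted(ts)))
    return g


def make_atom(name, residue, number, chain, side, xyz, complex_id="cx"):
    return AtomRecord(
        complex_id=complex_id, chain_id=chain, residue_name=residue,
        residue_number=number, atom_name=name, element=name[0],
        position=tuple(float(x) for x in xyz), side=side,
    )


@pytest.fixture
def worked_example_graphs():
    """The three-graph counting-matrix example (donor / acceptor-negative /
    donor-positive path plus two companions exercising the other columns)."""
    g1 = make_graph(
        [("A", {"DN"}), ("B", {"AC", "NG"}), ("C", {"DN", "PS"})],
        [("A", "B", {"hydrogen_bond"}), ("B", "C", {"salt_bridge"})],
        graph_id="G1",
    )
    g2 = make_graph(
        [("A", {"AC"}), ("B", {"DN", "PS"}), ("C", {"AC", "NG"}), ("D", {"DN"}),
         ("E", {"NG"})],
        [("A", "B", {"hydrogen_bond"}), ("B", "C", {"salt_bridge"}),
         ("C", "D", {"hydrogen_bond"}), ("B", "E", {"salt_bridge"})],
        graph_id="G2",
    )
    g3 = make_graph(
        [("A", {"DN", "PS"}), ("B", {"NG"}), ("C", {"DN", "PS"}), ("D", {"NG"})],
        [("A", "B", {"salt_bridge"}), ("A", "C", {"repulsive"}),
         ("B", "D", {"repulsive"})],
        graph_id="G3",
    )
    return [g1, g2, g3]
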