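"""Mapping mined patterns back onto concrete atoms and interactions.

Frequent patterns are not vertex-induced subgraphs of their occurrence
graphs, but available VF2 implementations match induced subgraphs only.
The standard workaround used here goes through line graphs: L(H) has one
vertex per edge of H, adjacent when the source edges share an endpoint, and
an edge-subgraph of H becomes a vertex-induced subgraph of L(H).  VF2 is
run on the line graphs with a node-match that applies subset-label
compatibility to both the joined edge labels and the endpoint label pairs;
every line-level match is then translated back to an atom-level node map
and re-verified on the original graphs (injectivity, adjacency, label
compatibility).  The verification step also discards artifacts of the
Whitney exception (K3 and K1,3 share a line graph without being
isomorphic), so the line-graph route is purely a matching device.

Pattern-side node labels used for matching are the display labels (the
roles exercised by the pattern's own edges); target-side labels are the
retained atom labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, List, Mapping, Sequence, Tuple

import networkx as nx

from .labels import labels_compatible
from .mining import FrequentPattern

EdgeKey = Tuple  # sorted node pair


def _edge_key(u, v) -> EdgeKey:
    return tuple(sorted((u, v), key=repr))


def line_graph(h: nx.Graph, node_labels: Mapping | None = None) -> nx.Graph:
    """Line graph of a labeled simple graph.

    Line nodes are the sorted edge keys of ``h`` and carry the source edge's
    ``types`` plus the (unordered) pair of endpoint label sets; line edges
    join nodes whose source edges share an endpoint.  ``node_labels``
    overrides the per-node label sets (used to substitute display labels on
    the pattern side).
    """
    if h.number_of_edges() == 0:
        raise ValueError("line graph of an edgeless graph is undefined here")
    labels = {v: (node_labels[v] if node_labels is not None else h.nodes[v]["labels"])
              for v in h.nodes}
    lg = nx.Graph()
    for u, v, data in h.edges(data=True):
        key = _edge_key(u, v)
        lg.add_node(key, types=frozenset(data["types"]),
                    endpoint_labels=(labels[key[0]], labels[key[1]]))
    for e1, e2 in combinations(lg.nodes, 2):
        if set(e1) & set(e2):
            lg.add_edge(e1, e2)
    return lg


def _line_nodes_compatible(target_attrs: dict, pattern_attrs: dict) -> bool:
    if not labels_compatible(target_attrs["types"], pattern_attrs["types"]):
        return False
    ta, tb = target_attrs["endpoint_labels"]
    pa, pb = pattern_attrs["endpoint_labels"]
    return (labels_compatible(pa, ta) and labels_compatible(pb, tb)) or (
        labels_compatible(pa, tb) and labels_compatible(pb, ta)
    )


@dataclass(frozen=True)
class PatternMapping:
    """One verified embedding of a pattern into a target graph."""

    pattern_id: str
    graph_id: str
    node_map: Tuple[Tuple[int, object], ...]   # pattern node -> target node, sorted
    edge_map: Tuple[Tuple[EdgeKey, EdgeKey], ...]

    def as_dict(self) -> Dict[int, object]:
        return dict(self.node_map)


def _candidate_node_maps(pattern: nx.Graph,
                         edge_map: Dict[EdgeKey, EdgeKey]) -> List[Dict[int, object]]:
    """Reconstruct atom-level node maps from a line-level edge map."""
    if pattern.number_of_edges() == 1:
        (pu, pv) = next(iter(edge_map))
        (tu, tv) = edge_map[(pu, pv)]
        return [{pu: tu, pv: tv}, {pu: tv, pv: tu}]
    node_map: Dict[int, object] = {}
    for v in pattern.nodes:
        incident = [edge_map[_edge_key(v, w)] for w in pattern.neighbors(v)]
        if len(incident) >= 2:
            common = set(incident[0])
            for e in incident[1:]:
                common &= set(e)
            if len(common) != 1:
                return []
            node_map[v] = common.pop()
    for v in pattern.nodes:
        if v in node_map:
            continue
        w = next(iter(pattern.neighbors(v)))   # degree-1 node in a >=2-edge pattern
        if w not in node_map:
            return []
        te = edge_map[_edge_key(v, w)]
        if node_map[w] not in te:
            return []
        node_map[v] = te[0] if te[1] == node_map[w] else te[1]
    return [node_map]


def _verify(pattern: nx.Graph, display: Mapping[int, FrozenSet[str]],
            target: nx.Graph, node_map: Dict[int, object]) -> bool:
    if len(set(map(repr, node_map.values()))) != len(node_map):
        return False
    for v in pattern.nodes:
        if not labels_compatible(display[v], target.nodes[node_map[v]]["labels"]):
            return False
    for u, v, data in pattern.edges(data=True):
        tu, tv = node_map[u], node_map[v]
        if not target.has_edge(tu, tv):
            return False
        if not labels_compatible(data["types"], target.edges[tu, tv]["types"]):
            return False
    return True


def map_pattern(p: FrequentPattern, g: nx.Graph,
                pattern_id: str = "pattern") -> List[PatternMapping]:
    """All verified embeddings of pattern ``p`` into simple graph ``g``."""
    if p.n_edges == 0:
        raise ValueError("cannot map an edgeless pattern")
    display = p.display_labels or {v: p.graph.nodes[v]["labels"] for v in p.graph.nodes}
    lp = line_graph(p.graph, node_labels=display)
    if g.number_of_edges() == 0:
        return []
    lg = line_graph(g)
    gm = nx.algorithms.isomorphism.GraphMatcher(
        lg, lp, node_match=_line_nodes_compatible)

    graph_id = str(g.graph.get("graph_id", "graph"))
    seen = set()
    out: List[PatternMapping] = []
    for iso in gm.subgraph_isomorphisms_iter():
        edge_map = {pe: te for te, pe in iso.items()}
        for node_map in _candidate_node_maps(p.graph, edge_map):
            if not node_map or not _verify(p.graph, display, g, node_map):
                continue
            sig = frozenset((k, repr(v)) for k, v in node_map.items())
            if sig in seen:
                continue
            seen.add(sig)
            out.append(PatternMapping(
                pattern_id=pattern_id,
                graph_id=graph_id,
                node_map=tuple(sorted(node_map.items(), key=lambda kv: kv[0])),
                edge_map=tuple(sorted(
                    ((pe, _edge_key(node_map[pe[0]], node_map[pe[1]])) for pe in edge_map),
                    key=repr)),
            ))
    return out


class MappingConsistencyError(RuntimeError):
    """A mined occurrence could not be re-established by the mapper."""


def map_all(
    patterns: Sequence[FrequentPattern],
    graphs_by_id: Mapping[str, nx.Graph],
    pattern_ids: Sequence[str] | None = None,
) -> List[PatternMapping]:
    """Map every pattern onto each of its occurrence graphs.

    Raises :class:`MappingConsistencyError` if a claimed occurrence yields
    no verified mapping (miner/mapper disagreement).
    """
    ids = list(pattern_ids) if pattern_ids is not None else [
        f"p{i}" for i in range(len(patterns))]
    out: List[PatternMapping] = []
    for pid, p in zip(ids, patterns):
        for gid in p.occurrence_graph_ids:
            found = map_pattern(p, graphs_by_id[gid], pattern_id=pid)
            if not found:
                raise MappingConsistencyError(
                    f"pattern {pid} claims occurrence in graph {gid} "
                    "but no verified mapping exists")
            out.extend(found)
    return out


def residues_touched(mappings: Sequence[PatternMapping],
                     graphs_by_id: Mapping[str, nx.Graph]) -> Dict[str, set]:
    """Per-pattern set of residues reached by any mapping (via atom provenance)."""
    out: Dict[str, set] = {}
    for m in mappings:
        touched = out.setdefault(m.pattern_id, set())
        g = graphs_by_id[m.graph_id]
        for _, node in m.node_map:
            rec = g.nodes[node].get("record")
            if rec is not None:
                touched.add((rec.complex_id, rec.chain_id, rec.side,
                             rec.residue_name, rec.residue_number, rec.insertion_code))
    return out
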