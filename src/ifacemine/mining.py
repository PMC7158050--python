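"""Cluster-level frequent pattern mining.

Interface multigraphs are first flattened into labeled simple graphs (one
edge per adjacent atom pair, parallel interaction types joined into a single
sorted edge label); gSpan then mines each cluster with exact string equality
on labels, and the result is filtered to maximal patterns — those not
contained, label-exactly, in any other frequent pattern.

Because mining is label-exact, a pattern node carries the full retained
label of its source atoms.  ``derive_display_labels`` recovers the leaner
presentation labels: for each pattern node, the subset of its mined label
actually exercised by the pattern's own edges (an acceptor/negative oxygen
whose only pattern edge is a salt bridge displays just "negative").  These
display labels also drive the subset-matching step when patterns are mapped
back onto atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import networkx as nx
import pandas as pd

from . import gspan
from .labels import CHARGES, OPPOSITE_CHARGE, canonical_label

logger = logging.getLogger(__name__)


def type_set_label(types: Sequence[str]) -> str:
    return "/".join(sorted(set(types)))


def to_simple_graph(g: nx.MultiGraph | nx.Graph) -> nx.Graph:
    """Flatten a multigraph: one edge per adjacent pair, joined type labels.

    Nodes keep their retained label sets (attr ``labels``) plus a string
    form (attr ``label``); edges carry the sorted set of interaction types
    (attr ``types``) and its joined string (attr ``label``).
    """
    sg = nx.Graph()
    sg.graph.update(g.graph)
    for v, data in g.nodes(data=True):
        labs = frozenset(data["labels"])
        sg.add_node(v, labels=labs, label=canonical_label(labs),
                    **{k: data[k] for k in ("record", "side") if k in data})
    seen: Dict[Tuple, set] = {}
    dists: Dict[Tuple, list] = {}
    for u, v, data in g.edges(data=True):
        key = tuple(sorted((u, v), key=repr))
        bucket = seen.setdefault(key, set())
        if "types" in data:
            bucket.update(data["types"])
        else:
            bucket.add(data.get("interaction_type", data.get("label")))
        if "distance" in data:
            dists.setdefault(key, []).append(data["distance"])
        dists.setdefault(key, []).extend(data.get("distances", ()))
    for (u, v), types in seen.items():
        types = frozenset(t for t in types if t)
        sg.add_edge(u, v, types=types, label=type_set_label(types),
                    distances=tuple(sorted(dists.get((u, v), ()))))
    return sg


@dataclass
class FrequentPattern:
    """A mined pattern with canonical code, support and presentation labels."""

    graph: nx.Graph                     # nodes 0..m-1; attrs labels/label, edges types/label
    dfs_code: gspan.DFSCode
    support_count: int
    support_fraction: float
    occurrence_graph_ids: Tuple[str, ...]
    is_maximal: bool = False
    display_labels: Dict[int, FrozenSet[str]] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def _pattern_graph_with_sets(code_graph: nx.Graph) -> nx.Graph:
    g = nx.Graph()
    for v, data in code_graph.nodes(data=True):
        g.add_node(v, labels=frozenset(data["label"].split("/")), label=data["label"])
    for u, v, data in code_graph.edges(data=True):
        g.add_edge(u, v, types=frozenset(data["label"].split("/")), label=data["label"])
    return g


def gspan_mine(
    cluster_graphs: Sequence[nx.Graph],
    min_support: float,
    max_pattern_nodes: Optional[int] = None,
) -> List[FrequentPattern]:
    """Mine one cluster of simple graphs; returns patterns with display labels."""
    if len(cluster_graphs) == 0:
        raise ValueError("empty cluster")
    ids = [str(g.graph.get("graph_id", i)) for i, g in enumerate(cluster_graphs)]
    mined = gspan.mine(cluster_graphs, min_support, max_pattern_nodes)
    out: List[FrequentPattern] = []
    for mp in mined:
        pat = FrequentPattern(
            graph=_pattern_graph_with_sets(mp.graph),
            dfs_code=mp.code,
            support_count=mp.support_count,
            support_fraction=mp.support_count / len(cluster_graphs),
            occurrence_graph_ids=tuple(ids[i] for i in mp.occurrence_graph_ids),
        )
        pat.display_labels = derive_display_labels(pat)
        out.append(pat)
    return out


def _contains(big: FrequentPattern, small: FrequentPattern) -> bool:
    """Label-exact subgraph containment (non-induced) of small in big."""
    if small.n_nodes > big.n_nodes or small.n_edges > big.n_edges:
        return False
    gm = nx.algorithms.isomorphism.GraphMatcher(
        big.graph, small.graph,
        node_match=lambda a, b: a["label"] == b["label"],
        edge_match=lambda a, b: a["label"] == b["label"],
    )
    return any(True for _ in gm.subgraph_monomorphisms_iter())


def filter_maximal(patterns: Sequence[FrequentPattern]) -> List[FrequentPattern]:
    """Keep patterns not properly contained in any other mined pattern."""
    out: List[FrequentPattern] = []
    for p in patterns:
        contained = any(
            q.dfs_code != p.dfs_code and _contains(q, p) for q in patterns
        )
        p.is_maximal = not contained
        if not contained:
            out.append(p)
    return out


def derive_display_labels(p: FrequentPattern) -> Dict[int, FrozenSet[str]]:
    """Per-node subset of the mined label exercised by the pattern's edges."""
    display: Dict[int, FrozenSet[str]] = {}
    for v in p.graph.nodes:
        own = p.graph.nodes[v]["labels"]
        used: set = set()
        for _, w, data in p.graph.edges(v, data=True):
            partner = p.graph.nodes[w]["labels"]
            for t in data["types"]:
                if t == "aromatic_stacking" and "AR" in own:
                    used.add("AR")
                elif t == "hydrophobic" and "HB" in own:
                    used.add("HB")
                elif t == "hydrogen_bond":
                    if "AC" in own and "DN" in partner:
                        used.add("AC")
                    if "DN" in own and "AC" in partner:
                        used.add("DN")
                elif t == "salt_bridge":
                    used.update(c for c in CHARGES
                                if c in own and OPPOSITE_CHARGE[c] in partner)
                elif t == "repulsive":
                    used.update(c for c in CHARGES if c in own and c in partner)
        if not used:
            logger.warning(
                "pattern node %s: no edge-consistent role labels; falling back "
                "to the mined label %s", v, p.graph.nodes[v]["label"])
            used = set(own)
        display[v] = frozenset(used)
    return display


def support_sweep(
    cluster_graphs: Sequence[nx.Graph],
    grid: Sequence[float] = tuple(round(0.1 * i, 1) for i in range(1, 11)),
    max_pattern_nodes: Optional[int] = None,
) -> pd.DataFrame:
    """Mine at each support of the grid and summarize pattern statistics."""
    if len(grid) == 0:
        raise ValueError("empty support grid")
    rows = []
    for s in grid:
        pats = gspan_mine(cluster_graphs, s, max_pattern_nodes)
        maximal = filter_maximal(list(pats))
        rows.append({
            "min_support": s,
            "patterns": len(pats),
            "maximal_patterns": len(maximal),
            "max_pattern_nodes": max((p.n_nodes for p in pats), default=0),
        })
    return pd.DataFrame(rows)
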