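"""Frequent connected-subgraph mining over labeled simple graphs (gSpan).

Patterns are grown edge by edge along the rightmost path of their DFS tree
and identified by their minimum DFS code, the canonical form that makes
duplicate detection a code comparison instead of isomorphism testing.  A
DFS code is a sequence of 5-tuples ``(i, j, li, le, lj)`` over DFS discovery
indices; forward edges have ``i < j``, backward edges ``i > j``.  Support is
transaction-based: the number of distinct dataset graphs containing at least
one embedding of the pattern.

Node and edge labels are opaque strings compared for exact equality here;
the subset-label semantics of the wider pipeline is applied later, at
mapping time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cmp_to_key
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import networkx as nx

CodeEdge = Tuple[int, int, Tuple[str, str, str]]  # (i, j, (li, le, lj))
DFSCode = Tuple[CodeEdge, ...]


@dataclass(frozen=True)
class _Graph:
    """Dense integer-indexed view of a labeled simple graph."""

    vlabel: Tuple[str, ...]
    adj: Tuple[Tuple[Tuple[int, str], ...], ...]  # adj[u] = ((v, elabel), ...)


def _from_networkx(g: nx.Graph) -> Tuple[_Graph, List]:
    nodes = sorted(g.nodes, key=repr)
    index = {v: i for i, v in enumerate(nodes)}
    vlabel = tuple(str(g.nodes[v]["label"]) for v in nodes)
    adj: List[List[Tuple[int, str]]] = [[] for _ in nodes]
    for u, v, data in g.edges(data=True):
        le = str(data["label"])
        adj[index[u]].append((index[v], le))
        adj[index[v]].append((index[u], le))
    return _Graph(vlabel, tuple(tuple(sorted(a)) for a in adj)), nodes


def _cmp_edge(e1: CodeEdge, e2: CodeEdge) -> int:
    """gSpan's total order on DFS-code edges sharing a code prefix."""
    if e1 == e2:
        return 0
    i1, j1, l1 = e1
    i2, j2, l2 = e2
    f1, f2 = i1 < j1, i2 < j2
    if f1 and f2:
        if j1 != j2:
            return -1 if j1 < j2 else 1
        if i1 != i2:
            return -1 if i1 > i2 else 1
        return -1 if l1 < l2 else 1
    if not f1 and not f2:
        if i1 != i2:
            return -1 if i1 < i2 else 1
        if j1 != j2:
            return -1 if j1 < j2 else 1
        return -1 if l1 < l2 else 1
    if f1:  # e1 forward, e2 backward
        return -1 if j1 <= i2 else 1
    # e1 backward, e2 forward
    return -1 if i1 < j2 else 1


_EDGE_KEY = cmp_to_key(_cmp_edge)


def _num_vertices(code: DFSCode) -> int:
    return max(max(i, j) for i, j, _ in code) + 1


def _rightmost_path(code: DFSCode) -> Tuple[int, ...]:
    """DFS ids from root to rightmost vertex, derived from forward edges."""
    parent: Dict[int, int] = {}
    rightmost = 0
    for i, j, _ in code:
        if i < j:  # forward
            parent[j] = i
            rightmost = j
    path = [rightmost]
    while path[-1] != 0:
        path.append(parent[path[-1]])
    return tuple(reversed(path))


# An embedding maps code vertices to graph vertices and tracks used edges.
_Embedding = Tuple[int, Tuple[int, ...], FrozenSet[FrozenSet[int]]]


def _extensions(
    code: DFSCode,
    embeddings: Sequence[_Embedding],
    graphs: Sequence[_Graph],
    max_nodes: Optional[int] = None,
) -> Dict[CodeEdge, List[_Embedding]]:
    """Rightmost-path extensions of ``code`` across all its embeddings."""
    rmp = _rightmost_path(code)
    vr = rmp[-1]
    m = _num_vertices(code)
    existing = {frozenset((i, j)) for i, j, _ in code}
    out: Dict[CodeEdge, List[_Embedding]] = {}

    for gid, vmap, used in embeddings:
        g = graphs[gid]
        gvr = vmap[vr]
        on_path_graph = {vmap[vi]: vi for vi in rmp}
        mapped = set(vmap)
        # backward: rightmost vertex to an earlier rightmost-path vertex
        for gw, le in g.adj[gvr]:
            vi = on_path_graph.get(gw)
            if vi is None or vi == vr:
                continue
            if frozenset((vr, vi)) in existing:
                continue
            if frozenset((gvr, gw)) in used:
                continue
            ext = (vr, vi, (g.vlabel[gvr], le, g.vlabel[gw]))
            out.setdefault(ext, []).append((gid, vmap, used | {frozenset((gvr, gw))}))
        # forward: any rightmost-path vertex to a fresh graph vertex
        if max_nodes is not None and m >= max_nodes:
            continue
        for vi in rmp:
            gvi = vmap[vi]
            for gw, le in g.adj[gvi]:
                if gw in mapped:
                    continue
                ext = (vi, m, (g.vlabel[gvi], le, g.vlabel[gw]))
                out.setdefault(ext, []).append(
                    (gid, vmap + (gw,), used | {frozenset((gvi, gw))})
                )
    return out


def _initial_embeddings(graphs: Sequence[_Graph]) -> Dict[CodeEdge, List[_Embedding]]:
    out: Dict[CodeEdge, List[_Embedding]] = {}
    for gid, g in enumerate(graphs):
        for u in range(len(g.vlabel)):
            for v, le in g.adj[u]:
                la, lb = g.vlabel[u], g.vlabel[v]
                if (la, lb) > (lb, la):
                    continue  # keep orientations whose labels are sorted
                ext = (0, 1, (la, le, lb))
                out.setdefault(ext, []).append(
                    (gid, (u, v), frozenset({frozenset((u, v))}))
                )
    return out


def graph_from_code(code: DFSCode) -> nx.Graph:
    g = nx.Graph()
    for i, j, (li, le, lj) in code:
        g.add_node(i, label=li)
        g.add_node(j, label=lj)
        g.add_edge(i, j, label=le)
    return g


def _self_embeddings(code1: CodeEdge, g: _Graph) -> List[_Embedding]:
    _, _, (la, le, lb) = code1
    out: List[_Embedding] = []
    for u in range(len(g.vlabel)):
        if g.vlabel[u] != la:
            continue
        for v, el in g.adj[u]:
            if el == le and g.vlabel[v] == lb:
                out.append((0, (u, v), frozenset({frozenset((u, v))})))
    return out


def is_min(code: DFSCode) -> bool:
    """True iff ``code`` is the minimum DFS code of the graph it encodes."""
    pattern = _from_networkx(graph_from_code(code))[0]
    first = min(_initial_embeddings([pattern]), key=_EDGE_KEY)
    if code[0] != first:
        return False
    embeddings = _self_embeddings(first, pattern)
    cur: DFSCode = (first,)
    while len(cur) < len(code):
        exts = _extensions(cur, embeddings, [pattern])
        best = min(exts, key=_EDGE_KEY)
        if code[len(cur)] != best:
            return False
        embeddings = exts[best]
        cur = cur + (best,)
    return True


def min_dfs_code(g: nx.Graph) -> DFSCode:
    """Canonical minimum DFS code of a connected labeled simple graph."""
    if g.number_of_edges() == 0:
        raise ValueError("DFS codes are defined for graphs with at least one edge")
    if not nx.is_connected(g):
        raise ValueError("graph must be connected")
    pattern = _from_networkx(g)[0]
    first = min(_initial_embeddings([pattern]), key=_EDGE_KEY)
    embeddings = _self_embeddings(first, pattern)
    code: DFSCode = (first,)
    n_edges = g.number_of_edges()
    while len(code) < n_edges:
        exts = _extensions(code, embeddings, [pattern])
        best = min(exts, key=_EDGE_KEY)
        embeddings = exts[best]
        code = code + (best,)
    return code


@dataclass
class MinedPattern:
    """A frequent connected subgraph with canonical code and occurrences."""

    code: DFSCode
    support_count: int
    occurrence_graph_ids: Tuple[int, ...]

    @property
    def graph(self) -> nx.Graph:
        return graph_from_code(self.code)


def mine(
    graphs: Sequence[nx.Graph],
    min_support: float,
    max_pattern_nodes: Optional[int] = None,
) -> List[MinedPattern]:
    """All frequent connected subgraph patterns (>= 1 edge) of a dataset.

    ``min_support`` is the fraction of dataset graphs a pattern must occur
    in; the count threshold is ``ceil(min_support * len(graphs))``.  Node
    attribute ``label`` and edge attribute ``label`` carry the (string)
    labels compared for equality.
    """
    if not 0.0 < min_support <= 1.0:
        raise ValueError("min_support must lie in (0, 1]")
    if len(graphs) == 0:
        raise ValueError("empty dataset")
    dense = [_from_networkx(g)[0] for g in graphs]
    min_count = max(1, math.ceil(min_support * len(graphs) - 1e-9))
    results: List[MinedPattern] = []

    def recurse(code: DFSCode, embeddings: List[_Embedding]) -> None:
        if not is_min(code):
            return
        gids = tuple(sorted({gid for gid, _, _ in embeddings}))
        results.append(MinedPattern(code, len(gids), gids))
        exts = _extensions(code, embeddings, dense, max_pattern_nodes)
        for ext in sorted(exts, key=_EDGE_KEY):
            embs = exts[ext]
            if len({gid for gid, _, _ in embs}) >= min_count:
                recurse(code + (ext,), embs)

    init = _initial_embeddings(dense)
    for ext in sorted(init, key=_EDGE_KEY):
        embs = init[ext]
        if len({gid for gid, _, _ in embs}) >= min_count:
            recurse((ext,), embs)
    return results
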