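"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: frequent-subgraph
counts come from exhaustive connected-edge-subset enumeration grouped by
isomorphism, and pattern mappings from a plain recursive injective-map
search.  Both stay feasible only on the tiny instances the tests use.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Dict, FrozenSet, List, Mapping, Sequence, Tuple

import networkx as nx
import numpy as np


def random_labeled_graph(rng: np.random.Generator, n_nodes: int,
                         extra_edges: int, node_labels: Sequence[str],
                         edge_labels: Sequence[str]) -> nx.Graph:
    """Connected random graph with string labels (attrs ``label``)."""
    g = nx.Graph()
    for i in range(n_nodes):
        g.add_node(i, label=str(node_labels[rng.integers(len(node_labels))]))
    for i in range(1, n_nodes):
        j = int(rng.integers(i))
        g.add_edge(i, j, label=str(edge_labels[rng.integers(len(edge_labels))]))
    for _ in range(extra_edges):
        i, j = rng.choice(n_nodes, size=2, replace=False)
        if not g.has_edge(int(i), int(j)):
            g.add_edge(int(i), int(j),
                       label=str(edge_labels[rng.integers(len(edge_labels))]))
    return g


def _iso(a: nx.Graph, b: nx.Graph) -> bool:
    return nx.is_isomorphic(
        a, b,
        node_match=lambda x, y: x["label"] == y["label"],
        edge_match=lambda x, y: x["label"] == y["label"])


def connected_edge_subgraphs(g: nx.Graph) -> List[nx.Graph]:
    """All connected subgraphs of g induced by non-empty edge subsets."""
    edges = list(g.edges())
    out: List[nx.Graph] = []
    for r in range(1, len(edges) + 1):
        for subset in combinations(edges, r):
            h = nx.Graph()
            for u, v in subset:
                h.add_node(u, label=g.nodes[u]["label"])
                h.add_node(v, label=g.nodes[v]["label"])
                h.add_edge(u, v, label=g.edges[u, v]["label"])
            if nx.is_connected(h):
                out.append(h)
    return out


def enumerate_frequent(graphs: Sequence[nx.Graph], min_support: float
                       ) -> List[Tuple[nx.Graph, int]]:
    """(representative graph, support count) for every frequent pattern class."""
    classes: List[Tuple[nx.Graph, set]] = []  # representative, set of gids
    for gid, g in enumerate(graphs):
        seen_here: List[nx.Graph] = []
        for h in connected_edge_subgraphs(g):
            if any(_iso(h, s) for s in seen_here):
                continue
            seen_here.append(h)
            for rep, gids in classes:
                if _iso(h, rep):
                    gids.add(gid)
                    break
            else:
                classes.append((h, {gid}))
    threshold = max(1, math.ceil(min_support * len(graphs) - 1e-9))
    return [(rep, len(gids)) for rep, gids in classes if len(gids) >= threshold]


def _compatible(a: FrozenSet[str], b: FrozenSet[str]) -> bool:
    return a <= b or b <= a


def brute_force_mappings(
    pattern: nx.Graph,
    display: Mapping[object, FrozenSet[str]],
    target: nx.Graph,
) -> List[Dict[object, object]]:
    """All injective label-compatible embeddings of pattern into target.

    Node labels use the subset rule on ``display`` (pattern side) vs the
    target's ``labels`` attribute; edge label sets likewise.
    """
    pnodes = sorted(pattern.nodes, key=repr)
    tnodes = sorted(target.nodes, key=repr)
    results: List[Dict[object, object]] = []

    def extend(i: int, assignment: Dict[object, object]) -> None:
        if i == len(pnodes):
            results.append(dict(assignment))
            return
        v = pnodes[i]
        for t in tnodes:
            if t in assignment.values():
                continue
            if not _compatible(frozenset(display[v]),
                               frozenset(target.nodes[t]["labels"])):
                continue
            ok = True
            for w in pattern.neighbors(v):
                if w not in assignment:
                    continue
                if not target.has_edge(t, assignment[w]):
                    ok = False
                    break
                if not _compatible(frozenset(pattern.edges[v, w]["types"]),
                                   frozenset(target.edges[t, assignment[w]]["types"])):
                    ok = False
                    break
            if ok:
                assignment[v] = t
                extend(i + 1, assignment)
                del assignment[v]

    extend(0, {})
    return results


def best_rank_d_error(X: np.ndarray, d: int) -> float:
    """Frobenius error of the best rank-d approximation via eig of X^T X."""
    gram = X.T @ X
    evals = np.linalg.eigvalsh(gram)[::-1]
    evals = np.clip(evals, 0.0, None)
    return float(np.sqrt(evals[d:].sum()))


def rank_for_variance(X: np.ndarray, threshold: float) -> int:
    """Smallest d retaining ``threshold`` of variance, via eig of X^T X."""
    gram = X.T @ X
    evals = np.sort(np.clip(np.linalg.eigvalsh(gram), 0.0, None))[::-1]
    evals = evals[evals > evals[0] * 1e-12]
    frac = np.cumsum(evals) / evals.sum()
    return int(np.searchsorted(frac, threshold - 1e-12) + 1)
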