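"""Serialization of graphs, patterns and mappings.

Interface graph datasets travel as JSON node-link files (atom provenance,
label lists, typed edges with distances) with a GraphML twin for graph
tools; patterns and mappings as JSON; matrices and reports as CSV.  All
writers sort keys so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence

import networkx as nx

from .interface import AtomRecord
from .mining import FrequentPattern
from .mapping import PatternMapping
from . import gspan


def _record_dict(rec: AtomRecord) -> dict:
    return {
        "complex_id": rec.complex_id,
        "chain_id": rec.chain_id,
        "residue_name": rec.residue_name,
        "residue_number": rec.residue_number,
        "insertion_code": rec.insertion_code,
        "atom_name": rec.atom_name,
        "element": rec.element,
        "position": list(rec.position),
        "side": rec.side,
    }


def _record_from_dict(d: dict) -> AtomRecord:
    return AtomRecord(
        complex_id=d["complex_id"], chain_id=d["chain_id"],
        residue_name=d["residue_name"], residue_number=d["residue_number"],
        insertion_code=d.get("insertion_code", ""), atom_name=d["atom_name"],
        element=d.get("element", ""), position=tuple(d["position"]),
        side=d["side"],
    )


def graph_to_json_obj(g: nx.MultiGraph | nx.Graph) -> dict:
    nodes = []
    keys = sorted(g.nodes, key=repr)
    index = {k: i for i, k in enumerate(keys)}
    for k in keys:
        data = g.nodes[k]
        nd = {"id": index[k], "labels": sorted(data["labels"])}
        if "record" in data:
            nd["atom"] = _record_dict(data["record"])
        else:
            nd["name"] = str(k)
        nodes.append(nd)
    edges = []
    for u, v, data in g.edges(data=True):
        e = {"source": index[u], "target": index[v]}
        if "interaction_type" in data:
            e["type"] = data["interaction_type"]
        elif "types" in data:
            e["types"] = sorted(data["types"])
        if "distance" in data:
            e["distance"] = round(float(data["distance"]), 4)
        edges.append(e)
    edges.sort(key=lambda e: (e["source"], e["target"],
                              e.get("type", "/".join(e.get("types", [])))))
    return {
        "graph_id": str(g.graph.get("graph_id", "")),
        "complex_id": g.graph.get("complex_id", ""),
        "component_index": g.graph.get("component_index", 0),
        "nodes": nodes,
        "edges": edges,
    }


def graph_from_json_obj(obj: dict, multigraph: bool = True) -> nx.Graph:
    g: nx.Graph = nx.MultiGraph() if multigraph else nx.Graph()
    g.graph["graph_id"] = obj.get("graph_id", "")
    g.graph["complex_id"] = obj.get("complex_id", "")
    g.graph["component_index"] = obj.get("component_index", 0)
    id_to_key: Dict[int, object] = {}
    for nd in obj["nodes"]:
        if "atom" in nd:
            rec = _record_from_dict(nd["atom"])
            key = rec.key
            g.add_node(key, record=rec, labels=frozenset(nd["labels"]), side=rec.side)
        else:
            key = nd.get("name", nd["id"])
            g.add_node(key, labels=frozenset(nd["labels"]))
        id_to_key[nd["id"]] = key
    for e in obj["edges"]:
        u, v = id_to_key[e["source"]], id_to_key[e["target"]]
        attrs = {}
        if "type" in e:
            attrs["interaction_type"] = e["type"]
        if "types" in e:
            attrs["types"] = frozenset(e["types"])
        if "distance" in e:
            attrs["distance"] = e["distance"]
        if multigraph and "type" in e:
            g.add_edge(u, v, key=e["type"], **attrs)
        else:
            g.add_edge(u, v, **attrs)
    return g


def write_dataset_json(graphs: Sequence[nx.Graph], path: str | Path) -> None:
    obj = {"graphs": [graph_to_json_obj(g) for g in graphs]}
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def read_dataset_json(path: str | Path, multigraph: bool = True) -> List[nx.Graph]:
    obj = json.loads(Path(path).read_text())
    return [graph_from_json_obj(o, multigraph=multigraph) for o in obj["graphs"]]


def write_dataset_graphml(graphs: Sequence[nx.Graph], directory: str | Path) -> List[Path]:
    """One GraphML file per graph (attributes flattened to strings)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for g in graphs:
        h = nx.MultiGraph() if g.is_multigraph() else nx.Graph()
        for k, data in g.nodes(data=True):
            attrs = {"labels": "/".join(sorted(data["labels"]))}
            if "record" in data:
                rec = data["record"]
                attrs.update(chain=rec.chain_id, residue=rec.residue_name,
                             residue_number=rec.residue_number,
                             atom=rec.atom_name, side=rec.side)
            h.add_node(repr(k), **attrs)
        for u, v, data in g.edges(data=True):
            attrs = {}
            if "interaction_type" in data:
                attrs["type"] = data["interaction_type"]
            if "types" in data:
                attrs["type"] = "/".join(sorted(data["types"]))
            if "distance" in data:
                attrs["distance"] = float(data["distance"])
            h.add_edge(repr(u), repr(v), **attrs)
        gid = str(g.graph.get("graph_id", len(written)))
        out = directory / f"{gid}.graphml"
        nx.write_graphml(h, out)
        written.append(out)
    return written


def pattern_to_json_obj(p: FrequentPattern, pattern_id: str) -> dict:
    return {
        "pattern_id": pattern_id,
        "dfs_code": [[i, j, list(labels)] for i, j, labels in p.dfs_code],
        "nodes": [
            {"id": v, "labels": sorted(p.graph.nodes[v]["labels"]),
             "display_labels": sorted(p.display_labels.get(v, p.graph.nodes[v]["labels"]))}
            for v in sorted(p.graph.nodes)
        ],
        "edges": [
            {"source": u, "target": v, "types": sorted(d["types"])}
            for u, v, d in sorted(p.graph.edges(data=True), key=lambda e: (e[0], e[1]))
        ],
        "support_count": p.support_count,
        "support_fraction": round(p.support_fraction, 6),
        "occurrence_graph_ids": list(p.occurrence_graph_ids),
        "is_maximal": p.is_maximal,
    }


def pattern_from_json_obj(obj: dict) -> FrequentPattern:
    g = nx.Graph()
    display = {}
    for nd in obj["nodes"]:
        labs = frozenset(nd["labels"])
        g.add_node(nd["id"], labels=labs, label="/".join(sorted(labs)))
        display[nd["id"]] = frozenset(nd["display_labels"])
    for e in obj["edges"]:
        types = frozenset(e["types"])
        g.add_edge(e["source"], e["target"], types=types,
                   label="/".join(sorted(types)))
    code = tuple((i, j, tuple(labels)) for i, j, labels in obj["dfs_code"])
    return FrequentPattern(
        graph=g, dfs_code=code, support_count=obj["support_count"],
        support_fraction=obj["support_fraction"],
        occurrence_graph_ids=tuple(obj["occurrence_graph_ids"]),
        is_maximal=obj["is_maximal"], display_labels=display,
    )


def write_patterns_json(patterns: Sequence[FrequentPattern], path: str | Path,
                        pattern_ids: Sequence[str] | None = None) -> None:
    ids = list(pattern_ids) if pattern_ids else [f"p{i}" for i in range(len(patterns))]
    obj = {"patterns": [pattern_to_json_obj(p, pid) for pid, p in zip(ids, patterns)]}
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def read_patterns_json(path: str | Path) -> Dict[str, FrequentPattern]:
    obj = json.loads(Path(path).read_text())
    return {o["pattern_id"]: pattern_from_json_obj(o) for o in obj["patterns"]}


def write_mappings_json(mappings: Sequence[PatternMapping], path: str | Path) -> None:
    obj = {
        "mappings": [
            {
                "pattern_id": m.pattern_id,
                "graph_id": m.graph_id,
                "node_map": [[pn, repr(tn)] for pn, tn in m.node_map],
                "edge_map": [[list(map(repr, pe)), list(map(repr, te))]
                             for pe, te in m.edge_map],
            }
            for m in mappings
        ]
    }
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
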