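"""Precision/recall of mined patterns against literature reference items.

A pattern is *relevant* when it matches at least one reference item.  Two
kinds of item are supported: a residue item (e.g. "the reactive serine,
SER195") matches when any atom-level mapping of the pattern touches one of
the listed residues; a micro-structure item (e.g. the two-donor/one-acceptor
oxyanion-hole arrangement) matches when its small labeled graph embeds in
the pattern under the same subset-label compatibility used by the mapper.

Per clustering group: precision = relevant patterns / patterns and
recall = matched reference ids / reference ids.  The overall row pools
patterns across groups for precision; overall recall counts reference ids
matched anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd
import yaml

from .labels import as_label_set, labels_compatible
from .mining import FrequentPattern

ResidueTuple = Tuple[str, str, str, str, int, str]  # complex, chain, side, name, number, icode


@dataclass(frozen=True)
class ResidueSpec:
    """One acceptable residue for a reference item (author numbering)."""

    res_name: str
    res_number: int
    side: Optional[str] = None        # restrict to chain group "P" or "I"
    chain_id: Optional[str] = None
    complex_id: Optional[str] = None

    def matches(self, touched: ResidueTuple) -> bool:
        complex_id, chain_id, side, name, number, _ = touched
        if name.upper() != self.res_name.upper() or number != self.res_number:
            return False
        if self.side is not None and side != self.side:
            return False
        if self.chain_id is not None and chain_id != self.chain_id:
            return False
        if self.complex_id is not None and complex_id != self.complex_id:
            return False
        return True


@dataclass(frozen=True)
class ReferenceItem:
    """A literature-derived relevant residue (or set of alternatives) or motif."""

    item_id: str
    residues: Tuple[ResidueSpec, ...] = ()
    structure: Optional[nx.Graph] = None   # nodes: labels sets; edges: types sets

    def __post_init__(self) -> None:
        if not self.residues and self.structure is None:
            raise ValueError(f"reference item {self.item_id!r} has no rule")


def _structure_matches(rule: nx.Graph, p: FrequentPattern) -> bool:
    display = p.display_labels or {v: p.graph.nodes[v]["labels"] for v in p.graph.nodes}

    def node_match(pattern_attrs, rule_attrs):
        return labels_compatible(rule_attrs["labels"], pattern_attrs["_display"])

    def edge_match(pattern_attrs, rule_attrs):
        return labels_compatible(rule_attrs["types"], pattern_attrs["types"])

    work = p.graph.copy()
    for v in work.nodes:
        work.nodes[v]["_display"] = display[v]
    gm = nx.algorithms.isomorphism.GraphMatcher(
        work, rule, node_match=node_match, edge_match=edge_match)
    return any(True for _ in gm.subgraph_monomorphisms_iter())


def pattern_relevant(
    p: FrequentPattern,
    touched_residues: Set[ResidueTuple],
    reference: Sequence[ReferenceItem],
) -> Set[str]:
    """Ids of the reference items matched by one pattern."""
    if len(reference) == 0:
        raise ValueError("empty reference set")
    matched: Set[str] = set()
    for item in reference:
        if any(spec.matches(t) for spec in item.residues for t in touched_residues):
            matched.add(item.item_id)
            continue
        if item.structure is not None and _structure_matches(item.structure, p):
            matched.add(item.item_id)
    return matched


@dataclass
class GroupEvaluation:
    group_id: str
    patterns: List[FrequentPattern]
    touched: List[Set[ResidueTuple]] = field(default_factory=list)


def precision_recall(
    groups: Mapping[str, Tuple[Sequence[FrequentPattern], Sequence[Set[ResidueTuple]]]],
    reference: Sequence[ReferenceItem],
) -> pd.DataFrame:
    """Per-group and overall precision/recall table.

    ``groups`` maps group id to (patterns, per-pattern touched-residue sets).
    Values are rounded to 2 decimals in the returned report.
    """
    if not groups:
        raise ValueError("no groups to evaluate")
    if not any(len(pats) for pats, _ in groups.values()):
        raise ValueError("no patterns in any group")
    n_ref = len(reference)
    if n_ref == 0:
        raise ValueError("empty reference set")

    rows = []
    total_patterns = 0
    total_relevant = 0
    all_matched: Set[str] = set()
    for gid in sorted(groups, key=str):
        patterns, touched = groups[gid]
        if len(patterns) != len(touched):
            raise ValueError(f"group {gid}: patterns and touched sets differ in length")
        matched_here: Set[str] = set()
        relevant = 0
        for p, t in zip(patterns, touched):
            ids = pattern_relevant(p, t, reference)
            if ids:
                relevant += 1
                matched_here |= ids
        n = len(patterns)
        rows.append({
            "group": str(gid),
            "patterns": n,
            "precision": round(relevant / n, 2) if n else 0.0,
            "recall": round(len(matched_here) / n_ref, 2),
            "residues": ",".join(sorted(matched_here)),
        })
        total_patterns += n
        total_relevant += relevant
        all_matched |= matched_here

    rows.append({
        "group": "All",
        "patterns": total_patterns,
        "precision": round(total_relevant / total_patterns, 2),
        "recall": round(len(all_matched) / n_ref, 2),
        "residues": ",".join(sorted(all_matched)),
    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reference file parsing
# ---------------------------------------------------------------------------

def load_reference_items(path: str) -> List[ReferenceItem]:
    """Read reference items from a YAML file.

    Layout::

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
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    items: List[ReferenceItem] = []
    seen = set()
    for entry in raw["items"]:
        item_id = str(entry["id"])
        if item_id in seen:
            raise ValueError(f"duplicate reference item id {item_id!r}")
        seen.add(item_id)
        residues = tuple(
            ResidueSpec(
                res_name=str(r["res_name"]),
                res_number=int(r["res_number"]),
                side=r.get("side"),
                chain_id=r.get("chain_id"),
                complex_id=r.get("complex_id"),
            )
            for r in entry.get("residues", [])
        )
        structure = None
        if "structure" in entry:
            structure = nx.Graph()
            for nd in entry["structure"]["nodes"]:
                structure.add_node(nd["id"], labels=as_label_set(nd["labels"]))
            for ed in entry["structure"]["edges"]:
                structure.add_edge(ed["u"], ed["v"], types=frozenset(ed["types"]))
        items.append(ReferenceItem(item_id=item_id, residues=residues, structure=structure))
    return items
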