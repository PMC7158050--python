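"""Interface contact graphs.

Builds labeled bipartite multigraphs from protein-protein complexes: parse a
PDB file, assign physicochemical labels to heavy atoms of the two chain
groups, compute cross-chain atomic contacts under per-type distance windows,
prune node labels to those exercised by at least one contact, and split the
resulting multigraph into connected components.  One connected component is
one graph of the mining dataset.

Contact model: atoms *i*, *j* on opposite sides of the interface are in
contact when their Euclidean distance falls inside the closed window of an
interaction type whose endpoint-label condition they satisfy:

=================  =========================  =====  =====
interaction        endpoint condition          min Å  max Å
=================  =========================  =====  =====
aromatic_stacking  two aromatic atoms          1.5    3.5
hydrogen_bond      one acceptor + one donor    2.0    3.0
hydrophobic        two hydrophobic atoms       2.0    3.8
repulsive          two like charges            2.0    6.0
salt_bridge        two opposite charges        2.0    6.0
=================  =========================  =====  =====

A single atom pair may satisfy several types at once (e.g. a carboxylate
oxygen against a guanidinium nitrogen at 2.8 Å forms both a hydrogen bond
and a salt bridge), hence the multigraph.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import yaml
from scipy.spatial import cKDTree

from .labels import CHARGES, OPPOSITE_CHARGE, LabelSet, as_label_set

logger = logging.getLogger(__name__)

#: the five interaction types, in canonical order
INTERACTION_TYPES = (
    "aromatic_stacking",
    "hydrogen_bond",
    "hydrophobic",
    "repulsive",
    "salt_bridge",
)

AtomKey = Tuple[str, str, int, str, str]  # complex, chain, resnum, icode, atom


@dataclass(frozen=True)
class AtomRecord:
    """A typed heavy atom with provenance and interface side (P or I)."""

    complex_id: str
    chain_id: str
    residue_name: str
    residue_number: int
    atom_name: str
    element: str
    position: Tuple[float, float, float]
    side: str  # "P" or "I"
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if self.side not in ("P", "I"):
            raise ValueError(f"side must be 'P' or 'I', got {self.side!r}")
        if not all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")

    @property
    def key(self) -> AtomKey:
        return (
            self.complex_id,
            self.chain_id,
            self.residue_number,
            self.insertion_code,
            self.atom_name,
        )

    @property
    def residue_id(self) -> Tuple[str, str, int, str]:
        return (self.complex_id, self.chain_id, self.residue_number, self.insertion_code)


@dataclass(frozen=True)
class TypeCriterion:
    """Distance window (closed) for one interaction type."""

    min_dist: float
    max_dist: float

    def __post_init__(self) -> None:
        if not self.min_dist < self.max_dist:
            raise ValueError("min distance must be below max distance")

    def contains(self, d: float) -> bool:
        return self.min_dist <= d <= self.max_dist


@dataclass(frozen=True)
class ContactCriteria:
    """Per-type distance windows; defaults are the standard cutoffs above."""

    windows: Mapping[str, TypeCriterion] = field(
        default_factory=lambda: {
            "aromatic_stacking": TypeCriterion(1.5, 3.5),
            "hydrogen_bond": TypeCriterion(2.0, 3.0),
            "hydrophobic": TypeCriterion(2.0, 3.8),
            "repulsive": TypeCriterion(2.0, 6.0),
            "salt_bridge": TypeCriterion(2.0, 6.0),
        }
    )

    def __post_init__(self) -> None:
        missing = set(INTERACTION_TYPES) - set(self.windows)
        if missing:
            raise ValueError(f"criteria missing interaction types: {sorted(missing)}")

    @property
    def max_cutoff(self) -> float:
        return max(w.max_dist for w in self.windows.values())

    def with_overrides(self, overrides: Mapping[str, Tuple[float, float]]) -> "ContactCriteria":
        windows = dict(self.windows)
        for t, (lo, hi) in overrides.items():
            if t not in INTERACTION_TYPES:
                raise ValueError(f"unknown interaction type {t!r}")
            windows[t] = TypeCriterion(float(lo), float(hi))
        return ContactCriteria(windows)


@dataclass(frozen=True)
class InteractionEdge:
    """One typed contact between atoms on opposite interface sides."""

    a: AtomRecord
    b: AtomRecord
    interaction_type: str
    distance: float


class PDBParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# atom typing
# ---------------------------------------------------------------------------

TypingTable = Dict[Tuple[str, str], LabelSet]


def load_typing_table(path: Optional[str] = None) -> TypingTable:
    """Load the (residue, atom) -> label-set map.

    Reads the packaged default table unless ``path`` points at a user table
    with the same layout (``backbone`` defaults plus per-residue entries that
    may override them).
    """
    if path is None:
        text = resources.files("ifacemine.data").joinpath("atom_types.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    backbone = {a: raw.get("backbone", {}).get(a, []) for a in raw.get("backbone", {})}
    table: TypingTable = {}
    for res, atoms in raw["residues"].items():
        merged = dict(backbone)
        merged.update(atoms or {})
        for atom, labs in merged.items():
            table[(res.upper(), atom.upper())] = as_label_set(labs or [])
    return table


def assign_atom_labels(atom: AtomRecord, typing_table: TypingTable) -> LabelSet:
    """Full (pre-pruning) label set for an atom; empty set if untyped."""
    labels = typing_table.get((atom.residue_name.upper(), atom.atom_name.upper()))
    if labels is None:
        logger.warning(
            "atom %s %s/%s%s not in typing table; it will carry no labels",
            atom.residue_name, atom.chain_id, atom.residue_number, atom.atom_name,
        )
        return frozenset()
    return labels


# ---------------------------------------------------------------------------
# structure parsing
# ---------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def parse_structure(
    pdb_text: str,
    chain_groups: Tuple[Iterable[str], Iterable[str]],
    complex_id: str = "complex",
    include_hetatm: bool = False,
) -> List[AtomRecord]:
    """Parse PDB-format text into side-tagged heavy-atom records.

    ``chain_groups`` is a pair of disjoint chain-id sets: the first group is
    tagged side ``P``, the second side ``I``.  Hydrogens, waters and (by
    default) HETATM ligands are dropped; only the first model of multi-model
    files is read; for disordered atoms the highest-occupancy altloc is kept.
    """
    from Bio.PDB import PDBParser

    group_p, group_i = (set(chain_groups[0]), set(chain_groups[1]))
    if not group_p or not group_i:
        raise ValueError("both chain groups must be non-empty")
    if group_p & group_i:
        raise ValueError(f"chain groups must be disjoint; both contain {sorted(group_p & group_i)}")

    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(complex_id, io.StringIO(pdb_text))
    except Exception as exc:  # Bio.PDB raises assorted exceptions on bad input
        raise PDBParseError(f"malformed PDB content: {exc}") from exc
    models = list(structure)
    if not models:
        raise PDBParseError("no models found in PDB content")
    model = models[0]

    available = {ch.id for ch in model}
    missing = (group_p | group_i) - available
    if missing:
        raise ValueError(
            f"chains {sorted(missing)} not present; available chains: {sorted(available)}"
        )

    # disordered atoms appear once per altloc in the unpacked list; keep the
    # highest-occupancy copy per atom key
    deduped: Dict[AtomKey, AtomRecord] = {}
    occ_of: Dict[AtomKey, float] = {}
    for chain in model:
        if chain.id in group_p:
            side = "P"
        elif chain.id in group_i:
            side = "I"
        else:
            continue
        for residue in chain:
            hetflag, resseq, icode = residue.id
            resname = residue.get_resname().strip()
            if resname in _WATER_NAMES:
                continue
            if hetflag.strip() and not include_hetatm:
                continue
            for atom in residue.get_unpacked_list():
                if atom.element == "H" or atom.get_name().startswith("H"):
                    continue
                rec = AtomRecord(
                    complex_id=complex_id,
                    chain_id=chain.id,
                    residue_name=resname,
                    residue_number=int(resseq),
                    atom_name=atom.get_name(),
                    element=atom.element or "",
                    position=tuple(float(x) for x in atom.get_coord()),
                    side=side,
                    insertion_code=icode.strip(),
                )
                occ = atom.get_occupancy()
                occ = 1.0 if occ is None else float(occ)
                if rec.key not in deduped or occ > occ_of[rec.key]:
                    deduped[rec.key] = rec
                    occ_of[rec.key] = occ
    return list(deduped.values())


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def _type_satisfied(t: str, la: LabelSet, lb: LabelSet) -> bool:
    if t == "aromatic_stacking":
        return "AR" in la and "AR" in lb
    if t == "hydrogen_bond":
        return ("AC" in la and "DN" in lb) or ("DN" in la and "AC" in lb)
    if t == "hydrophobic":
        return "HB" in la and "HB" in lb
    if t == "repulsive":
        return any(c in la and c in lb for c in CHARGES)
    if t == "salt_bridge":
        return any(c in la and OPPOSITE_CHARGE[c] in lb for c in CHARGES)
    raise ValueError(f"unknown interaction type {t!r}")


def compute_contacts(
    atoms: Sequence[AtomRecord],
    labels: Mapping[AtomKey, LabelSet],
    criteria: Optional[ContactCriteria] = None,
) -> List[InteractionEdge]:
    """All typed cross-side contacts among ``atoms``.

    Emits at most one edge per (unordered atom pair, interaction type); a
    pair may yield several edges of different types.  Unlabeled atoms cannot
    satisfy any condition and contribute nothing.
    """
    criteria = criteria or ContactCriteria()
    p_atoms = [a for a in atoms if a.side == "P"]
    i_atoms = [a for a in atoms if a.side == "I"]
    if not p_atoms or not i_atoms:
        return []

    p_xyz = np.array([a.position for a in p_atoms])
    i_xyz = np.array([a.position for a in i_atoms])
    tree = cKDTree(i_xyz)
    pairs = tree.query_ball_point(p_xyz, r=criteria.max_cutoff)

    edges: List[InteractionEdge] = []
    for pi, neighbors in enumerate(pairs):
        a = p_atoms[pi]
        la = labels.get(a.key, frozenset())
        if not la:
            continue
        for ii in sorted(neighbors):
            b = i_atoms[ii]
            lb = labels.get(b.key, frozenset())
            if not lb:
                continue
            d = float(np.linalg.norm(p_xyz[pi] - i_xyz[ii]))
            for t in INTERACTION_TYPES:
                if criteria.windows[t].contains(d) and _type_satisfied(t, la, lb):
                    edges.append(InteractionEdge(a, b, t, d))
    return edges


# ---------------------------------------------------------------------------
# multigraph construction
# ---------------------------------------------------------------------------

def _exercised_labels(own: LabelSet, partner: LabelSet, t: str) -> LabelSet:
    """Labels of ``own`` that this edge type actually uses against ``partner``."""
    used: Set[str] = set()
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
        for c in CHARGES:
            if c in own and OPPOSITE_CHARGE[c] in partner:
                used.add(c)
    elif t == "repulsive":
        for c in CHARGES:
            if c in own and c in partner:
                used.add(c)
    return frozenset(used)


def build_interface_multigraph(
    atoms: Sequence[AtomRecord],
    edges: Sequence[InteractionEdge],
    labels: Mapping[AtomKey, LabelSet],
) -> nx.MultiGraph:
    """Bipartite labeled multigraph over the atoms that participate in contacts.

    Nodes are atom keys carrying the :class:`AtomRecord` and the *retained*
    label set: only labels exercised by at least one incident edge survive.
    Atoms with no contacts are dropped.
    """
    retained: Dict[AtomKey, Set[str]] = {}
    for e in edges:
        la = labels.get(e.a.key, frozenset())
        lb = labels.get(e.b.key, frozenset())
        retained.setdefault(e.a.key, set()).update(_exercised_labels(la, lb, e.interaction_type))
        retained.setdefault(e.b.key, set()).update(_exercised_labels(lb, la, e.interaction_type))

    by_key = {a.key: a for a in atoms}
    g = nx.MultiGraph()
    for key, labs in retained.items():
        rec = by_key[key]
        g.add_node(key, record=rec, labels=frozenset(labs), side=rec.side)
    for e in edges:
        g.add_edge(e.a.key, e.b.key, key=e.interaction_type,
                   interaction_type=e.interaction_type, distance=e.distance)
    assert nx.is_bipartite(g) or g.number_of_nodes() == 0
    return g


def extract_components(g: nx.MultiGraph) -> List[nx.MultiGraph]:
    """Connected components as independent graphs, ordered by smallest atom key."""
    comps = [g.subgraph(c).copy() for c in nx.connected_components(g)]
    comps.sort(key=lambda sg: min(sg.nodes))
    for i, sg in enumerate(comps):
        sg.graph["component_index"] = i
    return comps


def build_component_graphs(
    pdb_text: str,
    chain_groups: Tuple[Iterable[str], Iterable[str]],
    complex_id: str = "complex",
    criteria: Optional[ContactCriteria] = None,
    typing_table: Optional[TypingTable] = None,
) -> List[nx.MultiGraph]:
    """Full front-end: parse, label, contact, build and split one complex."""
    table = typing_table if typing_table is not None else load_typing_table()
    atoms = parse_structure(pdb_text, chain_groups, complex_id=complex_id)
    labels = {a.key: assign_atom_labels(a, table) for a in atoms}
    edges = compute_contacts(atoms, labels, criteria)
    g = build_interface_multigraph(atoms, edges, labels)
    comps = extract_components(g)
    for sg in comps:
        sg.graph["complex_id"] = complex_id
    return comps
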