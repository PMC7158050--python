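"""Deterministic synthetic fixtures for every pipeline stage.

Two generators, both fully seeded:

* :func:`generate_complex_fixture` writes PDB-format toy complexes with
  cross-chain atom pairs planted at exact distances inside the contact
  windows, plus decoy atoms placed beyond the largest cutoff, so the
  interface stage can be checked against known ground truth.  Geometry is a
  jittered lattice of isolated residue pairs; no physical plausibility
  (torsions, clashes) is claimed or needed.

* :func:`generate_graph_dataset` builds random labeled simple graphs with a
  connected motif embedded verbatim in a chosen fraction of them, rejection
  -sampling the noise so no accidental motif copy appears, which pins the
  motif's mining support to the planted fraction by construction.

A small Gaussian-block matrix generator for the clustering stage lives here
as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .interface import (
    INTERACTION_TYPES,
    AtomRecord,
    ContactCriteria,
    TypingTable,
    _type_satisfied,
    load_typing_table,
)
from .labels import as_label_set, canonical_label
from .mining import type_set_label

# ---------------------------------------------------------------------------
# PDB complex fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedContact:
    """A cross-chain atom pair placed at an exact distance.

    ``interaction_type`` None marks a near-miss decoy pair expected to
    produce no edge at all.
    """

    res_a: Tuple[str, str]      # (residue name, atom name) on chain group P
    res_b: Tuple[str, str]      # on chain group I
    interaction_type: Optional[str]
    distance: float


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    planted: Tuple[PlantedContact, ...] = (
        PlantedContact(("ASP", "OD1"), ("ARG", "NH1"), "salt_bridge", 4.0),
        PlantedContact(("SER", "OG"), ("GLY", "N"), "hydrogen_bond", 2.8),
        PlantedContact(("LEU", "CD1"), ("VAL", "CG1"), "hydrophobic", 3.5),
    )
    decoys_per_chain: int = 4
    complex_id: str = "fixture"
    chain_p: str = "A"
    chain_i: str = "B"
    pair_spacing: float = 25.0
    jitter: float = 0.5


def _expected_types(labels_a: FrozenSet[str], labels_b: FrozenSet[str],
                    distance: float, criteria: ContactCriteria) -> List[str]:
    return [t for t in INTERACTION_TYPES
            if criteria.windows[t].contains(distance)
            and _type_satisfied(t, labels_a, labels_b)]


def _pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                   resseq: int, xyz: Sequence[float], element: str) -> str:
    pad_name = f" {name:<3s}" if len(name) < 4 else name
    return (f"ATOM  {serial:5d} {pad_name:<4s} {resname:<3s} {chain}{resseq:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2s}")


def generate_complex_fixture(
    spec: FixtureSpec,
    criteria: Optional[ContactCriteria] = None,
    typing_table: Optional[TypingTable] = None,
) -> Tuple[str, dict]:
    """PDB text for one toy complex plus its ground-truth manifest.

    Each planted pair occupies its own lattice cell, far from every other
    pair, so running the interface stage over the output yields exactly the
    manifest's edges.  Returns ``(pdb_text, manifest)``.
    """
    criteria = criteria or ContactCriteria()
    table = typing_table if typing_table is not None else load_typing_table()
    rng = np.random.default_rng(spec.seed)
    cutoff = criteria.max_cutoff

    lines: List[str] = []
    serial = 0
    manifest_edges = []
    chain_b_atoms: List[dict] = []

    for i, pc in enumerate(spec.planted):
        la = table.get((pc.res_a[0], pc.res_a[1]))
        lb = table.get((pc.res_b[0], pc.res_b[1]))
        if la is None or lb is None:
            raise ValueError(f"planted atom not in typing table: {pc}")
        types = _expected_types(la, lb, pc.distance, criteria)
        if pc.interaction_type is None:
            if types:
                raise ValueError(
                    f"near-miss pair {pc} unexpectedly satisfies {types}")
        else:
            win = criteria.windows[pc.interaction_type]
            if not win.min_dist < pc.distance < win.max_dist:
                raise ValueError(
                    f"planted distance {pc.distance} outside the open window "
                    f"({win.min_dist}, {win.max_dist}) of {pc.interaction_type}")
            if pc.interaction_type not in types:
                raise ValueError(
                    f"labels of {pc} do not satisfy {pc.interaction_type}")

        base = np.array([i * spec.pair_spacing, 0.0, 0.0])
        base += rng.uniform(-spec.jitter, spec.jitter, size=3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos_a = base
        pos_b = base + pc.distance * direction

        serial += 1
        lines.append(_pdb_atom_line(serial, pc.res_a[1], pc.res_a[0],
                                    spec.chain_p, i + 1, pos_a, pc.res_a[1][0]))
        chain_b_atoms.append(dict(name=pc.res_b[1], resname=pc.res_b[0],
                                  resseq=i + 1, xyz=pos_b))
        manifest_edges.extend(
            {
                "a": [spec.complex_id, spec.chain_p, i + 1, "", pc.res_a[1]],
                "b": [spec.complex_id, spec.chain_i, i + 1, "", pc.res_b[1]],
                "type": t,
                "distance": pc.distance,
            }
            for t in types
        )

    # decoys: labeled atoms far (> cutoff) from everything on the other side
    n_pairs = max(1, len(spec.planted))
    for j in range(spec.decoys_per_chain):
        x = (j % n_pairs) * spec.pair_spacing + float(rng.uniform(-spec.jitter, spec.jitter))
        y_off = 40.0 + 10.0 * (j // n_pairs)
        serial += 1
        lines.append(_pdb_atom_line(serial, "CA", "GLY", spec.chain_p,
                                    100 + j, (x, y_off, 0.0), "C"))
    for entry in chain_b_atoms:
        serial += 1
        lines.append(_pdb_atom_line(serial, entry["name"], entry["resname"],
                                    spec.chain_i, entry["resseq"], entry["xyz"],
                                    entry["name"][0]))
    for j in range(spec.decoys_per_chain):
        x = (j % n_pairs) * spec.pair_spacing + float(rng.uniform(-spec.jitter, spec.jitter))
        y_off = -(40.0 + 10.0 * (j // n_pairs))
        serial += 1
        lines.append(_pdb_atom_line(serial, "CA", "GLY", spec.chain_i,
                                    100 + j, (x, y_off, 0.0), "C"))
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    manifest = {
        "complex_id": spec.complex_id,
        "chain_groups": [[spec.chain_p], [spec.chain_i]],
        "seed": spec.seed,
        "planted_edges": sorted(manifest_edges, key=lambda e: (e["a"], e["b"], e["type"])),
    }
    return pdb_text, manifest


# ---------------------------------------------------------------------------
# labeled graph datasets with planted motifs
# ---------------------------------------------------------------------------

DEFAULT_ALPHABET = (
    frozenset({"DN"}), frozenset({"AC"}), frozenset({"HB"}),
    frozenset({"AC", "NG"}), frozenset({"DN", "PS"}), frozenset({"AR"}),
)


def default_motif() -> nx.Graph:
    """Donor — acceptor/negative — donor/positive path (hydrogen bond + salt bridge)."""
    m = nx.Graph()
    m.add_node("m0", labels=frozenset({"DN"}))
    m.add_node("m1", labels=frozenset({"AC", "NG"}))
    m.add_node("m2", labels=frozenset({"DN", "PS"}))
    m.add_edge("m0", "m1", types=frozenset({"hydrogen_bond"}))
    m.add_edge("m1", "m2", types=frozenset({"salt_bridge"}))
    return m


@dataclass(frozen=True)
class GraphFixtureSpec:
    seed: int = 0
    n_graphs: int = 10
    planted_fraction: float = 0.8
    motif: nx.Graph = field(default_factory=default_motif)
    noise_nodes: int = 3
    noise_edges: int = 2
    label_alphabet: Tuple[FrozenSet[str], ...] = DEFAULT_ALPHABET
    edge_types: Tuple[str, ...] = INTERACTION_TYPES
    max_rejections: int = 500

    def __post_init__(self) -> None:
        n_planted = self.planted_fraction * self.n_graphs
        if abs(n_planted - round(n_planted)) > 1e-9:
            raise ValueError("planted_fraction * n_graphs must be an integer")
        if not nx.is_connected(self.motif):
            raise ValueError("motif must be connected")


def _finalize_attrs(g: nx.Graph, gid: str) -> None:
    g.graph["graph_id"] = gid
    g.graph["complex_id"] = f"synthetic-{gid}"
    for i, v in enumerate(sorted(g.nodes, key=str)):
        labs = g.nodes[v]["labels"]
        g.nodes[v]["label"] = canonical_label(labs)
        g.nodes[v]["record"] = AtomRecord(
            complex_id=f"synthetic-{gid}", chain_id="A", residue_name="GLY",
            residue_number=i + 1, atom_name="CA", element="C",
            position=(float(i), 0.0, 0.0), side="P",
        )
    for u, v, data in g.edges(data=True):
        data["label"] = type_set_label(data["types"])


def _contains_motif(g: nx.Graph, motif: nx.Graph, forbidden_only_noise: bool = False,
                    core: Optional[set] = None) -> bool:
    """Exact-label containment; optionally only embeddings using a noise node."""
    gm = nx.algorithms.isomorphism.GraphMatcher(
        g, motif,
        node_match=lambda a, b: a["labels"] == b["labels"],
        edge_match=lambda a, b: a["types"] == b["types"],
    )
    for iso in gm.subgraph_monomorphisms_iter():
        if forbidden_only_noise and core is not None:
            if set(iso.keys()) <= core:
                continue
        return True
    return False


def _random_noise_graph(rng: np.random.Generator, n_nodes: int, extra_edges: int,
                        alphabet, edge_types) -> nx.Graph:
    g = nx.Graph()
    names = [f"x{i}" for i in range(n_nodes)]
    for name in names:
        g.add_node(name, labels=alphabet[rng.integers(len(alphabet))])
    for i in range(1, n_nodes):  # random spanning tree keeps the graph connected
        j = int(rng.integers(i))
        g.add_edge(names[i], names[j],
                   types=frozenset({edge_types[rng.integers(len(edge_types))]}))
    for _ in range(extra_edges):
        i, j = rng.choice(n_nodes, size=2, replace=False)
        if not g.has_edge(names[i], names[j]):
            g.add_edge(names[i], names[j],
                       types=frozenset({edge_types[rng.integers(len(edge_types))]}))
    return g


def generate_graph_dataset(spec: GraphFixtureSpec) -> Tuple[List[nx.Graph], dict]:
    """Labeled graph dataset with a motif planted in a known graph subset."""
    rng = np.random.default_rng(spec.seed)
    n_planted = round(spec.planted_fraction * spec.n_graphs)
    planted_flags = [True] * n_planted + [False] * (spec.n_graphs - n_planted)
    graphs: List[nx.Graph] = []
    planted_ids: List[str] = []

    for gi, is_planted in enumerate(planted_flags):
        gid = f"g{gi}"
        for attempt in range(spec.max_rejections):
            if is_planted:
                g = spec.motif.copy()
                core = set(g.nodes)
                noise = _random_noise_graph(rng, max(spec.noise_nodes, 0),
                                            spec.noise_edges, spec.label_alphabet,
                                            spec.edge_types)
                g = nx.union(g, noise) if noise.number_of_nodes() else g
                # connect each noise component to the motif
                for comp in list(nx.connected_components(g)):
                    if comp <= core:
                        continue
                    u = sorted(comp, key=str)[0]
                    v = sorted(core, key=str)[int(rng.integers(len(core)))]
                    g.add_edge(u, v, types=frozenset(
                        {spec.edge_types[rng.integers(len(spec.edge_types))]}))
                if not _contains_motif(g, spec.motif, forbidden_only_noise=True,
                                       core=core):
                    break
            else:
                n_nodes = max(spec.noise_nodes, 2)
                g = _random_noise_graph(rng, n_nodes, spec.noise_edges,
                                        spec.label_alphabet, spec.edge_types)
                if not _contains_motif(g, spec.motif):
                    break
        else:
            raise RuntimeError(
                "rejection budget exhausted while avoiding accidental motif "
                "copies; use sparser noise or a larger label alphabet")
        _finalize_attrs(g, gid)
        graphs.append(g)
        if is_planted:
            planted_ids.append(gid)

    manifest = {
        "seed": spec.seed,
        "n_graphs": spec.n_graphs,
        "planted_fraction": spec.planted_fraction,
        "planted_graph_ids": planted_ids,
        "motif_nodes": sorted(spec.motif.nodes),
    }
    return graphs, manifest


# ---------------------------------------------------------------------------
# planted-block matrices for the clustering stage
# ---------------------------------------------------------------------------

def make_block_matrix(n_blocks: int, block_size: int = 25, dim: int = 6,
                      separation: float = 5.0, seed: int = 0
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Gaussian blobs with between/within distance ratio >= ``separation``.

    Returns (data, block labels).  Within-block spread is 1; centers are
    placed ``separation * sqrt(2 * dim)`` apart on random directions.
    """
    if dim < n_blocks:
        raise ValueError("dim must be >= n_blocks to separate the centers")
    rng = np.random.default_rng(seed)
    # typical within-block pair distance is ~ sqrt(2*dim); orthogonal centers
    # at this radius times `separation` give the required distance ratio
    scale = separation * math.sqrt(2.0 * dim)
    centers = np.eye(n_blocks, dim) * scale
    rows, labels = [], []
    for b in range(n_blocks):
        rows.append(centers[b] + rng.normal(size=(block_size, dim)))
        labels.extend([b] * block_size)
    return np.vstack(rows), np.asarray(labels)
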