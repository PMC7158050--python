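"""End-to-end orchestration: graphs -> features -> clusters -> patterns -> maps -> report.

Each stage persists its artifacts under the run directory and reads only the
previous stage's files, so single stages can be re-run in isolation and a
chained run reproduces the full pipeline exactly.  All randomness (k-means
seeding) flows from the single configured seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import pandas as pd
import yaml

from . import io as gio
from .clustering import ClusteringConfig, select_parameters, spectral_cluster
from .evaluation import load_reference_items, precision_recall
from .features import build_counting_matrix, reduce, svd_factorize
from .interface import ContactCriteria, build_component_graphs, load_typing_table
from .mapping import map_all, residues_touched
from .mining import filter_maximal, gspan_mine, support_sweep, to_simple_graph

logger = logging.getLogger(__name__)


@dataclass
class ComplexInput:
    complex_id: str
    chain_groups: Tuple[Tuple[str, ...], Tuple[str, ...]]
    pdb_path: Optional[str] = None
    pdb_text: Optional[str] = None

    def text(self) -> str:
        if self.pdb_text is not None:
            return self.pdb_text
        if self.pdb_path is None:
            raise ValueError(f"complex {self.complex_id}: no pdb_path or pdb_text")
        return Path(self.pdb_path).read_text()


@dataclass
class PipelineConfig:
    complexes: List[ComplexInput] = field(default_factory=list)
    criteria_overrides: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    typing_table_path: Optional[str] = None
    variance_threshold: float = 0.95
    n_max: int = 30
    min_support: float = 0.7
    support_grid: Tuple[float, ...] = ()
    max_pattern_nodes: Optional[int] = None
    seed: int = 0
    reference_path: Optional[str] = None
    output_dir: str = "ifacemine_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "complexes" not in raw or not raw["complexes"]:
            raise ValueError("config must list at least one complex")
        complexes = []
        for c in raw["complexes"]:
            if "chain_groups" not in c:
                raise ValueError(
                    f"complex {c.get('complex_id', '?')}: chain_groups is required")
            groups = c["chain_groups"]
            complexes.append(ComplexInput(
                complex_id=str(c.get("complex_id", c.get("pdb_path", "complex"))),
                chain_groups=(tuple(groups[0]), tuple(groups[1])),
                pdb_path=c.get("pdb_path"), pdb_text=c.get("pdb_text"),
            ))
        return cls(
            complexes=complexes,
            criteria_overrides={k: tuple(v) for k, v in
                                (raw.get("criteria_overrides") or {}).items()},
            typing_table_path=raw.get("typing_table"),
            variance_threshold=float(raw.get("variance_threshold", 0.95)),
            n_max=int(raw.get("n_max", 30)),
            min_support=float(raw.get("min_support", 0.7)),
            support_grid=tuple(raw.get("support_grid", ())),
            max_pattern_nodes=raw.get("max_pattern_nodes"),
            seed=int(raw.get("seed", 0)),
            reference_path=raw.get("reference"),
            output_dir=str(raw.get("output_dir", "ifacemine_run")),
        )

    def criteria(self) -> ContactCriteria:
        return ContactCriteria().with_overrides(self.criteria_overrides)


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"{path} is missing; run the '{producer}' stage first")
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_graphs(cfg: PipelineConfig, run_dir: Path) -> List[nx.MultiGraph]:
    out = run_dir / "graphs"
    out.mkdir(parents=True, exist_ok=True)
    table = load_typing_table(cfg.typing_table_path)
    criteria = cfg.criteria()
    dataset: List[nx.MultiGraph] = []
    for cx in cfg.complexes:
        comps = build_component_graphs(
            cx.text(), cx.chain_groups, complex_id=cx.complex_id,
            criteria=criteria, typing_table=table)
        for sg in comps:
            sg.graph["graph_id"] = f"{cx.complex_id}:{sg.graph['component_index']}"
        dataset.extend(comps)
        logger.info("complex %s: %d interface component(s)", cx.complex_id, len(comps))
    if not dataset:
        raise ValueError("no interface contacts found in any complex")
    gio.write_dataset_json(dataset, out / "dataset.json")
    gio.write_dataset_graphml(dataset, out / "graphml")
    return dataset


def stage_features(cfg: PipelineConfig, run_dir: Path) -> pd.DataFrame:
    dataset = gio.read_dataset_json(_require(run_dir / "graphs" / "dataset.json", "graphs"))
    out = run_dir / "features"
    out.mkdir(parents=True, exist_ok=True)
    X = build_counting_matrix(dataset)
    X.to_csv(out / "counting_matrix.csv", index_label="graph_id")
    return X


def stage_cluster(cfg: PipelineConfig, run_dir: Path) -> Dict[str, int]:
    xp = _require(run_dir / "features" / "counting_matrix.csv", "features")
    X = pd.read_csv(xp, index_col="graph_id")
    X.index = X.index.astype(str)
    out = run_dir / "cluster"
    out.mkdir(parents=True, exist_ok=True)

    ccfg = ClusteringConfig(variance_threshold=cfg.variance_threshold,
                            n_max=cfg.n_max, seed=cfg.seed)
    fac = svd_factorize(X)
    (d, n, k), report = select_parameters(X, ccfg, factorization=fac)
    report.to_csv(out / "per_d_report.csv", index=False)
    theta = reduce(X, d, factorization=fac)
    pd.DataFrame(theta.theta, index=X.index).to_csv(out / "theta.csv",
                                                    index_label="graph_id")
    result = spectral_cluster(theta, n, k, seed=cfg.seed, d=d)
    logger.info("selected d=%d n=%d k=%d (variance %.3f)",
                d, n, k, theta.variance_retained)
    rows = []
    for gid, cluster in result.assignments.items():
        complex_id, _, comp = gid.rpartition(":")
        rows.append({"graph_id": gid, "complex_id": complex_id or gid,
                     "component_index": comp, "cluster": cluster})
    pd.DataFrame(rows).to_csv(out / "assignments.csv", index=False)
    (out / "params.json").write_text(json.dumps(
        {"d": d, "n": n, "k": k, "seed": cfg.seed,
         "variance_retained": theta.variance_retained,
         "laplacian_eigenvalues": [float(v) for v in
                                   result.laplacian_eigenvalues[:cfg.n_max + 1]]},
        indent=1, sort_keys=True) + "\n")
    return result.assignments


def _clusters_from_files(run_dir: Path) -> Dict[int, List[nx.Graph]]:
    dataset = gio.read_dataset_json(_require(run_dir / "graphs" / "dataset.json", "graphs"))
    ap = _require(run_dir / "cluster" / "assignments.csv", "cluster")
    assignments = pd.read_csv(ap)
    by_id = {str(g.graph["graph_id"]): g for g in dataset}
    clusters: Dict[int, List[nx.Graph]] = {}
    for _, row in assignments.iterrows():
        g = by_id[str(row["graph_id"])]
        clusters.setdefault(int(row["cluster"]), []).append(to_simple_graph(g))
    return clusters


def stage_mine(cfg: PipelineConfig, run_dir: Path) -> Dict[int, list]:
    clusters = _clusters_from_files(run_dir)
    out = run_dir / "mine"
    out.mkdir(parents=True, exist_ok=True)
    all_patterns: Dict[int, list] = {}
    sweep_rows = []
    for cid in sorted(clusters):
        graphs = clusters[cid]
        patterns = gspan_mine(graphs, cfg.min_support, cfg.max_pattern_nodes)
        maximal = filter_maximal(patterns)
        ids = [f"c{cid}_p{i}" for i in range(len(maximal))]
        gio.write_patterns_json(maximal, out / f"cluster_{cid}_patterns.json",
                                pattern_ids=ids)
        all_patterns[cid] = maximal
        logger.info("cluster %d: %d graphs, %d frequent, %d maximal at support %.2f",
                    cid, len(graphs), len(patterns), len(maximal), cfg.min_support)
        if cfg.support_grid:
            sw = support_sweep(graphs, cfg.support_grid, cfg.max_pattern_nodes)
            sw.insert(0, "cluster", cid)
            sweep_rows.append(sw)
    if sweep_rows:
        pd.concat(sweep_rows, ignore_index=True).to_csv(
            out / "support_sweep.csv", index=False)
    return all_patterns


def stage_map(cfg: PipelineConfig, run_dir: Path) -> list:
    clusters = _clusters_from_files(run_dir)
    out = run_dir / "map"
    out.mkdir(parents=True, exist_ok=True)
    mine_dir = _require(run_dir / "mine", "mine")
    mappings = []
    touched_rows = []
    for cid in sorted(clusters):
        pfile = mine_dir / f"cluster_{cid}_patterns.json"
        if not pfile.exists():
            raise FileNotFoundError(f"{pfile} is missing; run the 'mine' stage first")
        patterns = gio.read_patterns_json(pfile)
        graphs_by_id = {str(g.graph["graph_id"]): g for g in clusters[cid]}
        ms = map_all(list(patterns.values()), graphs_by_id,
                     pattern_ids=list(patterns.keys()))
        mappings.extend(ms)
        touched = residues_touched(ms, graphs_by_id)
        for pid, residues in sorted(touched.items()):
            for r in sorted(residues):
                touched_rows.append({
                    "pattern_id": pid, "cluster": cid, "complex_id": r[0],
                    "chain_id": r[1], "side": r[2], "residue_name": r[3],
                    "residue_number": r[4], "insertion_code": r[5]})
    gio.write_mappings_json(mappings, out / "mappings.json")
    cols = ["pattern_id", "cluster", "complex_id", "chain_id", "side",
            "residue_name", "residue_number", "insertion_code"]
    pd.DataFrame(touched_rows, columns=cols).to_csv(out / "residues.csv", index=False)
    return mappings


def stage_evaluate(cfg: PipelineConfig, run_dir: Path) -> pd.DataFrame:
    if cfg.reference_path is None:
        raise ValueError("evaluation requires a reference file (config key 'reference')")
    reference = load_reference_items(cfg.reference_path)
    mine_dir = _require(run_dir / "mine", "mine")
    residues = pd.read_csv(_require(run_dir / "map" / "residues.csv", "map"))
    out = run_dir / "evaluate"
    out.mkdir(parents=True, exist_ok=True)

    groups = {}
    for pfile in sorted(mine_dir.glob("cluster_*_patterns.json")):
        cid = pfile.stem.split("_")[1]
        patterns = gio.read_patterns_json(pfile)
        pats, touched = [], []
        for pid, p in patterns.items():
            sub = residues[residues["pattern_id"] == pid]
            pats.append(p)
            touched.append({
                (row["complex_id"], str(row["chain_id"]), row["side"],
                 row["residue_name"], int(row["residue_number"]),
                 "" if pd.isna(row["insertion_code"]) else str(row["insertion_code"]))
                for _, row in sub.iterrows()})
        if pats:
            groups[cid] = (pats, touched)
    report = precision_recall(groups, reference)
    report.to_csv(out / "report.csv", index=False)
    return report


STAGES = ("graphs", "features", "cluster", "mine", "map", "evaluate")


def run_pipeline(cfg: PipelineConfig, through: str = "map") -> Path:
    """Run stages in order up to ``through`` (inclusive); returns the run dir."""
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}; choose from {STAGES}")
    run_dir = Path(cfg.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("ifacemine")
    root.addHandler(handler)
    try:
        for stage in STAGES[: STAGES.index(through) + 1]:
            logger.info("stage %s", stage)
            try:
                globals()[f"stage_{stage}"](cfg, run_dir)
            except Exception as exc:
                raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return run_dir
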