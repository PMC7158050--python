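"""Spectral clustering of interface graphs with eigen-gap model selection.

Rows of the reduced matrix Theta are compared by Euclidean distance; a
k-nearest-neighbor graph (symmetrized by union) carries the similarity
structure.  The number of neighbors k is swept as a percentage p of the row
count (1%..90%, step 1%) and fixed at the first value whose kNN graph is
fully connected — disconnected components would trivially impose themselves
as clusters.  The cluster count n is the position of the largest gap in the
ascending spectrum of the normalized symmetric Laplacian (eigen-gap
heuristic), and the final partition comes from seeded k-means on the
n smallest Laplacian eigenvectors.

`select_parameters` repeats the (k, n) evaluation for every SVD rank d that
retains the variance threshold and picks the triple with minimal k, breaking
ties by the modal n across qualifying ranks and then the smallest d, while
reporting the whole per-rank table for auditing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import laplacian as csgraph_laplacian
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .features import ReducedMatrix, SVDFactorization, select_rank, svd_factorize


@dataclass(frozen=True)
class ClusteringConfig:
    """Sweep grids and thresholds for parameter selection."""

    p_grid: Tuple[float, ...] = tuple(np.round(np.arange(0.01, 0.901, 0.01), 2))
    n_max: int = 30
    variance_threshold: float = 0.95
    gaussian_weights: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        ps = np.asarray(self.p_grid)
        if not (np.all(np.diff(ps) > 0) and ps[0] > 0 and ps[-1] <= 0.9):
            raise ValueError("p_grid must be strictly increasing within (0, 0.9]")


@dataclass
class ClusteringResult:
    k: int
    n: int
    d: int
    assignments: Dict[str, int]
    laplacian_eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))


def _as_matrix(theta: ReducedMatrix | np.ndarray) -> Tuple[np.ndarray, Tuple[str, ...]]:
    if isinstance(theta, ReducedMatrix):
        m = theta.theta
        ids = theta.graph_ids or tuple(str(i) for i in range(m.shape[0]))
        return m, ids
    m = np.asarray(theta, dtype=float)
    return m, tuple(str(i) for i in range(m.shape[0]))


def knn_similarity_graph(theta: ReducedMatrix | np.ndarray, k: int,
                         gaussian_weights: bool = False) -> nx.Graph:
    """Union-symmetrized k-nearest-neighbor graph over the rows of Theta.

    Edge (i, j) exists when j is among i's k nearest rows by Euclidean
    distance or vice versa.  Weights are 1 by default; with
    ``gaussian_weights`` they are exp(-dist^2 / (2 sigma^2)) with sigma the
    median kNN distance.
    """
    m, _ = _as_matrix(theta)
    r = m.shape[0]
    if not 1 <= k < r:
        raise ValueError(f"k must satisfy 1 <= k < {r}, got {k}")
    dist = cdist(m, m)
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]

    g = nx.Graph()
    g.add_nodes_from(range(r))
    knn_d = dist[np.arange(r)[:, None], order]
    sigma = float(np.median(knn_d)) if gaussian_weights else None
    for i in range(r):
        for j in order[i]:
            j = int(j)
            if gaussian_weights and sigma and sigma > 0:
                w = float(np.exp(-dist[i, j] ** 2 / (2 * sigma ** 2)))
            else:
                w = 1.0
            g.add_edge(i, j, weight=w, distance=float(dist[i, j]))
    return g


def select_k(theta: ReducedMatrix | np.ndarray,
             cfg: Optional[ClusteringConfig] = None) -> int:
    """Smallest swept k whose symmetrized kNN graph is fully connected."""
    cfg = cfg or ClusteringConfig()
    m, _ = _as_matrix(theta)
    r = m.shape[0]
    if r < 3:
        raise ValueError("need at least 3 rows to sweep k")
    tried = set()
    for p in cfg.p_grid:
        k = max(1, int(round(p * r)))
        k = min(k, r - 1)
        if k in tried:
            continue
        tried.add(k)
        if nx.is_connected(knn_similarity_graph(m, k)):
            return k
    raise ValueError(
        "no k in the swept grid produced a connected similarity graph; "
        "extend p_grid or inspect for duplicated rows"
    )


def laplacian_spectrum(graph: nx.Graph) -> Tuple[np.ndarray, np.ndarray]:
    """Ascending eigenvalues/eigenvectors of the normalized symmetric Laplacian."""
    A = nx.to_numpy_array(graph, nodelist=sorted(graph.nodes), weight="weight")
    L = csgraph_laplacian(A, normed=True)
    evals, evecs = np.linalg.eigh(L)
    return evals, evecs


def eigen_gap(eigenvalues: Sequence[float], n_max: int = 30) -> int:
    """Cluster count at the largest consecutive gap of the ascending spectrum.

    Considers n in [2, n_max]; the gap for n is lambda_{n+1} - lambda_n
    (1-based), ties broken toward smaller n.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size < 3:
        raise ValueError("need at least 3 eigenvalues for the eigen-gap heuristic")
    hi = min(n_max, ev.size - 1)
    gaps = ev[2:hi + 1] - ev[1:hi]   # gap for n = 2 .. hi
    return int(np.argmax(gaps)) + 2


def spectral_cluster(theta: ReducedMatrix | np.ndarray, n: int, k: int,
                     seed: int = 0, gaussian_weights: bool = False,
                     d: Optional[int] = None) -> ClusteringResult:
    """Partition rows of Theta into n groups by normalized spectral clustering."""
    m, ids = _as_matrix(theta)
    g = knn_similarity_graph(m, k, gaussian_weights=gaussian_weights)
    if not nx.is_connected(g):
        raise ValueError("similarity graph is disconnected; increase k")
    evals, evecs = laplacian_spectrum(g)
    emb = evecs[:, :n]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    emb = emb / np.where(norms > 0, norms, 1.0)
    km = KMeans(n_clusters=n, random_state=seed, n_init=10)
    labels = km.fit_predict(emb)
    # contiguous ids in order of first appearance, for stable output
    remap: Dict[int, int] = {}
    for lab in labels:
        remap.setdefault(int(lab), len(remap))
    assignments = {ids[i]: remap[int(labels[i])] for i in range(len(ids))}
    return ClusteringResult(
        k=k, n=n, d=d if d is not None else m.shape[1],
        assignments=assignments, laplacian_eigenvalues=evals,
    )


def select_parameters(
    X: pd.DataFrame | np.ndarray,
    cfg: Optional[ClusteringConfig] = None,
    factorization: Optional[SVDFactorization] = None,
) -> Tuple[Tuple[int, int, int], pd.DataFrame]:
    """Sweep qualifying SVD ranks and choose (d, n, k).

    For every rank d whose retained variance meets the threshold, computes
    the minimal connected k and the eigen-gap n; returns the selected
    (d, n, k) plus the full per-rank report.  Selection: minimal k; among
    ties the most frequent n across qualifying ranks; then the smallest d.
    """
    cfg = cfg or ClusteringConfig()
    fac = factorization if factorization is not None else svd_factorize(X)
    d_min = select_rank(fac.Sigma, cfg.variance_threshold)
    ids = tuple(X.index.astype(str)) if isinstance(X, pd.DataFrame) else ()

    rows: List[dict] = []
    for d in range(d_min, fac.rank + 1):
        theta = fac.U[:, :d] * fac.Sigma[:d]
        try:
            k = select_k(theta, cfg)
            g = knn_similarity_graph(theta, k, cfg.gaussian_weights)
            evals, _ = laplacian_spectrum(g)
            n = eigen_gap(evals, cfg.n_max)
            rows.append({"d": d, "variance": fac.variance_retained(d),
                         "k": k, "n": n, "connected": True})
        except ValueError:
            rows.append({"d": d, "variance": fac.variance_retained(d),
                         "k": -1, "n": -1, "connected": False})
    report = pd.DataFrame(rows)
    return choose_parameters(report), report


def choose_parameters(report: pd.DataFrame) -> Tuple[int, int, int]:
    """Apply the (d, n, k) selection rule to a per-rank report.

    Minimal k wins; among ranks tied on k the most frequent n (smaller n on
    a frequency tie); then the smallest rank d.
    """
    ok = report[report["connected"]]
    if ok.empty:
        raise ValueError("no qualifying rank produced a connected similarity graph")
    k_sel = int(ok["k"].min())
    tied = ok[ok["k"] == k_sel]
    n_sel = int(tied["n"].value_counts().sort_index().idxmax())
    d_sel = int(tied[tied["n"] == n_sel]["d"].min())
    return (d_sel, n_sel, k_sel)
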