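"""Counting-matrix encoding and truncated-SVD reduction.

Each interface graph is summarized by a fingerprint-style row of pair-label
counts: every unordered pair of *adjacent* nodes contributes one count to
the column named by joining the two endpoint label strings.  The resulting
graph-by-pair-label matrix X is reduced by truncated SVD, keeping the
smallest rank d whose squared singular values retain at least a configured
fraction (default 95%) of the total variance; the clustering input is
Theta = U_d Sigma_d.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .labels import canonical_label


def pair_label(a: Iterable[str], b: Iterable[str]) -> str:
    """Canonical column name for a pair of node label sets.

    Each side is serialized as sorted short codes joined by "/", the two
    sides are sorted lexicographically and joined by "-", so the result is
    symmetric: ``pair_label(a, b) == pair_label(b, a)``.
    """
    sa, sb = canonical_label(a), canonical_label(b)
    return "-".join(sorted((sa, sb)))


def build_counting_matrix(graphs: Sequence[nx.Graph]) -> pd.DataFrame:
    """Graph-by-pair-label count matrix for a dataset of labeled graphs.

    Accepts multigraphs or simple graphs; a node pair joined by any number
    of parallel edges counts exactly once.  Columns are the pair labels
    occurring anywhere in the dataset, sorted lexicographically; rows follow
    dataset order and are indexed by each graph's ``graph_id`` attribute
    (falling back to the positional index).
    """
    if len(graphs) == 0:
        raise ValueError("cannot build a counting matrix from an empty dataset")
    rows: List[dict] = []
    ids: List[str] = []
    for gi, g in enumerate(graphs):
        counts: dict = {}
        for u, v in {tuple(sorted((u, v), key=repr)) for u, v in g.edges()}:
            col = pair_label(g.nodes[u]["labels"], g.nodes[v]["labels"])
            counts[col] = counts.get(col, 0) + 1
        rows.append(counts)
        ids.append(str(g.graph.get("graph_id", gi)))
    df = pd.DataFrame(rows, index=ids).fillna(0).astype(int)
    return df.reindex(sorted(df.columns), axis=1)


@dataclass(frozen=True)
class SVDFactorization:
    """Thin SVD X = U diag(Sigma) V^T restricted to the numerical rank."""

    U: np.ndarray       # r x l, orthonormal columns
    Sigma: np.ndarray   # l positive singular values, descending
    V: np.ndarray       # c x l, orthonormal columns

    @property
    def rank(self) -> int:
        return len(self.Sigma)

    def variance_retained(self, d: int) -> float:
        s2 = self.Sigma ** 2
        return float(s2[:d].sum() / s2.sum())


def svd_factorize(X: np.ndarray | pd.DataFrame) -> SVDFactorization:
    """Thin SVD of the raw (uncentered) counting matrix, truncated to rank."""
    A = np.asarray(X, dtype=float)
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    tol = max(A.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    keep = s > tol
    if not keep.any():
        raise ValueError("matrix has rank zero; nothing to factorize")
    return SVDFactorization(U[:, keep], s[keep], Vt[keep].T)


def select_rank(sigma: Sequence[float], threshold: float = 0.95) -> int:
    """Smallest d whose cumulative squared singular values reach ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("variance threshold must lie in (0, 1]")
    s = np.asarray(sigma, dtype=float)
    if s.size == 0:
        raise ValueError("empty singular value sequence")
    frac = np.cumsum(s ** 2) / np.sum(s ** 2)
    return int(np.searchsorted(frac, threshold - 1e-12) + 1)


@dataclass(frozen=True)
class ReducedMatrix:
    """Rank-d reduction Theta = U_d Sigma_d plus bookkeeping."""

    theta: np.ndarray
    d: int
    variance_retained: float
    graph_ids: Tuple[str, ...] = ()


def reduce(X: np.ndarray | pd.DataFrame, d: int,
           factorization: SVDFactorization | None = None) -> ReducedMatrix:
    """Best rank-d reduction of X in the least-squares sense."""
    fac = factorization if factorization is not None else svd_factorize(X)
    if not 1 <= d <= fac.rank:
        raise ValueError(f"d must lie in [1, rank={fac.rank}], got {d}")
    theta = fac.U[:, :d] * fac.Sigma[:d]
    ids = tuple(X.index.astype(str)) if isinstance(X, pd.DataFrame) else ()
    return ReducedMatrix(theta=theta, d=d, variance_retained=fac.variance_retained(d),
                         graph_ids=ids)
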