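"""Normalization, scaling, feature selection, PCA and graph clustering.

Counts are log-normalized per cell (log1p of counts-per-10k, natural log),
genes are z-scored with the n-1 standard deviation, and cells are embedded
by exact truncated SVD of the centered matrix.  Clustering runs Leiden
community detection on a shared-nearest-neighbor graph in PC space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .containers import CountMatrix, NormMatrix

__all__ = [
    "normalize_log_cp10k",
    "zscore_genes",
    "select_hvgs",
    "compute_pca",
    "rank_genes_by_pc",
    "cluster_cells",
    "PCAResult",
]

SCALE_FACTOR = 10_000.0
ZSCORE_CLIP = 10.0  # clip z-scores before PCA to bound outlier leverage


@dataclass
class PCAResult:
    cell_scores: np.ndarray        # (n_cells, n_components)
    gene_loadings: np.ndarray      # (n_genes, n_components), orthonormal
    variance_explained: np.ndarray  # per-component proportion of total variance
    gene_ids: list[str]
    cell_ids: list[str]


def normalize_log_cp10k(counts: CountMatrix) -> NormMatrix:
    """log(1 + 10,000 * count / cell_total), natural log.

    Cells with zero total counts yield all-zero columns with a warning.
    """
    x = np.asarray(counts.values, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    totals = x.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cell(s) have zero total counts")
    safe = np.where(zero, 1.0, totals)
    values = np.log1p(SCALE_FACTOR * x / safe[None, :])
    values[:, zero] = 0.0
    return NormMatrix(
        values,
        list(counts.gene_ids),
        list(counts.cell_ids),
        provenance={"scale_factor": SCALE_FACTOR, "log_base": "e"},
    )


def zscore_genes(m: np.ndarray, sample_axis: int = 1) -> np.ndarray:
    """Z-score each gene across samples (n-1 denominator).

    Zero-variance genes map to all-zero rows with a warning.
    """
    m = np.asarray(m, dtype=float)
    n = m.shape[sample_axis]
    if n < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    mean = m.mean(axis=sample_axis, keepdims=True)
    sd = m.std(axis=sample_axis, ddof=1, keepdims=True)
    # a spread at rounding-error scale is no spread: dividing by it would
    # amplify cancellation noise into O(1) garbage
    flat = sd <= 1e-13 * np.maximum(1.0, np.abs(mean))
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance gene(s) set to zero")
    out = (m - mean) / np.where(flat, 1.0, sd)
    out[np.broadcast_to(flat, out.shape)] = 0.0
    return out


def select_hvgs(m: NormMatrix, n_top: int) -> list[str]:
    """Top genes by mean-standardized dispersion (variance/mean of the
    log-normalized values, z-scored within 20 mean bins).  Deterministic;
    ties broken by gene identifier."""
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > len(m.gene_ids):
        raise ValueError("n_top exceeds the number of genes")
    x = m.values
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    df = pd.DataFrame({"gene": m.gene_ids, "mean": mean, "disp": disp})
    df["bin"] = pd.qcut(df["mean"].rank(method="first"), q=20, labels=False)
    grp = df.groupby("bin")["disp"]
    mu, sd = grp.transform("mean"), grp.transform("std").replace(0.0, 1.0).fillna(1.0)
    df["std_disp"] = ((df["disp"] - mu) / sd).fillna(0.0)
    df.loc[var == 0, "std_disp"] = -np.inf  # zero-variance genes never selected
    df = df.sort_values(["std_disp", "gene"], ascending=[False, True])
    return df["gene"].head(n_top).tolist()


def compute_pca(
    m: np.ndarray,
    n_components: int,
    gene_ids: list[str] | None = None,
    cell_ids: list[str] | None = None,
) -> PCAResult:
    """Exact truncated SVD of the centered genes x cells matrix.

    Sign convention: each component is oriented so that its
    largest-magnitude gene loading is positive.
    """
    m = np.asarray(m, dtype=float)
    n_genes, n_cells = m.shape
    if n_components > min(n_genes, n_cells):
        raise ValueError("n_components exceeds matrix rank bound")
    centered = m - m.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = float((s**2).sum())
    k = n_components
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # orient: largest-|loading| positive
    flip = np.sign(u[np.abs(u).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    u = u * flip[None, :]
    vt = vt * flip[:, None]
    var = (s**2) / total if total > 0 else np.zeros(k)
    return PCAResult(
        cell_scores=(vt.T * s[None, :]),
        gene_loadings=u,
        variance_explained=var,
        gene_ids=list(gene_ids) if gene_ids is not None else [f"g{i}" for i in range(n_genes)],
        cell_ids=list(cell_ids) if cell_ids is not None else [f"c{i}" for i in range(n_cells)],
    )


def rank_genes_by_pc(m: np.ndarray, pca: PCAResult, component: int = 0,
                     gene_ids: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlation of each gene with a component's cell scores,
    sorted descending (ties by gene id).  Zero-variance genes get 0."""
    if not 0 <= component < pca.cell_scores.shape[1]:
        raise ValueError("component out of range")
    m = np.asarray(m, dtype=float)
    ids = list(gene_ids) if gene_ids is not None else list(pca.gene_ids)
    scores = pca.cell_scores[:, component]
    xc = m - m.mean(axis=1, keepdims=True)
    yc = scores - scores.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, xc @ yc / np.where(denom > 0, denom, 1.0), 0.0)
    df = pd.DataFrame({"gene": ids, "correlation": r})
    df = df.sort_values(["correlation", "gene"], ascending=[False, True])
    return df.reset_index(drop=True)


def _snn_graph(scores: np.ndarray, k_neighbors: int, prune: float = 1.0 / 15.0) -> ig.Graph:
    n = scores.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(scores)
    knn = nn.kneighbors_graph(scores, mode="connectivity")  # includes self
    shared = (knn @ knn.T).tocoo()
    union = 2 * k_neighbors - shared.data
    jac = shared.data / union
    keep = jac >= prune
    rows, cols, w = shared.row[keep], shared.col[keep], jac[keep]
    off = rows != cols
    adj = sp.coo_matrix((w[off], (rows[off], cols[off])), shape=(n, n))
    adj = ((adj + adj.T) / 2).tocoo()
    upper = adj.row < adj.col
    g = ig.Graph(
        n=n,
        edges=list(zip(adj.row[upper].tolist(), adj.col[upper].tolist())),
        edge_attrs={"weight": adj.data[upper].tolist()},
    )
    return g


def cluster_cells(pca: PCAResult, k_neighbors: int = 15,
                  resolution: float = 0.8, seed: int = 0) -> np.ndarray:
    """Leiden community detection on a shared-nearest-neighbor graph built
    from the cell scores.  Returns integer labels, stable under cell
    reordering up to relabeling."""
    if k_neighbors <= 0:
        raise ValueError("k_neighbors must be positive")
    n_cells = pca.cell_scores.shape[0]
    if k_neighbors >= n_cells:
        raise ValueError("k_neighbors must be smaller than the number of cells")
    g = _snn_graph(pca.cell_scores, k_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=-1,
    )
    return np.asarray(part.membership)
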