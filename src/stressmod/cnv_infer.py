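"""Reference-relative copy-number inference from expression.

A deliberately transparent single-pass pipeline: subtract the
reference-cell mean per gene, clip, smooth along each chromosome with a
truncated centered moving average over gene order, recenter each cell at
its median, and re-clip.  Cells are then partitioned into high/low
copy-number-burden groups by hierarchical clustering of their profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist

__all__ = ["infer_cnv_profile", "subcluster_cnv", "CNVProfile"]

DEFAULT_WINDOW = 101
DEFAULT_CLIP = 3.0


@dataclass
class CNVProfile:
    matrix: pd.DataFrame      # cells x genes, smoothed relative expression
    window: int
    reference_cells: list[str]
    clip: float
    gene_order: pd.DataFrame  # chromosome/start per ordered gene


def _moving_average_truncated(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1, truncated at the ends."""
    n = x.shape[1]
    half = window // 2
    cs = np.cumsum(x, axis=1)
    cs = np.concatenate([np.zeros((x.shape[0], 1)), cs], axis=1)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cs[:, hi] - cs[:, lo]) / (hi - lo)[None, :]


def infer_cnv_profile(
    norm,
    gene_meta: pd.DataFrame,
    ref_cells: list[str],
    window: int = DEFAULT_WINDOW,
    clip: float = DEFAULT_CLIP,
    query_cells: list[str] | None = None,
) -> CNVProfile:
    """Infer per-cell copy-number profiles relative to reference cells.

    ``gene_meta`` must provide chromosome and start for the genes (rows
    indexed by gene id); genes without positions are dropped with a warning
    (at least 80% must have positions).  ``query_cells`` defaults to all
    cells (the reference is always profiled too).
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd gene count")
    if not ref_cells:
        raise ValueError("reference cell set must be nonempty")
    known = [g for g in norm.gene_ids if g in gene_meta.index]
    frac = len(known) / len(norm.gene_ids)
    if frac < 0.8:
        raise ValueError(f"positions known for only {frac:.0%} of genes (need >= 80%)")
    if len(known) < len(norm.gene_ids):
        warnings.warn(f"{len(norm.gene_ids) - len(known)} gene(s) without positions dropped")

    meta = gene_meta.loc[known, ["chromosome", "start"]].copy()
    meta["gene_id"] = list(meta.index)
    meta = meta.reset_index(drop=True).sort_values(["chromosome", "start", "gene_id"])
    ordered = meta["gene_id"].tolist()
    for chrom, grp in meta.groupby("chromosome"):
        if len(grp) < window:
            warnings.warn(f"chromosome {chrom} has fewer genes than the window")

    gpos = {g: i for i, g in enumerate(norm.gene_ids)}
    rows = np.array([gpos[g] for g in ordered])
    cpos = {c: i for i, c in enumerate(norm.cell_ids)}
    ref_idx = np.array([cpos[c] for c in ref_cells])
    cells = list(query_cells) if query_cells is not None else list(norm.cell_ids)
    cell_idx = np.array([cpos[c] for c in cells])

    x = norm.values[np.ix_(rows, cell_idx)].T  # cells x genes
    ref_mean = norm.values[np.ix_(rows, ref_idx)].mean(axis=1)
    rel = np.clip(x - ref_mean[None, :], -clip, clip)

    smoothed = np.empty_like(rel)
    chroms = meta["chromosome"].to_numpy()
    start = 0
    while start < len(ordered):
        stop = start
        while stop < len(ordered) and chroms[stop] == chroms[start]:
            stop += 1
        smoothed[:, start:stop] = _moving_average_truncated(rel[:, start:stop], window)
        start = stop
    smoothed -= np.median(smoothed, axis=1, keepdims=True)
    smoothed = np.clip(smoothed, -clip, clip)

    return CNVProfile(
        matrix=pd.DataFrame(smoothed, index=cells, columns=ordered),
        window=window,
        reference_cells=list(ref_cells),
        clip=clip,
        gene_order=meta.set_index("gene_id")[["chromosome", "start"]],
    )


def subcluster_cnv(profile: CNVProfile, k: int = 2) -> pd.DataFrame:
    """Partition cells into k copy-number clusters named by burden.

    Average-linkage hierarchical clustering on Euclidean profile distance;
    burden = per-cell mean |profile|.  Clusters are renamed SCNV_hi ...
    SCNV_lo by descending mean burden.  A "no distinct SCNV structure"
    warning is emitted when the partition is degenerate: burden gap below
    0.02, a cluster holding under 5% of cells (a bare outlier split), or
    fewer than k distinct clusters.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    x = profile.matrix.to_numpy(dtype=float)
    if k > x.shape[0]:
        raise ValueError("k exceeds the number of cells")
    link = sch.linkage(pdist(x), method="average")
    raw = sch.fcluster(link, t=k, criterion="maxclust")
    burden = np.abs(x).mean(axis=1)
    means = pd.Series(burden).groupby(raw).mean().sort_values(ascending=False)
    names = {}
    for rank, cluster in enumerate(means.index):
        if rank == 0:
            names[cluster] = "SCNV_hi"
        elif rank == len(means) - 1:
            names[cluster] = "SCNV_lo"
        else:
            names[cluster] = f"SCNV_mid{rank}"
    sizes = pd.Series(raw).value_counts()
    if (
        len(means) < 2
        or means.iloc[0] - means.iloc[-1] < 0.02
        or sizes.min() < 0.05 * x.shape[0]
    ):
        warnings.warn("no distinct SCNV structure")
    return pd.DataFrame(
        {
            "cluster": [names[c] for c in raw],
            "burden": burden,
        },
        index=pd.Index(profile.matrix.index, name="cell_id"),
    )
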