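"""Two-group differential expression with Wilcoxon rank-sum testing.

Per gene: two-sided rank-sum p (exact enumeration for small tie-free
groups, tie- and continuity-corrected normal approximation otherwise),
log2 fold change on de-logged normalized values with a small pseudocount,
and Benjamini-Hochberg adjustment over all tested genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .containers import NormMatrix

__all__ = ["wilcoxon_de", "bh_adjust", "significant_genes"]

LFC_EPS = 1e-9
#: default significance gate for "shared DEG" classification
DEFAULT_PADJ_MAX = 0.05
DEFAULT_LFC_MIN = 0.25
EXACT_MAX_N = 10


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _rank_sum_p(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Vectorized two-sided rank-sum p values, genes along axis 0."""
    na, nb = xa.shape[1], xb.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        if max(na, nb) <= EXACT_MAX_N:
            out = np.empty(xa.shape[0])
            for i in range(xa.shape[0]):
                a, b = xa[i], xb[i]
                ties = len(np.unique(np.concatenate([a, b]))) < na + nb
                method = "asymptotic" if ties else "exact"
                out[i] = mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        else:
            out = mannwhitneyu(
                xa, xb, alternative="two-sided", method="asymptotic", axis=1
            ).pvalue
    # a gene whose values are all tied carries no evidence either way
    return np.where(np.isnan(out), 1.0, out)


def wilcoxon_de(
    m: NormMatrix,
    cells_a: list[str],
    cells_b: list[str],
    contrast: str = "a_vs_b",
) -> pd.DataFrame:
    """Differential expression of group A vs group B on log-normalized data.

    Returns a frame with gene, log2fc (A over B), p, padj, pct_a, pct_b.
    """
    set_a, set_b = set(cells_a), set(cells_b)
    if set_a & set_b:
        raise ValueError("cell groups must be disjoint")
    if len(set_a) < 2 or len(set_b) < 2:
        raise ValueError("each group needs at least 2 cells")
    pos = {c: i for i, c in enumerate(m.cell_ids)}
    try:
        ia = np.array([pos[c] for c in cells_a])
        ib = np.array([pos[c] for c in cells_b])
    except KeyError as exc:
        raise ValueError(f"unknown cell id {exc.args[0]!r}") from exc
    xa, xb = m.values[:, ia], m.values[:, ib]

    p = _rank_sum_p(xa, xb)
    mean_a = np.expm1(xa).mean(axis=1)
    mean_b = np.expm1(xb).mean(axis=1)
    log2fc = np.log2((mean_a + LFC_EPS) / (mean_b + LFC_EPS))
    df = pd.DataFrame(
        {
            "gene": m.gene_ids,
            "log2fc": log2fc,
            "p": p,
            "padj": bh_adjust(p),
            "pct_a": (xa > 0).mean(axis=1),
            "pct_b": (xb > 0).mean(axis=1),
        }
    )
    df["contrast"] = contrast
    return df


def significant_genes(
    deg: pd.DataFrame,
    padj_max: float = DEFAULT_PADJ_MAX,
    lfc_min: float = DEFAULT_LFC_MIN,
) -> pd.DataFrame:
    """Apply the shared-DEG significance gate: padj and absolute log2fc."""
    mask = (deg["padj"] < padj_max) & (deg["log2fc"].abs() >= lfc_min)
    return deg.loc[mask]
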