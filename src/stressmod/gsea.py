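"""Pre-ranked gene set enrichment analysis with a Monte-Carlo gene-
permutation null.

Genes are sorted by a ranking statistic (e.g. PC correlation or kME).  The
running enrichment score increments by ``|stat|^w / sum_set |stat|^w``
(w = 1) at set members and decrements by ``1/(N - N_hit)`` elsewhere; the
enrichment score (ES) is the signed maximum deviation.  Significance comes
from random same-size gene sets drawn with a fixed seed; NES normalizes ES
by the mean null |ES| of matching sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import bh_adjust

__all__ = ["preranked_gsea", "GSEAResult", "enrichment_score"]

DEFAULT_MIN_SIZE = 5
DEFAULT_N_PERM = 10_000
WEIGHT = 1.0
_PERM_BLOCK = 2_000


@dataclass
class GSEAResult:
    set_name: str
    es: float
    nes: float
    p: float
    padj: float = np.nan
    leading_edge: list[str] = field(default_factory=list)
    n_genes_in_set: int = 0
    n_perm_used: int = 0
    seed: int = 0
    degenerate: bool = False


def _es_from_positions(pos: np.ndarray, w: np.ndarray, n_genes: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ES for batches of hit-position vectors.

    ``pos``: (B, k) sorted ascending positions into the ranked list;
    ``w``: per-position weights |stat|^w.  Returns (ES, extremum position).
    The running score peaks just after each hit and dips just before it;
    only those candidates can be the extremum.
    """
    B, k = pos.shape
    miss_step = 1.0 / (n_genes - k)
    sw = w[pos]
    denom = sw.sum(axis=1, keepdims=True)
    denom = np.where(denom > 0, denom, 1.0)
    up = np.cumsum(sw, axis=1) / denom
    offs = (pos - np.arange(k)[None, :]) * miss_step
    peaks = up - offs                   # value just after hit j
    valleys = peaks - sw / denom        # value just before hit j
    i_max = peaks.argmax(axis=1)
    i_min = valleys.argmin(axis=1)
    es_pos = peaks[np.arange(B), i_max]
    es_neg = valleys[np.arange(B), i_min]
    take_pos = es_pos >= -es_neg
    es = np.where(take_pos, es_pos, es_neg)
    ext = np.where(take_pos, pos[np.arange(B), i_max], pos[np.arange(B), i_min])
    return es, ext


def enrichment_score(stats: np.ndarray, hit_mask: np.ndarray, weight: float = WEIGHT) -> float:
    """ES of one gene set against an already-sorted statistic vector."""
    stats = np.asarray(stats, dtype=float)
    n = stats.size
    pos = np.flatnonzero(hit_mask)
    if pos.size == 0 or pos.size == n:
        raise ValueError("gene set must be a proper nonempty subset of the ranking")
    w = np.abs(stats) ** weight
    es, _ = _es_from_positions(pos[None, :], w, n)
    return float(es[0])


def preranked_gsea(
    ranked: pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    min_size: int = DEFAULT_MIN_SIZE,
    weight: float = WEIGHT,
) -> pd.DataFrame:
    """Run pre-ranked GSEA for a collection of gene sets.

    ``ranked`` maps gene id -> statistic.  p values use the "+1"
    pseudo-count ``(1 + #{|ES_null| >= |ES|}) / (1 + n_perm)``; BH
    adjustment is applied across the tested sets.  Sets overlapping the
    universe in fewer than ``min_size`` genes are skipped with a note.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse null")
    stats = ranked.astype(float)
    if not np.all(np.isfinite(stats.to_numpy())):
        raise ValueError("ranking statistics must be finite")
    # deterministic order: statistic descending, ties by gene id
    order = sorted(stats.index, key=lambda g: (-stats[g], g))
    stats = stats.loc[order]
    genes = np.asarray(stats.index)
    gpos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    w = np.abs(stats.to_numpy()) ** weight

    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}

    def null_es(k: int) -> np.ndarray:
        if k not in null_cache:
            out = np.empty(n_perm)
            done = 0
            while done < n_perm:
                b = min(_PERM_BLOCK, n_perm - done)
                r = rng.random((b, n))
                pos = np.sort(np.argpartition(r, k, axis=1)[:, :k], axis=1)
                out[done : done + b], _ = _es_from_positions(pos, w, n)
                done += b
            null_cache[k] = out
        return null_cache[k]

    results: list[GSEAResult] = []
    for name in sorted(gene_sets):
        members = [g for g in gene_sets[name] if g in gpos]
        k = len(members)
        if k < min_size:
            warnings.warn(f"gene set {name!r} overlaps ranking in {k} < {min_size} genes; skipped")
            continue
        pos = np.sort(np.array([gpos[g] for g in members]))
        if k == n:
            # every position a hit: the miss decrement is undefined
            denom = w[pos].sum() or 1.0
            es = float((np.cumsum(w[pos]) / denom).max())
            results.append(GSEAResult(
                set_name=name, es=es, nes=np.nan, p=np.nan,
                leading_edge=list(genes), n_genes_in_set=k,
                n_perm_used=0, seed=seed, degenerate=True,
            ))
            warnings.warn(f"gene set {name!r} covers the whole ranking; flagged degenerate")
            continue
        es_arr, ext_arr = _es_from_positions(pos[None, :], w, n)
        es, ext = float(es_arr[0]), int(ext_arr[0])
        null = null_es(k)
        p = (1.0 + np.count_nonzero(np.abs(null) >= abs(es))) / (1.0 + n_perm)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        scale = np.abs(same_sign).mean() if same_sign.size else np.abs(null).mean()
        nes = es / scale if scale > 0 else np.nan
        if es >= 0:
            leading = [genes[i] for i in pos if i <= ext]
        else:
            leading = [genes[i] for i in pos if i >= ext]
        results.append(GSEAResult(
            set_name=name, es=es, nes=nes, p=p, leading_edge=leading,
            n_genes_in_set=k, n_perm_used=n_perm, seed=seed,
        ))

    df = pd.DataFrame([{
        "set_name": r.set_name, "es": r.es, "nes": r.nes, "p": r.p,
        "n_genes": r.n_genes_in_set, "leading_edge": ",".join(r.leading_edge),
        "n_perm_used": r.n_perm_used, "seed": r.seed, "degenerate": r.degenerate,
    } for r in results])
    if not df.empty:
        ok = df["p"].notna()
        padj = np.full(len(df), np.nan)
        if ok.any():
            padj[ok.to_numpy()] = bh_adjust(df.loc[ok, "p"].to_numpy())
        df["padj"] = padj
    return df
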