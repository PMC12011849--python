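"""Consensus weighted co-expression network analysis across donors.

Cells are first aggregated into per-donor metacells (kNN averaging in PC
space) to de-noise correlation estimates.  Per donor, a signed adjacency
``((1 + cor)/2) ** beta`` is raised to a scale-free soft threshold, turned
into a topological overlap matrix (TOM), and donor TOMs are integrated by
quantile-scaled element-wise consensus (default: parallel minimum).
Modules come from average-linkage clustering of 1 - TOM with a static cut;
each module is summarized by its eigengene (first PC of the z-scored
member genes) and every gene by its kME (correlation with the eigengene).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "Metacells",
    "ModuleSet",
    "make_metacells",
    "pick_soft_threshold",
    "build_adjacency",
    "compute_tom",
    "consensus_tom",
    "detect_modules",
    "module_eigengenes",
    "compute_kme",
    "module_trait_correlation",
    "top_hub_genes",
    "reassign_by_kme",
]

GREY = "grey"
#: size-rank module naming convention
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
]

DEFAULT_K_AGG = 25
DEFAULT_MAX_SHARED = 10
DEFAULT_MIN_MODULE_SIZE = 25
DEFAULT_CUT_HEIGHT = 0.995
DEFAULT_POWERS = tuple(range(1, 21))


@dataclass
class Metacells:
    """Per-donor kNN-aggregated pseudocells."""

    expr: np.ndarray                 # (n_genes, n_metacells), mean normalized values
    gene_ids: list[str]
    donor: np.ndarray                # per-metacell donor label
    membership: list[list[str]]      # constituent cell ids per metacell

    @property
    def n_metacells(self) -> int:
        return self.expr.shape[1]


@dataclass
class ModuleSet:
    """Gene-module assignment plus eigengene / kME / trait summaries."""

    assignment: pd.Series            # gene_id -> module label ('grey' = unassigned)
    eigengenes: pd.DataFrame         # metacell x module
    kme: pd.DataFrame                # gene x module
    soft_power: dict[str, int] = field(default_factory=dict)
    trait_cor: pd.DataFrame | None = None

    def members(self, module: str) -> list[str]:
        return sorted(self.assignment.index[self.assignment == module])

    def modules(self) -> list[str]:
        return [m for m in self.eigengenes.columns]


# ----------------------------------------------------------------------
# metacells
# ----------------------------------------------------------------------

def make_metacells(
    norm,
    pca,
    donors: np.ndarray | pd.Series,
    k_agg: int = DEFAULT_K_AGG,
    max_shared: int = DEFAULT_MAX_SHARED,
    seed: int = 0,
) -> Metacells:
    """Greedy kNN metacell aggregation within each donor.

    Seed cells are visited in a seeded random order; each metacell averages
    a seed with its ``k_agg - 1`` nearest neighbors in PC space and is
    rejected when it overlaps any accepted metacell in more than
    ``max_shared`` cells.  Donors with fewer than ``k_agg`` cells are
    skipped with a warning.
    """
    if k_agg < 1:
        raise ValueError("k_agg must be >= 1")
    donors = np.asarray(donors)
    rng = np.random.default_rng(seed)
    cell_ids = np.asarray(norm.cell_ids)
    expr_cols: list[np.ndarray] = []
    mc_donor: list[str] = []
    membership: list[list[str]] = []
    for donor in sorted(pd.unique(donors)):
        idx = np.flatnonzero(donors == donor)
        if idx.size < k_agg:
            warnings.warn(f"donor {donor!r} has fewer than k_agg cells; skipped")
            continue
        scores = pca.cell_scores[idx]
        nn = NearestNeighbors(n_neighbors=k_agg).fit(scores)
        _, neigh = nn.kneighbors(scores)  # includes self at position 0
        order = rng.permutation(idx.size)
        overlap_count = np.zeros(idx.size, dtype=int)  # membership multiplicity
        cell_to_mcs: list[list[int]] = [[] for _ in range(idx.size)]
        n_accepted = 0
        for s in order:
            members = neigh[s]
            # max overlap with any single accepted metacell
            mc_hits: dict[int, int] = {}
            for c in members:
                for mc in cell_to_mcs[c]:
                    mc_hits[mc] = mc_hits.get(mc, 0) + 1
            if mc_hits and max(mc_hits.values()) > max_shared:
                continue
            cols = idx[members]
            expr_cols.append(norm.values[:, cols].mean(axis=1))
            mc_donor.append(str(donor))
            membership.append([str(c) for c in cell_ids[cols]])
            for c in members:
                cell_to_mcs[c].append(n_accepted)
            overlap_count[members] += 1
            n_accepted += 1
    if not expr_cols:
        raise ValueError("no metacells could be constructed")
    return Metacells(
        expr=np.column_stack(expr_cols),
        gene_ids=list(norm.gene_ids),
        donor=np.asarray(mc_donor),
        membership=membership,
    )


# ----------------------------------------------------------------------
# network construction
# ----------------------------------------------------------------------

def _corr(x: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation; zero-variance rows yield zeros."""
    xc = x - x.mean(axis=1, keepdims=True)
    sd = xc.std(axis=1)
    safe = np.where(sd > 0, sd, 1.0)
    z = xc / safe[:, None]
    c = z @ z.T / x.shape[1]
    c[sd == 0, :] = 0.0
    c[:, sd == 0] = 0.0
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def build_adjacency(expr: np.ndarray, beta: float) -> np.ndarray:
    """Signed adjacency ``((1 + cor)/2) ** beta`` with unit diagonal.

    Zero-variance genes keep rows/columns of zeros (flagged by a warning);
    callers typically exclude them beforehand.
    """
    expr = np.asarray(expr, dtype=float)
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 metacells")
    sd = expr.std(axis=1)
    if np.any(sd == 0):
        warnings.warn(f"{int((sd == 0).sum())} zero-variance gene(s) in adjacency")
    a = ((1.0 + _corr(expr)) / 2.0) ** beta
    a[sd == 0, :] = 0.0
    a[:, sd == 0] = 0.0
    np.fill_diagonal(a, 1.0)
    return a


def _scale_free_r2(adj: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index from the connectivity histogram."""
    k = adj.sum(axis=0) - 1.0
    k = k[k > 0]
    if k.size < 3 or np.allclose(k, k[0]):
        return np.nan
    hist, edges = np.histogram(k, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    keep = (hist > 0) & (centers > 0)
    if keep.sum() < 3:
        return np.nan
    x = np.log10(centers[keep])
    y = np.log10(hist[keep] / hist.sum())
    if np.allclose(x, x[0]):
        return np.nan
    slope, _ = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    return -np.sign(slope) * r**2


def pick_soft_threshold(
    metacells: Metacells,
    powers: tuple[int, ...] | list[int] = DEFAULT_POWERS,
    r2_target: float = 0.8,
) -> dict[str, int]:
    """Smallest power per donor whose signed scale-free fit R^2 reaches the
    target; falls back to the maximum-R^2 power with a warning."""
    powers = list(powers)
    if not powers or any(b <= 0 for b in powers) or sorted(powers) != powers:
        raise ValueError("powers must be a nonempty ascending list of positive integers")
    chosen: dict[str, int] = {}
    for donor in sorted(pd.unique(metacells.donor)):
        x = metacells.expr[:, metacells.donor == donor]
        sd = x.std(axis=1)
        x = x[sd > 0]
        corr = _corr(x)
        base = (1.0 + corr) / 2.0
        r2s = []
        for beta in powers:
            r2s.append(_scale_free_r2(base**beta))
        r2s = np.asarray(r2s)
        ok = np.flatnonzero(np.nan_to_num(r2s, nan=-np.inf) >= r2_target)
        if ok.size:
            chosen[donor] = powers[ok[0]]
        else:
            if np.all(np.isnan(r2s)):
                warnings.warn(f"degenerate connectivity for donor {donor!r}; using max power fallback")
                chosen[donor] = powers[-1]
            else:
                warnings.warn(
                    f"no power reaches R^2 >= {r2_target} for donor {donor!r}; using max-R^2 power"
                )
                chosen[donor] = powers[int(np.nanargmax(r2s))]
    return chosen


def compute_tom(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a signed adjacency.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_{u != i,j} a_iu a_uj`` and ``k_i = sum_{u != i} a_iu``.
    """
    adj = np.asarray(adj, dtype=float)
    if adj.shape[0] != adj.shape[1] or not np.allclose(adj, adj.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if not np.allclose(np.diag(adj), 1.0):
        raise ValueError("adjacency diagonal must be 1")
    a2 = adj @ adj
    # (A@A)_ij = l_ij + 2 a_ij when diag(A) = 1
    l = a2 - 2.0 * adj
    k = adj.sum(axis=0) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - adj
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + adj) / denom
    tom[~np.isfinite(tom)] = 0.0
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def consensus_tom(toms: list[np.ndarray], quantile: float = 0.0) -> np.ndarray:
    """Quantile consensus of donor TOMs after 95th-percentile scaling.

    Each TOM is multiplicatively scaled so its off-diagonal 95th percentile
    matches the first donor's, then the element-wise ``quantile`` is taken
    (0 = the classical parallel minimum).
    """
    if not toms:
        raise ValueError("need at least one TOM")
    n = toms[0].shape[0]
    for t in toms:
        if t.shape != (n, n):
            raise ValueError("TOMs must share gene order and size")
    iu = np.triu_indices(n, k=1)
    ref = np.percentile(toms[0][iu], 95) if n > 1 else 1.0
    scaled = []
    for t in toms:
        q = np.percentile(t[iu], 95) if n > 1 else 1.0
        factor = ref / q if q > 0 else 1.0
        st = np.clip(t * factor, 0.0, 1.0)
        np.fill_diagonal(st, 1.0)
        scaled.append(st)
    cons = np.quantile(np.stack(scaled), quantile, axis=0)
    np.fill_diagonal(cons, 1.0)
    return cons


# ----------------------------------------------------------------------
# module detection and characterization
# ----------------------------------------------------------------------

def _mean_offdiag(tom: np.ndarray, idx: np.ndarray) -> float:
    sub = tom[np.ix_(idx, idx)]
    m = len(idx)
    return float((sub.sum() - m) / (m * (m - 1))) if m > 1 else 1.0


def _refine_branch(tom: np.ndarray, idx: np.ndarray, min_module_size: int,
                   split_ratio: float) -> list[np.ndarray]:
    """Recursively split a branch whose best bipartition has much weaker
    topological overlap across the halves than within them.

    Two distinct but condition-correlated modules can fuse below a static
    cut height; this deterministic refinement recovers them (a light
    version of what the dynamic tree-cut family does by branch shape).
    """
    if len(idx) < 2 * min_module_size:
        return [idx]
    sub = 1.0 - np.clip(tom[np.ix_(idx, idx)], 0.0, 1.0)
    np.fill_diagonal(sub, 0.0)
    lab = sch.fcluster(sch.linkage(squareform(sub, checks=False), method="average"),
                       t=2, criterion="maxclust")
    parts = [idx[lab == 1], idx[lab == 2]]
    if min(len(p) for p in parts) < min_module_size:
        return [idx]
    within = min(_mean_offdiag(tom, p) for p in parts)
    cross = float(tom[np.ix_(parts[0], parts[1])].mean())
    if cross < split_ratio * within:
        return (_refine_branch(tom, parts[0], min_module_size, split_ratio)
                + _refine_branch(tom, parts[1], min_module_size, split_ratio))
    return [idx]


def detect_modules(
    tom: np.ndarray,
    gene_ids: list[str],
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    split_ratio: float = 0.5,
) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Detected branches are recursively re-split when a clear bipartition
    exists (cross-branch TOM below ``split_ratio`` times the weaker
    within-half TOM).  Branches smaller than ``min_module_size`` are merged
    into 'grey'; surviving modules are named by descending size using the
    conventional color sequence.
    """
    n = tom.shape[0]
    if n != len(gene_ids):
        raise ValueError("gene_ids must match TOM size")
    dissim = 1.0 - np.clip(tom, 0.0, 1.0)
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    link = sch.linkage(condensed, method="average")
    raw = sch.fcluster(link, t=cut_height, criterion="distance")
    refined = np.array(raw)
    next_label = raw.max() + 1
    for c in np.unique(raw):
        idx = np.flatnonzero(raw == c)
        parts = _refine_branch(tom, idx, min_module_size, split_ratio)
        for p in parts[1:]:
            refined[p] = next_label
            next_label += 1
    labels = pd.Series(refined, index=pd.Index(gene_ids, name="gene_id"))
    sizes = labels.value_counts()
    keep = sizes[sizes >= min_module_size].index
    out = pd.Series(GREY, index=labels.index, dtype=object)
    # deterministic size-rank naming; ties by smallest member gene id
    ranked = sorted(
        keep,
        key=lambda c: (-int(sizes[c]), min(labels.index[labels == c])),
    )
    if not ranked:
        warnings.warn("no module exceeds min_module_size; all genes grey")
    for i, c in enumerate(ranked):
        name = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
        out[labels == c] = name
    return out


def module_eigengenes(metacells: Metacells, assignment: pd.Series) -> pd.DataFrame:
    """First principal component of each module's z-scored member genes,
    unit variance, oriented to correlate positively with the module's mean
    expression."""
    mods = sorted(m for m in assignment.unique() if m != GREY)
    if not mods:
        raise ValueError("assignment contains no modules")
    gpos = {g: i for i, g in enumerate(metacells.gene_ids)}
    cols = {}
    for mod in mods:
        genes = [g for g in assignment.index[assignment == mod]]
        rows = np.array([gpos[g] for g in genes])
        x = metacells.expr[rows]
        sd = x.std(axis=1, ddof=1)
        mean = x.mean(axis=1)
        z = (x - mean[:, None]) / np.where(sd > 0, sd, 1.0)[:, None]
        z[sd == 0] = 0.0
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        avg = z.mean(axis=0)
        if np.corrcoef(eig, avg)[0, 1] < 0:
            eig = -eig
        esd = eig.std(ddof=1)
        cols[mod] = eig / (esd if esd > 0 else 1.0)
    return pd.DataFrame(cols, index=pd.RangeIndex(metacells.n_metacells, name="metacell"))


def compute_kme(metacells: Metacells, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of every gene with every module eigengene."""
    x = metacells.expr
    xc = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)
    zero = sd == 0
    e = eigengenes.to_numpy(dtype=float)
    ec = e - e.mean(axis=0, keepdims=True)
    denom = np.outer(np.sqrt((xc**2).sum(axis=1)), np.sqrt((ec**2).sum(axis=0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        kme = np.where(denom > 0, xc @ ec / np.where(denom > 0, denom, 1.0), 0.0)
    kme[zero, :] = 0.0
    return pd.DataFrame(
        np.clip(kme, -1.0, 1.0),
        index=pd.Index(metacells.gene_ids, name="gene_id"),
        columns=eigengenes.columns,
    )


def module_trait_correlation(eigengenes: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation and two-sided t-test p per (module, trait).

    Constant traits are dropped with a warning.
    """
    n = len(eigengenes)
    rows = []
    for trait in traits.columns:
        y = traits[trait].to_numpy(dtype=float)
        if np.std(y) == 0:
            warnings.warn(f"constant trait {trait!r} dropped")
            continue
        for mod in eigengenes.columns:
            x = eigengenes[mod].to_numpy(dtype=float)
            r = float(np.corrcoef(x, y)[0, 1])
            r = max(min(r, 1.0), -1.0)
            if abs(r) >= 1.0 - 1e-15:
                p = 0.0
            else:
                tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
                p = 2.0 * t_dist.sf(abs(tstat), df=n - 2)
            rows.append({"module": mod, "trait": trait, "r": r, "p": p})
    return pd.DataFrame(rows)


def top_hub_genes(kme: pd.DataFrame, assignment: pd.Series, module: str, n: int = 10) -> list[str]:
    """Member genes of a module sorted by descending kME (ties by id)."""
    if module not in kme.columns:
        raise ValueError(f"unknown module {module!r}")
    members = [g for g in assignment.index[assignment == module]]
    if n > len(members):
        warnings.warn(f"requested {n} hub genes but module has {len(members)}")
    ranked = sorted(members, key=lambda g: (-kme.loc[g, module], g))
    return ranked[:n]


def reassign_by_kme(assignment: pd.Series, kme: pd.DataFrame, gap: float = 0.1) -> pd.Series:
    """Optional refinement: relabel an assigned gene to its max-kME module
    when that kME exceeds the kME for its current module by more than
    ``gap``.  Grey genes are left untouched."""
    out = assignment.copy()
    for g in assignment.index:
        cur = assignment[g]
        if cur == GREY or cur not in kme.columns:
            continue
        best = kme.loc[g].idxmax()
        if best != cur and kme.loc[g, best] - kme.loc[g, cur] > gap:
            out[g] = best
    return out
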