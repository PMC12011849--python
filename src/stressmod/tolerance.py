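"""Stress-tolerance quadrant classification and module down-selection.

Genes significant in both the cytokine contrast (T vs C) and the
resistant-cell contrast (resistant vs other starved cells) are "shared
DEGs" and fall in a quadrant by the sign pair of their fold changes:
concordant induction is stress-tolerant, discordant is stress-sensitive.
Candidate modules are those dominated by tolerant-up shared DEGs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .diffexpr import DEFAULT_LFC_MIN, DEFAULT_PADJ_MAX

__all__ = [
    "classify_gene_tolerance",
    "downselect_modules",
    "module_tolerance_composition",
]

QUADRANTS = ("tolerant_up", "sensitive_up", "tolerant_down", "sensitive_down", "unshared")
DEFAULT_MIN_SHARED = 5


def classify_gene_tolerance(
    deg_ct: pd.DataFrame,
    deg_r: pd.DataFrame,
    assignment: pd.Series | None = None,
    padj_max: float = DEFAULT_PADJ_MAX,
    lfc_min: float = DEFAULT_LFC_MIN,
) -> pd.DataFrame:
    """Assign each gene a tolerance quadrant from the two DEG contrasts.

    ``deg_ct`` is oriented so positive log2fc means up in cytokine-treated
    (T) cells; ``deg_r`` so positive means up in resistant cells relative
    to other starved cells.  Genes significant (padj and |lfc| gates) in
    both contrasts get a quadrant; all others are "unshared".
    """
    a = deg_ct.set_index("gene")
    b = deg_r.set_index("gene")
    if set(a.index) != set(b.index):
        raise ValueError("the two DEG tables must cover the same gene universe")
    b = b.loc[a.index]
    sig_a = (a["padj"] < padj_max) & (a["log2fc"].abs() >= lfc_min)
    sig_b = (b["padj"] < padj_max) & (b["log2fc"].abs() >= lfc_min)
    shared = (sig_a & sig_b).to_numpy()
    up_ct = (a["log2fc"] > 0).to_numpy()
    up_r = (b["log2fc"] > 0).to_numpy()
    quadrant = np.where(
        ~shared,
        "unshared",
        np.where(
            up_ct,
            np.where(up_r, "tolerant_up", "sensitive_up"),
            np.where(~up_r, "tolerant_down", "sensitive_down"),
        ),
    )
    out = pd.DataFrame(
        {
            "gene": a.index,
            "lfc_CT": a["log2fc"].to_numpy(),
            "lfc_rMDSC": b["log2fc"].to_numpy(),
            "quadrant": quadrant,
        }
    )
    if assignment is not None:
        out["module"] = out["gene"].map(assignment).fillna("grey")
    return out.reset_index(drop=True)


def module_tolerance_composition(assignment: pd.Series, tol: pd.DataFrame) -> pd.DataFrame:
    """Per-module counts and fractions of tolerant_up / sensitive_up /
    other among its shared DEGs."""
    tol = tol.copy()
    tol["module"] = tol["gene"].map(assignment).fillna("grey")
    shared = tol[tol["quadrant"] != "unshared"]
    rows = []
    for mod in sorted(m for m in assignment.unique()):
        sub = shared[shared["module"] == mod]
        n = len(sub)
        n_tol = int((sub["quadrant"] == "tolerant_up").sum())
        n_sen = int((sub["quadrant"] == "sensitive_up").sum())
        n_other = n - n_tol - n_sen
        rows.append(
            {
                "module": mod,
                "n_shared": n,
                "n_tolerant_up": n_tol,
                "n_sensitive_up": n_sen,
                "n_other": n_other,
                "frac_tolerant_up": n_tol / n if n else 0.0,
                "frac_sensitive_up": n_sen / n if n else 0.0,
                "frac_other": n_other / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)


def downselect_modules(
    assignment: pd.Series,
    tol: pd.DataFrame,
    min_shared: int = DEFAULT_MIN_SHARED,
) -> list[str]:
    """Candidate modules: at least ``min_shared`` shared DEGs with a
    tolerant_up majority, ranked by tolerant_up fraction then count."""
    comp = module_tolerance_composition(assignment, tol)
    comp = comp[comp["module"] != "grey"]
    cand = comp[
        (comp["n_shared"] >= min_shared)
        & (comp["n_tolerant_up"] > comp["n_shared"] / 2.0)
    ]
    if cand.empty:
        warnings.warn("no module passes down-selection")
        return []
    cand = cand.sort_values(
        ["frac_tolerant_up", "n_tolerant_up", "module"],
        ascending=[False, False, True],
    )
    return cand["module"].tolist()
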