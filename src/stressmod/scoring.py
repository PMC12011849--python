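"""Signature scoring, ROC discrimination, centroid label transfer and
multivariate pathway association.

A signature score is the per-sample mean of z-scored expression over a
gene set.  Discrimination between sample classes is summarized by the
rank (Mann-Whitney) AUC, cross-checked against the AUC of predicted
probabilities from a univariate logistic fit — the two agree under any
increasing monotone transform of the scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score, roc_curve

from .preprocess import zscore_genes

__all__ = [
    "signature_score",
    "roc_auc",
    "evaluate_module_separation",
    "CentroidLabelTransfer",
    "transfer_labels",
    "multivariate_association",
    "RocReport",
]

MAX_LOGIT_SLOPE = 30.0  # cap under perfect separation


@dataclass
class RocReport:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    logit_intercept: float
    logit_slope: float
    separable: bool = False
    labels_used: str = ""
    extras: dict = field(default_factory=dict)


def signature_score(expr: pd.DataFrame, genes: list[str], name: str = "signature") -> pd.Series:
    """Mean of per-gene z-scores (across samples) over the signature genes.

    Genes absent from the matrix are dropped with a warning listing them.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    present = [g for g in genes if g in expr.index]
    missing = sorted(set(genes) - set(present))
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    if missing:
        warnings.warn(f"signature genes absent from matrix: {missing}")
    z = zscore_genes(expr.loc[present].to_numpy(dtype=float), sample_axis=1)
    return pd.Series(z.mean(axis=0), index=expr.columns, name=name)


def _logistic_fit(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, bool]:
    """Newton-Raphson univariate logistic fit; slope capped on separation."""
    x = np.column_stack([np.ones_like(scores), scores])
    beta = np.zeros(2)
    separable = False
    for _ in range(200):
        eta = np.clip(x @ beta, -500, 500)
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = x.T @ (labels - p)
        if np.linalg.norm(grad) < 1e-10:
            break
        w = p * (1.0 - p)
        hess = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            separable = True
            break
        beta = beta + step
        if abs(beta[1]) > MAX_LOGIT_SLOPE:
            separable = True
            scale = MAX_LOGIT_SLOPE / abs(beta[1])
            beta = beta * scale
            break
    if separable:
        warnings.warn("perfect separation: logistic slope capped; AUC from ranks")
    return float(beta[0]), float(beta[1]), separable


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with half credit for ties."""
    r = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = r[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(scores: np.ndarray | pd.Series, labels: np.ndarray | pd.Series,
            labels_used: str = "") -> RocReport:
    """Rank AUC plus ROC curve, with a logistic-fit cross-check.

    The rank AUC is authoritative; the probability-based AUC from the
    logistic fit must agree (monotone-transform invariance) whenever the
    fitted slope is positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    intercept, slope, separable = _logistic_fit(scores, labels)
    auc_rank = _rank_auc(scores, labels)
    eta = intercept + slope * scores
    probs = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    if slope > 0:
        # the predicted probabilities order exactly as the scores when the
        # slope is positive, so their trapezoid-ROC AUC must equal the rank
        # AUC; compare on the score ordering itself, where float saturation
        # or underflow of the link cannot create artificial ties
        auc_prob = roc_auc_score(labels, scores)
        if abs(auc_prob - auc_rank) > 1e-9:
            raise AssertionError("logistic-probability AUC disagrees with rank AUC")
    fpr, tpr, _ = roc_curve(labels, probs if slope > 0 else scores)
    return RocReport(
        auc=auc_rank, fpr=fpr, tpr=tpr,
        logit_intercept=intercept, logit_slope=slope,
        separable=separable, labels_used=labels_used,
    )


def evaluate_module_separation(
    assignment: pd.Series,
    expr: pd.DataFrame,
    contrasts: dict[str, pd.Series],
) -> pd.DataFrame:
    """Module x contrast AUC table from member-gene signature scores.

    Each contrast maps sample id -> {0, 1}; samples missing from a
    contrast are excluded for it.  The "best" module maximizes the minimum
    AUC across contrasts (column ``min_auc``; empty modules are skipped).
    """
    rows = []
    modules = sorted(m for m in assignment.unique() if m != "grey")
    for mod in modules:
        genes = [g for g in assignment.index[assignment == mod] if g in expr.index]
        if not genes:
            continue
        scores = signature_score(expr, genes, name=mod)
        row: dict = {"module": mod}
        for cname, labels in contrasts.items():
            common = labels.index.intersection(scores.index)
            rep = roc_auc(scores.loc[common], labels.loc[common], labels_used=cname)
            row[f"auc_{cname}"] = rep.auc
        row["min_auc"] = min(v for k, v in row.items() if k.startswith("auc_"))
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df["best"] = df["min_auc"] == df["min_auc"].max()
    return df


class CentroidLabelTransfer:
    """Transparent centroid-correlation label transfer (sklearn-style).

    Reference and query are z-scored independently over their own samples
    on the shared genes; each query sample is assigned the reference label
    whose centroid has the highest Spearman correlation, with softmax of
    the correlations as confidence.  Deliberately simpler than anchor-based
    transfer; deterministic.
    """

    min_shared_genes = 50

    def __init__(self) -> None:
        self.centroids_: pd.DataFrame | None = None

    def fit(self, ref_expr: pd.DataFrame, ref_labels: pd.Series | np.ndarray):
        labels = pd.Series(np.asarray(ref_labels), index=ref_expr.columns)
        z = pd.DataFrame(
            zscore_genes(ref_expr.to_numpy(dtype=float), 1),
            index=ref_expr.index, columns=ref_expr.columns,
        )
        self.centroids_ = z.T.groupby(labels).mean().T
        self.classes_ = list(self.centroids_.columns)
        return self

    def _check_fitted(self) -> None:
        if self.centroids_ is None:
            raise RuntimeError("fit must be called before predict")

    def predict_proba(self, query_expr: pd.DataFrame) -> pd.DataFrame:
        self._check_fitted()
        shared = query_expr.index.intersection(self.centroids_.index)
        if len(shared) < self.min_shared_genes:
            raise ValueError(
                f"only {len(shared)} shared genes; need >= {self.min_shared_genes}"
            )
        zq = zscore_genes(query_expr.loc[shared].to_numpy(dtype=float), 1)
        cent = self.centroids_.loc[shared].to_numpy(dtype=float)
        # Spearman = Pearson on ranks
        rq = rankdata(zq, axis=0)
        rc = rankdata(cent, axis=0)
        rqc = rq - rq.mean(axis=0, keepdims=True)
        rcc = rc - rc.mean(axis=0, keepdims=True)
        denom = np.outer(
            np.sqrt((rqc**2).sum(axis=0)), np.sqrt((rcc**2).sum(axis=0))
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            cor = np.where(denom > 0, rqc.T @ rcc / np.where(denom > 0, denom, 1.0), 0.0)
        e = np.exp(cor - cor.max(axis=1, keepdims=True))
        conf = e / e.sum(axis=1, keepdims=True)
        return pd.DataFrame(conf, index=query_expr.columns, columns=self.classes_)

    def predict(self, query_expr: pd.DataFrame) -> pd.Series:
        proba = self.predict_proba(query_expr)
        return proba.idxmax(axis=1)


def transfer_labels(
    ref_expr: pd.DataFrame,
    ref_labels: pd.Series | np.ndarray,
    query_expr: pd.DataFrame,
) -> pd.DataFrame:
    """Fit + predict convenience wrapper around CentroidLabelTransfer."""
    clf = CentroidLabelTransfer().fit(ref_expr, ref_labels)
    proba = clf.predict_proba(query_expr)
    return pd.DataFrame(
        {
            "predicted": proba.idxmax(axis=1),
            "confidence": proba.max(axis=1),
        },
        index=query_expr.columns,
    )


def multivariate_association(
    response: np.ndarray | pd.Series,
    covariate_a: np.ndarray | pd.Series,
    covariate_b: np.ndarray | pd.Series,
) -> pd.DataFrame:
    """OLS of a per-cell pathway score on two profile scores.

    Returns coefficient and two-sided t-test p for the intercept and both
    covariates; collinear covariates (|r| >= 0.99) are rejected.
    """
    y = np.asarray(response, dtype=float)
    a = np.asarray(covariate_a, dtype=float)
    b = np.asarray(covariate_b, dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 observations")
    r_ab = np.corrcoef(a, b)[0, 1]
    if abs(r_ab) >= 0.99:
        raise ValueError(f"covariates are collinear (|r| = {abs(r_ab):.3f})")
    x = sm.add_constant(np.column_stack([a, b]))
    fit = sm.OLS(y, x).fit()
    return pd.DataFrame(
        {
            "term": ["intercept", "covariate_a", "covariate_b"],
            "coefficient": fit.params,
            "p": fit.pvalues,
        }
    ).reset_index(drop=True)
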