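"""Lightweight in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Integer gene x cell (or gene x sample) count table with aligned
    identifier vectors."""

    values: np.ndarray  # (n_genes, n_cells) nonnegative integers
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("matrix shape does not match identifier vectors")
        if np.any(self.values < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class NormMatrix:
    """Log-normalized gene x cell expression with normalization provenance."""

    values: np.ndarray  # (n_genes, n_cells), log scale, >= 0
    gene_ids: list[str]
    cell_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("matrix shape does not match identifier vectors")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class SCDataset:
    """A simulated single-cell experiment: counts plus aligned metadata and
    the hidden ground truth used only for evaluation."""

    counts: CountMatrix
    cell_meta: pd.DataFrame  # index: cell_id; donor, group, resistant, cnv_carrier
    gene_meta: pd.DataFrame  # index: gene_id; chromosome, start, end, module, tolerance_class
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.cell_meta.index) != list(self.counts.cell_ids):
            raise ValueError("cell_meta rows must align with count columns")
        if list(self.gene_meta.index) != list(self.counts.gene_ids):
            raise ValueError("gene_meta rows must align with count rows")


@dataclass
class BulkDataset:
    """A simulated multi-source bulk experiment on a log expression scale."""

    expr: pd.DataFrame        # genes x samples, log scale
    sample_meta: pd.DataFrame  # index: sample_id; source, is_mdsc

    def __post_init__(self) -> None:
        if list(self.sample_meta.index) != list(self.expr.columns):
            raise ValueError("sample_meta rows must align with expression columns")
        # every source needs at least one MDSC and one control sample
        for src, grp in self.sample_meta.groupby("source"):
            flags = grp["is_mdsc"].astype(bool)
            if not (flags.any() and (~flags).any()):
                raise ValueError(f"source {src!r} lacks an MDSC or control sample")
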