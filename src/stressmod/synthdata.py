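"""Synthetic single-cell and multi-source bulk data generator.

The single-cell generator emulates a three-arm myeloid culture design:
control monocytes (C), cytokine-induced MDSC-like cells (T), and
cytokine-treated cells under serum starvation (TS) containing a resistant
subpopulation.  Counts follow a negative-binomial law around cell-specific
library sizes; planted modules are driven by shared per-cell latent Gaussian
factors, and planted copy-number blocks multiply the mean expression of
spanned genes in carrier cells.  The bulk generator emulates a multi-source
paired MDSC/control design with per-source batch offsets, where
stress-tolerant module genes are induced in every MDSC sample but
stress-sensitive module genes only in a subset of sources.

All randomness is controlled by ``SimConfig.seed``; identical configs give
bit-identical output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CnvBlock, PlantedModule, SimConfig
from .containers import BulkDataset, CountMatrix, SCDataset

__all__ = ["simulate_sc_experiment", "simulate_bulk_sources"]

_GENE_SPACING = 1_000  # synthetic bp between gene starts; only order matters
_GENE_LENGTH = 500


def _universe_rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    """Generator for fixed gene-universe properties (baselines, stress
    program); keyed by universe shape, not by the experiment seed."""
    return np.random.default_rng([7771 + stream, cfg.n_genes])


def _gene_table(cfg: SimConfig) -> pd.DataFrame:
    chroms = cfg.chromosome_of()
    starts = np.empty(cfg.n_genes, dtype=int)
    pos = 0
    prev = None
    for i, c in enumerate(chroms):
        if c != prev:
            pos = 0
            prev = c
        starts[i] = pos
        pos += _GENE_SPACING
    module = np.array([""] * cfg.n_genes, dtype=object)
    tol = np.array(["none"] * cfg.n_genes, dtype=object)
    idx = {g: i for i, g in enumerate(cfg.gene_ids())}
    for mod in cfg.modules:
        for g in mod.gene_ids:
            module[idx[g]] = mod.name
            tol[idx[g]] = mod.tolerance_class
    return pd.DataFrame(
        {
            "chromosome": chroms,
            "start": starts,
            "end": starts + _GENE_LENGTH,
            "module": module,
            "tolerance_class": tol,
        },
        index=pd.Index(cfg.gene_ids(), name="gene_id"),
    )


def _cnv_gene_indices(cfg: SimConfig, block: CnvBlock) -> np.ndarray:
    chroms = np.asarray(cfg.chromosome_of())
    on_chrom = np.flatnonzero(chroms == block.chromosome)
    return on_chrom[block.start_gene : block.start_gene + block.length]


def simulate_sc_experiment(cfg: SimConfig) -> SCDataset:
    """Draw a single-cell count matrix with planted structure.

    Per cell, gene means are ``library_size * softmax(eta)`` where ``eta``
    stacks a per-gene baseline, module latent factors scaled by their
    loading, group/resistance log-shifts and ``ln(2) * dosage`` for
    copy-number carrier cells; counts are negative binomial with a shared
    dispersion (gamma-Poisson mixture).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    gene_ids = cfg.gene_ids()
    n_genes = cfg.n_genes

    # --- cells -------------------------------------------------------
    donors, groups, cell_ids = [], [], []
    for d in range(cfg.n_donors):
        for g in cfg.groups:
            for j in range(cfg.n_cells_per_group):
                donors.append(f"D{d + 1}")
                groups.append(g)
                cell_ids.append(f"D{d + 1}_{g}_{j:04d}")
    donors_arr = np.asarray(donors)
    groups_arr = np.asarray(groups)
    n_cells = len(cell_ids)

    is_ts = groups_arr == "TS"
    resistant = np.zeros(n_cells, dtype=bool)
    resistant[is_ts] = rng.random(is_ts.sum()) < cfg.resistant_fraction
    treated = groups_arr != "C"
    carrier = np.zeros(n_cells, dtype=bool)
    carrier[treated] = rng.random(treated.sum()) < cfg.cnv_carrier_fraction

    # --- log-mean construction --------------------------------------
    # gene baselines and the starvation-stress program are fixed
    # properties of the synthetic gene universe (shared by every
    # simulated experiment), not per-draw randomness
    base = _universe_rng(cfg, 0).normal(0.0, cfg.base_logmean_sd, size=n_genes)
    eta = np.tile(base[:, None], (1, n_cells))

    gidx0 = {g: i for i, g in enumerate(gene_ids)}
    if cfg.stress_gene_ids:
        rows = np.array([gidx0[g] for g in cfg.stress_gene_ids])
        # full-length universe vector so the program is stable across configs
        shift = _universe_rng(cfg, 1).normal(0.0, cfg.ts_stress_sd, size=n_genes)
        stressed = np.flatnonzero(is_ts & ~resistant)
        eta[np.ix_(rows, stressed)] += shift[rows][:, None]

    if cfg.resistant_marker_gene_ids:
        rows = np.array([gidx0[g] for g in cfg.resistant_marker_gene_ids])
        shift = _universe_rng(cfg, 2).normal(0.0, cfg.resistant_marker_sd, size=n_genes)
        res_cells = np.flatnonzero(is_ts & resistant)
        eta[np.ix_(rows, res_cells)] += shift[rows][:, None]

    gidx = {g: i for i, g in enumerate(gene_ids)}
    for mod in cfg.modules:
        rows = np.array([gidx[g] for g in mod.gene_ids])
        latent = rng.normal(0.0, 1.0, size=n_cells)
        eta[np.ix_(rows, np.arange(n_cells))] += mod.latent_loading * latent[None, :]
        shift = np.zeros(n_cells)
        shift[groups_arr == "T"] = mod.effect_T
        shift[is_ts & resistant] = mod.effect_TS_resistant
        shift[is_ts & ~resistant] = mod.effect_TS_other
        eta[rows[:, None], np.arange(n_cells)[None, :]] += shift[None, :]

    for blk in cfg.cnv_blocks:
        rows = _cnv_gene_indices(cfg, blk)
        eta[np.ix_(rows, np.flatnonzero(carrier))] += np.log(2.0) * blk.log2_dosage

    # --- sampling ----------------------------------------------------
    log_mu, log_sd = cfg.library_size_lognormal
    lib = np.exp(rng.normal(log_mu, log_sd, size=n_cells))
    # normalize by the constant baseline partition function so that planted
    # log-mean shifts are exact in expectation (shifted cells then carry a
    # slightly larger realized library, as real perturbations do)
    z_base = np.exp(base).sum()
    mu = np.exp(eta) / z_base * lib[None, :]
    r = 1.0 / cfg.nb_dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    counts = rng.poisson(lam).astype(np.int64)

    cell_meta = pd.DataFrame(
        {
            "donor": donors_arr,
            "group": groups_arr,
            "resistant": resistant,
            "cnv_carrier": carrier,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    truth = {
        "modules": {m.name: list(m.gene_ids) for m in cfg.modules},
        "tolerance_class": {m.name: m.tolerance_class for m in cfg.modules},
        "effects": {
            m.name: {
                "latent_loading": m.latent_loading,
                "effect_T": m.effect_T,
                "effect_TS_resistant": m.effect_TS_resistant,
                "effect_TS_other": m.effect_TS_other,
            }
            for m in cfg.modules
        },
        "cnv_blocks": [
            {
                "chromosome": b.chromosome,
                "start_gene": b.start_gene,
                "length": b.length,
                "log2_dosage": b.log2_dosage,
                "gene_ids": [gene_ids[i] for i in _cnv_gene_indices(cfg, b)],
            }
            for b in cfg.cnv_blocks
        ],
        "resistant_cells": [c for c, f in zip(cell_ids, resistant) if f],
        "cnv_carrier_cells": [c for c, f in zip(cell_ids, carrier) if f],
        "seed": cfg.seed,
    }
    return SCDataset(
        counts=CountMatrix(counts, gene_ids, cell_ids),
        cell_meta=cell_meta,
        gene_meta=_gene_table(cfg),
        truth=truth,
    )


def simulate_bulk_sources(cfg: SimConfig) -> BulkDataset:
    """Draw a multi-source bulk log-expression matrix.

    Each source receives a Gaussian per-gene batch offset (sd
    ``source_batch_sd``) shared by its samples.  Tolerant-module genes are
    shifted by their ``effect_T`` in every MDSC sample; sensitive-module
    genes only in the first ``n_sensitive_sources`` sources.
    """
    cfg.validate()
    if cfg.n_sources < 2:
        raise ValueError("n_sources must be >= 2")
    if cfg.n_samples_per_arm < 1:
        raise ValueError("n_samples_per_arm must be >= 1")
    # independent stream from the single-cell draw, still seed-determined
    rng = np.random.default_rng([cfg.seed, 0xB01D])
    gene_ids = cfg.gene_ids()
    n_genes = cfg.n_genes

    sample_ids, sources, is_mdsc = [], [], []
    for s in range(cfg.n_sources):
        for arm, flag in (("ctrl", False), ("mdsc", True)):
            for j in range(cfg.n_samples_per_arm):
                sample_ids.append(f"S{s + 1}_{arm}_{j + 1}")
                sources.append(f"S{s + 1}")
                is_mdsc.append(flag)
    n_samples = len(sample_ids)
    src_index = np.array([int(s[1:].split("_")[0]) - 1 for s in sample_ids])
    mdsc = np.asarray(is_mdsc)

    base = rng.normal(5.0, 1.0, size=n_genes)
    batch = rng.normal(0.0, cfg.source_batch_sd, size=(n_genes, cfg.n_sources))
    noise = rng.normal(0.0, cfg.bulk_noise_sd, size=(n_genes, n_samples))
    expr = base[:, None] + batch[:, src_index] + noise

    gidx = {g: i for i, g in enumerate(gene_ids)}
    sensitive_sources = set(range(min(cfg.n_sensitive_sources, cfg.n_sources)))
    for mod in cfg.modules:
        rows = np.array([gidx[g] for g in mod.gene_ids])
        if mod.tolerance_class == "tolerant":
            cols = np.flatnonzero(mdsc)
        elif mod.tolerance_class == "sensitive":
            cols = np.flatnonzero(mdsc & np.isin(src_index, list(sensitive_sources)))
        else:
            continue
        if cols.size:
            expr[np.ix_(rows, cols)] += mod.effect_T

    sample_meta = pd.DataFrame(
        {"source": sources, "is_mdsc": mdsc},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return BulkDataset(
        expr=pd.DataFrame(expr, index=gene_ids, columns=sample_ids),
        sample_meta=sample_meta,
    )
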