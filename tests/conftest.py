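"""Shared fixtures: one simulated experiment (and its derived stages) is
reused across the suite so expensive steps run once."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import stressmod as sm
from stressmod.config import SimConfig, default_config

FIXTURE_SEED = 3


@pytest.fixture(scope="session")
def cfg():
    return default_config(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def sc_data(cfg):
    return sm.simulate_sc_experiment(cfg)


@pytest.fixture(scope="session")
def norm(sc_data):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.normalize_log_cp10k(sc_data.counts)


@pytest.fixture(scope="session")
def pca(norm):
    z = np.clip(sm.zscore_genes(norm.values, 1), -10, 10)
    return sm.compute_pca(z, 30, gene_ids=norm.gene_ids, cell_ids=norm.cell_ids)


@pytest.fixture(scope="session")
def metacells(norm, pca, sc_data):
    return sm.make_metacells(norm, pca, sc_data.cell_meta["donor"], seed=0)


@pytest.fixture(scope="session")
def consensus_modules(metacells):
    """Per-donor soft threshold -> TOM -> consensus -> module detection."""
    pick = sm.pick_soft_threshold(metacells)
    toms = []
    for donor in sorted(set(metacells.donor)):
        sub = metacells.expr[:, metacells.donor == donor]
        toms.append(sm.compute_tom(sm.build_adjacency(sub, pick[donor])))
    cons = sm.consensus_tom(toms)
    assignment = sm.detect_modules(cons, metacells.gene_ids)
    eig = sm.module_eigengenes(metacells, assignment)
    kme = sm.compute_kme(metacells, eig)
    return {
        "soft_power": pick, "toms": toms, "consensus": cons,
        "assignment": assignment, "eigengenes": eig, "kme": kme,
    }


@pytest.fixture(scope="session")
def truth_contrast_degs(sc_data, norm):
    """DEG tables for the two contrasts using ground-truth labels."""
    meta = sc_data.cell_meta
    t = list(meta.index[meta["group"] == "T"])
    c = list(meta.index[meta["group"] == "C"])
    ts = meta[meta["group"] == "TS"]
    res = list(ts.index[ts["resistant"]])
    other = list(ts.index[~ts["resistant"]])
    deg_ct = sm.wilcoxon_de(norm, t, c, contrast="T_vs_C")
    deg_r = sm.wilcoxon_de(norm, res, other, contrast="resistant_vs_otherTS")
    return deg_ct, deg_r


def null_config(seed: int = 0, n_cells: int = 300, n_genes: int = 600) -> SimConfig:
    """All effects zero, no planted structure: pure sampling noise."""
    return SimConfig(
        n_donors=1, n_cells_per_group=n_cells, n_genes=n_genes,
        modules=[], cnv_blocks=[], seed=seed,
    )


@pytest.fixture(scope="session")
def bulk_data(cfg):
    return sm.simulate_bulk_sources(cfg)
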