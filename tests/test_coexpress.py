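"""Consensus co-expression network construction and module summaries."""

import numpy as np
import pandas as pd
import pytest

import stressmod as sm
from stressmod.coexpress import (
    Metacells,
    _scale_free_r2,
    reassign_by_kme,
)


def _metacells_from(expr, gene_ids=None, donor=None):
    expr = np.asarray(expr, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(expr.shape[0])]
    donor = donor if donor is not None else np.array(["D1"] * expr.shape[1])
    return Metacells(expr, gene_ids, np.asarray(donor),
                     [[f"c{j}"] for j in range(expr.shape[1])])


class TestMetacells:
    def test_k_agg_one_returns_cells(self, norm, pca, sc_data):
        mc = sm.make_metacells(norm, pca, sc_data.cell_meta["donor"],
                               k_agg=1, max_shared=0, seed=0)
        assert mc.n_metacells == len(norm.cell_ids)
        # each metacell is a single cell: expression matches exactly
        pos = {c: i for i, c in enumerate(norm.cell_ids)}
        for j in range(0, mc.n_metacells, 500):
            (cell,) = mc.membership[j]
            np.testing.assert_array_equal(mc.expr[:, j], norm.values[:, pos[cell]])

    def test_aggregation_is_exact_mean(self, norm, pca, sc_data, metacells):
        pos = {c: i for i, c in enumerate(norm.cell_ids)}
        for j in (0, len(metacells.membership) // 2):
            cols = [pos[c] for c in metacells.membership[j]]
            np.testing.assert_allclose(
                metacells.expr[:, j], norm.values[:, cols].mean(axis=1), atol=1e-12)
            assert len(cols) == 25

    def test_denoising_boosts_module_correlation(self, cfg, norm, metacells):
        """Planted-module gene pairs correlate more on metacells than on
        raw cells."""
        gpos = {g: i for i, g in enumerate(norm.gene_ids)}
        rows = [gpos[g] for g in cfg.modules[0].gene_ids[:20]]
        def mean_offdiag(x):
            c = np.corrcoef(x)
            return c[np.triu_indices_from(c, k=1)].mean()
        assert mean_offdiag(metacells.expr[rows]) > mean_offdiag(norm.values[rows]) + 0.1

    def test_small_donor_skipped_with_warning(self, norm, pca):
        donors = np.array(["tiny"] * 3 + ["big"] * (len(norm.cell_ids) - 3))
        with pytest.warns(UserWarning, match="fewer than k_agg"):
            mc = sm.make_metacells(norm, pca, donors, k_agg=10, seed=0)
        assert set(mc.donor) == {"big"}


class TestAdjacency:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        expr = np.vstack([x, 2 * x + 1, -x])
        adj = sm.build_adjacency(expr, beta=6)
        assert adj[0, 1] == pytest.approx(1.0)
        assert adj[0, 2] == pytest.approx(0.0)

    def test_zero_correlation_value(self):
        # orthogonal, zero-mean patterns: cor = 0 -> a = 0.5 ** beta
        expr = np.array([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]])
        adj = sm.build_adjacency(expr, beta=6)
        assert adj[0, 1] == pytest.approx(0.5**6)
        assert adj[0, 1] == pytest.approx(0.015625)

    def test_too_few_metacells_rejected(self):
        with pytest.raises(ValueError):
            sm.build_adjacency(np.ones((3, 2)), beta=6)


class TestTOM:
    def test_hand_example_uniform_half(self):
        adj = np.full((3, 3), 0.5)
        np.fill_diagonal(adj, 1.0)
        tom = sm.compute_tom(adj)
        assert tom[0, 1] == pytest.approx(0.5)

    def test_zero_offdiagonal(self):
        tom = sm.compute_tom(np.eye(4))
        assert np.all(tom[~np.eye(4, dtype=bool)] == 0)
        assert np.all(np.diag(tom) == 1)

    @pytest.mark.parametrize("n", [20, 30])
    def test_matches_triple_loop_oracle(self, n):
        rng = np.random.default_rng(n)
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = sm.compute_tom(a)
        k = a.sum(axis=0) - 1
        expected = np.eye(n)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                expected[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
        np.testing.assert_allclose(tom, expected, atol=1e-12)
        assert np.allclose(tom, tom.T) and tom.min() >= 0 and tom.max() <= 1

    def test_asymmetric_rejected(self):
        bad = np.eye(3)
        bad[0, 1] = 0.5
        with pytest.raises(ValueError):
            sm.compute_tom(bad)


class TestConsensus:
    def test_identical_inputs_passthrough(self):
        rng = np.random.default_rng(1)
        t = rng.random((6, 6))
        t = (t + t.T) / 2
        np.fill_diagonal(t, 1.0)
        np.testing.assert_allclose(sm.consensus_tom([t, t]), t, atol=1e-12)

    def test_minimum_after_scaling(self):
        t1 = np.full((4, 4), 0.2); np.fill_diagonal(t1, 1.0)
        t2 = np.full((4, 4), 0.6); np.fill_diagonal(t2, 1.0)
        cons = sm.consensus_tom([t1, t2], quantile=0.0)
        # t2 is scaled down to t1's level; minimum is 0.2 off-diagonal
        assert cons[0, 1] == pytest.approx(0.2)

    def test_consensus_below_each_scaled_donor(self):
        rng = np.random.default_rng(2)
        toms = []
        for _ in range(3):
            t = rng.random((8, 8)) * 0.8
            t = (t + t.T) / 2
            np.fill_diagonal(t, 1.0)
            toms.append(t)
        cons = sm.consensus_tom(toms, quantile=0.0)
        iu = np.triu_indices(8, 1)
        ref = np.percentile(toms[0][iu], 95)
        for t in toms:
            scaled = np.clip(t * (ref / np.percentile(t[iu], 95)), 0, 1)
            assert np.all(cons[iu] <= scaled[iu] + 1e-12)

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            sm.consensus_tom([np.eye(3), np.eye(4)])


class TestSoftThreshold:
    def test_uniform_correlation_falls_back_with_warning(self):
        x = np.linspace(0, 1, 12)
        expr = np.vstack([x] * 8)  # identical genes: constant connectivity
        mc = _metacells_from(expr)
        with pytest.warns(UserWarning):
            pick = sm.pick_soft_threshold(mc, powers=[1, 2, 3])
        assert pick["D1"] in (1, 2, 3)

    def test_matches_independent_criterion_oracle(self, metacells):
        """An independently coded smallest-beta-reaching-R2 rule lands
        within +/-2 of the packaged choice."""
        donor = sorted(set(metacells.donor))[0]
        x = metacells.expr[:, metacells.donor == donor]
        x = x[x.std(axis=1) > 0]
        powers = list(range(1, 21))
        pick = sm.pick_soft_threshold(metacells, powers)[donor]
        corr = np.corrcoef(x)
        base = (1 + np.clip(corr, -1, 1)) / 2
        r2s = np.array([_scale_free_r2(base**beta) for beta in powers])
        ok = np.flatnonzero(np.nan_to_num(r2s, nan=-np.inf) >= 0.8)
        if ok.size:
            chosen = powers[ok[0]]
        else:
            chosen = powers[int(np.nanargmax(r2s))]
        assert abs(chosen - pick) <= 2

    def test_r2_invariant_to_gene_order(self, metacells):
        donor = sorted(set(metacells.donor))[0]
        x = metacells.expr[:, metacells.donor == donor]
        x = x[x.std(axis=1) > 0]
        adj = sm.build_adjacency(x, beta=6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(adj.shape[0])
        assert _scale_free_r2(adj) == pytest.approx(
            _scale_free_r2(adj[np.ix_(perm, perm)]), abs=1e-12)

    def test_invalid_powers_rejected(self, metacells):
        with pytest.raises(ValueError):
            sm.pick_soft_threshold(metacells, powers=[])
        with pytest.raises(ValueError):
            sm.pick_soft_threshold(metacells, powers=[3, 1])


class TestModuleDetection:
    def _block_tom(self, sizes=(10, 10), n_background=0, within=0.7, between=0.05):
        n = sum(sizes) + n_background
        tom = np.full((n, n), between)
        start = 0
        for s in sizes:
            tom[start:start + s, start:start + s] = within
            start += s
        np.fill_diagonal(tom, 1.0)
        return tom

    def test_two_planted_blocks_exact(self):
        tom = self._block_tom()
        genes = [f"g{i:02d}" for i in range(20)]
        asg = sm.detect_modules(tom, genes, min_module_size=5, cut_height=0.5)
        got = {m: set(asg.index[asg == m]) for m in set(asg) - {"grey"}}
        expected = [set(genes[:10]), set(genes[10:])]
        assert len(got) == 2
        assert sorted(got.values(), key=len) == sorted(expected, key=len) or \
            list(got.values())[0] in expected

    def test_oversized_min_module_all_grey(self):
        tom = self._block_tom()
        with pytest.warns(UserWarning, match="grey"):
            asg = sm.detect_modules(tom, [f"g{i}" for i in range(20)],
                                    min_module_size=50, cut_height=0.5)
        assert set(asg) == {"grey"}

    def test_gene_permutation_invariance(self):
        tom = self._block_tom(sizes=(8, 7), n_background=5)
        genes = [f"g{i:02d}" for i in range(20)]
        asg = sm.detect_modules(tom, genes, min_module_size=5, cut_height=0.5)
        rng = np.random.default_rng(4)
        perm = rng.permutation(20)
        asg_p = sm.detect_modules(tom[np.ix_(perm, perm)],
                                  [genes[i] for i in perm],
                                  min_module_size=5, cut_height=0.5)
        # same partition, gene-by-gene, up to module label names
        mapping = {}
        for g in genes:
            mapping.setdefault(asg[g], set()).add(asg_p[g])
        assert all(len(v) == 1 for v in mapping.values())

    def test_planted_module_recovery_on_simulation(self, sc_data, consensus_modules):
        asg = consensus_modules["assignment"]
        for name, genes in sc_data.truth["modules"].items():
            best = max(
                len(set(asg.index[asg == m]) & set(genes))
                / len(set(asg.index[asg == m]) | set(genes))
                for m in set(asg) - {"grey"}
            )
            assert best >= 0.8, f"{name} recovered with Jaccard {best:.2f}"


class TestEigengenesAndKme:
    def test_single_gene_module(self):
        rng = np.random.default_rng(0)
        expr = rng.normal(size=(3, 10))
        mc = _metacells_from(expr)
        asg = pd.Series(["m1", "grey", "grey"], index=mc.gene_ids)
        eig = sm.module_eigengenes(mc, asg)
        z = (expr[0] - expr[0].mean()) / expr[0].std(ddof=1)
        assert abs(np.corrcoef(eig["m1"], z)[0, 1]) == pytest.approx(1.0)
        kme = sm.compute_kme(mc, eig)
        assert kme.loc["g0", "m1"] == pytest.approx(1.0)

    def test_two_identical_genes(self):
        x = np.sin(np.arange(12))
        mc = _metacells_from(np.vstack([x, x]))
        asg = pd.Series(["m1", "m1"], index=mc.gene_ids)
        eig = sm.module_eigengenes(mc, asg)
        assert abs(np.corrcoef(eig["m1"], x)[0, 1]) == pytest.approx(1.0)

    def test_eigengene_is_optimal_direction(self):
        """PCA optimality: no single member gene's direction explains more
        projected variance than the eigengene."""
        rng = np.random.default_rng(5)
        latent = rng.normal(size=30)
        expr = 0.8 * latent[None, :] + rng.normal(scale=0.6, size=(6, 30))
        mc = _metacells_from(expr)
        asg = pd.Series(["m1"] * 6, index=mc.gene_ids)
        eig = sm.module_eigengenes(mc, asg)["m1"].to_numpy()
        z = (expr - expr.mean(1, keepdims=True)) / expr.std(1, ddof=1, keepdims=True)
        var_eig = ((z @ (eig / np.linalg.norm(eig))) ** 2).sum()
        for i in range(6):
            d = z[i] / np.linalg.norm(z[i])
            assert var_eig >= ((z @ d) ** 2).sum() - 1e-9

    def test_orthogonal_gene_has_zero_kme(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        mc = _metacells_from(np.vstack([x, y]))
        asg = pd.Series(["m1", "grey"], index=mc.gene_ids)
        eig = sm.module_eigengenes(mc, asg)
        kme = sm.compute_kme(mc, eig)
        assert kme.loc["g1", "m1"] == pytest.approx(0.0, abs=1e-12)

    def test_members_prefer_own_module(self, sc_data, consensus_modules):
        asg, kme = consensus_modules["assignment"], consensus_modules["kme"]
        planted = set(g for gs in sc_data.truth["modules"].values() for g in gs)
        members = [g for g in asg.index if asg[g] != "grey" and g in planted]
        own_best = np.mean([kme.loc[g].idxmax() == asg[g] for g in members])
        assert own_best >= 0.95


class TestTraitsAndHubs:
    def test_trait_equal_to_eigengene(self, consensus_modules):
        eig = consensus_modules["eigengenes"]
        mod = eig.columns[0]
        traits = pd.DataFrame({"self": eig[mod], "flipped": -eig[mod]})
        tc = sm.module_trait_correlation(eig, traits)
        r_self = tc[(tc["module"] == mod) & (tc["trait"] == "self")]["r"].iloc[0]
        r_flip = tc[(tc["module"] == mod) & (tc["trait"] == "flipped")]["r"].iloc[0]
        assert r_self == pytest.approx(1.0)
        assert r_flip == pytest.approx(-1.0)

    def test_constant_trait_dropped(self, consensus_modules):
        eig = consensus_modules["eigengenes"]
        with pytest.warns(UserWarning, match="constant trait"):
            tc = sm.module_trait_correlation(
                eig, pd.DataFrame({"flat": np.ones(len(eig))}))
        assert tc.empty

    def test_tolerant_module_tracks_resistant_cells(
            self, sc_data, metacells, consensus_modules):
        """The detected counterpart of the planted tolerant module has the
        top correlation with the resistant-cell trait."""
        asg = consensus_modules["assignment"]
        eig = consensus_modules["eigengenes"]
        tol_genes = set(sc_data.truth["modules"]["planted_tolerant"])
        tol_mod = max(set(asg) - {"grey"},
                      key=lambda m: len(set(asg.index[asg == m]) & tol_genes))
        res = sc_data.cell_meta["resistant"]
        grp = sc_data.cell_meta["group"]
        ts_frac = np.array([ (grp.loc[m] == "TS").mean() for m in metacells.membership])
        in_ts = ts_frac > 0.5  # the contrast lives within the starved arm
        trait = pd.DataFrame(
            {"resistant": [res.loc[m].mean() for m in metacells.membership]})
        tc = sm.module_trait_correlation(
            eig[in_ts].reset_index(drop=True), trait[in_ts].reset_index(drop=True)
        ).sort_values("r", ascending=False)
        r_tol = tc.set_index("module").loc[tol_mod, "r"]
        # the resistant cells' own marker program may edge it out, but the
        # tolerant module must be strongly positive and near the top
        assert r_tol > 0.5
        assert tol_mod in list(tc["module"].head(2))

    def test_top_hub_genes_prefix_and_warning(self, consensus_modules):
        asg, kme = consensus_modules["assignment"], consensus_modules["kme"]
        mod = [m for m in kme.columns if (asg == m).sum() >= 10][0]
        full = sm.top_hub_genes(kme, asg, mod, n=(asg == mod).sum())
        assert sm.top_hub_genes(kme, asg, mod, n=5) == full[:5]
        with pytest.warns(UserWarning):
            sm.top_hub_genes(kme, asg, mod, n=10_000)

    def test_kme_reassignment_moves_only_clear_cases(self, consensus_modules):
        asg, kme = consensus_modules["assignment"], consensus_modules["kme"]
        out = reassign_by_kme(asg, kme, gap=0.1)
        moved = asg.index[(out != asg)]
        for g in moved:
            assert kme.loc[g, out[g]] - kme.loc[g, asg[g]] > 0.1
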