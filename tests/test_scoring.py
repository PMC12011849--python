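"""Signature scoring, ROC/AUC, label transfer, multivariate association."""

import numpy as np
import pandas as pd
import pytest

import stressmod as sm


def _expr(rows, genes=None, samples=None):
    rows = np.asarray(rows, dtype=float)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    samples = samples or [f"s{i}" for i in range(rows.shape[1])]
    return pd.DataFrame(rows, index=genes, columns=samples)


class TestSignatureScore:
    def test_antisymmetric_pair_cancels(self):
        expr = _expr([[1, 2, 3], [3, 2, 1]])
        scores = sm.signature_score(expr, ["g0", "g1"])
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_single_gene_is_zscore(self):
        scores = sm.signature_score(_expr([[1, 2, 3]]), ["g0"])
        np.testing.assert_allclose(scores, [-1.0, 0.0, 1.0])

    def test_scores_mean_zero_and_affine_invariance(self):
        rng = np.random.default_rng(0)
        expr = _expr(rng.normal(size=(30, 12)))
        genes = [f"g{i}" for i in range(0, 30, 3)]
        scores = sm.signature_score(expr, genes)
        assert abs(scores.mean()) < 1e-12
        rescaled = expr.copy()
        rescaled.iloc[0] = 5.0 * rescaled.iloc[0] - 2.0
        np.testing.assert_allclose(
            scores, sm.signature_score(rescaled, genes), atol=1e-12)

    def test_missing_genes_warn_or_reject(self):
        expr = _expr([[1, 2, 3]])
        with pytest.warns(UserWarning, match="absent"):
            sm.signature_score(expr, ["g0", "nope"])
        with pytest.raises(ValueError):
            sm.signature_score(expr, ["nope"])


class TestRocAuc:
    def test_perfect_separation(self):
        with pytest.warns(UserWarning, match="separation"):
            rep = sm.roc_auc([0.1, 0.2, 0.9, 0.8], [0, 0, 1, 1])
        assert rep.auc == 1.0 and rep.separable

    def test_interleaved_example(self):
        rep = sm.roc_auc([1.0, 2.0, 3.0, 4.0], [0, 1, 0, 1])
        assert rep.auc == pytest.approx(0.75)

    def test_ties_get_half_credit(self):
        rep = sm.roc_auc([1.0, 1.0], [0, 1])
        assert rep.auc == pytest.approx(0.5)

    def test_negation_symmetry(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=60)
        y = rng.integers(0, 2, size=60)
        y[0], y[1] = 0, 1
        a = sm.roc_auc(s, y).auc
        b = sm.roc_auc(-s, y).auc
        assert a + b == pytest.approx(1.0)

    def test_logistic_probability_auc_equals_rank_auc(self):
        """Monotone-transform invariance holds on random draws."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            s = rng.normal(size=80)
            y = (s + rng.normal(scale=1.5, size=80) > 0).astype(int)
            if y.min() == y.max():
                continue
            rep = sm.roc_auc(s, y)  # raises internally if they disagree
            assert 0.0 <= rep.auc <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sm.roc_auc([1.0, 2.0], [1, 1])

    def test_roc_curve_monotone(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=50)
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        rep = sm.roc_auc(s, y)
        assert np.all(np.diff(rep.fpr) >= 0) and np.all(np.diff(rep.tpr) >= 0)
        assert (rep.fpr[0], rep.tpr[0]) == (0.0, 0.0)
        assert (rep.fpr[-1], rep.tpr[-1]) == (1.0, 1.0)


class TestModuleSeparation:
    def test_null_module_near_half(self):
        rng = np.random.default_rng(4)
        expr = _expr(rng.normal(size=(40, 200)))
        labels = pd.Series(rng.integers(0, 2, size=200), index=expr.columns)
        labels.iloc[:2] = [0, 1]
        asg = pd.Series(["m1"] * 20 + ["grey"] * 20, index=expr.index)
        table = sm.evaluate_module_separation(asg, expr, {"null": labels})
        assert abs(table["auc_null"].iloc[0] - 0.5) < 0.15

    def test_tolerant_module_best_on_bulk(self, cfg, bulk_data, sc_data):
        """Cross-source discrimination: the planted tolerant module beats
        the sensitive and neutral ones on the multi-source bulk design."""
        asg = pd.Series("grey", index=bulk_data.expr.index, dtype=object)
        for mod in cfg.modules:
            asg[mod.gene_ids] = mod.name
        labels = bulk_data.sample_meta["is_mdsc"].astype(int)
        table = sm.evaluate_module_separation(
            asg, bulk_data.expr, {"mdsc": labels}).set_index("module")
        assert table.loc["planted_tolerant", "best"]
        assert table.loc["planted_tolerant", "auc_mdsc"] > \
            table.loc["planted_sensitive", "auc_mdsc"]


class TestLabelTransfer:
    def test_reference_reproduced(self):
        rng = np.random.default_rng(5)
        centers = {"a": rng.normal(size=60), "b": rng.normal(size=60)}
        cols, labels = [], []
        for name, mu in centers.items():
            for i in range(20):
                cols.append(mu + rng.normal(scale=0.4, size=60))
                labels.append(name)
        expr = _expr(np.column_stack(cols))
        labels = pd.Series(labels, index=expr.columns)
        pred = sm.transfer_labels(expr, labels, expr)
        assert (pred["predicted"] == labels).all()

    def test_centroids_classify_as_themselves(self):
        rng = np.random.default_rng(6)
        ref = _expr(rng.normal(size=(80, 30)))
        labels = pd.Series(["x"] * 15 + ["y"] * 15, index=ref.columns)
        clf = sm.CentroidLabelTransfer().fit(ref, labels)
        query = clf.centroids_.copy()
        query.columns = ["qx", "qy"]
        pred = clf.predict(query)
        assert list(pred) == ["x", "y"]

    def test_too_few_shared_genes_rejected(self):
        rng = np.random.default_rng(7)
        ref = _expr(rng.normal(size=(60, 10)))
        labels = pd.Series(["x"] * 5 + ["y"] * 5, index=ref.columns)
        clf = sm.CentroidLabelTransfer().fit(ref, labels)
        query = _expr(rng.normal(size=(10, 4)),
                      genes=[f"other{i}" for i in range(10)])
        with pytest.raises(ValueError, match="shared genes"):
            clf.predict(query)

    def test_resistant_cells_recovered_across_experiments(self, cfg, sc_data, norm):
        """Query cells regenerated from the same model (new seed) are
        assigned resistant/other with accuracy >= 0.9."""
        import dataclasses

        grp = sc_data.cell_meta["group"]
        ts = list(grp.index[grp == "TS"])
        ref_labels = sc_data.cell_meta.loc[ts, "resistant"].map(
            {True: "resistant", False: "other"})
        query_ds = sm.simulate_sc_experiment(dataclasses.replace(cfg, seed=cfg.seed + 100))
        qnorm = sm.normalize_log_cp10k(query_ds.counts)
        qgrp = query_ds.cell_meta["group"]
        qts = list(qgrp.index[qgrp == "TS"])
        pred = sm.transfer_labels(norm.to_frame()[ts], ref_labels,
                                  qnorm.to_frame()[qts])
        truth = query_ds.cell_meta.loc[qts, "resistant"]
        acc = ((pred["predicted"] == "resistant") == truth).mean()
        assert acc >= 0.9
        assert ((pred["confidence"] > 0.5) | np.isclose(pred["confidence"], 0.5)).all()


class TestMultivariateAssociation:
    def test_exact_recovery(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        res = sm.multivariate_association(a, a, b).set_index("term")
        assert res.loc["covariate_a", "coefficient"] == pytest.approx(1.0, abs=1e-10)
        assert res.loc["covariate_a", "p"] < 1e-10
        assert res.loc["covariate_b", "coefficient"] == pytest.approx(0.0, abs=1e-10)

    def test_additive_recovery_with_noise(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=1000)
        b = rng.normal(size=1000)
        y = a + b + rng.normal(scale=0.1, size=1000)
        res = sm.multivariate_association(y, a, b).set_index("term")
        assert res.loc["covariate_a", "coefficient"] == pytest.approx(1.0, abs=0.05)
        assert res.loc["covariate_b", "coefficient"] == pytest.approx(1.0, abs=0.05)

    def test_permutation_breaks_association(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        y = a + b
        hits = 0
        reps = 100
        for _ in range(reps):
            res = sm.multivariate_association(
                rng.permutation(y), a, b).set_index("term")
            hits += res.loc["covariate_a", "p"] < 0.05
        # null p values: rejections stay within binomial error of 5%
        assert hits / reps < 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_collinear_rejected_and_min_n(self):
        a = np.arange(20.0)
        with pytest.raises(ValueError, match="collinear"):
            sm.multivariate_association(a, a, 2 * a + 1e-9)
        with pytest.raises(ValueError, match="observations"):
            sm.multivariate_association(a[:5], a[:5], a[:5] ** 2)
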