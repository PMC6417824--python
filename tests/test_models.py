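"""Feature selection and phenotype classifiers."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mi2p import (
    CohortDesign,
    ModelSpec,
    average_roc,
    cross_validate,
    l1_select,
    qvalue_prefilter,
    simulate_abundance_matrix,
    train_predictor,
    tree_select,
)
from mi2p.models import ROC_GRID, PhenotypeClassifier


def toy_table(rng, n_genes=20, n_per_group=20, signal_genes=(), shift=4.0):
    samples = [f"c{i}" for i in range(n_per_group)] + [f"h{i}" for i in range(n_per_group)]
    labels = {s: ("case" if s.startswith("c") else "control") for s in samples}
    X = rng.normal(5, 1, size=(n_genes, 2 * n_per_group))
    for g in signal_genes:
        X[g, :n_per_group] += shift
    table = pd.DataFrame(np.abs(X), index=[f"g{i}" for i in range(n_genes)], columns=samples)
    return table, labels


class TestQvaluePrefilter:
    def test_group_identical_rows_all_removed(self):
        samples = [f"s{i}" for i in range(12)]
        labels = {s: ("case" if i < 6 else "control") for i, s in enumerate(samples)}
        table = pd.DataFrame(
            np.tile(np.arange(12.0), (5, 1)), index=[f"g{i}" for i in range(5)], columns=samples
        )
        # identical across groups after relabeling: every row has the same
        # values in both groups
        table.loc[:] = np.tile(np.r_[np.arange(6.0), np.arange(6.0)], (5, 1))
        assert qvalue_prefilter(table, labels, 0.05).shape[0] == 0

    def test_cutoff_one_keeps_all_in_order(self, rng):
        table, labels = toy_table(rng)
        kept = qvalue_prefilter(table, labels, 1.0)
        assert list(kept.index) == list(table.index)

    def test_recovers_planted_markers(self):
        design = CohortDesign(fold_change=4.0, abundance_dispersion=0.5, seed=42)
        table, labels, truth = simulate_abundance_matrix(design)
        kept = set(qvalue_prefilter(table, labels, 0.05).index)
        recovered = len(kept & set(truth.marker_ids)) / len(truth.marker_ids)
        assert recovered >= 0.8

    def test_degenerate_labels_rejected(self, rng):
        table, labels = toy_table(rng)
        with pytest.raises(ValueError):
            qvalue_prefilter(table, {s: "case" for s in table.columns}, 0.05)


class TestTreeSelect:
    def test_separating_gene_selected(self, rng):
        table, labels = toy_table(rng, signal_genes=(3,), shift=6.0)
        assert "g3" in tree_select(table, labels, seed=0)

    def test_identical_columns_fall_back_to_all(self):
        samples = [f"s{i}" for i in range(8)]
        labels = {s: ("case" if i < 4 else "control") for i, s in enumerate(samples)}
        table = pd.DataFrame(np.ones((5, 8)), index=[f"g{i}" for i in range(5)], columns=samples)
        assert tree_select(table, labels, seed=0) == list(table.index)

    def test_seed_determinism(self, rng):
        table, labels = toy_table(rng, signal_genes=(1, 2))
        assert tree_select(table, labels, seed=7) == tree_select(table, labels, seed=7)


class TestL1Select:
    def test_null_table_nearly_empty_under_strong_penalty(self, rng):
        table, labels = toy_table(rng, n_genes=50)
        sel = l1_select(table, labels, penalty_strength=20.0)
        assert len(sel) <= 5  # << 10% of genes on pure noise

    def test_separating_gene_selected(self, rng):
        table, labels = toy_table(rng, signal_genes=(4,), shift=6.0)
        assert "g4" in l1_select(table, labels, penalty_strength=1.0)

    def test_weak_penalty_keeps_nearly_all(self, rng):
        table, labels = toy_table(rng, n_genes=10, signal_genes=(0,))
        sel = l1_select(table, labels, penalty_strength=1e-4)
        assert len(sel) >= 8


class TestTrainPredictor:
    def test_decision_tree_memorizes_separable_data(self):
        table = pd.DataFrame(
            [[10.0, 9.0, 1.0, 0.5], [0.2, 0.1, 5.0, 6.0]],
            index=["g0", "g1"],
            columns=["a", "b", "c", "d"],
        )
        labels = {"a": "case", "b": "case", "c": "control", "d": "control"}
        clf = train_predictor(table, labels, ModelSpec(family="DT"))
        assert (clf.predict(table.T) == np.array(["case", "case", "control", "control"])).all()

    def test_rf_seed_determinism(self, rng):
        table, labels = toy_table(rng, signal_genes=(0,))
        a = train_predictor(table, labels, ModelSpec(family="RF", seed=3))
        b = train_predictor(table, labels, ModelSpec(family="RF", seed=3))
        assert np.array_equal(a.case_probability(table.T), b.case_probability(table.T))

    @pytest.mark.parametrize("family", ["RF", "SVM", "DT", "KN", "NN"])
    def test_probabilities_valid_across_families(self, rng, family):
        table, labels = toy_table(rng, n_per_group=25, signal_genes=(0, 1))
        spec = ModelSpec(family=family, n_hidden=64)  # small RBM keeps this quick
        clf = train_predictor(table, labels, spec)
        p = clf.case_probability(table.T)
        assert np.isfinite(p).all() and (p >= 0).all() and (p <= 1).all()

    def test_single_class_rejected(self, rng):
        table, _ = toy_table(rng)
        with pytest.raises(ValueError):
            train_predictor(table, {s: "case" for s in table.columns}, ModelSpec())


class TestCrossValidate:
    def test_separable_data_reaches_auc_one(self):
        design = CohortDesign(fold_change=16.0, abundance_dispersion=0.25, seed=9)
        table, labels, _ = simulate_abundance_matrix(design)
        res = cross_validate(table, labels, ModelSpec(family="RF"), scheme="kfold5")
        assert res.mean_auc >= 0.99
        grid, tpr = res.averaged_roc
        assert tpr[0] == 0.0 and tpr[-1] == 1.0
        assert (np.diff(tpr) >= -1e-12).all()

    def test_permuted_labels_are_chance_level(self):
        design = CohortDesign(fold_change=4.0, seed=10)
        table, labels, _ = simulate_abundance_matrix(design)
        rng = np.random.default_rng(10)
        values = rng.permutation([labels[s] for s in table.columns])
        permuted = dict(zip(table.columns, values))
        res = cross_validate(table, permuted, ModelSpec(family="RF"), scheme="kfold5")
        assert 0.4 <= res.mean_auc <= 0.6

    def test_loocv_auc_equals_pairwise_concordance(self, rng):
        table, labels = toy_table(rng, n_genes=6, n_per_group=8, signal_genes=(0,), shift=2.0)
        res = cross_validate(
            table, labels, ModelSpec(family="DT"), scheme="loocv", selection=None, q_cutoff=1.0
        )
        # recompute pooled scores the same way and count concordant pairs
        y = np.array([labels[s] for s in table.columns])
        from mi2p.models import _fit_select_score

        scores = np.empty(y.size)
        for i in range(y.size):
            train = np.setdiff1d(np.arange(y.size), [i])
            scores[i] = _fit_select_score(
                table, y, train, np.array([i]), ModelSpec(family="DT"), 1.0, None
            )[0]
        cases = scores[y == "case"]
        controls = scores[y == "control"]
        pairs = [(c, h) for c, h in itertools.product(cases, controls)]
        concordance = np.mean([1.0 if c > h else (0.5 if c == h else 0.0) for c, h in pairs])
        assert res.mean_auc == pytest.approx(concordance, abs=1e-12)

    def test_unknown_scheme_rejected(self, rng):
        table, labels = toy_table(rng)
        with pytest.raises(ValueError):
            cross_validate(table, labels, scheme="kfold7")


class TestAverageRoc:
    def test_identity_and_midpoint(self):
        tpr = np.linspace(0, 1, ROC_GRID.size) ** 0.5
        grid, avg = average_roc([(ROC_GRID, tpr)])
        assert np.allclose(avg, tpr)
        _, avg2 = average_roc([(ROC_GRID, tpr), (ROC_GRID, np.ones_like(tpr))])
        assert np.allclose(avg2, (tpr + 1) / 2)

    def test_monotone_preserved(self, rng):
        curves = []
        for _ in range(4):
            t = np.sort(rng.uniform(size=ROC_GRID.size))
            curves.append((ROC_GRID, t))
        _, avg = average_roc(curves)
        assert (np.diff(avg) >= 0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_roc([])

    def test_mismatched_grid_rejected(self):
        with pytest.raises(ValueError):
            average_roc([(ROC_GRID, ROC_GRID), (ROC_GRID[:50], ROC_GRID[:50])])


class TestSklearnInterface:
    def test_get_set_params_round_trip(self):
        clf = PhenotypeClassifier(family="RF", n_trees=10)
        params = clf.get_params()
        assert params["n_trees"] == 10
        clf.set_params(n_trees=50)
        assert clf.get_params()["n_trees"] == 50

    def test_clone_and_pipeline_compose(self, rng):
        from sklearn.base import clone
        from sklearn.pipeline import make_pipeline

        from mi2p.models import WilcoxonSelector

        table, labels = toy_table(rng, signal_genes=(0,))
        X = table.T.to_numpy()
        y = np.array([labels[s] for s in table.columns])
        pipe = make_pipeline(WilcoxonSelector(q_cutoff=1.0), PhenotypeClassifier(family="DT"))
        pipe.fit(X, y)
        assert set(pipe.predict(X)) <= {"case", "control"}
        clone(pipe)
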