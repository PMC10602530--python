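"""Stacked ensemble: splits, transform, base learners, stacking, evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import beta

import scrsdx as sx
from scrsdx.ensemble import (
    CLASS_ORDER,
    CVConfig,
    collapse_labels,
    collapse_to_three,
    diagnose_subjects,
    evaluate,
    fit_base_learners,
    fit_meta,
    fit_transform,
    model_correlation,
    predict_cells,
    split_train_test,
    train_ensemble,
)
from scrsdx.mda import MDAClassifier


class TestSplit:
    def test_balanced_cell_split_arithmetic(self):
        y = np.repeat(list(CLASS_ORDER), 20)
        plan = split_train_test(y, None, ratio=0.8, grouping="cell", seed=0)
        assert len(plan.train_idx) == 80 and len(plan.test_idx) == 20
        test_labels = pd.Series(y[plan.test_idx]).value_counts()
        assert (test_labels == 4).all()

    def test_subject_grouping_is_leak_free(self):
        rng = np.random.default_rng(0)
        subjects = np.repeat([f"s{i}" for i in range(20)], 5)
        y = np.repeat(rng.permutation(np.repeat(list(CLASS_ORDER), 4)), 5)
        plan = split_train_test(y, subjects, grouping="subject", seed=1)
        assert not (set(subjects[plan.train_idx]) & set(subjects[plan.test_idx]))

    def test_same_seed_same_plan(self):
        y = np.repeat(list(CLASS_ORDER), 10)
        p1 = split_train_test(y, None, grouping="cell", seed=7)
        p2 = split_train_test(y, None, grouping="cell", seed=7)
        assert np.array_equal(p1.test_idx, p2.test_idx)

    def test_singleton_class_errors(self):
        y = np.array(["a", "a", "b"])
        with pytest.raises(ValueError):
            split_train_test(y, None, grouping="cell", seed=0)

    def test_repeated_splits_cover_all_units(self):
        from scrsdx.ensemble import repeated_splits
        y = np.repeat(list(CLASS_ORDER), 10)
        plans = repeated_splits(y, None, grouping="cell", seed=0, n_repeats=5)
        assert len(plans) == 5
        tested = set()
        for p in plans:
            tested.update(p.test_idx.tolist())
        assert len(tested) > len(y) * 0.5  # most units reach the test set

    def test_grouped_split_never_leaks_over_many_seeds(self):
        """1000 random seeds, no subject ever straddles the partitions."""
        rng = np.random.default_rng(3)
        subjects = np.repeat([f"s{i}" for i in range(25)], 4)
        y = np.repeat(rng.permutation(np.repeat(list(CLASS_ORDER), 5)), 4)
        for seed in range(1000):
            plan = split_train_test(y, subjects, grouping="subject", seed=seed)
            assert not (set(subjects[plan.train_idx]) & set(subjects[plan.test_idx]))


class TestTransform:
    def test_train_scores_centered(self, rng):
        X = rng.normal(5, 2, (40, 30))
        t = fit_transform(X)
        Z = t.transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-9)

    def test_component_variances_non_increasing(self, rng):
        X = rng.normal(0, 1, (50, 20)) * np.linspace(5, 0.1, 20)
        t = fit_transform(X)
        ev = t.pca.explained_variance_
        assert (np.diff(ev) <= 1e-12).all()

    def test_rank_two_data_has_two_components(self, rng):
        u = rng.normal(0, 1, (60, 2))
        X = u @ rng.normal(0, 1, (2, 40))
        t = fit_transform(X, n_components=100)
        assert t.effective_rank == 2

    def test_respects_n_minus_one_cap(self, rng):
        X = rng.normal(0, 1, (12, 200))
        t = fit_transform(X, n_components=100)
        assert t.n_components == 11


def _gauss_scores(rng, n=60, d=5, sep=8.0, classes=("HC", "MS")):
    X = np.vstack([rng.normal(sep * i, 1.0, (n // len(classes), d))
                   for i in range(len(classes))])
    y = np.repeat(list(classes), n // len(classes))
    return X, y


class TestBaseLearners:
    def test_separable_scores_all_learners_accurate(self, rng):
        X, y = _gauss_scores(rng)
        base = fit_base_learners(X, y, cv=CVConfig(3, 1), seed=0)
        assert all(acc > 0.95 for acc in base.cv_accuracy.values()), base.cv_accuracy
        assert base.oof.shape == (60, 8 * 2)

    def test_permuted_labels_near_chance(self, rng):
        X, y = _gauss_scores(rng)
        y_perm = rng.permutation(y)
        base = fit_base_learners(X, y_perm, cv=CVConfig(3, 1), seed=0)
        se = np.sqrt(0.5 * 0.5 / len(y_perm))
        for name, acc in base.cv_accuracy.items():
            assert abs(acc - 0.5) < 3 * se + 0.15, (name, acc)

    def test_oof_rows_are_probability_simplices(self, rng):
        X, y = _gauss_scores(rng)
        base = fit_base_learners(X, y, cv=CVConfig(3, 1), seed=0)
        for k in range(8):
            block = base.oof[:, 2 * k: 2 * (k + 1)]
            np.testing.assert_allclose(block.sum(axis=1), 1.0, atol=1e-6)

    def test_small_class_reduces_folds_with_warning(self, rng):
        X = rng.normal(0, 1, (14, 3))
        y = np.array(["a"] * 10 + ["b"] * 4)
        with pytest.warns(UserWarning, match="reducing folds"):
            fit_base_learners(X, y, cv=CVConfig(10, 1), seed=0)


class TestMeta:
    def test_constant_correct_features_reproduced(self):
        y = np.repeat(["a", "b"], 30)
        onehot = pd.get_dummies(y).to_numpy(float)
        oof = np.hstack([onehot] * 8)
        meta = fit_meta(oof, y, seed=0)
        assert (meta.predict(oof) == y).all()

    def test_complementary_learners_combined(self, rng):
        """Two base learners see disjoint informative features; the stack
        must beat both."""
        n = 400
        b1 = rng.integers(0, 2, n)
        b2 = rng.integers(0, 2, n)
        y = np.array(["HC", "MildME", "ModME", "MS"])[2 * b1 + b2]
        noise = 0.35
        p1 = np.column_stack([b1 == 0, b1 == 1]).astype(float)
        p1 = np.clip(p1 + rng.normal(0, noise, p1.shape), 0.01, None)
        p1 /= p1.sum(1, keepdims=True)
        p2 = np.column_stack([b2 == 0, b2 == 1]).astype(float)
        p2 = np.clip(p2 + rng.normal(0, noise, p2.shape), 0.01, None)
        p2 /= p2.sum(1, keepdims=True)
        oof = np.hstack([p1, p2])
        tr, te = np.arange(0, 300), np.arange(300, n)
        meta = fit_meta(oof[tr], y[tr], seed=0)
        acc = np.mean(meta.predict(oof[te]) == y[te])
        acc1 = np.mean((b1[te] == 1) == (p1[te, 1] > 0.5))  # best single-bit accuracy ~ half the classes
        assert acc > 0.8  # each bit alone caps 4-class accuracy at ~0.5
        assert acc > acc1 / 2 + 0.25

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            fit_meta(np.ones((5, 4)), np.array(["a"] * 5))


class TestMDA:
    def test_one_subclass_matches_lda(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        X = np.vstack([rng.normal(0, 1, (60, 4)), rng.normal(2.5, 1, (60, 4))])
        y = np.repeat(["a", "b"], 60)
        mda = MDAClassifier(n_subclasses=1, random_state=0).fit(X, y)
        lda = LinearDiscriminantAnalysis().fit(X, y)
        agree = np.mean(mda.predict(X) == lda.predict(X))
        assert agree > 0.99

    def test_mixture_structure_learned(self, rng):
        # XOR layout: class means coincide, only the mixture structure tells
        Xa = np.vstack([rng.normal(c, 0.8, (40, 2))
                        for c in ([4.0, 4.0], [-4.0, -4.0])])
        Xb = np.vstack([rng.normal(c, 0.8, (40, 2))
                        for c in ([4.0, -4.0], [-4.0, 4.0])])
        X = np.vstack([Xa, Xb])
        y = np.repeat(["a", "b"], 80)
        mda = MDAClassifier(n_subclasses=2, random_state=0).fit(X, y)
        assert np.mean(mda.predict(X) == y) > 0.95
        p = mda.predict_proba(X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)


@pytest.fixture(scope="module")
def separable_model():
    rng = np.random.default_rng(11)
    X = np.vstack([rng.normal(6 * i, 1.0, (30, 6)) for i in range(5)])
    y = np.repeat(list(CLASS_ORDER), 30)
    model = train_ensemble(X, y, None, cv=CVConfig(3, 1), seed=0)
    return model, X, y


class TestPredictDiagnose:
    def test_probabilities_sum_to_one(self, separable_model):
        model, X, y = separable_model
        proba, labels = predict_cells(model, X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_perfectly_separated_train_accuracy(self, separable_model):
        model, X, y = separable_model
        _, labels = predict_cells(model, X)
        assert (labels == y).mean() == 1.0

    def test_marginalization_consistency(self, separable_model):
        model, X, y = separable_model
        proba, labels5 = predict_cells(model, X)
        p3 = collapse_to_three(proba)
        np.testing.assert_allclose(p3.sum(axis=1), 1.0, atol=1e-9)
        # collapsing hard 5-class labels equals arg-max over collapsed probs
        # whenever the ME mass is concentrated on one subclass
        lab3 = collapse_labels(labels5)
        assert set(lab3) <= {"HC", "ME", "MS"}

    def test_diagnose_unanimous_cells(self):
        proba = pd.DataFrame({"HC": [0.1, 0.2], "MS": [0.9, 0.8]})
        labels = np.array(["MS", "MS"])
        for agg in ("mean_prob", "majority"):
            d = diagnose_subjects(None, proba, labels, ["s1", "s1"], aggregator=agg)
            assert d["diagnosis"].iloc[0] == "MS"

    def test_majority_vote(self):
        proba = pd.DataFrame({"HC": [0.4, 0.4, 0.6], "ME": [0.6, 0.6, 0.4]})
        labels = np.array(["ME", "ME", "HC"])
        d = diagnose_subjects(None, proba, labels, ["s"] * 3, aggregator="majority")
        assert d["diagnosis"].iloc[0] == "ME"

    def test_mean_prob_tie_flagged_first_class_wins(self):
        proba = pd.DataFrame({"HC": [0.6, 0.4], "MS": [0.4, 0.6]})
        labels = np.array(["HC", "MS"])
        d = diagnose_subjects(None, proba, labels, ["s", "s"], aggregator="mean_prob")
        assert d["diagnosis"].iloc[0] == "HC"
        assert bool(d["tie"].iloc[0])


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.repeat(list(CLASS_ORDER), 4)
        s = evaluate(y, y)
        assert s.accuracy == 1.0
        np.testing.assert_allclose(np.diag(s.matrix_percent), 100.0)
        assert (s.sensitivity == 1.0).all() and (s.specificity == 1.0).all()

    def test_binomial_ci_matches_beta_oracle(self):
        truth = np.array(["a"] * 5 + ["b"] * 5)
        pred = truth.copy()
        pred[0] = "b"  # 9 of 10 correct
        s = evaluate(pred, truth, classes=["a", "b"])
        lo = beta.ppf(0.025, 9, 2)
        hi = beta.ppf(0.975, 10, 1)
        assert s.accuracy == pytest.approx(0.9)
        assert s.ci95[0] == pytest.approx(lo, abs=1e-9)
        assert s.ci95[1] == pytest.approx(hi, abs=1e-9)
        assert s.ci95 == (pytest.approx(0.5550, abs=1e-4), pytest.approx(0.9975, abs=1e-4))

    def test_single_class_truth_specificity_nan(self):
        truth = np.array(["a", "a", "a"])
        pred = np.array(["a", "a", "b"])
        s = evaluate(pred, truth, classes=["a", "b"])
        assert np.isnan(s.specificity["a"])
        assert np.isnan(s.sensitivity["b"])

    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(5)
        truth = rng.choice(["a", "b", "c"], 60)
        pred = rng.choice(["a", "b", "c"], 60)
        s = evaluate(pred, truth, classes=["a", "b", "c"])
        np.testing.assert_allclose(s.matrix_percent.sum(axis=1), 100.0)

    def test_unknown_label_errors(self):
        with pytest.raises(ValueError):
            evaluate(np.array(["a", "z"]), np.array(["a", "a"]), classes=["a", "b"])


class TestModelCorrelation:
    def _base(self, traces):
        from scrsdx.ensemble import BaseLearnerSet, LEARNER_NAMES
        names = LEARNER_NAMES[: len(traces)]
        return BaseLearnerSet(
            names=names, classes=["a", "b"], fitted={}, oof=np.zeros((2, 2)),
            traces=dict(zip(names, traces)), cv_accuracy={}, chosen={},
        )

    def test_self_and_identical_traces(self, rng):
        t = rng.uniform(0.5, 1.0, 30)
        corr = model_correlation(self._base([t, t.copy()]))
        assert corr.iloc[0, 0] == pytest.approx(1.0)
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_independent_traces_low_correlation(self, rng):
        traces = [rng.uniform(0, 1, 50) for _ in range(8)]
        corr = model_correlation(self._base(traces)).to_numpy()
        off = corr[~np.eye(8, dtype=bool)]
        assert np.nanmean(np.abs(off)) < 0.3

    def test_constant_trace_is_nan(self, rng):
        corr = model_correlation(self._base([np.full(10, 0.8), rng.uniform(0, 1, 10)]))
        assert np.isnan(corr.iloc[0, 0]) and np.isnan(corr.iloc[0, 1])
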