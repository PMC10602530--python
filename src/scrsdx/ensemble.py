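"""Two-layer stacked ensemble diagnosis from SCRS.

Pipeline: stratified (optionally subject-grouped) 80/20 train/test split
-> center/scale + PCA to <=100 components fitted on the train set only
-> eight base classifiers (LDA, XGBoost, linear SVM, RBF SVM, multilayer
perceptron, random forest, mixture discriminant analysis, gradient
boosting machine), each evaluated by repeated stratified cross-validation
(default 10-fold x 5 repeats) producing out-of-fold (OOF) class
probabilities -> a gradient-boosting meta-learner stacked on the
8 x n_classes OOF probability features -> cell-level diagnosis, then
subject-level aggregation (meta-GBM over per-subject class fractions,
majority vote, or mean probability).

Leakage rules: the transform and every learner see train data only; in
subject-grouped mode no subject's cells ever straddle the partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.proportion import proportion_confint
from xgboost import XGBClassifier

from .core import CellSpectrum
from .mda import MDAClassifier

__all__ = [
    "CLASS_ORDER",
    "LEARNER_NAMES",
    "SplitPlan",
    "CVConfig",
    "FeatureTransform",
    "BaseLearnerSet",
    "EnsembleModel",
    "ConfusionSummary",
    "scrs_matrix",
    "split_train_test",
    "repeated_splits",
    "fit_transform",
    "fit_base_learners",
    "fit_meta",
    "train_ensemble",
    "predict_cells",
    "collapse_to_three",
    "diagnose_subjects",
    "evaluate",
    "model_correlation",
]

# fixed class order (also the tie-break order)
CLASS_ORDER = ("HC", "MildME", "ModME", "SevME", "MS")
THREE_CLASS_ORDER = ("HC", "ME", "MS")
LEARNER_NAMES = ("lda", "xgb", "svm_linear", "svm_radial", "mlp", "rf", "mda", "gbm")


def _class_sort_key(classes) -> list:
    order = {c: i for i, c in enumerate(CLASS_ORDER)}
    return sorted(classes, key=lambda c: (order.get(c, len(order)), str(c)))


def scrs_matrix(cells: list[CellSpectrum], groups: dict[str, str]):
    """Stack SCRS into (X, labels, subject_ids) arrays."""
    X = np.vstack([c.intensities for c in cells])
    labels = np.asarray([groups[c.subject_id] for c in cells])
    subjects = np.asarray([c.subject_id for c in cells])
    return X, labels, subjects


# --------------------------------------------------------------------------
# splitting

@dataclass
class SplitPlan:
    train_idx: np.ndarray
    test_idx: np.ndarray
    ratio: float
    grouping: str
    seed: int

    def assert_valid(self, labels: np.ndarray, subject_ids: np.ndarray | None = None):
        assert len(np.intersect1d(self.train_idx, self.test_idx)) == 0
        assert len(self.train_idx) + len(self.test_idx) == len(labels)
        for part in (self.train_idx, self.test_idx):
            assert set(labels[part]) == set(labels)
        if self.grouping == "subject" and subject_ids is not None:
            assert not (
                set(subject_ids[self.train_idx]) & set(subject_ids[self.test_idx])
            ), "subject straddles train/test"


def split_train_test(labels, subject_ids=None, ratio: float = 0.8,
                     grouping: str = "subject", seed: int = 0) -> SplitPlan:
    """Stratified split; grouping='subject' keeps a subject's cells together."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    if grouping == "subject":
        if subject_ids is None:
            raise ValueError("subject grouping requires subject_ids")
        subject_ids = np.asarray(subject_ids)
        subj_label = {}
        for s, l in zip(subject_ids, labels):
            if subj_label.setdefault(s, l) != l:
                raise ValueError(f"subject {s} has mixed labels")
        units = np.array(list(subj_label))
        unit_labels = np.array([subj_label[u] for u in units])
    elif grouping == "cell":
        units = np.arange(len(labels))
        unit_labels = labels
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    test_units = []
    for cls in _class_sort_key(set(unit_labels)):
        members = units[unit_labels == cls]
        if len(members) < 2:
            raise ValueError(f"class {cls!r} has a single unit; cannot split")
        members = rng.permutation(members)
        n_test = int(round(len(members) * (1.0 - ratio)))
        n_test = min(max(n_test, 1), len(members) - 1)
        test_units.extend(members[:n_test])
    test_units = set(test_units)
    if grouping == "subject":
        test_mask = np.array([s in test_units for s in subject_ids])
    else:
        test_mask = np.zeros(len(labels), dtype=bool)
        test_mask[list(test_units)] = True
    plan = SplitPlan(
        train_idx=np.flatnonzero(~test_mask), test_idx=np.flatnonzero(test_mask),
        ratio=ratio, grouping=grouping, seed=seed,
    )
    plan.assert_valid(labels, None if subject_ids is None else np.asarray(subject_ids))
    return plan


def repeated_splits(labels, subject_ids=None, ratio: float = 0.8,
                    grouping: str = "subject", seed: int = 0,
                    n_repeats: int = 5) -> list[SplitPlan]:
    """Cycle the split seed so every unit reaches the test set at least once
    with high probability; performance is then averaged across repeats."""
    return [
        split_train_test(labels, subject_ids, ratio, grouping, seed + k)
        for k in range(n_repeats)
    ]


# --------------------------------------------------------------------------
# feature transform

@dataclass
class FeatureTransform:
    scaler: StandardScaler
    pca: PCA
    n_components: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.pca.transform(self.scaler.transform(np.asarray(X, float)))

    @property
    def effective_rank(self) -> int:
        ev = self.pca.explained_variance_
        return int(np.sum(ev > 1e-10 * max(ev[0], 1e-300)))


def fit_transform(X_train: np.ndarray, n_components: int = 100) -> FeatureTransform:
    """Center/scale + PCA fitted on train only; <= min(100, n-1, p) PCs."""
    X_train = np.asarray(X_train, float)
    n, p = X_train.shape
    if n < 2:
        raise ValueError("need >= 2 training spectra")
    scaler = StandardScaler()  # zero-variance channels get scale 1
    Xs = scaler.fit_transform(X_train)
    k = int(min(n_components, n - 1, p))
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(Xs)
    return FeatureTransform(scaler=scaler, pca=pca, n_components=k)


# --------------------------------------------------------------------------
# base learners

def _learner_grids(seed: int) -> dict[str, list]:
    """Small fixed hyperparameter grids (most are singletons)."""
    return {
        "lda": [LinearDiscriminantAnalysis()],
        "xgb": [
            XGBClassifier(
                n_estimators=60, max_depth=3, learning_rate=0.3, subsample=0.8,
                tree_method="hist", n_jobs=1, verbosity=0, random_state=seed,
                use_label_encoder=False, eval_metric="mlogloss",
            )
        ],
        "svm_linear": [SVC(kernel="linear", C=1.0, probability=True, random_state=seed)],
        "svm_radial": [
            SVC(kernel="rbf", C=10.0, gamma="scale", probability=True, random_state=seed)
        ],
        "mlp": [
            MLPClassifier(hidden_layer_sizes=(h,), alpha=1e-3, max_iter=400,
                          random_state=seed)
            for h in (8, 32, 64)
        ],
        "rf": [RandomForestClassifier(n_estimators=150, n_jobs=1, random_state=seed)],
        "mda": [MDAClassifier(n_subclasses=3, random_state=seed)],
        "gbm": [
            GradientBoostingClassifier(n_estimators=80, max_depth=2,
                                       learning_rate=0.1, random_state=seed)
        ],
    }


@dataclass
class CVConfig:
    n_folds: int = 10
    n_repeats: int = 5


@dataclass
class BaseLearnerSet:
    names: tuple
    classes: list
    fitted: dict                     # name -> estimator refit on full train
    oof: np.ndarray                  # n_train x (8 * n_classes)
    traces: dict                     # name -> per-(fold,repeat) accuracy array
    cv_accuracy: dict                # name -> mean CV accuracy
    chosen: dict                     # name -> chosen grid index


def fit_base_learners(X: np.ndarray, y, cv: CVConfig | None = None,
                      seed: int = 0) -> BaseLearnerSet:
    """Repeated stratified CV for all eight learners.

    For each learner and each grid point the OOF class probabilities are
    recorded per repeat and averaged; the grid point with the best mean CV
    accuracy wins.  The per-resample accuracy trace of the winning
    configuration is kept for the model-correlation analysis.  If a class
    is smaller than the fold count, the fold count is reduced (warning).
    """
    cv = cv or CVConfig()
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = _class_sort_key(set(y))
    min_class = int(np.bincount(pd.factorize(y)[0]).min())
    n_folds = cv.n_folds
    if min_class < n_folds:
        n_folds = max(2, min_class)
        warnings.warn(
            f"smallest class has {min_class} members; reducing folds to {n_folds}"
        )
    splitter = RepeatedStratifiedKFold(
        n_splits=n_folds, n_repeats=cv.n_repeats, random_state=seed
    )
    folds = list(splitter.split(X, y))

    y_enc = y
    # XGBoost needs integer labels
    class_to_int = {c: i for i, c in enumerate(classes)}
    y_int = np.array([class_to_int[c] for c in y])

    grids = _learner_grids(seed)
    fitted, traces, cv_acc, chosen = {}, {}, {}, {}
    oof_blocks = []
    for name in LEARNER_NAMES:
        best = None
        for gi, proto in enumerate(grids[name]):
            oof_sum = np.zeros((len(y), len(classes)))
            oof_cnt = np.zeros(len(y))
            trace = []
            for tr, te in folds:
                est = clone(proto)
                yy = y_int if name == "xgb" else y_enc
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(X[tr], yy[tr])
                p = _proba_in_class_order_generic(est, X[te], classes, name)
                oof_sum[te] += p
                oof_cnt[te] += 1
                pred = np.asarray([classes[j] for j in np.argmax(p, axis=1)])
                trace.append(float(np.mean(pred == y[te])))
            trace = np.asarray(trace)
            cand = {
                "oof": oof_sum / np.maximum(oof_cnt, 1)[:, None],
                "trace": trace, "acc": float(trace.mean()), "gi": gi, "proto": proto,
            }
            if best is None or cand["acc"] > best["acc"]:
                best = cand
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = clone(best["proto"])
            est.fit(X, y_int if name == "xgb" else y_enc)
        fitted[name] = est
        traces[name] = best["trace"]
        cv_acc[name] = best["acc"]
        chosen[name] = best["gi"]
        oof_blocks.append(best["oof"])
    oof = np.hstack(oof_blocks)
    return BaseLearnerSet(
        names=LEARNER_NAMES, classes=classes, fitted=fitted, oof=oof,
        traces=traces, cv_accuracy=cv_acc, chosen=chosen,
    )


def _proba_in_class_order_generic(est, X, classes, name) -> np.ndarray:
    p = est.predict_proba(X)
    if name == "xgb":
        est_classes = [classes[int(i)] for i in est.classes_]
    else:
        est_classes = list(est.classes_)
    out = np.zeros((X.shape[0], len(classes)))
    for j, c in enumerate(classes):
        if c in est_classes:
            out[:, j] = p[:, est_classes.index(c)]
    s = out.sum(axis=1, keepdims=True)
    s[s == 0] = 1.0
    return out / s


def fit_meta(oof: np.ndarray, y, seed: int = 0) -> GradientBoostingClassifier:
    """GBM meta-learner stacked on the 8 x n_classes OOF probabilities."""
    y = np.asarray(y)
    if len(set(y)) < 2:
        raise ValueError("meta-learner needs >= 2 classes")
    meta = GradientBoostingClassifier(
        n_estimators=100, max_depth=2, learning_rate=0.1, random_state=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        meta.fit(np.asarray(oof, float), y)
    return meta


# --------------------------------------------------------------------------
# the assembled model

@dataclass
class EnsembleModel:
    transform: FeatureTransform
    base: BaseLearnerSet
    meta: GradientBoostingClassifier
    classes: list
    subject_aggregator: str = "meta_gbm"
    subject_meta: GradientBoostingClassifier | None = None

    def base_probabilities(self, X: np.ndarray) -> np.ndarray:
        Z = self.transform.transform(X)
        blocks = [
            _proba_in_class_order_generic(self.base.fitted[name], Z, self.classes, name)
            for name in self.base.names
        ]
        return np.hstack(blocks)


def train_ensemble(X_train: np.ndarray, y_train, subject_ids_train=None,
                   cv: CVConfig | None = None, seed: int = 0,
                   n_components: int = 100,
                   subject_aggregator: str = "meta_gbm") -> EnsembleModel:
    """Fit transform, base learners, meta-learner and subject aggregator."""
    transform = fit_transform(X_train, n_components=n_components)
    Z = transform.transform(X_train)
    base = fit_base_learners(Z, y_train, cv=cv, seed=seed)
    meta = fit_meta(base.oof, y_train, seed=seed)
    model = EnsembleModel(
        transform=transform, base=base, meta=meta, classes=base.classes,
        subject_aggregator=subject_aggregator,
    )
    if subject_aggregator == "meta_gbm" and subject_ids_train is not None:
        subjects = pd.unique(np.asarray(subject_ids_train))
        if len(subjects) >= 20:
            proba, _ = predict_cells(model, X_train)
            feats, labs = _subject_fraction_features(
                proba, np.asarray(y_train), np.asarray(subject_ids_train), model.classes
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sm = GradientBoostingClassifier(
                    n_estimators=60, max_depth=2, random_state=seed
                )
                sm.fit(feats, labs)
            model.subject_meta = sm
    return model


def predict_cells(model: EnsembleModel, X: np.ndarray):
    """Per-cell class probabilities (simplex) and arg-max labels.

    Ties break toward the earlier class in the fixed order
    HC < MildME < ModME < SevME < MS.
    """
    feats = model.base_probabilities(np.asarray(X, float))
    p = model.meta.predict_proba(feats)
    meta_classes = list(model.meta.classes_)
    cols = [meta_classes.index(c) for c in model.classes]
    p = p[:, cols]
    p = p / p.sum(axis=1, keepdims=True)
    labels = np.asarray([model.classes[j] for j in np.argmax(p, axis=1)])
    proba = pd.DataFrame(p, columns=model.classes)
    return proba, labels


def collapse_to_three(proba: pd.DataFrame) -> pd.DataFrame:
    """Marginalize Mild/Mod/Sev ME probabilities into a single ME class."""
    out = pd.DataFrame(index=proba.index)
    out["HC"] = proba.get("HC", 0.0)
    me_cols = [c for c in ("MildME", "ModME", "SevME") if c in proba.columns]
    out["ME"] = proba[me_cols].sum(axis=1) if me_cols else 0.0
    out["MS"] = proba.get("MS", 0.0)
    return out


def collapse_labels(labels) -> np.ndarray:
    return np.asarray(
        ["ME" if l in ("MildME", "ModME", "SevME") else l for l in np.asarray(labels)]
    )


def _subject_fraction_features(proba: pd.DataFrame, y_cells, subject_ids, classes):
    feats, labs = [], []
    labels = np.asarray([classes[j] for j in np.argmax(proba.to_numpy(), axis=1)])
    for s in pd.unique(subject_ids):
        m = subject_ids == s
        frac = np.array([np.mean(labels[m] == c) for c in classes])
        mean_p = proba.to_numpy()[m].mean(axis=0)
        feats.append(np.concatenate([frac, mean_p]))
        labs.append(y_cells[m][0])
    return np.vstack(feats), np.asarray(labs)


def diagnose_subjects(model: EnsembleModel | None, proba: pd.DataFrame,
                      labels: np.ndarray, subject_ids,
                      aggregator: str | None = None) -> pd.DataFrame:
    """Aggregate cell-level predictions into one diagnosis per subject.

    ``mean_prob``: arg-max of the averaged cell probabilities;
    ``majority``: modal cell label; ``meta_gbm``: gradient-boosting model
    over per-subject class-fraction features (falls back to mean_prob when
    no subject model was trained).  Ties break by the fixed class order
    and are flagged.
    """
    subject_ids = np.asarray(subject_ids)
    classes = list(proba.columns)
    agg = aggregator or (model.subject_aggregator if model else "mean_prob")
    if agg == "meta_gbm" and (model is None or model.subject_meta is None):
        agg = "mean_prob"
    rows = []
    for s in pd.unique(subject_ids):
        m = subject_ids == s
        tie = False
        if agg == "majority":
            counts = np.array([np.sum(labels[m] == c) for c in classes])
            best = counts.max()
            tie = int(np.sum(counts == best)) > 1
            diag = classes[int(np.argmax(counts))]
            conf = best / counts.sum()
        elif agg == "meta_gbm":
            frac = np.array([np.mean(labels[m] == c) for c in classes])
            mean_p = proba.to_numpy()[m].mean(axis=0)
            p = model.subject_meta.predict_proba(
                np.concatenate([frac, mean_p])[None, :]
            )[0]
            sm_classes = list(model.subject_meta.classes_)
            pv = np.array([p[sm_classes.index(c)] if c in sm_classes else 0.0
                           for c in classes])
            best = pv.max()
            tie = int(np.sum(pv == best)) > 1
            diag = classes[int(np.argmax(pv))]
            conf = float(best)
        else:  # mean_prob
            mean_p = proba.to_numpy()[m].mean(axis=0)
            best = mean_p.max()
            tie = int(np.sum(mean_p == best)) > 1
            diag = classes[int(np.argmax(mean_p))]
            conf = float(best)
        rows.append({"subject_id": s, "diagnosis": diag, "confidence": conf,
                     "n_cells": int(m.sum()), "tie": tie, "aggregator": agg})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# evaluation

@dataclass
class ConfusionSummary:
    classes: list
    matrix_percent: pd.DataFrame       # rows = true class, sums to 100
    counts: pd.DataFrame
    sensitivity: pd.Series
    specificity: pd.Series
    accuracy: float
    ci95: tuple
    n_test: int


def evaluate(predictions, truth, classes=None) -> ConfusionSummary:
    """Row-percent confusion matrix, per-class sensitivity/specificity
    (one-vs-rest), accuracy with exact (Clopper-Pearson) 95% CI."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    classes = list(classes) if classes is not None else _class_sort_key(set(truth))
    bad = set(predictions) - set(classes) | (set(truth) - set(classes))
    if bad:
        raise ValueError(f"labels outside class set: {sorted(bad)}")
    n = len(truth)
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(truth, predictions):
        counts.loc[t, p] += 1
    row_sums = counts.sum(axis=1)
    pct = counts.div(row_sums.replace(0, np.nan), axis=0) * 100.0
    sens, spec = {}, {}
    for c in classes:
        tp = counts.loc[c, c]
        fn = row_sums[c] - tp
        fp = counts[c].sum() - tp
        tn = n - tp - fn - fp
        sens[c] = np.nan if (tp + fn) == 0 else tp / (tp + fn)
        spec[c] = np.nan if (tn + fp) == 0 else tn / (tn + fp)
    correct = int(np.sum(predictions == truth))
    acc = correct / n
    lo, hi = proportion_confint(correct, n, alpha=0.05, method="beta")
    return ConfusionSummary(
        classes=classes, matrix_percent=pct, counts=counts,
        sensitivity=pd.Series(sens), specificity=pd.Series(spec),
        accuracy=acc, ci95=(float(lo), float(hi)), n_test=n,
    )


def model_correlation(base: BaseLearnerSet) -> pd.DataFrame:
    """Pearson r between the learners' resampled accuracy traces."""
    names = list(base.names)
    k = len(names)
    any_trace = next(iter(base.traces.values()))
    if len(any_trace) < 3:
        raise ValueError("need >= 3 resamples for a correlation matrix")
    out = np.full((k, k), np.nan)
    for i, a in enumerate(names):
        ta = base.traces[a]
        if np.std(ta) > 0:
            out[i, i] = 1.0
        for j in range(i + 1, k):
            tb = base.traces[names[j]]
            if np.std(ta) > 0 and np.std(tb) > 0:
                out[i, j] = out[j, i] = float(np.corrcoef(ta, tb)[0, 1])
    return pd.DataFrame(out, index=names, columns=names)
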