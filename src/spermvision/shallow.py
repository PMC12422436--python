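"""Shallow classifiers and the extractor x selector x classifier grid.

Classifiers: SVM with RBF kernel K(x,z) = exp(-gamma ||x-z||^2) where
gamma = 1 / (D' * meanVar(X_train)), SVM with linear kernel (both with
C = 1 and one-vs-one multi-class voting), and kNN (k = 3 by default,
Euclidean distance, majority vote, vote ties -> lowest class index,
distance ties -> lower training-row index).

The grid evaluates every (extractor tag, selector, classifier)
configuration with stratified k-fold cross-validation: per fold the
selector is fitted on training rows only, train and test are
transformed, standardized with training statistics, and the classifier
is fitted and scored.  Rankings sort by mean accuracy, then mean F1,
then configuration order.
"""

from __future__ import annotations

import csv
import io as _io
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .metrics import classwise_metrics, confusion_matrix, stratified_kfold
from .selection import ALL_METHODS, fit_selector, apply_selection, default_k

__all__ = [
    "ClassifierSpec", "GridRecord", "KNNClassifier", "fit_classifier",
    "predict_classifier", "enumerate_grid", "run_grid", "rank_records",
    "records_to_csv", "records_to_json", "PRESETS",
]

CLASSIFIER_KINDS = ("svm_rbf", "svm_linear", "knn", "rf")

PRESETS = {
    "paper40": (("gap", "gmp"), ALL_METHODS, ("svm_rbf", "knn")),
    "full": (("cbam", "gap", "gmp", "prefinal"), ALL_METHODS, ("svm_rbf", "svm_linear", "knn")),
    "full+rf": (("cbam", "gap", "gmp", "prefinal"), ALL_METHODS,
                ("svm_rbf", "svm_linear", "knn", "rf")),
}


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "svm_rbf"
    c: float = 1.0
    k_neighbors: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier {self.kind!r}; expected one of {CLASSIFIER_KINDS}")
        if self.c <= 0:
            raise ValueError("C must be > 0")
        if self.k_neighbors < 1 or self.k_neighbors % 2 == 0:
            raise ValueError("k_neighbors must be odd and >= 1")


class KNNClassifier:
    """Euclidean kNN with the tie rules stated above."""

    def __init__(self, k: int = 3):
        self.k = k

    def fit(self, x, y):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=int)
        self.n_classes = int(self.y.max()) + 1
        return self

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if x.shape[1] != self.x.shape[1]:
            raise ValueError(f"dimension mismatch: trained on D={self.x.shape[1]}, got {x.shape[1]}")
        out = np.empty(len(x), dtype=int)
        for i, q in enumerate(x):
            d = np.sqrt(((self.x - q) ** 2).sum(axis=1))
            nearest = np.argsort(d, kind="stable")[: self.k]   # stable: low index wins ties
            votes = np.bincount(self.y[nearest], minlength=self.n_classes)
            out[i] = int(votes.argmax())                       # argmax: low class wins ties
        return out


class _Standardizer:
    """Per-column mean-0/sd-1 scaling; constant columns map to 0."""

    def fit(self, x):
        x = np.asarray(x, dtype=float)
        self.mean = x.mean(axis=0)
        sd = x.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd


def fit_classifier(x_train, y_train, spec: ClassifierSpec):
    """Fit one shallow classifier on standardized training features."""
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training fold contains a single class")
    if spec.kind == "knn":
        return KNNClassifier(spec.k_neighbors).fit(x_train, y_train)
    if spec.kind == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(n_estimators=200, random_state=spec.seed,
                                      n_jobs=1).fit(x_train, y_train)
    kernel = "rbf" if spec.kind == "svm_rbf" else "linear"
    # gamma="scale" is exactly 1 / (D' * meanVar(X_train))
    model = SVC(C=spec.c, kernel=kernel, gamma="scale", random_state=spec.seed)
    return model.fit(x_train, y_train)


def predict_classifier(model, x_test) -> np.ndarray:
    return np.asarray(model.predict(x_test), dtype=int)


def enumerate_grid(extractors, selectors, classifiers) -> list[tuple]:
    """Cartesian product in deterministic extractor-major order."""
    extractors, selectors, classifiers = list(extractors), list(selectors), list(classifiers)
    if not (extractors and selectors and classifiers):
        raise ValueError("extractor, selector and classifier sets must be non-empty")
    for s in selectors:
        if s not in ALL_METHODS:
            raise ValueError(f"unknown selector {s!r}")
    for c in classifiers:
        if c not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier {c!r}")
    return [(e, s, c) for e in extractors for s in selectors for c in classifiers]


def preset_grid(name: str) -> list[tuple]:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; expected one of {sorted(PRESETS)}")
    return enumerate_grid(*PRESETS[name])


@dataclass
class GridRecord:
    extractor_tag: str
    selector_method: str
    classifier_kind: str
    fold_accuracies: list = field(default_factory=list)
    mean_accuracy: float = 0.0      # all metrics in percent
    mean_precision: float = 0.0
    mean_recall: float = 0.0
    mean_f1: float = 0.0
    fold_predictions: list = field(default_factory=list)
    fold_test_indices: list = field(default_factory=list)

    @property
    def config(self) -> tuple:
        return (self.extractor_tag, self.selector_method, self.classifier_kind)


def run_grid(features: dict, y: np.ndarray, configs: list[tuple], n_folds: int = 5,
             seed: int = 0, k: int | None = None) -> list[GridRecord]:
    """Evaluate every configuration under shared stratified folds.

    ``features`` maps extractor tags to (N, D) arrays or FeatureMatrix
    objects.  Selector fits are cached per (tag, selector, fold) since
    they are classifier-independent.
    """
    y = np.asarray(y, dtype=int)
    n_classes = int(y.max()) + 1
    mats = {}
    for tag in {cfg[0] for cfg in configs}:
        if tag not in features:
            raise ValueError(f"missing features for extractor tag {tag!r}")
        f = features[tag]
        mats[tag] = np.asarray(getattr(f, "data", f), dtype=float)

    folds = stratified_kfold(y, n_folds, seed)
    sel_cache: dict = {}
    records = []
    for tag, sel_method, clf_kind in configs:
        x_all = mats[tag]
        rec = GridRecord(tag, sel_method, clf_kind)
        per_fold_metrics = []
        for fold_id, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
            key = (tag, sel_method, fold_id)
            if key not in sel_cache:
                kk = k if k is not None else default_k(x_all.shape[1])
                sel_cache[key] = fit_selector(sel_method, x_all[train_idx], y[train_idx],
                                              k=kk, seed=seed, fitted_on=f"fold{fold_id}")
            sel = sel_cache[key]
            xt = apply_selection(x_all[train_idx], sel)
            xs = apply_selection(x_all[test_idx], sel)
            scaler = _Standardizer().fit(xt)
            clf = fit_classifier(scaler.transform(xt), y[train_idx],
                                 ClassifierSpec(kind=clf_kind, seed=seed))
            pred = predict_classifier(clf, scaler.transform(xs))
            cm = confusion_matrix(y[test_idx], pred, n_classes)
            rep = classwise_metrics(cm, warn_degenerate=False)
            rec.fold_accuracies.append(rep["accuracy"])
            per_fold_metrics.append((rep["macro_precision"], rep["macro_recall"], rep["macro_f1"]))
            rec.fold_predictions.append(pred.tolist())
            rec.fold_test_indices.append(test_idx.tolist())
        rec.mean_accuracy = float(np.mean(rec.fold_accuracies))
        rec.mean_precision = float(np.mean([m[0] for m in per_fold_metrics]))
        rec.mean_recall = float(np.mean([m[1] for m in per_fold_metrics]))
        rec.mean_f1 = float(np.mean([m[2] for m in per_fold_metrics]))
        records.append(rec)
    return records


def rank_records(records: list[GridRecord]) -> list[GridRecord]:
    """Sort by mean accuracy desc, ties by F1 desc, then configuration order."""
    order = sorted(range(len(records)),
                   key=lambda i: (-records[i].mean_accuracy, -records[i].mean_f1, i))
    return [records[i] for i in order]


def records_to_csv(records: list[GridRecord]) -> str:
    """Ranked CSV with the columns of the published result tables."""
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["Rank", "Feature Layer", "Selection", "Classifier",
                     "Accuracy", "Precision", "Recall", "F1-Score"])
    for rank, rec in enumerate(rank_records(records), start=1):
        writer.writerow([
            rank, rec.extractor_tag, rec.selector_method, rec.classifier_kind,
            f"{rec.mean_accuracy:.2f}", f"{rec.mean_precision:.2f}",
            f"{rec.mean_recall:.2f}", f"{rec.mean_f1:.2f}",
        ])
    return buf.getvalue()


def records_to_json(records: list[GridRecord]) -> str:
    payload = [{
        "extractor": r.extractor_tag,
        "selector": r.selector_method,
        "classifier": r.classifier_kind,
        "fold_accuracies": r.fold_accuracies,
        "mean_accuracy": r.mean_accuracy,
        "mean_precision": r.mean_precision,
        "mean_recall": r.mean_recall,
        "mean_f1": r.mean_f1,
        "fold_predictions": r.fold_predictions,
        "fold_test_indices": r.fold_test_indices,
    } for r in rank_records(records)]
    return json.dumps(payload, indent=2)
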