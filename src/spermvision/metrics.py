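"""Confusion-matrix metrics, CV summaries, and McNemar's paired test.

Per-class metrics follow the one-vs-rest convention: for class c,
TP = cm[c,c], FP = column sum - TP, FN = row sum - TP, and

    precision = 100 * TP / (TP + FP)
    recall    = 100 * TP / (TP + FN)
    F1        = 2 * P * R / (P + R)

with 0/0 defined as 0 (warned).  Macro metrics are unweighted class
means.  Percentages are rounded half-up to two decimals for display;
full precision is retained internally.
"""

from __future__ import annotations

import warnings
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "round2", "confusion_matrix", "classwise_from_counts", "classwise_metrics",
    "mcnemar_test", "stratified_kfold", "cv_summary",
]


def round2(x: float) -> float:
    """Round half-up to two decimals (matches printed tables)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """counts[i, j] = #{samples with true class i predicted as j}."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    for name, arr in (("true", y_true), ("predicted", y_pred)):
        bad = np.flatnonzero((arr < 0) | (arr >= n_classes))
        if len(bad):
            raise ValueError(
                f"{name} label {arr[bad[0]]} at index {bad[0]} outside [0, {n_classes})"
            )
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _prf(tp: float, fp: float, fn: float, warn: bool = True) -> tuple[float, float, float]:
    def ratio(num, den, what):
        if den == 0:
            if warn:
                warnings.warn(f"{what}: 0/0 encountered, defining it as 0")
            return 0.0
        return 100.0 * num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    if f1 == 0.0 and precision + recall == 0 and warn:
        pass  # already warned through precision/recall
    return precision, recall, f1


def classwise_from_counts(counts, warn_degenerate: bool = True) -> dict:
    """Per-class and macro metrics from (TP, FP, FN) triples.

    ``counts`` is a sequence of (tp, fp, fn); used to reproduce published
    worked examples where only those counts are printed.
    """
    per_class = []
    for tp, fp, fn in counts:
        p, r, f1 = _prf(tp, fp, fn, warn=warn_degenerate)
        per_class.append({"tp": int(tp), "fp": int(fp), "fn": int(fn),
                          "precision": p, "recall": r, "f1": f1})
    macro_p = float(np.mean([c["precision"] for c in per_class]))
    macro_r = float(np.mean([c["recall"] for c in per_class]))
    macro_f1 = float(np.mean([c["f1"] for c in per_class]))
    return {"per_class": per_class, "macro_precision": macro_p,
            "macro_recall": macro_r, "macro_f1": macro_f1}


def classwise_metrics(cm: np.ndarray, warn_degenerate: bool = True) -> dict:
    """Full classwise report from a confusion matrix (percent metrics)."""
    cm = np.asarray(cm)
    if cm.size == 0:
        raise ValueError("empty confusion matrix")
    counts = []
    for c in range(cm.shape[0]):
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        counts.append((tp, fp, fn))
    report = classwise_from_counts(counts, warn_degenerate=warn_degenerate)
    total = cm.sum()
    report["accuracy"] = 100.0 * np.trace(cm) / total if total else 0.0
    report["display"] = {
        "per_class": [{**c, "precision": round2(c["precision"]),
                       "recall": round2(c["recall"]), "f1": round2(c["f1"])}
                      for c in report["per_class"]],
        "macro_precision": round2(report["macro_precision"]),
        "macro_recall": round2(report["macro_recall"]),
        "macro_f1": round2(report["macro_f1"]),
        "accuracy": round2(report["accuracy"]),
    }
    return report


def mcnemar_test(y_true, pred_a, pred_b) -> tuple[float, float]:
    """Continuity-corrected McNemar chi-square on the discordant pairs.

    b = #(A correct, B wrong), c = #(A wrong, B correct);
    chi2 = (|b - c| - 1)^2 / (b + c); p from chi-square with 1 df.
    b + c = 0 -> (0, 1).
    """
    y_true, pred_a, pred_b = map(np.asarray, (y_true, pred_a, pred_b))
    if not (len(y_true) == len(pred_a) == len(pred_b)):
        raise ValueError(
            f"length mismatch: {len(y_true)} true, {len(pred_a)} A, {len(pred_b)} B"
        )
    a_ok, b_ok = pred_a == y_true, pred_b == y_true
    b = int(np.sum(a_ok & ~b_ok))
    c = int(np.sum(~a_ok & b_ok))
    if b + c == 0:
        return 0.0, 1.0
    chi2 = (abs(b - c) - 1) ** 2 / (b + c)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def stratified_kfold(y, n_folds: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified folds; per-class counts differ by <= 1 across folds.

    Returns the list of test-index arrays (one per fold); they partition
    the sample range.
    """
    y = np.asarray(y)
    for cls in np.unique(y):
        n = int(np.sum(y == cls))
        if n < n_folds:
            raise ValueError(f"class {cls} has only {n} members, fewer than {n_folds} folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(y)), y)]


def cv_summary(fold_accuracies) -> dict:
    """Mean, sample std, the mean±std interval, and a t-based 95% CI.

    The mean±std interval matches the convention used in the published
    cross-validation table; the t-based CI is the statistically standard
    alternative, reported separately and labeled.
    """
    acc = np.asarray(fold_accuracies, dtype=float)
    if len(acc) < 2:
        raise ValueError("cv_summary requires at least 2 folds")
    mean = float(acc.mean())
    std = float(acc.std(ddof=1))
    half = float(stats.t.ppf(0.975, df=len(acc) - 1) * std / np.sqrt(len(acc)))
    return {
        "fold_accuracies": acc.tolist(),
        "mean": mean,
        "std": std,
        "interval_mean_pm_std": (mean - std, mean + std),
        "t_ci95": (mean - half, mean + half),
        "display": {
            "mean": round2(mean), "std": round2(std),
            "interval_mean_pm_std": (round2(mean - std), round2(mean + std)),
            "t_ci95": (round2(mean - half), round2(mean + half)),
        },
    }
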