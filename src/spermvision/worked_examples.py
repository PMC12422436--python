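"""Published worked-example confusion counts for the two benchmarks.

These are the per-class (TP, FP, FN) counts reported for the
best-performing configurations on SMIDS (GAP + PCA + SVM-RBF) and
HuSHeM (GAP + RF + SVM-RBF), together with the precision / recall / F1
percentages printed next to them.  They serve as exact arithmetic
oracles: recomputing the metrics from the counts must reproduce every
printed cell at two decimals.
"""

from __future__ import annotations

from .metrics import classwise_from_counts, round2

__all__ = ["SMIDS_BEST", "HUSHEM_BEST", "verify_worked_examples"]

# class name -> (TP, FP, FN, precision %, recall %, F1 %)
SMIDS_BEST = {
    "rows": {
        "Normal Sperm":   (168, 5, 7, 97.11, 96.00, 96.55),
        "Abnormal Sperm": (168, 8, 6, 95.45, 96.55, 96.00),
        "Non-Sperm":      (166, 7, 7, 95.95, 95.95, 95.95),
    },
    "macro": {"precision": 96.17, "recall": 96.17, "f1": 96.17},
}

HUSHEM_BEST = {
    "rows": {
        "Normal":    (13, 0, 1, 100.00, 92.86, 96.30),
        "Tapered":   (13, 1, 0, 92.86, 100.00, 96.30),
        "Pyriform":  (15, 1, 0, 93.75, 100.00, 96.77),
        "Amorphous": (7, 0, 1, 100.00, 87.50, 93.33),
    },
    "macro": {"precision": 96.65, "recall": 95.09, "f1": 95.68},
}


def verify_worked_examples() -> dict:
    """Recompute every metric cell from its counts; report matches and diffs."""
    results = {}
    for name, table in (("smids", SMIDS_BEST), ("hushem", HUSHEM_BEST)):
        counts = [(tp, fp, fn) for tp, fp, fn, *_ in table["rows"].values()]
        report = classwise_from_counts(counts, warn_degenerate=False)
        rows = []
        for (cls, (tp, fp, fn, p_exp, r_exp, f_exp)), got in zip(
            table["rows"].items(), report["per_class"]
        ):
            rows.append({
                "class": cls,
                "expected": (p_exp, r_exp, f_exp),
                "computed": (round2(got["precision"]), round2(got["recall"]), round2(got["f1"])),
            })
        macro_computed = {
            "precision": round2(report["macro_precision"]),
            "recall": round2(report["macro_recall"]),
            "f1": round2(report["macro_f1"]),
        }
        results[name] = {
            "rows": rows,
            "macro_expected": table["macro"],
            "macro_computed": macro_computed,
            "all_match": all(r["expected"] == r["computed"] for r in rows)
            and macro_computed == table["macro"],
        }
    return results
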