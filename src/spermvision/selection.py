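"""Feature selection: four base methods and their six pairwise intersections.

Base methods (all reduce an N x D matrix to k features or components):

* ``pca`` — mean-centered projection onto the top-k eigenvectors of the
  feature covariance (a linear projection, not an index subset);
* ``chi2`` — features are min-max scaled to [0, 1]; the score of feature
  j is sum_c (O_jc - E_jc)^2 / E_jc where O_jc is the class-c sum of
  feature j and E_jc the class prior times the feature total (terms with
  E = 0 contribute 0); top-k scores are kept;
* ``rf`` — mean impurity-decrease importances from a seeded random
  forest, top-k;
* ``variance`` — top-k features by sample variance.

All rank ties break toward the lower feature index.  Intersections keep
the indices in the top-k of both parents; the PCA ranking of individual
features uses explained-variance-weighted absolute loadings.  When an
intersection has fewer than two members it is back-filled from the union
of the parent top-k sets ordered by mean rank, so every selector yields
at least two columns.  The default k is ceil(D / 8), an 8:1 reduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "BASE_METHODS", "INTERSECTION_METHODS", "ALL_METHODS", "SelectionResult",
    "default_k", "chi2_scores", "pca_feature_importance", "select_features",
    "intersect_selections", "apply_selection", "fit_selector",
]

BASE_METHODS = ("pca", "chi2", "rf", "variance")
INTERSECTION_METHODS = (
    "pca∩chi2", "pca∩rf", "pca∩variance", "chi2∩rf", "chi2∩variance", "rf∩variance",
)
ALL_METHODS = BASE_METHODS + INTERSECTION_METHODS


@dataclass
class SelectionResult:
    method: str
    k: int
    indices: np.ndarray | None = None          # sorted ascending, or None
    mean: np.ndarray | None = None             # PCA center
    components: np.ndarray | None = None       # (D, k) orthonormal loadings
    fitted_on: str = ""
    parent_rankings: dict = field(default_factory=dict)

    @property
    def is_projection(self) -> bool:
        return self.components is not None

    @property
    def output_dim(self) -> int:
        return self.components.shape[1] if self.is_projection else len(self.indices)


def default_k(d: int) -> int:
    """The 8:1 reduction ratio used throughout the evaluation grid."""
    return int(np.ceil(d / 8))


def _top_k(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest scores; ties -> lower index; sorted ascending."""
    order = np.lexsort((np.arange(len(scores)), -scores))
    return np.sort(order[:k])


def _rank(scores: np.ndarray) -> np.ndarray:
    """rank[i] = position of feature i in the descending score order (0 best)."""
    order = np.lexsort((np.arange(len(scores)), -scores))
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(len(scores))
    return ranks


def chi2_scores(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Class-sum contingency chi-square score per feature on [0,1]-scaled data."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(axis=0), x.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    xs = (x - lo) / span
    classes = np.unique(y)
    observed = np.stack([xs[y == c].sum(axis=0) for c in classes])     # (C, D)
    priors = np.array([(y == c).mean() for c in classes])[:, None]
    expected = priors * xs.sum(axis=0)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    return terms.sum(axis=0)


def _variance_scores(x: np.ndarray) -> np.ndarray:
    return np.var(x, axis=0)


def _rf_scores(x: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    forest = RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    forest.fit(x, y)
    return forest.feature_importances_


def _fit_pca(x: np.ndarray, k: int) -> PCA:
    pca = PCA(n_components=k, svd_solver="full", random_state=0)
    pca.fit(np.asarray(x, dtype=np.float64))
    return pca


def pca_feature_importance(x: np.ndarray, k: int) -> np.ndarray:
    """Per-feature PCA score: sum_j evr_j * |V[i, j]| over the top-k components."""
    x = np.asarray(x, dtype=float)
    k = min(k, x.shape[1], x.shape[0])
    pca = _fit_pca(x, k)
    loadings = np.abs(pca.components_.T)                   # (D, k)
    return loadings @ pca.explained_variance_ratio_


def _base_scores(x, y, method: str, k: int, seed: int) -> np.ndarray:
    if method == "pca":
        return pca_feature_importance(x, k)
    if method == "chi2":
        if y is None:
            raise ValueError("chi2 selection requires labels")
        return chi2_scores(x, y)
    if method == "rf":
        if y is None:
            raise ValueError("rf selection requires labels")
        return _rf_scores(x, y, seed)
    if method == "variance":
        return _variance_scores(x)
    raise ValueError(f"unknown base method {method!r}; expected one of {BASE_METHODS}")


def _clip_k(k: int, x: np.ndarray) -> int:
    d = x.shape[1]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > d:
        warnings.warn(f"k={k} exceeds feature count D={d}; clipping to {d}")
        k = d
    return k


def select_features(x: np.ndarray, y, method: str, k: int | None = None,
                    seed: int = 0, fitted_on: str = "") -> SelectionResult:
    """Fit one base selection method on training rows."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature matrix contains non-finite values")
    k = _clip_k(k if k is not None else default_k(x.shape[1]), x)
    if method == "pca":
        k_eff = min(k, x.shape[0])
        pca = _fit_pca(x, k_eff)
        return SelectionResult(method, k_eff, mean=pca.mean_.copy(),
                               components=pca.components_.T.copy(), fitted_on=fitted_on)
    scores = _base_scores(x, y, method, k, seed)
    return SelectionResult(method, k, indices=_top_k(scores, k), fitted_on=fitted_on)


def intersect_selections(method_a: str, method_b: str, x: np.ndarray, y,
                         k: int | None = None, seed: int = 0,
                         fitted_on: str = "") -> SelectionResult:
    """Index set Top_k(A) ∩ Top_k(B), back-filled by mean rank to >= 2 members."""
    if method_a == method_b:
        raise ValueError("intersection requires two distinct base methods")
    for m in (method_a, method_b):
        if m not in BASE_METHODS:
            raise ValueError(f"unknown base method {m!r}; expected one of {BASE_METHODS}")
    x = np.asarray(x, dtype=float)
    k = _clip_k(k if k is not None else default_k(x.shape[1]), x)
    scores_a = _base_scores(x, y, method_a, k, seed)
    scores_b = _base_scores(x, y, method_b, k, seed)
    top_a, top_b = _top_k(scores_a, k), _top_k(scores_b, k)
    common = np.intersect1d(top_a, top_b)
    if len(common) < 2:
        ranks = (_rank(scores_a) + _rank(scores_b)) / 2.0
        pool = np.setdiff1d(np.union1d(top_a, top_b), common)
        order = pool[np.lexsort((pool, ranks[pool]))]
        need = 2 - len(common)
        common = np.sort(np.concatenate([common, order[:need]]).astype(int))
    return SelectionResult(
        f"{method_a}∩{method_b}", k, indices=common, fitted_on=fitted_on,
        parent_rankings={method_a: top_a, method_b: top_b},
    )


def fit_selector(method: str, x: np.ndarray, y, k: int | None = None,
                 seed: int = 0, fitted_on: str = "") -> SelectionResult:
    """Dispatch: base method name or 'a∩b' intersection name."""
    if method in BASE_METHODS:
        return select_features(x, y, method, k, seed, fitted_on)
    if "∩" in method:
        a, b = method.split("∩")
        b = "variance" if b == "var" else b
        return intersect_selections(a, b, x, y, k, seed, fitted_on)
    raise ValueError(f"unknown selection method {method!r}; expected one of {ALL_METHODS}")


def apply_selection(x: np.ndarray, sel: SelectionResult) -> np.ndarray:
    """Apply a fitted selector to (possibly held-out) rows."""
    x = np.asarray(x, dtype=float)
    if sel.is_projection:
        if x.shape[1] != sel.components.shape[0]:
            raise ValueError(
                f"dimension mismatch: X has D={x.shape[1]}, projection expects "
                f"D={sel.components.shape[0]}"
            )
        return (x - sel.mean) @ sel.components
    if sel.indices.max() >= x.shape[1]:
        raise ValueError(
            f"selection indices reach {sel.indices.max()} but X has only "
            f"D={x.shape[1]} columns"
        )
    return x[:, sel.indices]
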