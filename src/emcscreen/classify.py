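"""Decision-tree screening and its diagnostic metrics.

Trees are grown by recursive binary splitting on Gini's diversity
index ``1 − Σ f(i)²``, with the split chosen by exhaustive search over
midpoints of sorted unique feature values.  Hyper-parameters (depth,
minimum leaf size, split budget) are tuned by stratified 10-fold
cross-validation; generalisation is measured by leave-one-out
cross-validation and summarised as a confusion matrix with per-class
sensitivity, specificity, PPV and NPV.

The published screening split points (vertical displaced-mode cosine
similarity at 0.74, smooth-mode positional-error adjusted R² at 0.99)
are exposed as a fixed partial rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .stp import STPFeatures

__all__ = [
    "TreeNode",
    "ConfusionMatrix",
    "ClassCounts",
    "ClassMetrics",
    "gini_impurity",
    "grow_tree",
    "predict",
    "tune_tree_cv",
    "loocv_evaluate",
    "published_screening_rule",
    "one_vs_rest_counts",
    "class_metrics",
    "overall_accuracy",
    "round_half_away",
    "DEFAULT_PARAM_GRID",
]

#: default CV grid over (max_depth, min_leaf)
DEFAULT_PARAM_GRID: Tuple[Dict[str, int], ...] = tuple(
    {"max_depth": d, "min_leaf": m}
    for d in range(1, 7) for m in range(1, 6)
)

PUBLISHED_SIMILARITY_THRESHOLD = 0.74
PUBLISHED_ADJ_R2_THRESHOLD = 0.99


def gini_impurity(fractions: Sequence[float], tol: float = 1e-8) -> float:
    """Gini's diversity index ``1 − Σ f(i)²`` of class fractions."""
    f = np.asarray(fractions, dtype=float)
    if np.any(f < 0):
        raise ValueError("fractions must be non-negative")
    if abs(f.sum() - 1.0) > tol:
        raise ValueError("fractions must sum to 1")
    return float(1.0 - np.sum(f * f))


@dataclass
class TreeNode:
    """One node of a grown decision tree."""

    fractions: Dict[str, float]
    label: str
    n: int = 0  # training samples reaching the node
    feature: Optional[str] = None  # split feature name (internal nodes)
    feature_index: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None  # feature <= threshold
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def impurity(self) -> float:
        return gini_impurity(list(self.fractions.values()))

    def to_dict(self) -> dict:
        d = {"fractions": self.fractions, "label": self.label}
        if not self.is_leaf:
            d.update(
                feature=self.feature, threshold=self.threshold,
                left=self.left.to_dict(), right=self.right.to_dict(),
            )
        return d


def _node_stats(y: np.ndarray, classes: Sequence[str]) -> Tuple[Dict[str, float], str]:
    counts = {c: int(np.sum(y == c)) for c in classes}
    n = len(y)
    fractions = {c: counts[c] / n for c in classes}
    # majority label; ties broken by class order for determinism
    label = max(classes, key=lambda c: (counts[c], -list(classes).index(c)))
    return fractions, label


def _best_split(
    X: np.ndarray, y_codes: np.ndarray, n_classes: int, min_leaf: int
) -> Optional[Tuple[int, float, float]]:
    """Exhaustive (feature, threshold) search minimising weighted Gini.

    Candidate thresholds are midpoints of consecutive distinct sorted
    values.  Ties in impurity are broken by lower feature index, then
    lower threshold.  Returns ``(feature, threshold, weighted_gini)``
    or None when no admissible split exists.
    """
    n, d = X.shape
    best: Optional[Tuple[float, int, float]] = None
    onehot = np.eye(n_classes)[y_codes]
    for j in range(d):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        cum = np.cumsum(onehot[order], axis=0)  # class counts left of cut
        total = cum[-1]
        # cut after position i puts i+1 samples left
        sizes_left = np.arange(1, n)
        distinct = xs[1:] != xs[:-1]
        ok = distinct & (sizes_left >= min_leaf) & (n - sizes_left >= min_leaf)
        if not np.any(ok):
            continue
        left = cum[:-1][ok]
        nl = sizes_left[ok].astype(float)
        nr = n - nl
        right = total - left
        gini_l = 1.0 - np.sum((left / nl[:, None]) ** 2, axis=1)
        gini_r = 1.0 - np.sum((right / nr[:, None]) ** 2, axis=1)
        weighted = (nl * gini_l + nr * gini_r) / n
        thresholds = 0.5 * (xs[:-1][ok] + xs[1:][ok])
        # lowest impurity; ties → lowest threshold (feature order is the
        # outer loop, strict < keeps the earlier feature)
        order2 = np.lexsort((thresholds, weighted))
        i = order2[0]
        cand = (float(weighted[i]), j, float(thresholds[i]))
        if best is None or cand[0] < best[0] - 1e-15:
            best = cand
    if best is None:
        return None
    w, j, thr = best
    return j, thr, w


def grow_tree(
    X: np.ndarray,
    y: Sequence[str],
    feature_names: Optional[Sequence[str]] = None,
    max_depth: Optional[int] = None,
    min_leaf: int = 1,
    max_splits: Optional[int] = None,
) -> TreeNode:
    """Grow a Gini decision tree by recursive binary splitting.

    Splitting stops at node purity, the depth limit, the global split
    budget, or when no split leaves ``min_leaf`` samples per child.
    All-identical feature rows with mixed labels become a majority-label
    leaf.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per label")
    if X.shape[0] < 1:
        raise ValueError("need at least one sample")
    classes = sorted(set(y.tolist()))
    code = {c: i for i, c in enumerate(classes)}
    y_codes = np.array([code[v] for v in y])
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    budget = [math.inf if max_splits is None else int(max_splits)]

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        fractions, label = _node_stats(y[idx], classes)
        node = TreeNode(fractions=fractions, label=label, n=idx.size)
        if (gini_impurity(list(fractions.values())) == 0.0
                or (max_depth is not None and depth >= max_depth)
                or budget[0] <= 0
                or idx.size < 2 * min_leaf or idx.size < 2):
            return node
        found = _best_split(X[idx], y_codes[idx], len(classes), min_leaf)
        if found is None:
            return node
        j, thr, _weighted = found
        budget[0] -= 1
        mask = X[idx, j] <= thr
        node.feature = str(feature_names[j])
        node.feature_index = j
        node.threshold = thr
        node.left = build(idx[mask], depth + 1)
        node.right = build(idx[~mask], depth + 1)
        return node

    return build(np.arange(X.shape[0]), 0)


def predict(tree: TreeNode, X: np.ndarray) -> np.ndarray:
    """Predicted class labels for each row of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty(X.shape[0], dtype=object)
    for i, row in enumerate(X):
        node = tree
        while not node.is_leaf:
            node = node.left if row[node.feature_index] <= node.threshold else node.right
        out[i] = node.label
    return out


def _impute_medians(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Replace NaNs by per-column training medians (returned for reuse)."""
    X = np.array(X, dtype=float, copy=True)
    med = np.nanmedian(X, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    nan_r, nan_c = np.nonzero(~np.isfinite(X))
    X[nan_r, nan_c] = med[nan_c]
    return X, med


def tune_tree_cv(
    X: np.ndarray,
    y: Sequence[str],
    param_grid: Sequence[Dict[str, int]] = DEFAULT_PARAM_GRID,
    k: int = 10,
    seed: Optional[int] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> Tuple[Dict[str, int], TreeNode]:
    """Pick tree hyper-parameters by stratified k-fold CV, refit on all data.

    The parameter set with the lowest mean validation error wins; ties
    keep the earliest grid entry.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if len(y) < k:
        raise ValueError("k exceeds the number of samples")
    if not param_grid:
        raise ValueError("empty parameter grid")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y.astype(str)))
    best_err, best_params = None, None
    for params in param_grid:
        errs = []
        for tr, te in folds:
            Xtr, med = _impute_medians(X[tr])
            tree = grow_tree(Xtr, y[tr], feature_names, **params)
            Xte = np.array(X[te], copy=True)
            nan_r, nan_c = np.nonzero(~np.isfinite(Xte))
            Xte[nan_r, nan_c] = med[nan_c]
            errs.append(float(np.mean(predict(tree, Xte) != y[te])))
        mean_err = float(np.mean(errs))
        if best_err is None or mean_err < best_err - 1e-12:
            best_err, best_params = mean_err, dict(params)
    Xall, _ = _impute_medians(X)
    final = grow_tree(Xall, y, feature_names, **best_params)
    return best_params, final


@dataclass
class ConfusionMatrix:
    """Class-by-class counts; rows are true classes, columns predicted."""

    labels: List[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square in the labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[str], y_pred: Sequence[str],
        labels: Optional[Sequence[str]] = None,
    ) -> "ConfusionMatrix":
        if labels is None:
            labels = sorted(set(list(y_true)) | set(list(y_pred)))
        labels = list(labels)
        idx = {c: i for i, c in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[idx[t], idx[p]] += 1
        return cls(labels=labels, counts=counts)


def loocv_evaluate(
    X: np.ndarray,
    y: Sequence[str],
    params: Optional[Dict[str, int]] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> ConfusionMatrix:
    """Leave-one-out evaluation: train on n−1, predict the held-out one."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    n = len(y)
    if n < 2:
        raise ValueError("need at least two samples")
    params = dict(params or {})
    preds = []
    for i in range(n):
        keep = np.arange(n) != i
        Xtr, med = _impute_medians(X[keep])
        tree = grow_tree(Xtr, y[keep], feature_names, **params)
        row = np.array(X[i], copy=True)
        row[~np.isfinite(row)] = med[~np.isfinite(row)]
        preds.append(predict(tree, row[None, :])[0])
    labels = sorted(set(y.tolist()))
    return ConfusionMatrix.from_predictions(y, preds, labels)


def published_screening_rule(
    features: Union[STPFeatures, Dict[str, float]],
    ped_axis: str = "horizontal",
) -> str:
    """Apply the two published screening splits.

    Root: vertical displaced-mode cosine similarity ≤ 0.74 → patient.
    Otherwise, smooth-mode positional-error adjusted R² > 0.99 →
    healthy.  Remaining branches of the published tree are not
    enumerated in the text, so everything else is indeterminate.
    """
    get = features.values if isinstance(features, STPFeatures) else features
    sim_name = "cosine_similarity_vertical_displaced"
    r2_name = f"ped_adj_r2_{ped_axis}_smooth"
    for name in (sim_name, r2_name):
        if name not in get or not np.isfinite(get[name]):
            raise ValueError(f"required feature {name!r} missing")
    if get[sim_name] <= PUBLISHED_SIMILARITY_THRESHOLD:
        return "patient"
    if get[r2_name] > PUBLISHED_ADJ_R2_THRESHOLD:
        return "healthy"
    return "indeterminate"


@dataclass(frozen=True)
class ClassCounts:
    """One-vs-rest counts for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ClassMetrics:
    """Diagnostic percentages; NaN marks an undefined (0/0) metric."""

    sensitivity: float  # TPR = TP / (TP + FN)
    specificity: float  # TNR = TN / (TN + FP)
    ppv: float  # TP / (TP + FP)
    npv: float  # TN / (TN + FN)


def one_vs_rest_counts(cm: ConfusionMatrix, cls: str) -> ClassCounts:
    """Collapse a multi-class confusion matrix for one class."""
    if cls not in cm.labels:
        raise KeyError(f"unknown class {cls!r}")
    i = cm.labels.index(cls)
    tp = int(cm.counts[i, i])
    fp = int(cm.counts[:, i].sum()) - tp
    fn = int(cm.counts[i, :].sum()) - tp
    tn = cm.total - tp - fp - fn
    return ClassCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio_pct(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def class_metrics(counts: ClassCounts) -> ClassMetrics:
    """Sensitivity, specificity, PPV and NPV (percent)."""
    return ClassMetrics(
        sensitivity=_ratio_pct(counts.tp, counts.tp + counts.fn),
        specificity=_ratio_pct(counts.tn, counts.tn + counts.fp),
        ppv=_ratio_pct(counts.tp, counts.tp + counts.fp),
        npv=_ratio_pct(counts.tn, counts.tn + counts.fn),
    )


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """``100 × trace / total`` percent."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def round_half_away(value: float, decimals: int = 0) -> float:
    """Round half away from zero (report formatting, not banker's)."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor
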