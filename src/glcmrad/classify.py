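"""Tumor-type classification: three model families under 10-fold CV.

The classifier families mirror the study design: a Gini decision tree with
a small documented hyperparameter search, a 500-tree bootstrap random
forest whose class is a majority vote over trees, and a Gaussian-kernel
multiclass SVM (one-vs-one) with a searched box constraint / kernel scale
and optional feature standardization.  Evaluation pools out-of-fold
predictions from a stratified k-fold partition of scans into one confusion
matrix; per-class accuracy, specificity, sensitivity and F-score follow
the one-vs-rest confusion-matrix formulas, with percentile-bootstrap 95%
confidence intervals and one-vs-rest ROC/AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .imaging import ValidationError

__all__ = [
    "MODEL_FAMILIES",
    "ConfusionMatrix",
    "ClassifierReport",
    "train_decision_tree",
    "train_random_forest",
    "train_svm",
    "forest_vote_scores",
    "crossvalidate",
    "confusion_metrics",
    "roc_auc",
    "feature_importance",
    "confidence_interval",
]

MODEL_FAMILIES = ("tree", "forest", "svm")


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k) or np.any(self.counts < 0):
            raise ValidationError("confusion matrix must be square nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, cls: str) -> dict[str, int]:
        if cls not in self.classes:
            raise ValidationError(f"unknown class {cls!r}")
        k = self.classes.index(cls)
        tp = int(self.counts[k, k])
        fn = int(self.counts[k].sum() - tp)
        fp = int(self.counts[:, k].sum() - tp)
        tn = self.total - tp - fn - fp
        return {"TP": tp, "TN": tn, "FP": fp, "FN": fn}


def confusion_metrics(cm: ConfusionMatrix, cls: str) -> dict[str, float]:
    """One-vs-rest accuracy, specificity, sensitivity and F-score.

    Accuracy = (TP+TN)/(TP+FP+FN+TN); Specificity = TN/(FP+TN);
    Sensitivity = TP/(TP+FN); F-score = 2TP/(2TP+FP+FN).  Zero denominators
    yield NaN rather than a silent 0.
    """
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    c = cm.one_vs_rest(cls)
    tp, tn, fp, fn = c["TP"], c["TN"], c["FP"], c["FN"]

    def _div(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    return {
        "accuracy": _div(tp + tn, tp + fp + fn + tn),
        "specificity": _div(tn, fp + tn),
        "sensitivity": _div(tp, tp + fn),
        "f_score": _div(2 * tp, 2 * tp + fp + fn),
    }


def _clean_table(features: pd.DataFrame, labels: Sequence[str]):
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("features and labels disagree in length")
    if np.isnan(X).any():
        raise ValidationError("feature table contains missing values")
    if np.unique(y).size < 2:
        raise ValidationError("at least two classes required")
    return X, y


def train_decision_tree(
    features: pd.DataFrame,
    labels: Sequence[str],
    seed: int = 0,
    search_folds: int = 3,
    max_leaf_grid: Sequence[int] = (4, 8, 16, 32, None),
    min_leaf_grid: Sequence[int] = (1, 3, 5),
) -> DecisionTreeClassifier:
    """Gini decision tree with a grid search over tree-size parameters.

    The grid (maximum leaf count, minimum observations per leaf) is chosen
    by minimizing stratified cross-validation error — a deterministic
    stand-in for a black-box hyperparameter optimizer.
    """
    X, y = _clean_table(features, labels)
    base = DecisionTreeClassifier(criterion="gini", random_state=seed)
    grid = {"max_leaf_nodes": list(max_leaf_grid), "min_samples_leaf": list(min_leaf_grid)}
    cv = StratifiedKFold(n_splits=min(search_folds, np.bincount(
        pd.factorize(y)[0]).min()), shuffle=True, random_state=seed)
    gs = GridSearchCV(base, grid, cv=cv, n_jobs=1)
    gs.fit(X, y)
    return gs.best_estimator_


def train_random_forest(
    features: pd.DataFrame,
    labels: Sequence[str],
    n_trees: int = 500,
    seed: int = 0,
) -> RandomForestClassifier:
    """Bootstrap forest of ``n_trees`` Gini trees with random feature subsets."""
    X, y = _clean_table(features, labels)
    model = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return model


def forest_vote_scores(model: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Per-class fraction of trees voting for the class (hard majority vote).

    The ensemble's class is the argmax of these vote fractions; ties break
    toward the first class in the fitted label order.
    """
    X = np.asarray(X, dtype=float)
    k = len(model.classes_)
    votes = np.zeros((X.shape[0], k))
    lut = {c: i for i, c in enumerate(model.classes_)}
    for tree in model.estimators_:
        pred = np.asarray(tree.predict(X))
        if pred.dtype.kind in "fiu":  # trees in a forest see encoded labels
            idx = pred.astype(int)
        else:
            idx = np.array([lut[p] for p in pred])
        votes[np.arange(X.shape[0]), idx] += 1.0
    return votes / len(model.estimators_)


def train_svm(
    features: pd.DataFrame,
    labels: Sequence[str],
    seed: int = 0,
    search_folds: int = 3,
    c_grid: Sequence[float] = (0.1, 1.0, 10.0, 100.0),
    gamma_grid: Sequence[str | float] = ("scale", 0.01, 0.1),
) -> Pipeline:
    """Gaussian-kernel one-vs-one SVM with searched C, kernel scale and
    standardization on/off."""
    X, y = _clean_table(features, labels)
    pipe = Pipeline(
        [("scale", StandardScaler()), ("svc", SVC(kernel="rbf", random_state=seed,
                                                  decision_function_shape="ovr"))]
    )
    grid = {
        "scale": [StandardScaler(), "passthrough"],
        "svc__C": list(c_grid),
        "svc__gamma": list(gamma_grid),
    }
    cv = StratifiedKFold(n_splits=min(search_folds, np.bincount(
        pd.factorize(y)[0]).min()), shuffle=True, random_state=seed)
    gs = GridSearchCV(pipe, grid, cv=cv, n_jobs=1)
    gs.fit(X, y)
    return gs.best_estimator_


_TRAINERS = {
    "tree": train_decision_tree,
    "forest": train_random_forest,
    "svm": train_svm,
}


def _scores_for(model, family: str, X: np.ndarray) -> np.ndarray:
    if family == "forest":
        return forest_vote_scores(model, X)
    if family == "tree":
        return model.predict_proba(X)
    # SVM: aggregated one-vs-rest decision values from the one-vs-one votes
    return model.decision_function(X)


def roc_auc(scores: np.ndarray, labels: Sequence[str], cls: str,
            classes: Optional[Sequence[str]] = None):
    """One-vs-rest ROC by threshold sweep and trapezoid AUC.

    With tied scores the AUC equals the rank-sum (Mann-Whitney) probability
    estimator; all scores equal gives 0.5.
    """
    y = np.asarray(labels)
    if classes is None:
        classes = sorted(set(y))
    classes = list(classes)
    if cls not in classes:
        raise ValidationError(f"unknown class {cls!r}")
    pos = (y == cls).astype(int)
    if pos.sum() == 0 or pos.sum() == pos.size:
        raise ValidationError("ROC needs both positive and negative examples")
    s = np.asarray(scores)
    col = s[:, classes.index(cls)] if s.ndim == 2 else s
    fpr, tpr, _ = roc_curve(pos, col)
    return float(roc_auc_score(pos, col)), np.column_stack([fpr, tpr])


def confidence_interval(
    values_fn,
    n_items: int,
    seed: int = 0,
    n_boot: int = 2000,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI of a pooled-prediction metric.

    ``values_fn(indices)`` must return the metric recomputed on a resample
    of the pooled out-of-fold predictions.  NaN resamples (empty one-vs-rest
    cells) are dropped.
    """
    if n_boot < 100:
        raise ValidationError("need >= 100 bootstrap resamples")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n_items, size=n_items)
        stats[b] = values_fn(idx)
    stats = stats[~np.isnan(stats)]
    lo, hi = np.percentile(stats, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))


@dataclass
class ClassifierReport:
    """Cross-validation results for one (family, region, GLCM size) setting."""

    family: str
    classes: tuple[str, ...]
    confusion: ConfusionMatrix
    per_class: pd.DataFrame
    fold_confusions: list[ConfusionMatrix]
    accuracy: float
    n_scans: int
    n_levels: Optional[int] = None
    region: Optional[str] = None
    roc_points: dict[str, np.ndarray] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"Model family: {self.family}   scans: {self.n_scans}   "
            f"region: {self.region or '-'}   GLCM size: {self.n_levels or '-'}",
            f"Pooled cross-validated accuracy: {self.accuracy:.3f}",
            "",
            self.per_class.round(3).to_string(),
        ]
        return "\n".join(lines)


def crossvalidate(
    family: str,
    features: pd.DataFrame,
    labels: Sequence[str],
    k: int = 10,
    seed: int = 0,
    groups: Optional[Sequence[str]] = None,
    n_boot: int = 2000,
    n_levels: Optional[int] = None,
    region: Optional[str] = None,
    **train_kwargs,
) -> ClassifierReport:
    """Stratified k-fold cross-validation of one model family.

    Folds partition individual scans (the default, matching the study
    design) or whole animals when ``groups`` is given, so repeat scans of
    one animal never straddle folds in that mode.  Out-of-fold predictions
    are pooled into a single confusion matrix; per-class metrics carry
    percentile-bootstrap 95% CIs over the pooled predictions.
    """
    if family not in MODEL_FAMILIES:
        raise ValidationError(f"unknown model family {family!r}")
    X, y = _clean_table(features, labels)
    n = X.shape[0]
    if groups is not None:
        groups = np.asarray(groups)
        units = pd.unique(groups)
    else:
        units = np.arange(n)
        groups = units
    if k > len(units):
        raise ValidationError(f"k={k} exceeds the {len(units)} partition units")
    classes = tuple(sorted(set(y)))
    # stratify units by their (single) class
    unit_class = pd.Series(y, index=np.arange(n)).groupby(
        pd.Series(groups, index=np.arange(n))).first()
    unit_ids = unit_class.index.to_numpy()
    unit_y = unit_class.to_numpy()
    min_class = pd.Series(unit_y).value_counts().min()
    if k <= min_class:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        fold_iter = splitter.split(unit_ids, unit_y)
    else:
        # too many folds for per-class stratification (k up to leave-one-out):
        # plain shuffled folds over units
        from sklearn.model_selection import KFold

        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        fold_iter = splitter.split(unit_ids)

    oof_pred = np.empty(n, dtype=object)
    oof_scores = np.zeros((n, len(classes)))
    fold_cms = []
    for f, (tr_u, te_u) in enumerate(fold_iter):
        tr = np.isin(groups, unit_ids[tr_u])
        te = np.isin(groups, unit_ids[te_u])
        model = _TRAINERS[family](pd.DataFrame(X[tr]), y[tr], seed=seed + f,
                                  **train_kwargs)
        scores = _scores_for(model, family, X[te])
        model_classes = list(getattr(model, "classes_", None)
                             if hasattr(model, "classes_")
                             else model[-1].classes_)
        # map score columns into the report's class order; a class absent
        # from this fold's training set can never be predicted
        full = np.full((scores.shape[0], len(classes)), -np.inf)
        for ci, c in enumerate(model_classes):
            full[:, classes.index(c)] = scores[:, ci]
        scores = full
        pred = np.asarray(classes)[scores.argmax(axis=1)]
        oof_pred[te] = pred
        oof_scores[te] = scores
        fold_cms.append(
            ConfusionMatrix(_sk_confusion(y[te], pred, labels=list(classes)), classes)
        )

    pooled = ConfusionMatrix(
        _sk_confusion(y, oof_pred.astype(str), labels=list(classes)), classes
    )
    accuracy = float((oof_pred.astype(str) == y).mean())

    rows = {}
    roc_points = {}
    ypred = oof_pred.astype(str)
    for cls in classes:
        m = confusion_metrics(pooled, cls)
        auc, pts = roc_auc(oof_scores, y, cls, classes=classes)
        roc_points[cls] = pts
        row = {"auc": auc}
        for name in ("accuracy", "specificity", "sensitivity", "f_score"):
            row[name] = m[name]

        # each pooled prediction falls in exactly one one-vs-rest cell for
        # this class; bootstrapping then only needs category counts
        is_pos = y == cls
        is_pred = ypred == cls
        cat = np.where(is_pos & is_pred, 0,
              np.where(~is_pos & ~is_pred, 1,
              np.where(~is_pos & is_pred, 2, 3)))  # TP, TN, FP, FN

        def _metric_from_counts(c, name):
            tp, tn, fp, fn_ = (float(x) for x in c)
            num, den = {
                "accuracy": (tp + tn, tp + tn + fp + fn_),
                "specificity": (tn, fp + tn),
                "sensitivity": (tp, tp + fn_),
                "f_score": (2 * tp, 2 * tp + fp + fn_),
            }[name]
            return num / den if den > 0 else float("nan")

        for name in ("accuracy", "specificity", "sensitivity", "f_score"):
            def fn(idx, name=name):
                counts = np.bincount(cat[idx], minlength=4)
                return _metric_from_counts(counts, name)

            lo, hi = confidence_interval(fn, n, seed=seed, n_boot=n_boot)
            row[f"{name}_ci_low"], row[f"{name}_ci_high"] = lo, hi

        col = oof_scores[:, classes.index(cls)]

        def auc_fn(idx, col=col):
            # rank-sum AUC estimator (equals trapezoid ROC with tie averaging)
            p = is_pos[idx]
            n1 = int(p.sum())
            n0 = p.size - n1
            if n1 == 0 or n0 == 0:
                return float("nan")
            r = sps.rankdata(col[idx])
            return float((r[p].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))

        row["auc_ci_low"], row["auc_ci_high"] = confidence_interval(
            auc_fn, n, seed=seed, n_boot=n_boot
        )
        rows[cls] = row

    per_class = pd.DataFrame(rows).T
    return ClassifierReport(
        family=family,
        classes=classes,
        confusion=pooled,
        per_class=per_class,
        fold_confusions=fold_cms,
        accuracy=accuracy,
        n_scans=n,
        n_levels=n_levels,
        region=region,
        roc_points=roc_points,
    )


def feature_importance(model: RandomForestClassifier,
                       feature_names: Sequence[str]) -> pd.Series:
    """Split-gain importance normalized by the number of branch nodes.

    For every node that splits on a feature, the weighted impurity decrease
    of the split is credited to that feature; credits are summed over all
    trees and divided by the forest's total branch-node count.  Features
    never used in a split score exactly 0.  Returned sorted descending.
    """
    if not hasattr(model, "estimators_") or not model.estimators_:
        raise ValidationError("model is not a trained forest")
    names = list(feature_names)
    gains = np.zeros(len(names))
    n_branch = 0
    for est in model.estimators_:
        t = est.tree_
        n_total = t.weighted_n_node_samples[0]
        for node in range(t.node_count):
            left, right = t.children_left[node], t.children_right[node]
            if left == -1:
                continue
            n_branch += 1
            w = t.weighted_n_node_samples
            gain = (
                w[node] * t.impurity[node]
                - w[left] * t.impurity[left]
                - w[right] * t.impurity[right]
            ) / n_total
            gains[t.feature[node]] += gain
    if n_branch == 0:
        raise ValidationError("forest has no branch nodes")
    return pd.Series(gains / n_branch, index=names).sort_values(ascending=False)
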