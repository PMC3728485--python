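"""Nested cross-validated classification of feature tables.

Exemplars are parsed into ten (approximately equal, stratified) outer bins;
nine are used for training — including feature ranking, forward subset
selection and hyperparameter tuning, all via an *inner* 10-fold CV on those
nine bins only — and the tenth is scored.  Everything fitted (ICA models,
time-point selections, rankings, tuned hyperparameters) therefore never sees
an outer-test exemplar; this no-leakage contract is the core guarantee of the
decoder and is verified bit-for-bit in the test suite.

Four classifier families are supported: the reduced-error-pruned decision
tree (:class:`~icdecode.tree.PrunedDecisionTree`), Gaussian naive Bayes,
SVM, and AdaBoost over decision stumps.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import StratifiedKFold, KFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .eeg import FeatureTable
from .tree import PrunedDecisionTree

__all__ = [
    "CVSpec",
    "ClassifierSpec",
    "CVReport",
    "make_folds",
    "rank_features",
    "forward_select",
    "fit_tree",
    "fit_classifier",
    "predict",
    "run_nested_cv",
]

FAMILIES = ("decision_tree", "naive_bayes", "svm", "adaboost")


@dataclass(frozen=True)
class CVSpec:
    outer_folds: int = 10
    inner_folds: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")


def _default_grid(family: str) -> dict[str, list]:
    # first grid point doubles as the family's working default during
    # forward selection (tuning proper happens afterwards on the subset)
    return {
        "decision_tree": {"min_samples_leaf": [10, 40]},
        "naive_bayes": {},
        "svm": {"kernel": ["linear", "rbf"], "C": [0.1, 1.0, 10.0]},
        "adaboost": {"n_estimators": [25, 50, 100]},
    }[family]


@dataclass
class ClassifierSpec:
    family: str
    grid: dict[str, list] | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")
        if self.grid is None:
            self.grid = _default_grid(self.family)

    def grid_points(self) -> list[dict]:
        if not self.grid:
            return [{}]
        keys = list(self.grid)
        return [dict(zip(keys, combo))
                for combo in itertools.product(*(self.grid[k] for k in keys))]


@dataclass
class CVReport:
    fold_accuracies: list[float]
    per_exemplar_predictions: NDArray
    fold_assignment: NDArray
    selected_subsets: list[list[int]]
    chosen_params: list[dict]
    classifier_family: str
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    def to_json(self, path=None) -> str:
        payload = {
            "classifier_family": self.classifier_family,
            "seed": self.seed,
            "fold_accuracies": self.fold_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "per_exemplar_predictions": self.per_exemplar_predictions.tolist(),
            "fold_assignment": self.fold_assignment.tolist(),
            "selected_subsets": self.selected_subsets,
            "chosen_params": self.chosen_params,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            from pathlib import Path
            Path(path).write_text(text)
        return text


# ----------------------------------------------------------------------

def make_folds(labels: ArrayLike, spec: CVSpec) -> NDArray:
    """Assign each exemplar to one of ``outer_folds`` bins.

    Sizes differ by at most one; stratified by label when enabled;
    deterministic per seed.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < spec.outer_folds:
        raise ValueError("fewer exemplars than folds")
    if spec.stratified:
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < spec.outer_folds:
            raise ValueError(
                "a class has fewer exemplars than folds; disable "
                "stratification or reduce folds"
            )
        splitter = StratifiedKFold(n_splits=spec.outer_folds, shuffle=True,
                                   random_state=spec.seed)
    else:
        splitter = KFold(n_splits=spec.outer_folds, shuffle=True,
                         random_state=spec.seed)
    assignment = np.empty(n, dtype=int)
    for k, (_, test_idx) in enumerate(splitter.split(np.zeros(n), labels)):
        assignment[test_idx] = k
    return assignment


def rank_features(X: ArrayLike, y: ArrayLike) -> NDArray:
    """Feature order by descending absolute Welch two-sample t statistic.

    Constant features get t = 0 and sink to the back; ties break by column
    index (stable sort).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("ranking requires both classes present")
    a, b = X[y == classes[0]], X[y == classes[1]]
    va = a.var(axis=0, ddof=1) / len(a)
    vb = b.var(axis=0, ddof=1) / len(b)
    denom = np.sqrt(va + vb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (a.mean(axis=0) - b.mean(axis=0)) / denom, 0.0)
    return np.argsort(-np.abs(t), kind="stable")


def _make_estimator(family: str, params: dict, seed: int | None):
    if family == "decision_tree":
        return PrunedDecisionTree(random_state=seed, **params)
    if family == "naive_bayes":
        return GaussianNB(**params)
    if family == "svm":
        return SVC(random_state=seed, **params)
    if family == "adaboost":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            random_state=seed, **params)
    raise ValueError(f"unknown classifier family {family!r}")


def _safe_fit_predict(est, Xtr, ytr, Xte):
    try:
        est.fit(Xtr, ytr)
    except ValueError:
        # degenerate training split (e.g. leaf floor unreachable):
        # fall back to majority vote
        vals, counts = np.unique(ytr, return_counts=True)
        return np.full(len(Xte), vals[np.argmax(counts)])
    return est.predict(Xte)


def _inner_cv_accuracy(X, y, cols, family, params, inner_folds, seed) -> float:
    cols = np.asarray(cols, dtype=int)
    _, counts = np.unique(y, return_counts=True)
    n_splits = int(min(inner_folds, counts.min()))
    if n_splits < 2:
        raise ValueError("too few exemplars per class for inner CV")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(X, y):
        est = _make_estimator(family, params, seed)
        pred = _safe_fit_predict(est, X[tr][:, cols], y[tr], X[te][:, cols])
        correct += (pred == y[te]).sum()
    return correct / len(y)


def forward_select(
    X: ArrayLike,
    y: ArrayLike,
    ranking: ArrayLike,
    classifier: ClassifierSpec,
    inner_folds: int = 10,
    seed: int | None = 0,
    patience: int = 3,
    max_features: int | None = None,
) -> list[int]:
    """Ranked forward feature-subset selection by inner-CV accuracy.

    Features are added in rank order; the prefix with the highest inner-CV
    accuracy is returned, stopping after ``patience`` consecutive additions
    without improvement.  Evaluation uses the supplied rows only (call with
    training-fold rows to respect the firewall).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    ranking = list(np.asarray(ranking, dtype=int))
    if not ranking:
        raise ValueError("empty ranking")
    if max_features is not None:
        ranking = ranking[:max_features]
    params = {k: v[0] for k, v in (classifier.grid or {}).items()}
    best_score, best_subset = -np.inf, ranking[:1]
    since_improve = 0
    for i in range(1, len(ranking) + 1):
        score = _inner_cv_accuracy(X, y, ranking[:i], classifier.family,
                                   params, inner_folds, seed)
        if score > best_score + 1e-12:
            best_score, best_subset = score, ranking[:i]
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= patience:
                break
    return list(best_subset)


def _tune(X, y, cols, classifier: ClassifierSpec, inner_folds, seed) -> dict:
    best_score, best_params = -np.inf, {}
    for params in classifier.grid_points():
        score = _inner_cv_accuracy(X, y, cols, classifier.family, params,
                                   inner_folds, seed)
        if score > best_score + 1e-12:
            best_score, best_params = score, params
    return best_params


def fit_tree(X: ArrayLike, y: ArrayLike, min_instances_per_leaf: int = 40,
             pruning_fraction: float = 1 / 3,
             seed: int | None = 0) -> PrunedDecisionTree:
    """Fit the reduced-error-pruned decision tree (functional wrapper)."""
    est = PrunedDecisionTree(min_samples_leaf=min_instances_per_leaf,
                             pruning_fraction=pruning_fraction,
                             random_state=seed)
    return est.fit(X, y)


def fit_classifier(X: ArrayLike, y: ArrayLike, spec: ClassifierSpec,
                   params: dict | None = None, seed: int | None = 0):
    """Fit one classifier family with explicit (or first-grid-point) params."""
    if params is None:
        params = {k: v[0] for k, v in (spec.grid or {}).items()}
    est = _make_estimator(spec.family, params, seed)
    return est.fit(np.asarray(X, dtype=float), np.asarray(y))


def predict(model, rows: ArrayLike) -> NDArray:
    return model.predict(np.asarray(rows, dtype=float))


# ----------------------------------------------------------------------

def run_nested_cv(
    features,
    classifier: ClassifierSpec,
    cv: CVSpec = CVSpec(),
    feature_selection: bool = True,
    tune: bool = True,
    max_features: int | None = None,
) -> CVReport:
    """Nested cross-validated decoding.

    ``features`` is either a :class:`~icdecode.eeg.FeatureTable` (fixed
    exemplar x feature matrix) or a *per-fold builder* — an object with a
    ``labels`` array, ``fit(train_idx)`` and ``features(idx, held_out)``
    methods — so that ICA fitting and time-point selection re-run inside
    every outer fold on the training bins alone.
    """
    builder = None
    if isinstance(features, FeatureTable):
        labels = features.y
    else:
        builder = features
        labels = np.asarray(builder.labels)
    n = len(labels)
    assignment = make_folds(labels, cv)
    preds = np.empty(n, dtype=labels.dtype)
    fold_acc, subsets, chosen = [], [], []
    for k in range(cv.outer_folds):
        test_idx = np.where(assignment == k)[0]
        train_idx = np.where(assignment != k)[0]
        if builder is not None:
            builder.fit(train_idx)
            Xtr = builder.features(train_idx, held_out=False)
            Xte = builder.features(test_idx, held_out=True)
            ytr, yte = labels[train_idx], labels[test_idx]
        else:
            Xtr, Xte = features.X[train_idx], features.X[test_idx]
            ytr, yte = labels[train_idx], labels[test_idx]

        ranking = rank_features(Xtr, ytr)
        if feature_selection:
            cols = forward_select(Xtr, ytr, ranking, classifier,
                                  inner_folds=cv.inner_folds, seed=cv.seed,
                                  max_features=max_features)
        else:
            cols = list(ranking)
        params = (_tune(Xtr, ytr, cols, classifier, cv.inner_folds, cv.seed)
                  if tune and classifier.grid else
                  {k_: v[0] for k_, v in (classifier.grid or {}).items()})
        est = _make_estimator(classifier.family, params, cv.seed)
        pred = _safe_fit_predict(est, Xtr[:, cols], ytr, Xte[:, cols])
        preds[test_idx] = pred
        fold_acc.append(float((pred == yte).mean()))
        subsets.append([int(c) for c in cols])
        chosen.append(params)
    return CVReport(
        fold_accuracies=fold_acc,
        per_exemplar_predictions=preds,
        fold_assignment=assignment,
        selected_subsets=subsets,
        chosen_params=chosen,
        classifier_family=classifier.family,
        seed=cv.seed,
    )
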