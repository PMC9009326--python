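"""Classifier registry, cross-validated model selection, scoring, persistence.

The registry ships a small set of deterministic classifiers over the
4-feature representation: a logistic model tree (information-gain splits
with ridge-regularized logistic leaves), plain logistic regression, a
decision tree, Gaussian naive Bayes and k-nearest-neighbors.  All are
evaluated with the SAME stratified folds so accuracies are comparable; the
best mean accuracy wins, ties broken by balanced accuracy then registry
order.  Scores are in [0, 1] but are not calibrated probabilities.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

from operonmerge._errors import ValidationError
from operonmerge.instances import MergeCandidate, TrainingInstance

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

# ---------------------------------------------------------------------------
# models


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))


def _fit_ridge_logistic(X: np.ndarray, y: np.ndarray, ridge: float) -> tuple[np.ndarray, float]:
    """L2-regularized logistic fit; returns (coef, intercept).

    Shared by the plain logistic spec and the LMT leaves so that a depth-0
    tree reproduces plain logistic regression exactly.
    """
    lr = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=1000)
    lr.fit(X, y)
    return lr.coef_[0].copy(), float(lr.intercept_[0])


def _laplace_rate(y: np.ndarray) -> float:
    # Clamped into (0, 1) even for pure nodes.
    return (float(np.sum(y == 1)) + 1.0) / (len(y) + 2.0)


class LogisticRegressionModel:
    """Ridge-regularized logistic regression over the 4 features."""

    def __init__(self, ridge: float = 1.0):
        self.ridge = ridge
        self.coef_: np.ndarray | None = None
        self.intercept_: float | None = None
        self.base_rate_: float | None = None

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int = 0) -> "LogisticRegressionModel":
        _check_two_classes(y)
        self.base_rate_ = _laplace_rate(y)
        self.coef_, self.intercept_ = _fit_ridge_logistic(X, y, self.ridge)
        return self

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise ValidationError("model is not fitted")
        return _sigmoid(X @ self.coef_ + self.intercept_)

    def state_dict(self) -> dict:
        return {
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_,
            "base_rate": self.base_rate_,
        }

    def load_state(self, state: dict) -> None:
        self.coef_ = np.asarray(state["coef"], dtype=float)
        self.intercept_ = float(state["intercept"])
        self.base_rate_ = state.get("base_rate")


def _entropy(y: np.ndarray) -> float:
    n = len(y)
    if n == 0:
        return 0.0
    p = float(np.mean(y))
    out = 0.0
    for q in (p, 1.0 - p):
        if q > 0:
            out -= q * math.log2(q)
    return out


def _best_split(X: np.ndarray, y: np.ndarray, min_leaf: int) -> tuple[int, float, float] | None:
    """Best (feature, threshold, gain) by information gain, or None.

    Thresholds are midpoints between consecutive sorted unique values; both
    children must keep at least ``min_leaf`` instances.  Ties go to the
    lowest feature index, then the lowest threshold (deterministic).
    """
    n = len(y)
    parent = _entropy(y)
    best: tuple[int, float, float] | None = None
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs, ys = X[order, j], y[order]
        for i in range(min_leaf, n - min_leaf + 1):
            if xs[i - 1] == xs[i]:
                continue
            thr = (xs[i - 1] + xs[i]) / 2.0
            gain = parent - (i / n) * _entropy(ys[:i]) - ((n - i) / n) * _entropy(ys[i:])
            if gain > 1e-12 and (best is None or gain > best[2] + 1e-12):
                best = (j, float(thr), float(gain))
    return best


@dataclass
class _TreeNode:
    feature: int | None = None
    threshold: float | None = None
    left: "_TreeNode | None" = None
    right: "_TreeNode | None" = None
    # leaf payload: either a logistic model or a constant rate
    coef: np.ndarray | None = None
    intercept: float | None = None
    rate: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


class LogisticModelTreeModel:
    """Binary information-gain tree with a ridge logistic model at each leaf.

    ``max_depth=0`` degenerates to plain logistic regression.  A leaf whose
    instances carry a single label falls back to a Laplace-clamped constant
    score strictly inside (0, 1).
    """

    def __init__(self, max_depth: int = 3, min_leaf: int = 10, ridge: float = 1.0):
        if min_leaf < 2:
            raise ValidationError(f"min_leaf must be >= 2, got {min_leaf}")
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.ridge = ridge
        self.root_: _TreeNode | None = None
        self.leaf_kind = "logistic"

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int = 0) -> "LogisticModelTreeModel":
        _check_two_classes(y)
        self.root_ = self._grow(X, y, depth=0)
        return self

    def _grow(self, X: np.ndarray, y: np.ndarray, depth: int) -> _TreeNode:
        if depth < self.max_depth and len(y) >= 2 * self.min_leaf:
            split = _best_split(X, y, self.min_leaf)
            if split is not None:
                j, thr, _gain = split
                mask = X[:, j] <= thr
                return _TreeNode(
                    feature=j,
                    threshold=thr,
                    left=self._grow(X[mask], y[mask], depth + 1),
                    right=self._grow(X[~mask], y[~mask], depth + 1),
                )
        return self._make_leaf(X, y)

    def _make_leaf(self, X: np.ndarray, y: np.ndarray) -> _TreeNode:
        if self.leaf_kind == "logistic" and len(np.unique(y)) == 2:
            coef, intercept = _fit_ridge_logistic(X, y, self.ridge)
            return _TreeNode(coef=coef, intercept=intercept)
        return _TreeNode(rate=_laplace_rate(y))

    def _leaf_for(self, x: np.ndarray) -> _TreeNode:
        node = self.root_
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        if self.root_ is None:
            raise ValidationError("model is not fitted")
        out = np.empty(len(X))
        for i, x in enumerate(np.asarray(X, dtype=float)):
            leaf = self._leaf_for(x)
            if leaf.rate is not None:
                out[i] = leaf.rate
            else:
                out[i] = float(_sigmoid(np.array([x @ leaf.coef + leaf.intercept]))[0])
        return out

    def state_dict(self) -> dict:
        return {"tree": _node_to_dict(self.root_)}

    def load_state(self, state: dict) -> None:
        self.root_ = _node_from_dict(state["tree"])


class DecisionTreeModel(LogisticModelTreeModel):
    """The same information-gain tree with constant (Laplace) leaf scores."""

    def __init__(self, max_depth: int = 5, min_leaf: int = 5):
        super().__init__(max_depth=max_depth, min_leaf=min_leaf)
        self.leaf_kind = "constant"

    def _make_leaf(self, X: np.ndarray, y: np.ndarray) -> _TreeNode:
        return _TreeNode(rate=_laplace_rate(y))


def _node_to_dict(node: _TreeNode) -> dict:
    if node.is_leaf:
        if node.rate is not None:
            return {"rate": node.rate}
        return {"coef": node.coef.tolist(), "intercept": node.intercept}
    return {
        "feature": node.feature,
        "threshold": node.threshold,
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }


def _node_from_dict(data: dict) -> _TreeNode:
    if "feature" in data:
        return _TreeNode(
            feature=data["feature"],
            threshold=data["threshold"],
            left=_node_from_dict(data["left"]),
            right=_node_from_dict(data["right"]),
        )
    if "rate" in data:
        return _TreeNode(rate=data["rate"])
    return _TreeNode(coef=np.asarray(data["coef"]), intercept=data["intercept"])


class GaussianNBModel:
    """Gaussian naive Bayes (scikit-learn backed)."""

    def __init__(self):
        self._nb: GaussianNB | None = None

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int = 0) -> "GaussianNBModel":
        _check_two_classes(y)
        self._nb = GaussianNB().fit(X, y)
        return self

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        if self._nb is None:
            raise ValidationError("model is not fitted")
        return self._nb.predict_proba(X)[:, 1]

    def state_dict(self) -> dict:
        return {
            "theta": self._nb.theta_.tolist(),
            "var": self._nb.var_.tolist(),
            "class_prior": self._nb.class_prior_.tolist(),
            "classes": self._nb.classes_.tolist(),
        }

    def load_state(self, state: dict) -> None:
        nb = GaussianNB()
        nb.classes_ = np.asarray(state["classes"])
        nb.theta_ = np.asarray(state["theta"])
        nb.var_ = np.asarray(state["var"])
        nb.class_prior_ = np.asarray(state["class_prior"])
        self._nb = nb


class KNNModel:
    """k-nearest-neighbors; the persisted state is the training sample itself."""

    def __init__(self, n_neighbors: int = 5):
        self.n_neighbors = n_neighbors
        self._knn: KNeighborsClassifier | None = None
        self._X: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int = 0) -> "KNNModel":
        _check_two_classes(y)
        k = min(self.n_neighbors, len(y))
        self._knn = KNeighborsClassifier(n_neighbors=k).fit(X, y)
        self._X, self._y = np.asarray(X, float), np.asarray(y, int)
        return self

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        if self._knn is None:
            raise ValidationError("model is not fitted")
        return self._knn.predict_proba(X)[:, 1]

    def state_dict(self) -> dict:
        return {"X": self._X.tolist(), "y": self._y.tolist()}

    def load_state(self, state: dict) -> None:
        self.fit(np.asarray(state["X"], float), np.asarray(state["y"], int))


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValidationError("training data must contain both labels")


# ---------------------------------------------------------------------------
# registry


@dataclass(frozen=True)
class ClassifierSpec:
    """Named, reproducible recipe for a scoring model."""

    name: str
    hyperparameters: Mapping[str, object]
    factory: Callable[..., object]

    def build(self):
        return self.factory(**self.hyperparameters)


def default_registry() -> list[ClassifierSpec]:
    """Registry order is the deterministic tie-break order."""
    return [
        ClassifierSpec(
            "logistic_model_tree",
            {"max_depth": 3, "min_leaf": 10, "ridge": 1.0},
            LogisticModelTreeModel,
        ),
        ClassifierSpec("logistic_regression", {"ridge": 1.0}, LogisticRegressionModel),
        ClassifierSpec("decision_tree", {"max_depth": 5, "min_leaf": 5}, DecisionTreeModel),
        ClassifierSpec("naive_bayes", {}, GaussianNBModel),
        ClassifierSpec("knn", {"n_neighbors": 5}, KNNModel),
    ]


def registry_by_name(names: Sequence[str] | None = None) -> list[ClassifierSpec]:
    registry = default_registry()
    if names is None:
        return registry
    by_name = {spec.name: spec for spec in registry}
    try:
        return [by_name[n] for n in names]
    except KeyError as exc:
        raise ValidationError(f"unknown classifier {exc.args[0]!r}") from None


# ---------------------------------------------------------------------------
# cross-validation and selection


@dataclass(frozen=True)
class CVReport:
    classifier: str
    fold_accuracies: tuple[float, ...]
    mean_accuracy: float
    balanced_accuracy: float
    seed: int


def instances_to_xy(instances: Sequence[TrainingInstance]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([inst.features.as_array() for inst in instances])
    y = np.array([1 if inst.label == "positive" else 0 for inst in instances])
    return X, y


def cross_validate(
    instances: Sequence[TrainingInstance],
    specs: Sequence[ClassifierSpec],
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> list[CVReport]:
    """Stratified k-fold CV; identical folds for every spec (same seed).

    Accuracy is the fraction of held-out instances whose thresholded score
    (strictly greater than ``threshold`` means positive) matches the label.
    """
    X, y = instances_to_xy(instances)
    for label in (0, 1):
        count = int(np.sum(y == label))
        if count < k:
            raise ValidationError(
                f"label {label} has {count} instances; needs >= k={k}"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    reports = []
    for spec in specs:
        fold_accs = []
        correct_by_label = {0: [0, 0], 1: [0, 0]}  # label -> [correct, total]
        for train_idx, test_idx in folds:
            model = spec.build()
            model.fit(X[train_idx], y[train_idx], seed=seed)
            pred = (model.predict_score(X[test_idx]) > threshold).astype(int)
            fold_accs.append(float(np.mean(pred == y[test_idx])))
            for label in (0, 1):
                mask = y[test_idx] == label
                correct_by_label[label][0] += int(np.sum(pred[mask] == label))
                correct_by_label[label][1] += int(np.sum(mask))
        per_label = [
            correct_by_label[label][0] / correct_by_label[label][1] for label in (0, 1)
        ]
        reports.append(
            CVReport(
                classifier=spec.name,
                fold_accuracies=tuple(fold_accs),
                mean_accuracy=float(np.mean(fold_accs)),
                balanced_accuracy=float(np.mean(per_label)),
                seed=seed,
            )
        )
        logger.info(
            "CV %s: mean=%.4f balanced=%.4f",
            spec.name,
            reports[-1].mean_accuracy,
            reports[-1].balanced_accuracy,
        )
    return reports


def select_best(
    reports: Sequence[CVReport], specs: Sequence[ClassifierSpec]
) -> ClassifierSpec:
    """Highest mean accuracy; ties by balanced accuracy, then registry order."""
    if not reports:
        raise ValidationError("select_best needs at least one report")
    by_name = {spec.name: i for i, spec in enumerate(specs)}
    best = max(
        reports,
        key=lambda r: (r.mean_accuracy, r.balanced_accuracy, -by_name[r.classifier]),
    )
    return specs[by_name[best.classifier]]


def train_full(
    spec: ClassifierSpec, instances: Sequence[TrainingInstance], seed: int = 0
):
    """Fit the spec on every instance; deterministic given (data, seed)."""
    X, y = instances_to_xy(instances)
    _check_two_classes(y)
    model = spec.build()
    model.fit(X, y, seed=seed)
    return model


def score_and_decide(
    model, candidates: Sequence[MergeCandidate], threshold: float = 0.5
) -> list[MergeCandidate]:
    """Score featurized candidates; merged iff score strictly > threshold.

    The score is a classifier output in [0, 1], not a calibrated
    probability.
    """
    if not candidates:
        return []
    for cand in candidates:
        if cand.features is None:
            raise ValidationError(
                f"candidate ({cand.prior1.operon_id}, {cand.prior2.operon_id}) "
                "is not featurized"
            )
    X = np.array([cand.features.as_array() for cand in candidates])
    scores = np.clip(model.predict_score(X), 0.0, 1.0)
    return [
        replace(cand, score=float(s), merged=bool(s > threshold))
        for cand, s in zip(candidates, scores)
    ]


def logistic_model_tree_fit(
    instances: Sequence[TrainingInstance],
    max_depth: int = 3,
    min_leaf: int = 10,
    seed: int = 0,
) -> LogisticModelTreeModel:
    """Convenience fit of the native logistic model tree."""
    X, y = instances_to_xy(instances)
    model = LogisticModelTreeModel(max_depth=max_depth, min_leaf=min_leaf)
    return model.fit(X, y, seed=seed)


# ---------------------------------------------------------------------------
# persistence

_MODEL_CLASSES = {
    "logistic_model_tree": LogisticModelTreeModel,
    "logistic_regression": LogisticRegressionModel,
    "decision_tree": DecisionTreeModel,
    "naive_bayes": GaussianNBModel,
    "knn": KNNModel,
}


def save_model(model, spec: ClassifierSpec, path: str | Path) -> None:
    """Persist a fitted model as a self-describing versioned JSON text file."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "classifier": spec.name,
        "hyperparameters": dict(spec.hyperparameters),
        "state": model.state_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_model(path: str | Path):
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValidationError(f"unsupported model format version {version!r}")
    name = payload["classifier"]
    if name not in _MODEL_CLASSES:
        raise ValidationError(f"unknown classifier {name!r} in model file")
    model = _MODEL_CLASSES[name](**payload["hyperparameters"])
    model.load_state(payload["state"])
    return model


def write_cv_report(
    reports: Sequence[CVReport], path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("classifier\tmean_accuracy\tbalanced_accuracy\tfold_accuracies\tseed\n")
        for rep in sorted(reports, key=lambda r: -r.mean_accuracy):
            folds = ",".join(f"{a:.6f}" for a in rep.fold_accuracies)
            fh.write(
                f"{rep.classifier}\t{rep.mean_accuracy:.6f}\t"
                f"{rep.balanced_accuracy:.6f}\t{folds}\t{rep.seed}\n"
            )
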