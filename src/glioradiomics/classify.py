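"""Leave-one-out classification of tumor subregions and its metrics.

Four learner families are supported: k-nearest neighbors, Gaussian naive
Bayes, random forest and a multilayer perceptron.  Every fold standardizes
features on its training rows only (no leakage into the held-out sample).
The multiclass problem is dissected into four one-vs-rest binary problems
to report per-class recall, precision, F1, accuracy and AUC:

    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F1        = 2 * precision * recall / (precision + recall)
    accuracy  = (TP + TN) / (TP + FP + TN + FN)

Overall (multiclass) accuracy is the confusion-matrix trace over the total,
which for leave-one-out equals the mean of the per-fold accuracies.
"""
from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as sk_confusion_matrix
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from ._types import REGION_NAMES

logger = logging.getLogger(__name__)

FAMILIES = ("knn", "naive_bayes", "random_forest", "mlp")

#: Default hyperparameter grids, in declared (tie-breaking) order.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "knn": {
        "n_neighbors": list(range(1, 31)),
        "metric": ["euclidean", "manhattan", "minkowski"],
    },
    "naive_bayes": {},
    "random_forest": {
        "max_features": list(range(100, 2001, 100)),
        "max_depth": [None] + list(range(10, 111, 10)),
    },
    "mlp": {
        "hidden_layer_sizes": [(128, 64), (256, 128), (64,), (128, 64, 32)],
    },
}

DEFAULT_PARAMS: dict[str, dict] = {
    "knn": {"n_neighbors": 5, "metric": "euclidean"},
    "naive_bayes": {},
    "random_forest": {"n_estimators": 500, "max_features": 8, "max_depth": None},
    "mlp": {"hidden_layer_sizes": (128, 64)},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """One learner family with its chosen parameters and search grid."""

    family: str
    params: Mapping = field(default_factory=dict)
    grid: Mapping[str, list] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; pick one of {FAMILIES}")

    def resolved_params(self) -> dict:
        return {**DEFAULT_PARAMS[self.family], **dict(self.params)}

    def resolved_grid(self) -> dict[str, list]:
        return dict(self.grid) if self.grid is not None else dict(DEFAULT_GRIDS[self.family])


def make_estimator(spec: ClassifierSpec, n_features: int) -> Pipeline:
    """Standardization + classifier pipeline for one spec."""
    params = spec.resolved_params()
    if spec.family == "knn":
        clf = KNeighborsClassifier(**params)
    elif spec.family == "naive_bayes":
        clf = GaussianNB(**params)
    elif spec.family == "random_forest":
        params = dict(params)
        if isinstance(params.get("max_features"), (int, np.integer)):
            # grids may quote more candidate features than the table has
            params["max_features"] = int(min(params["max_features"], n_features))
        clf = RandomForestClassifier(random_state=spec.seed, n_jobs=1, **params)
    elif spec.family == "mlp":
        clf = MLPClassifier(
            random_state=spec.seed, early_stopping=True, max_iter=300, **params
        )
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(spec.family)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-class one-vs-rest metrics plus the overall multiclass accuracy."""

    classes: list[str]
    recall: dict[str, float]
    precision: dict[str, float]
    f1: dict[str, float]
    accuracy: dict[str, float]
    overall_accuracy: float
    auc: dict[str, float | None] = field(default_factory=dict)
    zero_denominator_flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "classes": self.classes,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "overall_accuracy": self.overall_accuracy,
            "auc": self.auc,
            "zero_denominator_flags": self.zero_denominator_flags,
        }


def metrics_from_confusion(
    counts: np.ndarray, classes: Sequence[str]
) -> MetricsReport:
    """One-vs-rest dissection of a multiclass confusion matrix.

    ``counts[i, j]`` is the number of samples of true class i predicted as
    class j.  Metrics with a zero denominator are reported as 0 and flagged.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("confusion matrix must be square")
    if counts.shape[0] != len(classes):
        raise ValueError("class list does not match matrix size")
    if (counts < 0).any():
        raise ValueError("confusion counts must be nonnegative")
    total = int(counts.sum())
    recall, precision, f1, accuracy = {}, {}, {}, {}
    flags: list[str] = []

    def safe(num: float, den: float, what: str) -> float:
        if den == 0:
            flags.append(what)
            return 0.0
        return num / den

    for k, cls in enumerate(classes):
        tp = int(counts[k, k])
        fn = int(counts[k].sum()) - tp
        fp = int(counts[:, k].sum()) - tp
        tn = total - tp - fn - fp
        recall[cls] = safe(tp, tp + fn, f"recall/{cls}")
        precision[cls] = safe(tp, tp + fp, f"precision/{cls}")
        f1[cls] = safe(
            2 * precision[cls] * recall[cls], precision[cls] + recall[cls], f"f1/{cls}"
        )
        accuracy[cls] = safe(tp + tn, total, f"accuracy/{cls}")
    overall = safe(float(np.trace(counts)), total, "overall_accuracy")
    return MetricsReport(
        classes=list(classes), recall=recall, precision=precision, f1=f1,
        accuracy=accuracy, overall_accuracy=overall,
        zero_denominator_flags=flags,
    )


def roc_auc(
    probabilities: np.ndarray, labels: Sequence[str], classes: Sequence[str]
) -> dict[str, float | None]:
    """One-vs-rest AUC per class by the rank (Mann-Whitney) statistic.

    A class without both a positive and a negative sample has no defined
    AUC and is reported as None.
    """
    probabilities = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels)
    out: dict[str, float | None] = {}
    for k, cls in enumerate(classes):
        y = (labels == cls).astype(int)
        if y.min() == y.max():
            logger.warning("AUC undefined for class %s (degenerate labels)", cls)
            out[cls] = None
            continue
        out[cls] = float(roc_auc_score(y, probabilities[:, k]))
    return out


def roc_curves(
    probabilities: np.ndarray, labels: Sequence[str], classes: Sequence[str]
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-class one-vs-rest ROC coordinates (fpr, tpr, thresholds)."""
    labels = np.asarray(labels)
    curves = {}
    for k, cls in enumerate(classes):
        y = (labels == cls).astype(int)
        if y.min() == y.max():
            continue
        curves[cls] = roc_curve(y, probabilities[:, k])
    return curves


def majority_vote(
    votes: Sequence[str], probabilities: np.ndarray | None = None
) -> str:
    """Label with > 50% of the votes; ties fall back to mean class probability.

    ``probabilities`` rows must align with ``votes`` and columns with the
    sorted set of voted labels when the tie-break is needed.
    """
    votes = list(votes)
    if not votes:
        raise ValueError("majority vote over an empty prediction list")
    labels, counts = np.unique(votes, return_counts=True)
    top = counts.argmax()
    if counts[top] * 2 > len(votes):
        return str(labels[top])
    if probabilities is None:
        # deterministic fallback: first label among the most voted
        best = labels[counts == counts.max()]
        return str(best[0])
    mean_prob = np.asarray(probabilities, dtype=np.float64).mean(axis=0)
    return str(labels[int(np.argmax(mean_prob))])


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    """Held-out predictions and aggregate metrics of one LOOCV run."""

    spec: ClassifierSpec
    classes: list[str]
    true_labels: list[str]
    predicted_labels: list[str]
    probabilities: np.ndarray
    confusion: np.ndarray
    metrics: MetricsReport
    sample_ids: list[tuple[str, str]] = field(default_factory=list)

    def predictions_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"true_label": self.true_labels, "predicted_label": self.predicted_labels}
        )
        if self.sample_ids:
            df.insert(0, "subject_id", [s for s, _ in self.sample_ids])
            df.insert(1, "region_label", [r for _, r in self.sample_ids])
        for k, cls in enumerate(self.classes):
            df[f"prob_{cls}"] = self.probabilities[:, k]
        return df

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "family": self.spec.family,
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.spec.resolved_params().items()},
            "seed": self.spec.seed,
            "classes": self.classes,
            "confusion_matrix": self.confusion.tolist(),
            "metrics": self.metrics.as_dict(),
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _split_xy(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list]:
    meta = [c for c in ("subject_id", "region_label") if c in features.columns]
    if "region_label" not in features.columns:
        raise ValueError("feature table needs a region_label column")
    X = features.drop(columns=meta).to_numpy(dtype=np.float64)
    y = features["region_label"].to_numpy()
    ids = list(zip(features.get("subject_id", pd.Series([""] * len(features))), y))
    return X, y, ids


def fit_fold(
    features: pd.DataFrame, spec: ClassifierSpec, held_out: int
) -> Pipeline:
    """Fit the pipeline for one fold (training rows exclude ``held_out``)."""
    X, y, _ = _split_xy(features)
    train = np.ones(len(y), dtype=bool)
    train[held_out] = False
    model = make_estimator(spec, n_features=X.shape[1])
    model.fit(X[train], y[train])
    return model


def loocv(features: pd.DataFrame, spec: ClassifierSpec) -> CvResult:
    """Leave-one-out cross-validation over the rows of a feature table.

    Each row is one (subject, subregion) sample.  Standardization and model
    fitting happen inside each fold on the training rows only.
    """
    X, y, ids = _split_xy(features)
    n = len(y)
    if n < 2:
        raise ValueError("LOOCV needs at least 2 samples")
    classes = sorted(set(y), key=lambda c: REGION_NAMES.index(c)
                     if c in REGION_NAMES else len(REGION_NAMES))
    if len(classes) < 2:
        raise ValueError("LOOCV needs at least 2 classes")

    predicted: list[str] = []
    probs = np.zeros((n, len(classes)), dtype=np.float64)
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        fold_classes = set(y[train])
        if fold_classes != set(classes):
            logger.warning(
                "fold %d: training set lost class(es) %s; scoring with the rest",
                i, sorted(set(classes) - fold_classes),
            )
        model = make_estimator(spec, n_features=X.shape[1])
        model.fit(X[train], y[train])
        p = model.predict_proba(X[i: i + 1])[0]
        model_classes = list(model.classes_)
        for cls, pv in zip(model_classes, p):
            probs[i, classes.index(cls)] = pv
        predicted.append(str(model_classes[int(np.argmax(p))]))

    confusion = sk_confusion_matrix(y, predicted, labels=classes)
    metrics = metrics_from_confusion(confusion, classes)
    metrics.auc = roc_auc(probs, y, classes)
    return CvResult(
        spec=spec, classes=classes, true_labels=[str(v) for v in y],
        predicted_labels=predicted, probabilities=probs, confusion=confusion,
        metrics=metrics, sample_ids=ids,
    )


def grid_search(features: pd.DataFrame, spec: ClassifierSpec) -> ClassifierSpec:
    """Exhaustive LOOCV-accuracy search over the spec's grid.

    Ties are broken by the first grid point in declared order, so the result
    is deterministic.
    """
    grid = spec.resolved_grid()
    if not grid:
        return spec
    names = list(grid)
    best_spec, best_acc = None, -1.0
    for point in itertools.product(*(grid[n] for n in names)):
        params = {**dict(spec.params), **dict(zip(names, point))}
        candidate = replace(spec, params=params)
        acc = loocv(features, candidate).metrics.overall_accuracy
        logger.debug("grid point %s -> accuracy %.4f", params, acc)
        if acc > best_acc:
            best_spec, best_acc = candidate, acc
    logger.info("grid search chose %s (LOOCV accuracy %.4f)",
                best_spec.resolved_params(), best_acc)
    return best_spec
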