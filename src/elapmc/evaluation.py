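"""Confusion-matrix metrics, cross-validated benchmarking and summary stats.

Metrics follow the standard two-class definitions

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F1        = 2 / (recall^-1 + precision^-1) = 2 TP / (2 TP + FP + FN)

computed from the confusion matrix pooled over the out-of-fold predictions
of a stratified k-fold split (micro pooling — the published benchmark's F1
values are exactly harmonic means of the printed recall/precision, which is
what pooling yields). The baseline registry maps the 21 comparison
classifier configurations onto their closest scikit-learn equivalents.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold

from .exceptions import DomainError, ValidationError


@dataclasses.dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclasses.dataclass
class MetricsRecord:
    model_name: str
    accuracy: float
    recall: float
    precision: float
    f1: float
    confusion: ConfusionMatrix
    folds: int = 1


@dataclasses.dataclass
class BenchmarkTable:
    records: list[MetricsRecord]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [r.model_name for r in self.records],
                "accuracy": [r.accuracy for r in self.records],
                "recall": [r.recall for r in self.records],
                "precision": [r.precision for r in self.records],
                "f1": [r.f1 for r in self.records],
                "TP": [r.confusion.tp for r in self.records],
                "FN": [r.confusion.fn for r in self.records],
                "FP": [r.confusion.fp for r in self.records],
                "TN": [r.confusion.tn for r in self.records],
            }
        )


def confusion(y_true, y_pred, positive_class) -> ConfusionMatrix:
    """Two-class confusion counts with an explicit positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    t = y_true == positive_class
    p = y_pred == positive_class
    return ConfusionMatrix(
        tp=int(np.sum(t & p)),
        fn=int(np.sum(t & ~p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
    )


def metrics(cm: ConfusionMatrix) -> tuple[float, float, float, float]:
    """(accuracy, recall, precision, f1); undefined denominators yield NaN."""
    n = cm.n
    accuracy = (cm.tp + cm.tn) / n if n else math.nan
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else math.nan
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else math.nan
    denom = 2 * cm.tp + cm.fp + cm.fn
    f1 = 2 * cm.tp / denom if denom else math.nan
    return accuracy, recall, precision, f1


def f1_from_pr(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision."""
    if recall <= 0 and precision <= 0:
        return math.nan
    return 2.0 / (1.0 / recall + 1.0 / precision)


def cross_validate(
    X,
    y,
    model_spec,
    positive_class,
    k: int = 5,
    seed: int = 0,
    name: str | None = None,
) -> MetricsRecord:
    """Stratified k-fold CV; metrics from the pooled out-of-fold confusion.

    ``model_spec`` is any fit/predict estimator; it is cloned (or re-built
    via its factory callable) for every fold.
    """
    Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise DomainError("cross_validate handles exactly two classes")
    if counts.min() < k:
        raise DomainError(
            f"smallest class has {counts.min()} samples, fewer than k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    for train_idx, test_idx in skf.split(Xm, y):
        est = _fresh(model_spec)
        est.fit(Xm[train_idx], y[train_idx])
        y_pred[test_idx] = est.predict(Xm[test_idx])
    cm = confusion(y, y_pred, positive_class)
    acc, rec, prec, f1 = metrics(cm)
    return MetricsRecord(
        model_name=name or type(_fresh(model_spec)).__name__,
        accuracy=acc,
        recall=rec,
        precision=prec,
        f1=f1,
        confusion=cm,
        folds=k,
    )


def _fresh(model_spec):
    if callable(model_spec) and not hasattr(model_spec, "fit"):
        return model_spec()
    try:
        return clone(model_spec)
    except TypeError:
        import copy

        return copy.deepcopy(model_spec)


# ---------------------------------------------------------------------------
# baseline registry


class _KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-feature Gaussian kernel density class conditionals."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.priors_ = np.array([(y == c).mean() for c in self.classes_])
        self.kdes_ = []
        for c in self.classes_:
            Xc = X[y == c]
            feats = []
            for j in range(X.shape[1]):
                col = Xc[:, j]
                if np.ptp(col) < 1e-12:  # degenerate: fall back to tight normal
                    feats.append(("norm", col.mean(), max(col.std(), 1e-6)))
                else:
                    feats.append(("kde", stats.gaussian_kde(col), None))
            self.kdes_.append(feats)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        logp = np.zeros((X.shape[0], self.classes_.size))
        for ci, feats in enumerate(self.kdes_):
            logp[:, ci] = np.log(self.priors_[ci])
            for j, (kind, a, b) in enumerate(feats):
                if kind == "kde":
                    dens = np.maximum(a.evaluate(X[:, j]), 1e-300)
                else:
                    dens = np.maximum(stats.norm.pdf(X[:, j], a, b), 1e-300)
                logp[:, ci] += np.log(dens)
        return self.classes_[np.argmax(logp, axis=1)]


class _RUSBoost(BaseEstimator, ClassifierMixin):
    """Boosted shallow trees on a class-balanced random undersample.

    Approximates RUSBoost by undersampling the majority class to the
    minority size (seeded) before AdaBoost; adequate as a benchmark
    configuration stand-in.
    """

    def __init__(self, n_estimators=100, learning_rate=0.1, max_leaf_nodes=21, random_state=0):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_leaf_nodes = max_leaf_nodes
        self.random_state = random_state

    def fit(self, X, y):
        from sklearn.ensemble import AdaBoostClassifier
        from sklearn.tree import DecisionTreeClassifier

        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        classes, counts = np.unique(y, return_counts=True)
        n_min = counts.min()
        keep = np.concatenate(
            [
                rng.choice(np.flatnonzero(y == c), size=n_min, replace=False)
                for c in classes
            ]
        )
        self.est_ = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(
                max_leaf_nodes=self.max_leaf_nodes, random_state=0
            ),
            n_estimators=self.n_estimators,
            learning_rate=self.learning_rate,
            random_state=0,
        )
        self.est_.fit(X[keep], y[keep])
        return self

    def predict(self, X):
        return self.est_.predict(np.asarray(X, dtype=float))


def _squared_inverse(dist: np.ndarray) -> np.ndarray:
    return 1.0 / np.maximum(dist, 1e-12) ** 2


def baseline_zoo(name: str, n_features: int = 8, seed: int = 0):
    """Return a configured estimator for one of the 21 benchmark baselines.

    MATLAB-specific options are mapped to the nearest scikit-learn
    equivalents: "Kernel scale: Automatic" -> gamma="scale"; a Gaussian
    kernel scale s -> gamma = 1/s^2; "Maximum number of splits" m ->
    max_leaf_nodes = m + 1; subspace dimension 17 is clamped to the feature
    count. Unknown names raise with the list of valid names.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    sub_dim = min(17, n_features)
    registry: dict[str, Callable[[], object]] = {
        "Logistic regression": lambda: LogisticRegression(C=1e10, max_iter=5000),
        "Linear SVM": lambda: SVC(kernel="linear", C=1.0),
        "Ensemble bagged trees": lambda: BaggingClassifier(
            estimator=DecisionTreeClassifier(max_leaf_nodes=351, random_state=0),
            n_estimators=100,
            random_state=seed,
        ),
        "Ensemble subspace discriminant": lambda: BaggingClassifier(
            estimator=LinearDiscriminantAnalysis(),
            n_estimators=100,
            max_features=sub_dim,
            bootstrap=False,
            random_state=seed,
        ),
        "Linear discriminant": lambda: LinearDiscriminantAnalysis(),
        "Medium Gaussian SVM": lambda: SVC(kernel="rbf", C=1.0, gamma=1.0 / 5.8**2),
        "Quadratic SVM": lambda: SVC(kernel="poly", degree=2, coef0=1.0, gamma="scale", C=1.0),
        "Coarse Gaussian SVM": lambda: SVC(kernel="rbf", C=1.0, gamma=1.0 / 23.0**2),
        "Weighted KNN": lambda: KNeighborsClassifier(
            n_neighbors=10, weights=_squared_inverse
        ),
        "Gaussian naive Bayes": lambda: GaussianNB(),
        "Ensemble subspace KNN": lambda: BaggingClassifier(
            estimator=KNeighborsClassifier(n_neighbors=1),
            n_estimators=100,
            max_features=sub_dim,
            bootstrap=False,
            random_state=seed,
        ),
        "Medium KNN": lambda: KNeighborsClassifier(n_neighbors=10),
        "Cubic KNN": lambda: KNeighborsClassifier(n_neighbors=10, p=3),
        "Decision tree": lambda: DecisionTreeClassifier(
            max_leaf_nodes=5, criterion="gini", random_state=0
        ),
        "Kernel naive Bayes": lambda: _KernelNaiveBayes(),
        "Cubic SVM": lambda: SVC(kernel="poly", degree=3, coef0=1.0, gamma="scale", C=1.0),
        "Ensemble RUS boosted trees": lambda: _RUSBoost(random_state=seed),
        "Fine KNN": lambda: KNeighborsClassifier(n_neighbors=1),
        "Ensemble boosted trees": lambda: AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_leaf_nodes=21, random_state=0),
            n_estimators=100,
            learning_rate=0.1,
            random_state=seed,
        ),
        "Cosine KNN": lambda: KNeighborsClassifier(n_neighbors=10, metric="cosine"),
        "Fine Gaussian SVM": lambda: SVC(kernel="rbf", C=1.0, gamma=1.0 / 1.5**2),
    }
    if name not in registry:
        raise DomainError(
            f"unknown baseline {name!r}; valid names: {sorted(registry)}"
        )
    return registry[name]()


BASELINE_NAMES: tuple[str, ...] = (
    "Logistic regression",
    "Linear SVM",
    "Ensemble bagged trees",
    "Ensemble subspace discriminant",
    "Linear discriminant",
    "Medium Gaussian SVM",
    "Quadratic SVM",
    "Coarse Gaussian SVM",
    "Weighted KNN",
    "Gaussian naive Bayes",
    "Ensemble subspace KNN",
    "Medium KNN",
    "Cubic KNN",
    "Decision tree",
    "Kernel naive Bayes",
    "Cubic SVM",
    "Ensemble RUS boosted trees",
    "Fine KNN",
    "Ensemble boosted trees",
    "Cosine KNN",
    "Fine Gaussian SVM",
)


def run_benchmark(
    X,
    y,
    model_specs: dict[str, object] | Sequence[str],
    positive_class,
    k: int = 5,
    seed: int = 0,
) -> BenchmarkTable:
    """Cross-validate a set of models on one dataset.

    ``model_specs`` is either a mapping name -> estimator/factory or a
    sequence of baseline registry names.
    """
    if not isinstance(model_specs, dict):
        n_features = X.shape[1]
        model_specs = {
            n: baseline_zoo(n, n_features=n_features, seed=seed) for n in model_specs
        }
    if len(model_specs) < 2:
        raise DomainError("benchmark needs at least 2 models")
    records = [
        cross_validate(X, y, spec, positive_class, k=k, seed=seed, name=n)
        for n, spec in model_specs.items()
    ]
    return BenchmarkTable(records=records)


def rank_models(table: BenchmarkTable, metric: str = "accuracy") -> list[MetricsRecord]:
    """Records sorted by a metric, decreasing; ties broken by model name."""
    return sorted(table.records, key=lambda r: (-getattr(r, metric), r.model_name))


def summary_stats(table: BenchmarkTable, metric: str) -> tuple[float, float]:
    """Across-model sample mean and standard deviation of one metric."""
    vals = np.array([getattr(r, metric) for r in table.records], dtype=float)
    if vals.size < 3:
        raise DomainError("summary statistics need at least 3 models")
    return float(vals.mean()), float(vals.std(ddof=1))


def ks_normality(values: Sequence[float]) -> float:
    """One-sample KS p-value of standardized values against the standard normal.

    Values are standardized with their own sample mean/std before testing,
    so this is a Lilliefors-style screen (the p-value is conservative in the
    usual direction is *not* guaranteed; it is reported, not calibrated).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 3:
        raise DomainError("KS normality test needs at least 3 values")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise DomainError("constant values: KS normality test undefined")
    z = (vals - vals.mean()) / sd
    return float(stats.kstest(z, "norm").pvalue)
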