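"""Nine-classifier benchmark with stratified 10-fold cross-validation.

The model grid mirrors a classical heartbeat-classification comparison:
discriminant function analysis (linear and quadratic), naive Bayes
(Gaussian and per-feature kernel-density), support vector machines
(linear and RBF kernel, one-vs-all) and k-nearest neighbours
(k = 1, 5, 10).  Features are z-scored per fold with training-fold
statistics only; accuracy, per-class sensitivity/specificity and the
cross-validation-cumulated confusion matrix are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = [
    "ModelSpec",
    "BENCHMARK_MODELS",
    "KernelNaiveBayes",
    "build_estimator",
    "standardize_fold",
    "cross_validate",
    "run_benchmark",
    "confusion_matrix",
    "CvReport",
]

N_CLASSES = 4


@dataclass(frozen=True)
class ModelSpec:
    """One classifier configuration of the benchmark grid."""

    family: str   # DFA | NB | SVM | kNN
    variant: str
    hyperparameters: dict = field(default_factory=dict)

    @property
    def name(self) -> str:
        return f"{self.family}-{self.variant}"


#: the nine benchmark configurations of the comparison grid
BENCHMARK_MODELS: tuple[ModelSpec, ...] = (
    ModelSpec("kNN", "k1", {"k": 1}),
    ModelSpec("kNN", "k5", {"k": 5}),
    ModelSpec("kNN", "k10", {"k": 10}),
    ModelSpec("DFA", "linear"),
    ModelSpec("DFA", "quadratic"),
    ModelSpec("NB", "gaussian"),
    ModelSpec("NB", "kernel"),
    ModelSpec("SVM", "rbf", {"C": 1.0}),
    ModelSpec("SVM", "linear", {"C": 1.0}),
)


class KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with a per-feature, per-class Gaussian kernel density.

    Each univariate class-conditional density is a kernel estimate with
    Silverman's bandwidth; class log-likelihoods are the sums of feature
    log-densities plus the log prior.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self._train = {c: X[y == c] for c in self.classes_}
        self._bw = {}
        self._logprior = {}
        for c, Xc in self._train.items():
            n = len(Xc)
            sd = Xc.std(axis=0, ddof=1) if n > 1 else np.zeros(Xc.shape[1])
            iqr = np.subtract(*np.percentile(Xc, [75, 25], axis=0))
            spread = np.where(iqr > 0, np.minimum(sd, iqr / 1.34), sd)
            h = 0.9 * spread * n ** (-0.2)
            self._bw[c] = np.where(h > 0, h, 1e-3)
            self._logprior[c] = np.log(n / len(y))
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty((len(X), len(self.classes_)))
        for ci, c in enumerate(self.classes_):
            Xc, h = self._train[c], self._bw[c]
            ll = np.zeros(len(X))
            for j in range(X.shape[1]):
                z = (X[:, j, None] - Xc[None, :, j]) / h[j]
                dens = np.exp(-0.5 * z * z).mean(axis=1) / (h[j] * np.sqrt(2 * np.pi))
                ll += np.log(np.maximum(dens, 1e-300))
            out[:, ci] = ll + self._logprior[c]
        return out

    def predict(self, X):
        jll = self._joint_log_likelihood(X)
        return self.classes_[np.argmax(jll, axis=1)]


def build_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn estimator for one grid configuration."""
    hp = spec.hyperparameters
    if spec.family == "kNN":
        return KNeighborsClassifier(n_neighbors=hp.get("k", 5), metric="euclidean")
    if spec.family == "DFA":
        if spec.variant == "linear":
            return LinearDiscriminantAnalysis()
        # relative-area features are near-collinear; the per-class
        # covariances need a small ridge to stay invertible in every fold
        return QuadraticDiscriminantAnalysis(reg_param=1e-3)
    if spec.family == "NB":
        return GaussianNB() if spec.variant == "gaussian" else KernelNaiveBayes()
    if spec.family == "SVM":
        kernel = "rbf" if spec.variant == "rbf" else "linear"
        return OneVsRestClassifier(SVC(kernel=kernel, C=hp.get("C", 1.0), gamma="scale"))
    raise ValueError(f"unknown model family {spec.family!r}")


def standardize_fold(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray, dict]:
    """z-score both matrices with the training mean/SD.

    Zero-variance training features map to 0 in both matrices and are
    flagged in the returned stats.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.size == 0:
        raise ValueError("training matrix is empty")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    zero = sd == 0
    safe_sd = np.where(zero, 1.0, sd)
    tr = (train - mean) / safe_sd
    te = (test - mean) / safe_sd
    tr[:, zero] = 0.0
    te[:, zero] = 0.0
    return tr, te, {"mean": mean, "sd": sd, "zero_variance": zero}


@dataclass(frozen=True)
class CvReport:
    """Cross-validation outcome for one (feature set, model) pair."""

    fold_accuracies: np.ndarray
    mean_accuracy: float
    sensitivity: np.ndarray       # per class, TP / (TP + FN)
    specificity: np.ndarray       # per class, TN / (TN + FP)
    confusion: np.ndarray         # 4x4, rows = true class, cumulated over folds
    seed: int
    model: str = ""


def confusion_matrix(y_true, y_pred, n_classes: int = N_CLASSES) -> np.ndarray:
    """Counts with rows = real class, columns = classifier output."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences differ in length")
    for arr in (y_true, y_pred):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError("label outside the known classes")
    return _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))


def _se_sp(conf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    tp = np.diag(conf).astype(float)
    fn = conf.sum(axis=1) - tp
    fp = conf.sum(axis=0) - tp
    tn = conf.sum() - tp - fn - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        sp = np.where(tn + fp > 0, tn / (tn + fp), np.nan)
    return se, sp


def cross_validate(
    model: ModelSpec,
    matrix: np.ndarray,
    labels: np.ndarray,
    folds: int = 10,
    seed: int = 0,
) -> CvReport:
    """Stratified k-fold cross-validation with per-fold standardization."""
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_acc = []
    conf = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for train_idx, test_idx in skf.split(X, y):
        tr, te, _ = standardize_fold(X[train_idx], X[test_idx])
        est = build_estimator(model)
        est.fit(tr, y[train_idx])
        pred = est.predict(te)
        fold_acc.append(float(np.mean(pred == y[test_idx])))
        conf += confusion_matrix(y[test_idx], pred)
    se, sp = _se_sp(conf)
    return CvReport(
        fold_accuracies=np.array(fold_acc),
        mean_accuracy=float(np.mean(fold_acc)),
        sensitivity=se,
        specificity=sp,
        confusion=conf,
        seed=seed,
        model=model.name,
    )


def run_benchmark(
    feature_groups: dict[str, list[str]],
    models: tuple[ModelSpec, ...],
    matrix: pd.DataFrame,
    labels: np.ndarray,
    folds: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], CvReport]]:
    """Mean CV accuracy for every (feature group, model) cell.

    Returns the accuracy grid (groups as rows, models as columns) and the
    full per-cell reports.
    """
    missing = {g: [c for c in cols if c not in matrix.columns]
               for g, cols in feature_groups.items()}
    bad = {g: m for g, m in missing.items() if m}
    if bad:
        raise KeyError(f"feature groups reference unknown columns: {bad}")
    reports: dict[tuple[str, str], CvReport] = {}
    grid = pd.DataFrame(index=list(feature_groups), columns=[m.name for m in models],
                        dtype=float)
    for gname, cols in feature_groups.items():
        X = matrix[cols].to_numpy(dtype=float)
        for m in models:
            rep = cross_validate(m, X, labels, folds=folds, seed=seed)
            reports[(gname, m.name)] = rep
            grid.loc[gname, m.name] = rep.mean_accuracy
    return grid, reports
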