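"""Subject-level feature matrices over S and G1-vs-G2 classification.

Two classifiers are provided: an extreme learning machine (ELM) written
here — a single-hidden-layer network whose input weights are random and
fixed and whose output weights are the least-squares solution against
one-hot targets — and a sigmoid-kernel soft-margin SVM delegated to
scikit-learn. Evaluation is seeded stratified k-fold cross-validation
with a pooled confusion matrix, so every reported accuracy is
reproducible bit-for-bit from (data, classifier spec, folds, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import SubjectScan
from .select import DEFAULT_ELIGIBILITY_FLOOR, deviation_profile

FEATURE_MODES = ("peak_ratio", "peak_deviation", "mean_intensity")


@dataclass
class FeatureMatrix:
    """Subjects × |S| feature values with group labels.

    Default feature is ``peak_ratio`` — the selection statistic itself,
    max |deviation| over median |deviation| — so the features inherit
    the statistic's invariance to affine intensity changes. Ineligible
    voxels (median deviation at the floor) contribute 0.
    """

    X: np.ndarray
    y: np.ndarray
    subject_ids: list[str]
    feature_mode: str
    voxel_order: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.subject_ids), len(self.voxel_order)):
            raise ValueError("feature matrix shape does not match subjects × |S|")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")


@dataclass
class ElmModel:
    """Trained extreme learning machine (deterministic given seed)."""

    input_weights: np.ndarray  # |S| × H
    biases: np.ndarray  # H
    output_weights: np.ndarray  # H × classes
    classes: np.ndarray
    hidden_units: int
    seed: int


@dataclass
class ClassifierResult:
    """Pooled cross-validated classification outcome."""

    accuracy: float  # percent, pooled over folds
    per_fold_accuracies: list[float]
    confusion: np.ndarray  # 2×2, rows true / cols predicted, classes sorted
    classifier: str
    cv_folds: int
    seed: int
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy_percent": self.accuracy,
            "per_fold_accuracies": self.per_fold_accuracies,
            "confusion": self.confusion.tolist(),
            "classifier": self.classifier,
            "cv_folds": self.cv_folds,
            "seed": self.seed,
            "params": self.params,
        }


def build_feature_matrix(
    scans: list[SubjectScan],
    voxels: list[tuple[int, int, int]],
    feature_mode: str = "peak_ratio",
    eligibility_floor: float = DEFAULT_ELIGIBILITY_FLOOR,
) -> FeatureMatrix:
    """One row per subject, one column per voxel of S (sorted order).

    A subject's value at a voxel is averaged over their runs:
    ``peak_ratio`` = dev_max / median_dev (0 where median_dev is at the
    eligibility floor), ``peak_deviation`` = dev_max, ``mean_intensity``
    = temporal mean.
    """
    if not voxels:
        raise ValueError("voxel set S is empty")
    if feature_mode not in FEATURE_MODES:
        raise ValueError(f"feature_mode must be one of {FEATURE_MODES}")
    order = sorted(tuple(int(c) for c in v) for v in voxels)
    cols = tuple(np.array(order).T)

    by_subject: dict[str, list[SubjectScan]] = {}
    groups: dict[str, str] = {}
    for s in scans:
        by_subject.setdefault(s.subject_id, []).append(s)
        groups[s.subject_id] = s.group
    subject_ids = sorted(by_subject)

    X = np.zeros((len(subject_ids), len(order)))
    for r, sid in enumerate(subject_ids):
        per_run = []
        for scan in by_subject[sid]:
            p = deviation_profile(scan)
            if feature_mode == "peak_ratio":
                dev_max = p.dev_max[cols]
                med = p.median_dev[cols]
                vals = np.where(med > eligibility_floor, dev_max / np.maximum(med, eligibility_floor), 0.0)
            elif feature_mode == "peak_deviation":
                vals = p.dev_max[cols]
            else:
                vals = p.mu[cols]
            per_run.append(vals)
        X[r] = np.mean(per_run, axis=0)
    y = np.array([groups[sid] for sid in subject_ids])
    return FeatureMatrix(X=X, y=y, subject_ids=subject_ids, feature_mode=feature_mode, voxel_order=order)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def train_elm(
    X: np.ndarray,
    y: np.ndarray,
    hidden_units: int = 503,
    seed: int = 0,
    ridge: float = 1e-8,
) -> ElmModel:
    """Fit an ELM: random fixed hidden layer, least-squares output layer.

    Input weights and biases are drawn from a seeded standard normal;
    hidden activations are logistic; output weights solve the ridge-
    stabilized least-squares problem against one-hot class targets
    (ridge 1e-8 guards the normal equations without visibly biasing the
    fit). Retraining with the same seed reproduces the model exactly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2D with at least 2 rows")
    if hidden_units < 1:
        raise ValueError("hidden_units must be >= 1")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((X.shape[1], hidden_units))
    b = rng.standard_normal(hidden_units)
    H = _sigmoid(X @ W + b)
    T = (y[:, None] == classes[None, :]).astype(float)  # one-hot, classes sorted
    beta = np.linalg.solve(H.T @ H + ridge * np.eye(hidden_units), H.T @ T)
    return ElmModel(
        input_weights=W,
        biases=b,
        output_weights=beta,
        classes=classes,
        hidden_units=hidden_units,
        seed=seed,
    )


def predict_elm(model: ElmModel, X: np.ndarray) -> np.ndarray:
    """Class labels by argmax score; ties go to the first sorted class."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.input_weights.shape[0]:
        raise ValueError(
            f"feature count {X.shape[-1]} does not match model input size "
            f"{model.input_weights.shape[0]}"
        )
    scores = _sigmoid(X @ model.input_weights + model.biases) @ model.output_weights
    return model.classes[np.argmax(scores, axis=1)]


class ElmClassifier:
    """scikit-learn-style wrapper around train_elm/predict_elm."""

    def __init__(self, hidden_units: int = 503, seed: int = 0, ridge: float = 1e-8):
        self.hidden_units = hidden_units
        self.seed = seed
        self.ridge = ridge
        self.model_: ElmModel | None = None

    def fit(self, X, y):
        self.model_ = train_elm(X, y, self.hidden_units, self.seed, self.ridge)
        return self

    def predict(self, X):
        if self.model_ is None:
            raise RuntimeError("classifier is not fitted")
        return predict_elm(self.model_, X)


def train_svm_sigmoid(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.09,
    gamma: float | None = None,
    coef0: float = 0.0,
):
    """Soft-margin SVM with sigmoid kernel tanh(γ·x·x′ + c0).

    Delegates to scikit-learn's SVC. γ defaults to 1 / n_features and
    c0 to 0; C defaults to 1.09. Features are standardized (train-set
    mean/variance) before the kernel: tanh saturates on large raw dot
    products, so an unscaled sigmoid kernel degenerates to a constant
    kernel matrix on intensity-scale features.
    """
    if not C > 0:
        raise ValueError("C must be positive")
    clf = svm_sigmoid_classifier(C=C, gamma=gamma, coef0=coef0)
    return clf.fit(np.asarray(X, dtype=float), np.asarray(y))


def svm_sigmoid_classifier(C: float = 1.09, gamma: float | None = None, coef0: float = 0.0) -> Pipeline:
    """StandardScaler + sigmoid-kernel SVC as one fit/predict handle."""
    if not C > 0:
        raise ValueError("C must be positive")
    return make_pipeline(
        StandardScaler(),
        SVC(kernel="sigmoid", C=C, gamma=gamma if gamma is not None else "auto", coef0=coef0),
    )


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    classifier,
    folds: int = 10,
    seed: int = 0,
    name: str | None = None,
    params: dict | None = None,
) -> ClassifierResult:
    """Stratified k-fold CV with seeded shuffling and pooled confusion.

    ``classifier`` is either an estimator with fit/predict (cloned
    implicitly by refitting each fold) or a zero-argument factory
    returning one. Accuracy is 100 × trace(confusion) / sum(confusion)
    pooled over folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation needs both classes present")
    if counts.min() < folds:
        raise ValueError(
            f"each class needs at least {folds} members for {folds}-fold "
            f"stratified CV; smallest class has {counts.min()}"
        )
    factory = classifier if callable(classifier) and not hasattr(classifier, "fit") else None

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_true_all: list[np.ndarray] = []
    y_pred_all: list[np.ndarray] = []
    per_fold = []
    for train_idx, test_idx in skf.split(X, y):
        clf = factory() if factory is not None else classifier
        clf.fit(X[train_idx], y[train_idx])
        pred = np.asarray(clf.predict(X[test_idx]))
        y_true_all.append(y[test_idx])
        y_pred_all.append(pred)
        per_fold.append(100.0 * float(np.mean(pred == y[test_idx])))
    conf = confusion_matrix(np.concatenate(y_true_all), np.concatenate(y_pred_all), labels=classes)
    accuracy = 100.0 * float(np.trace(conf)) / float(conf.sum())
    return ClassifierResult(
        accuracy=accuracy,
        per_fold_accuracies=per_fold,
        confusion=conf,
        classifier=name or type(classifier).__name__,
        cv_folds=folds,
        seed=seed,
        params=params or {},
    )


def permuted_label_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    classifier_factory,
    n_permutations: int = 200,
    folds: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """CV accuracies under label permutation (an empirical chance null)."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    accs = np.empty(n_permutations)
    for i in range(n_permutations):
        y_perm = rng.permutation(y)
        res = cross_validate(X, y_perm, classifier_factory, folds=folds, seed=seed)
        accs[i] = res.accuracy
    return accs
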