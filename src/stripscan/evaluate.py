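"""Classifier battery, stratified splitting and pooled evaluation metrics.

Eight classical classifiers (SVM, wide/medium MLPs, LDA, bagged and boosted
trees, k-NN, Gaussian naive Bayes) are trained on a stratified 70/15/15
train/validation/test split and scored on the held-out test set with
micro-averaged (pooled one-vs-rest) sensitivity, specificity and overall
accuracy, in percent.

With K classes, pooling the per-class one-vs-rest counts ties the metrics
together algebraically: micro sensitivity equals accuracy (both are
trace/total), and pooled specificity equals ``1 - (1 - accuracy)/(K - 1)``
— every misclassified sample contributes one false positive against K-1
true-negative opportunities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "CLASSIFIER_NAMES",
    "SplitSpec",
    "EvalReport",
    "stratified_split",
    "make_classifier",
    "train_classifier",
    "evaluate",
    "run_battery",
]

CLASSIFIER_NAMES = (
    "svm",
    "wide_nn",
    "medium_nn",
    "lda",
    "ensemble_bagged",
    "knn",
    "ensemble_boosted",
    "naive_bayes",
)


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/validation/test fractions plus the split seed."""

    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {self.fractions}")
        if any(f <= 0 for f in self.fractions):
            raise ValueError("all fractions must be positive")


@dataclass
class EvalReport:
    """Per-classifier test-set evaluation with pooled one-vs-rest metrics."""

    classifier: str
    feature_set: str
    accuracy: float
    sensitivity: float
    specificity: float
    confusion: np.ndarray
    labels: np.ndarray
    per_class: pd.DataFrame = field(repr=False, default=None)


def stratified_split(labels, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index arrays (train, val, test), stratified per class, seeded.

    Per-class counts follow the fractions to within rounding (train and val
    rounded, test takes the remainder), so 3200 balanced samples split
    2240/480/480.  Partitions are disjoint and exhaustive.
    """
    y = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    f_tr, f_va, _ = spec.fractions
    tr, va, te = [], [], []
    for c in np.unique(y):
        members = rng.permutation(np.flatnonzero(y == c))
        n = len(members)
        n_tr = int(round(f_tr * n))
        n_va = int(round(f_va * n))
        if n_tr < 1 or n_va < 1 or n - n_tr - n_va < 1:
            raise ValueError(
                f"class {c!r} has only {n} samples; cannot fill all three partitions"
            )
        tr.extend(members[:n_tr])
        va.extend(members[n_tr : n_tr + n_va])
        te.extend(members[n_tr + n_va :])
    return (np.sort(np.array(tr)), np.sort(np.array(va)), np.sort(np.array(te)))


def make_classifier(name: str, seed: int = 0) -> Pipeline:
    """One of the eight battery members, wrapped with train-fit standardisation.

    Hyperparameters are fixed defaults (documented in the package docs):
    RBF one-vs-one SVM with the scale-gamma heuristic; 1x100 and 1x25 MLPs;
    LDA with pooled covariance; bagging of 30 trees; k-NN with k=10
    (Euclidean); AdaBoost of 30 depth-3 trees; Gaussian naive Bayes.
    """
    if name == "svm":
        clf = SVC(kernel="rbf", gamma="scale", C=1.0,
                  decision_function_shape="ovo", random_state=seed)
    elif name == "wide_nn":
        clf = MLPClassifier(hidden_layer_sizes=(100,), max_iter=1000, random_state=seed)
    elif name == "medium_nn":
        clf = MLPClassifier(hidden_layer_sizes=(25,), max_iter=1000, random_state=seed)
    elif name == "lda":
        clf = LinearDiscriminantAnalysis()
    elif name == "ensemble_bagged":
        clf = BaggingClassifier(DecisionTreeClassifier(random_state=seed),
                                n_estimators=30, random_state=seed)
    elif name == "knn":
        clf = KNeighborsClassifier(n_neighbors=10)
    elif name == "ensemble_boosted":
        clf = AdaBoostClassifier(DecisionTreeClassifier(max_depth=3, random_state=seed),
                                 n_estimators=30, random_state=seed)
    elif name == "naive_bayes":
        clf = GaussianNB()
    else:
        raise ValueError(f"unknown classifier {name!r}; valid names: {CLASSIFIER_NAMES}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def train_classifier(name: str, X_train, y_train, seed: int = 0) -> Pipeline:
    """Fit one battery member on the training split."""
    model = make_classifier(name, seed=seed)
    model.fit(np.asarray(X_train, dtype=np.float64), np.asarray(y_train))
    return model


def pooled_metrics(confusion: np.ndarray) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in percent from a KxK matrix.

    Per-class one-vs-rest TP/FP/FN/TN counts are pooled over classes before
    forming each ratio (micro averaging).
    """
    cm = np.asarray(confusion, dtype=np.float64)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.trace(cm)
    fp = cm.sum(axis=0) - np.diag(cm)   # per predicted class
    fn = cm.sum(axis=1) - np.diag(cm)   # per true class
    tn = total - (np.diag(cm) + fp + fn)
    sens = tp / (tp + fn.sum()) * 100.0
    spec = tn.sum() / (tn.sum() + fp.sum()) * 100.0
    acc = tp / total * 100.0
    return float(acc), float(sens), float(spec)


def evaluate(model, X_test, y_test, classifier: str = "", feature_set: str = "") -> EvalReport:
    """Score a fitted model on the test split."""
    y_test = np.asarray(y_test)
    if len(y_test) == 0:
        raise ValueError("test set is empty")
    labels = model.classes_ if hasattr(model, "classes_") else model[-1].classes_
    unknown = set(np.unique(y_test)) - set(labels)
    if unknown:
        raise ValueError(f"test labels outside training schema: {sorted(unknown)}")
    pred = model.predict(np.asarray(X_test, dtype=np.float64))
    cm = _sk_confusion(y_test, pred, labels=labels)
    acc, sens, spec = pooled_metrics(cm)
    diag = np.diag(cm)
    fp = cm.sum(axis=0) - diag
    fn = cm.sum(axis=1) - diag
    tn = cm.sum() - (diag + fp + fn)
    per_class = pd.DataFrame(
        {"label": labels, "tp": diag, "fp": fp, "fn": fn, "tn": tn}
    )
    return EvalReport(
        classifier=classifier, feature_set=feature_set,
        accuracy=round(acc, 2), sensitivity=round(sens, 2),
        specificity=round(spec, 2), confusion=cm, labels=np.asarray(labels),
        per_class=per_class,
    )


def run_battery(
    feature_sets: dict[str, np.ndarray],
    labels,
    spec: SplitSpec,
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES,
    seed: int = 0,
) -> tuple[list[EvalReport], pd.DataFrame]:
    """Train/evaluate every classifier on every feature set with one shared split.

    ``feature_sets`` maps a set name (e.g. ``All``, ``MRMR``, ``CNN``) to an
    aligned (n_samples, n_features) matrix.  All sets are split by the same
    sample indices so the 24 reports are comparable on the identical test
    samples.  Returns the reports plus a summary table with one row per
    (classifier, feature_set).
    """
    y = np.asarray(labels)
    sizes = {name: np.asarray(X).shape[0] for name, X in feature_sets.items()}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"feature sets are misaligned on sample count: {sizes}")
    tr, _va, te = stratified_split(y, spec)

    reports: list[EvalReport] = []
    rows = []
    for set_name, X in feature_sets.items():
        X = np.asarray(X, dtype=np.float64)
        for clf_name in classifiers:
            model = train_classifier(clf_name, X[tr], y[tr], seed=seed)
            rep = evaluate(model, X[te], y[te], classifier=clf_name, feature_set=set_name)
            reports.append(rep)
            rows.append((clf_name, set_name, rep.accuracy, rep.sensitivity, rep.specificity))
    summary = pd.DataFrame(
        rows, columns=["classifier", "feature_set", "accuracy", "sensitivity", "specificity"]
    )
    return reports, summary
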