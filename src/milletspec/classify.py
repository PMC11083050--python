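"""Cultivar classifiers and repeated-holdout evaluation.

Five models are benchmarked, each with fixed hyperparameters rather than a
tuning search: linear discriminant analysis (LDA); an RBF support vector
machine with sigma = 1 and C = 1 (gamma = 1/(2 sigma^2) = 0.5); k-nearest
neighbours with 5 neighbours and Euclidean distance; a Gini random forest;
and gradient tree boosting with learning rate 0.1, 1000 estimators and
maximum depth 10.  Evaluation is five repetitions of a stratified 80/20
train/test split; the headline figure is the mean test accuracy over the
repeats, and per-class precision/recall/F1 are computed on the test
predictions pooled across repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = [
    "ClassifierSpec",
    "EvalReport",
    "build_classifier",
    "evaluate_repeated_split",
    "per_class_metrics",
    "pca_feature_extractor",
    "default_specs",
]

_DEFAULT_HYPERPARAMETERS = {
    "LDA": {},
    "SVM": {"kernel": "rbf", "sigma": 1.0, "C": 1.0},
    "kNN": {"n_neighbors": 5, "metric": "euclidean"},
    "RF": {"criterion": "gini", "n_estimators": 500},
    "GTB": {"learning_rate": 0.1, "n_estimators": 1000, "max_depth": 10},
}


@dataclass
class ClassifierSpec:
    """Named classifier plus its hyperparameter map."""

    name: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _DEFAULT_HYPERPARAMETERS:
            raise ValueError(
                f"unknown classifier '{self.name}' "
                f"(expected one of {sorted(_DEFAULT_HYPERPARAMETERS)})"
            )
        merged = dict(_DEFAULT_HYPERPARAMETERS[self.name])
        unknown = set(self.hyperparameters) - set(merged)
        if unknown and self.name != "LDA":
            raise ValueError(f"{self.name}: unknown hyperparameter(s) {sorted(unknown)}")
        merged.update(self.hyperparameters)
        self.hyperparameters = merged

    @classmethod
    def default(cls, name: str) -> "ClassifierSpec":
        return cls(name=name)


def default_specs() -> list[ClassifierSpec]:
    """The five benchmark classifiers with their standard hyperparameters."""
    return [ClassifierSpec.default(n) for n in ("LDA", "SVM", "kNN", "RF", "GTB")]


def build_classifier(spec: ClassifierSpec, rng_seed: int | None = None):
    """Instantiate an untrained scikit-learn model honouring the spec.

    Stochastic models (RF, GTB) are seeded with ``rng_seed``.  The SVM's
    sigma follows the Gaussian-kernel convention gamma = 1/(2 sigma^2).
    """
    hp = spec.hyperparameters
    if spec.name == "LDA":
        return LinearDiscriminantAnalysis()
    if spec.name == "SVM":
        sigma = float(hp["sigma"])
        if sigma <= 0:
            raise ValueError("SVM: sigma must be positive")
        return SVC(kernel=hp["kernel"], C=float(hp["C"]), gamma=1.0 / (2.0 * sigma**2),
                   decision_function_shape="ovo")
    if spec.name == "kNN":
        k = int(hp["n_neighbors"])
        if k < 1:
            raise ValueError("kNN: n_neighbors must be >= 1")
        return KNeighborsClassifier(n_neighbors=k, metric=hp["metric"])
    if spec.name == "RF":
        n = int(hp["n_estimators"])
        if n < 1:
            raise ValueError("RF: n_estimators must be >= 1")
        return RandomForestClassifier(
            criterion=hp["criterion"], n_estimators=n, random_state=rng_seed, n_jobs=1
        )
    if spec.name == "GTB":
        if float(hp["learning_rate"]) <= 0:
            raise ValueError("GTB: learning_rate must be positive")
        return GradientBoostingClassifier(
            learning_rate=float(hp["learning_rate"]),
            n_estimators=int(hp["n_estimators"]),
            max_depth=int(hp["max_depth"]),
            random_state=rng_seed,
        )
    raise ValueError(f"unknown classifier '{spec.name}'")  # pragma: no cover


@dataclass
class EvalReport:
    """Repeated-holdout evaluation of one classifier.

    Accuracies are percentages; mean +/- sd (sample sd) over the repeats.
    The confusion matrix pools test predictions across repeats, so its row
    sums are the per-class test counts summed over repeats.
    """

    classifier: str
    train_accuracies: np.ndarray
    test_accuracies: np.ndarray
    class_labels: list
    confusion: np.ndarray
    per_class: pd.DataFrame

    @property
    def train_mean(self) -> float:
        return float(np.mean(self.train_accuracies))

    @property
    def train_sd(self) -> float:
        return float(np.std(self.train_accuracies, ddof=1))

    @property
    def test_mean(self) -> float:
        return float(np.mean(self.test_accuracies))

    @property
    def test_sd(self) -> float:
        return float(np.std(self.test_accuracies, ddof=1))

    def summary_row(self) -> dict:
        return {
            "classifier": self.classifier,
            "train_mean": round(self.train_mean, 2),
            "train_sd": round(self.train_sd, 2),
            "test_mean": round(self.test_mean, 2),
            "test_sd": round(self.test_sd, 2),
        }


def per_class_metrics(confusion: np.ndarray, class_labels=None) -> pd.DataFrame:
    """Precision, recall and F1 per class from a pooled confusion matrix.

    Classes never predicted get precision 0 with ``precision_defined=False``;
    classes absent from the test rows get recall 0 with
    ``recall_defined=False``.  F1 is 0 when precision + recall is 0.
    """
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square, got shape {cm.shape}")
    if np.any(cm < 0) or not np.issubdtype(cm.dtype, np.number):
        raise ValueError("confusion matrix must be non-negative")
    n = cm.shape[0]
    labels = list(class_labels) if class_labels is not None else list(range(n))
    tp = np.diag(cm).astype(float)
    pred_pos = cm.sum(axis=0).astype(float)
    actual_pos = cm.sum(axis=1).astype(float)

    precision = np.divide(tp, pred_pos, out=np.zeros(n), where=pred_pos > 0)
    recall = np.divide(tp, actual_pos, out=np.zeros(n), where=actual_pos > 0)
    pr = precision + recall
    f1 = np.divide(2 * precision * recall, pr, out=np.zeros(n), where=pr > 0)

    return pd.DataFrame(
        {
            "class": labels,
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": actual_pos.astype(int),
            "precision_defined": pred_pos > 0,
            "recall_defined": actual_pos > 0,
        }
    )


def pca_feature_extractor(k: int = 2):
    """Per-repeat feature factory: fit PCA on the training rows only."""
    from .chemometrics import fit_pca, transform_pca

    class _Extractor:
        def __init__(self, x_train: np.ndarray) -> None:
            self.model = fit_pca(x_train, k=k)

        def transform(self, x: np.ndarray) -> np.ndarray:
            return transform_pca(self.model, x)

    return _Extractor


def evaluate_repeated_split(
    features: np.ndarray,
    labels,
    specs: list[ClassifierSpec],
    test_fraction: float = 0.2,
    repeats: int = 5,
    base_seed: int = 0,
    feature_extractor=None,
) -> dict[str, EvalReport]:
    """Evaluate each spec over ``repeats`` stratified holdout splits.

    Each repeat draws a fresh stratified ``test_fraction`` split, optionally
    fits ``feature_extractor`` (e.g. PCA) on the training rows only, trains
    each classifier and scores both partitions.  Splits and model seeds
    derive from ``base_seed``, so identical seeds give identical reports.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    short = counts < max(repeats, 2)
    if np.any(short):
        bad = classes[short][0]
        raise ValueError(
            f"class '{bad}' has only {int(counts[short][0])} members; "
            f"need at least {max(repeats, 2)} for {repeats}-repeat stratified splitting"
        )
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")

    ss = np.random.SeedSequence(base_seed)
    state = [int(s) % (2**31) for s in ss.generate_state(repeats + repeats * len(specs))]
    split_seeds, fit_seeds = state[:repeats], state[repeats:]

    class_list = list(classes)
    results: dict[str, EvalReport] = {}
    per_spec_true: dict[str, list] = {s.name: [] for s in specs}
    per_spec_pred: dict[str, list] = {s.name: [] for s in specs}
    train_acc = {s.name: [] for s in specs}
    test_acc = {s.name: [] for s in specs}

    seed_i = 0
    for rep in range(repeats):
        x_tr, x_te, y_tr, y_te = train_test_split(
            x, y, test_size=test_fraction, random_state=split_seeds[rep], stratify=y
        )
        if feature_extractor is not None:
            fx = feature_extractor(x_tr)
            x_tr, x_te = fx.transform(x_tr), fx.transform(x_te)
        for spec in specs:
            model = build_classifier(spec, rng_seed=fit_seeds[seed_i])
            seed_i += 1
            model.fit(x_tr, y_tr)
            train_acc[spec.name].append(100.0 * float(np.mean(model.predict(x_tr) == y_tr)))
            pred = model.predict(x_te)
            test_acc[spec.name].append(100.0 * float(np.mean(pred == y_te)))
            per_spec_true[spec.name].append(y_te)
            per_spec_pred[spec.name].append(pred)

    index = {c: i for i, c in enumerate(class_list)}
    for spec in specs:
        yt = np.concatenate(per_spec_true[spec.name])
        yp = np.concatenate(per_spec_pred[spec.name])
        cm = np.zeros((len(class_list), len(class_list)), dtype=int)
        for t, p in zip(yt, yp):
            cm[index[t], index[p]] += 1
        results[spec.name] = EvalReport(
            classifier=spec.name,
            train_accuracies=np.array(train_acc[spec.name]),
            test_accuracies=np.array(test_acc[spec.name]),
            class_labels=class_list,
            confusion=cm,
            per_class=per_class_metrics(cm, class_list),
        )
    return results
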