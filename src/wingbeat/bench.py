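"""Five-algorithm classification bench over the six wingbeat features.

Algorithms: logistic regression (LR), gradient boosting (GB), random
forests (RF), support vector machines (SVM) and a fully connected deep
neural network (DNN). Each is trained per feature with fourfold
cross-validated grid selection, refit on the full training set, and
scored on the held-out test set by plain accuracy (correct / total).
LR, SVM and DNN see standardized features (training-fold statistics
only); the tree ensembles run on raw features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from wingbeat.dataset import LabeledCorpus, Split, balance_by_strata, filter_valid, make_folds, train_test_split
from wingbeat.dsp import FEATURE_NAMES, extract_features

ALGORITHM_NAMES = ("LR", "GB", "RF", "SVM", "DNN")
_STANDARDIZED = {"LR", "SVM", "DNN"}

VERDICTS = (
    "overfit_more_samples",
    "underfit_more_capacity",
    "no_overfitting",
    "no_error",
)


@dataclass(frozen=True)
class AlgorithmSpec:
    """One algorithm family and its hyperparameter grid.

    ``grid`` maps parameter names to candidate value lists; the cross
    product is searched in :func:`train_with_cv`. Grid order is the
    tie-break: earlier configurations are considered simpler.
    """

    name: str
    grid: Mapping[str, Sequence] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in ALGORITHM_NAMES:
            raise ValueError(f"unknown algorithm {self.name!r}")

    def configurations(self) -> list[dict]:
        if not self.grid:
            return [{}]
        return list(ParameterGrid(dict(self.grid)))


def default_algorithms(seed: int = 0) -> list[AlgorithmSpec]:
    """The five bench algorithms with single-configuration default grids."""
    return [AlgorithmSpec(name=n, seed=seed) for n in ALGORITHM_NAMES]


def build_estimator(name: str, params: Mapping | None = None, seed: int = 0) -> Pipeline:
    """Construct the (optionally standardized) sklearn pipeline for one config."""
    params = dict(params or {})
    if name == "LR":
        est = LogisticRegression(C=params.pop("C", 1.0), max_iter=2000, random_state=seed)
    elif name == "GB":
        est = XGBClassifier(
            n_estimators=params.pop("n_estimators", 60),
            max_depth=params.pop("max_depth", 3),
            learning_rate=params.pop("learning_rate", 0.2),
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            verbosity=0,
        )
    elif name == "RF":
        est = RandomForestClassifier(
            n_estimators=params.pop("n_estimators", 100),
            max_depth=params.pop("max_depth", None),
            n_jobs=1,
            random_state=seed,
        )
    elif name == "SVM":
        est = SVC(
            kernel=params.pop("kernel", "rbf"),
            C=params.pop("C", 10.0),
            gamma=params.pop("gamma", "scale"),
            random_state=seed,
        )
    elif name == "DNN":
        est = MLPClassifier(
            hidden_layer_sizes=params.pop("hidden_layer_sizes", (64, 32)),
            activation="relu",
            early_stopping=True,
            n_iter_no_change=20,
            validation_fraction=0.15,
            learning_rate_init=0.01,
            max_iter=500,
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown algorithm {name!r}")
    if params:
        est.set_params(**params)
    steps = [("scale", StandardScaler())] if name in _STANDARDIZED else []
    steps.append(("model", est))
    return Pipeline(steps)


@dataclass
class FittedModel:
    """A fitted pipeline plus the label vocabulary and feature it consumes."""

    pipeline: Pipeline
    classes: np.ndarray
    algorithm: str
    params: dict
    feature_name: str | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[self.pipeline.predict(np.asarray(X, dtype=float))]


@dataclass
class CVResult:
    """Grid-search record: per-configuration fold accuracies and the winner."""

    configurations: list[dict]
    fold_accuracies: np.ndarray  # n_configs x k
    mean_accuracies: np.ndarray  # n_configs
    best_index: int
    training_accuracy: float  # refit model on the full training set
    validation_accuracy: float  # best mean CV accuracy

    @property
    def best_configuration(self) -> dict:
        return self.configurations[self.best_index]


def _encode(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes, y = np.unique(np.asarray(labels), return_inverse=True)
    return classes, y


def evaluate_accuracy(model: FittedModel, test_features: np.ndarray,
                      test_labels: np.ndarray) -> float:
    """Accuracy = correct predictions / total predictions."""
    test_labels = np.asarray(test_labels)
    if len(test_labels) == 0:
        raise ValueError("test set must be non-empty")
    pred = model.predict(test_features)
    return float(np.mean(pred == test_labels))


def train_with_cv(
    train_features: np.ndarray,
    labels: np.ndarray,
    spec: AlgorithmSpec,
    folds: np.ndarray,
) -> tuple[FittedModel, CVResult]:
    """Fourfold cross-validated grid selection, then refit on all training data.

    ``folds`` holds fold ids (1..k) per training row. Every configuration is
    trained on k-1 folds and validated on the held-out fold, k times; the
    configuration with the best mean validation accuracy wins (ties go to
    the earlier, simpler configuration) and is refit on the full training
    set. Standardization statistics are always fitted on the training rows
    of the round at hand, never on validation or test data.
    """
    X = np.asarray(train_features, dtype=float)
    y_labels = np.asarray(labels)
    folds = np.asarray(folds)
    classes, y = _encode(y_labels)
    if len(classes) < 2:
        raise ValueError("training data must contain at least two classes")
    fold_ids = np.unique(folds)
    configs = spec.configurations()
    fold_acc = np.zeros((len(configs), len(fold_ids)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for ci, params in enumerate(configs):
            for fi, fold in enumerate(fold_ids):
                val = folds == fold
                pipe = build_estimator(spec.name, params, seed=spec.seed)
                pipe.fit(X[~val], y[~val])
                fold_acc[ci, fi] = np.mean(pipe.predict(X[val]) == y[val])
        means = fold_acc.mean(axis=1)
        best = int(np.argmax(means))  # first max -> simpler configuration
        pipe = build_estimator(spec.name, configs[best], seed=spec.seed)
        pipe.fit(X, y)
    train_acc = float(np.mean(pipe.predict(X) == y))
    model = FittedModel(pipeline=pipe, classes=classes, algorithm=spec.name,
                        params=dict(configs[best]))
    result = CVResult(
        configurations=[dict(c) for c in configs],
        fold_accuracies=fold_acc,
        mean_accuracies=means,
        best_index=best,
        training_accuracy=train_acc,
        validation_accuracy=float(means[best]),
    )
    return model, result


@dataclass(frozen=True)
class ErrorThresholds:
    """Decision thresholds for the train-vs-validation error analysis."""

    overfit_gap: float = 0.03  # training - validation gap that flags overfitting
    underfit_training: float = 0.90  # training accuracy below this flags underfitting
    perfect_slack: float = 1e-6  # both accuracies within this of 1.0 -> no error


def error_analysis(
    training_accuracy: float,
    validation_accuracy: float,
    thresholds: ErrorThresholds | None = None,
) -> str:
    """Classify the training/validation accuracy pair into a remedy verdict.

    Both perfect -> ``no_error``. Training considerably above validation ->
    ``overfit_more_samples`` (more training data would help). Training
    itself low -> ``underfit_more_capacity``. Otherwise ->
    ``no_overfitting`` (improvement must come from features or algorithm).
    """
    th = thresholds or ErrorThresholds()
    for acc in (training_accuracy, validation_accuracy):
        if not (0.0 <= acc <= 1.0):
            raise ValueError("accuracies must lie in [0, 1]")
    if (training_accuracy >= 1.0 - th.perfect_slack
            and validation_accuracy >= 1.0 - th.perfect_slack):
        return "no_error"
    if training_accuracy - validation_accuracy > th.overfit_gap:
        return "overfit_more_samples"
    if training_accuracy < th.underfit_training:
        return "underfit_more_capacity"
    return "no_overfitting"


@dataclass
class BenchmarkReport:
    """Accuracy grid (feature x algorithm) and error-analysis verdict for one task."""

    task: str
    grid: pd.DataFrame  # rows = features, columns = algorithms, test accuracy
    best_per_feature: dict[str, list[str]]  # feature -> algorithms attaining its max
    best_cells: list[tuple[str, str]]  # (feature, algorithm) attaining the grid max
    best_accuracy: float
    verdict: str
    training_accuracy: float
    validation_accuracy: float
    n_train: int
    n_test: int
    seed: int
    models: dict[tuple[str, str], FittedModel] = field(default_factory=dict, repr=False)
    cv_results: dict[tuple[str, str], CVResult] = field(default_factory=dict, repr=False)

    def to_text(self) -> str:
        """Plain-text accuracy table in the study's report layout (percent)."""
        lines = [f"Task: {self.task}  (train n={self.n_train}, test n={self.n_test})"]
        header = "Feature".ljust(26) + "".join(a.rjust(8) for a in self.grid.columns)
        lines.append(header)
        for feat in self.grid.index:
            row = feat.ljust(26)
            for alg in self.grid.columns:
                cell = f"{100 * self.grid.loc[feat, alg]:.1f}"
                if alg in self.best_per_feature[feat]:
                    cell += "*"
                row += cell.rjust(8)
            lines.append(row)
        lines.append(
            f"Best: {self.best_accuracy * 100:.1f}% "
            f"({', '.join(f'{f}/{a}' for f, a in self.best_cells)})"
        )
        lines.append(
            f"Error analysis: training {self.training_accuracy * 100:.1f}%, "
            f"validation {self.validation_accuracy * 100:.1f}% -> {self.verdict}"
        )
        return "\n".join(lines)

    def summary(self) -> dict:
        return {
            "task": self.task,
            "best_accuracy": self.best_accuracy,
            "best_cells": [list(c) for c in self.best_cells],
            "training_accuracy": self.training_accuracy,
            "validation_accuracy": self.validation_accuracy,
            "verdict": self.verdict,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "seed": self.seed,
        }


def feature_matrix(corpus: LabeledCorpus) -> dict[str, np.ndarray]:
    """Extract all six feature vectors for every recording, stacked per feature."""
    columns: dict[str, list[np.ndarray]] = {name: [] for name in FEATURE_NAMES}
    for rec in corpus.recordings:
        feats = extract_features(rec)
        for name in FEATURE_NAMES:
            columns[name].append(feats[name].values)
    return {name: np.vstack(vals) for name, vals in columns.items()}


def prepare_task(
    corpus: LabeledCorpus,
    task: str,
    seed: int = 0,
    quota: int | str | Mapping = "min",
    k_folds: int = 4,
) -> tuple[LabeledCorpus, Split]:
    """Task protocol: restrict, drop invalid, balance, split 75/25, make folds."""
    sub = corpus.for_task(task)
    sub, _ = filter_valid(sub)
    balanced = balance_by_strata(sub, strata=("genus", "sex"),
                                 per_stratum_quota=quota, seed=seed)
    split = train_test_split(balanced, train_fraction=0.75, seed=seed)
    split = make_folds(split, balanced.labels(), k=k_folds, seed=seed)
    return balanced, split


def run_benchmark(
    corpus: LabeledCorpus,
    task: str,
    features: Sequence[str] | None = None,
    algorithms: Sequence[AlgorithmSpec] | None = None,
    seed: int = 0,
) -> BenchmarkReport:
    """Full bench for one task: 6 features x 5 algorithms test-accuracy grid.

    Applies the task protocol (validity filter, balancing, 75/25 split,
    fourfold CV selection), populates every grid cell — scalar features
    included — and flags the best cell(s). The error analysis verdict is
    computed for the globally best cell.
    """
    features = list(features) if features is not None else list(FEATURE_NAMES)
    algorithms = list(algorithms) if algorithms is not None else default_algorithms(seed)
    balanced, split = prepare_task(corpus, task, seed=seed)
    X_all = feature_matrix(balanced)
    y = balanced.labels()
    tr, te = split.train_indices, split.test_indices

    grid = pd.DataFrame(index=features,
                        columns=[a.name for a in algorithms], dtype=float)
    models: dict[tuple[str, str], FittedModel] = {}
    cv_results: dict[tuple[str, str], CVResult] = {}
    for feat in features:
        X = X_all[feat]
        for alg in algorithms:
            model, cv = train_with_cv(X[tr], y[tr], alg, split.fold_assignment)
            model.feature_name = feat
            acc = evaluate_accuracy(model, X[te], y[te])
            grid.loc[feat, alg.name] = acc
            models[(feat, alg.name)] = model
            cv_results[(feat, alg.name)] = cv

    best_per_feature = {
        feat: grid.columns[np.isclose(grid.loc[feat], grid.loc[feat].max())].tolist()
        for feat in features
    }
    best_acc = float(grid.values.max())
    best_cells = [
        (feat, alg)
        for feat in features
        for alg in grid.columns
        if np.isclose(grid.loc[feat, alg], best_acc)
    ]
    top_feat, top_alg = best_cells[0]
    top_cv = cv_results[(top_feat, top_alg)]
    verdict = error_analysis(top_cv.training_accuracy, top_cv.validation_accuracy)
    return BenchmarkReport(
        task=task,
        grid=grid,
        best_per_feature=best_per_feature,
        best_cells=best_cells,
        best_accuracy=best_acc,
        verdict=verdict,
        training_accuracy=top_cv.training_accuracy,
        validation_accuracy=top_cv.validation_accuracy,
        n_train=len(tr),
        n_test=len(te),
        seed=seed,
        models=models,
        cv_results=cv_results,
    )


def classify_cascade(
    recording,
    genus_model: FittedModel,
    sex_model_aedes: FittedModel,
    sex_model_culex: FittedModel,
) -> dict:
    """Hierarchical classification: genus first, then the genus-specific sex model.

    All three models must declare the feature they consume (set when trained
    through the bench); a model without one is a configuration mismatch.
    Returns the predicted genus and sex with each model's decision.
    """
    models = {"genus": genus_model, "Aedes": sex_model_aedes, "Culex": sex_model_culex}
    for role, m in models.items():
        if m.feature_name is None:
            raise ValueError(f"{role} model does not declare its input feature")
    feats = extract_features(recording)

    def apply(m: FittedModel) -> str:
        return str(m.predict(feats[m.feature_name].values[None, :])[0])

    genus = apply(genus_model)
    sex_model = models.get(genus)
    if sex_model is None or genus not in ("Aedes", "Culex"):
        raise ValueError(f"no sex model for predicted genus {genus!r}")
    sex = apply(sex_model)
    return {"genus": genus, "sex": sex,
            "genus_model": genus_model.algorithm, "sex_model": sex_model.algorithm}
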