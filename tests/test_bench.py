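"""Model bench: CV selection, accuracy, error analysis, leakage, cascade."""

import pickle

import numpy as np
import pytest

from wingbeat.bench import (
    AlgorithmSpec,
    ErrorThresholds,
    FittedModel,
    classify_cascade,
    error_analysis,
    evaluate_accuracy,
    feature_matrix,
    train_with_cv,
)
from wingbeat.dataset import filter_valid, make_folds, split_by_labels
from wingbeat.sensor_sim import ClassProfile, synth_wingbeat


def gaussian_problem(delta_sigmas, n_per_class=80, seed=0):
    rng = np.random.default_rng(seed)
    X = np.concatenate([rng.standard_normal(n_per_class),
                        delta_sigmas + rng.standard_normal(n_per_class)])[:, None]
    y = np.repeat(["a", "b"], n_per_class)
    split = split_by_labels(y, seed=seed)
    split = make_folds(split, y, k=4)
    return X, y, split


@pytest.mark.parametrize("name", ["LR", "GB", "RF", "SVM", "DNN"])
def test_separated_gaussians_are_learned(name):
    """6-sigma class separation (Bayes error < 0.0015): CV accuracy >= 0.98."""
    X, y, split = gaussian_problem(6.0, seed=1)
    tr = split.train_indices
    _, cv = train_with_cv(X[tr], y[tr], AlgorithmSpec(name, seed=1),
                          split.fold_assignment)
    assert cv.validation_accuracy >= 0.98


def test_shuffled_labels_score_at_chance():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((200, 4))
    y = np.repeat(["a", "b"], 100)
    rng.shuffle(y)
    split = make_folds(split_by_labels(y, seed=2), y, k=4)
    tr = split.train_indices
    _, cv = train_with_cv(X[tr], y[tr], AlgorithmSpec("LR", seed=2),
                          split.fold_assignment)
    n_val = len(tr)
    half_width = 2.58 * np.sqrt(0.25 / n_val)
    assert abs(cv.validation_accuracy - 0.5) <= half_width


def test_singleton_grid_selected():
    X, y, split = gaussian_problem(3.0)
    tr = split.train_indices
    spec = AlgorithmSpec("LR", grid={"C": [0.5]})
    _, cv = train_with_cv(X[tr], y[tr], spec, split.fold_assignment)
    assert cv.best_configuration == {"C": 0.5}
    assert len(cv.configurations) == 1


def test_cv_selection_and_mean_bounds():
    X, y, split = gaussian_problem(2.0, seed=4)
    tr = split.train_indices
    spec = AlgorithmSpec("SVM", grid={"C": [0.01, 1.0, 100.0]})
    _, cv = train_with_cv(X[tr], y[tr], spec, split.fold_assignment)
    assert cv.best_index == int(np.argmax(cv.mean_accuracies))
    for ci in range(len(cv.configurations)):
        accs = cv.fold_accuracies[ci]
        assert accs.min() <= cv.mean_accuracies[ci] <= accs.max()
        assert cv.mean_accuracies[ci] == pytest.approx(accs.mean())
    assert np.all((cv.fold_accuracies >= 0) & (cv.fold_accuracies <= 1))


def test_single_class_training_rejected():
    X = np.zeros((20, 2))
    y = np.repeat(["a"], 20)
    folds = np.tile([1, 2, 3, 4], 5)
    with pytest.raises(ValueError, match="two classes"):
        train_with_cv(X, y, AlgorithmSpec("LR"), folds)


class _ConstantPipeline:
    def predict(self, X):
        return np.zeros(len(X), dtype=int)


def test_evaluate_accuracy_definition():
    model = FittedModel(pipeline=_ConstantPipeline(), classes=np.array(["a", "b"]),
                        algorithm="LR", params={})
    y = np.array(["a"] * 94 + ["b"] * 6)
    assert evaluate_accuracy(model, np.zeros((100, 1)), y) == pytest.approx(0.94)
    balanced = np.repeat(["a", "b"], 50)
    assert evaluate_accuracy(model, np.zeros((100, 1)), balanced) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        evaluate_accuracy(model, np.zeros((0, 1)), np.array([]))


def test_perfect_separation_scores_one():
    X, y, split = gaussian_problem(60.0, seed=5)
    tr, te = split.train_indices, split.test_indices
    model, _ = train_with_cv(X[tr], y[tr], AlgorithmSpec("SVM", seed=5),
                             split.fold_assignment)
    assert evaluate_accuracy(model, X[te], y[te]) == 1.0


# ------------------------------------------------------------ error analysis

@pytest.mark.parametrize("train_acc,val_acc,expected", [
    (1.00, 0.95, "overfit_more_samples"),
    (0.995, 0.995, "no_overfitting"),
    (1.00, 1.00, "no_error"),
    (0.70, 0.69, "underfit_more_capacity"),
])
def test_error_analysis_verdicts(train_acc, val_acc, expected):
    assert error_analysis(train_acc, val_acc) == expected


def test_error_analysis_rejects_bad_accuracy():
    with pytest.raises(ValueError):
        error_analysis(1.2, 0.5)


def test_error_analysis_custom_thresholds():
    th = ErrorThresholds(overfit_gap=0.10)
    assert error_analysis(1.00, 0.95, th) == "no_overfitting"


# ------------------------------------------------------------ leakage

def test_training_is_deterministic_and_ignores_test_data():
    """Refit models are bit-identical however the test labels are permuted."""
    X, y, split = gaussian_problem(2.0, seed=6)
    tr, te = split.train_indices, split.test_indices
    rng = np.random.default_rng(0)
    results = []
    for _ in range(2):
        model, _ = train_with_cv(X[tr], y[tr], AlgorithmSpec("LR", seed=6),
                                 split.fold_assignment)
        y_te = y[te].copy()
        rng.shuffle(y_te)  # different (permuted) test labels each round
        evaluate_accuracy(model, X[te], y_te)
        results.append(pickle.dumps(model.pipeline))
    assert results[0] == results[1]


# ------------------------------------------------------------ cascade

def _train_feature_model(corpus, column, feature="frequency_and_power", seed=0):
    X = feature_matrix(corpus)[feature]
    y = corpus.labels(column)
    split = make_folds(split_by_labels(y, seed=seed), y, k=4)
    model, _ = train_with_cv(X[split.train_indices], y[split.train_indices],
                             AlgorithmSpec("LR", seed=seed), split.fold_assignment)
    model.feature_name = feature
    return model


@pytest.fixture(scope="module")
def cascade_models(clean_corpus):
    kept, _ = filter_valid(clean_corpus)
    genus_model = _train_feature_model(kept.for_task("genus"), "genus")
    aedes_model = _train_feature_model(kept.for_task("sex_aedes"), "sex")
    culex_model = _train_feature_model(kept.for_task("sex_culex"), "sex")
    return genus_model, aedes_model, culex_model


def test_cascade_classifies_clear_culex_female(cascade_models):
    profile = ClassProfile(genus="Culex", sex="female", f1_mean=380.0, f1_sd=1.0,
                           peak_power_mean=-55.0, peak_power_sd=1.0,
                           harmonic_ratios=(0.3, 0.5, 0.15))
    rec = synth_wingbeat(profile, seed=21)
    out = classify_cascade(rec, *cascade_models)
    assert out["genus"] == "Culex"
    assert out["sex"] == "female"


def test_cascade_deterministic(cascade_models, one_flight):
    a = classify_cascade(one_flight, *cascade_models)
    b = classify_cascade(one_flight, *cascade_models)
    assert a == b


def test_cascade_error_propagation_bound(cascade_models, clean_corpus):
    """Joint cascade accuracy cannot exceed its weakest marginal stage."""
    genus_model, aedes_model, culex_model = cascade_models
    kept, _ = filter_valid(clean_corpus)
    recs = kept.recordings[::3]
    X = feature_matrix(type(kept)(recordings=list(recs)))["frequency_and_power"]
    genus_ok = genus_model.predict(X) == np.array([r.genus for r in recs])
    sex_pred = np.where(
        np.array([r.genus for r in recs]) == "Aedes",
        aedes_model.predict(X), culex_model.predict(X))
    sex_ok = sex_pred == np.array([r.sex for r in recs])
    joint = np.mean([classify_cascade(r, *cascade_models)["genus"] == r.genus
                     and classify_cascade(r, *cascade_models)["sex"] == r.sex
                     for r in recs])
    assert joint <= min(genus_ok.mean(), sex_ok.mean()) + 0.05


def test_cascade_requires_declared_features(cascade_models, one_flight):
    genus_model, aedes_model, culex_model = cascade_models
    anonymous = FittedModel(pipeline=genus_model.pipeline, classes=genus_model.classes,
                            algorithm="LR", params={}, feature_name=None)
    with pytest.raises(ValueError, match="feature"):
        classify_cascade(one_flight, anonymous, aedes_model, culex_model)
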