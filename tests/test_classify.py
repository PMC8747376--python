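"""Classifiers, cross-validation, metrics and the ablation experiment."""

import numpy as np
import pandas as pd
import pytest

from maizephen import (
    ClassifierSpec,
    ConfusionMatrix,
    KNNClassifier,
    LDAClassifier,
    SceneConfig,
    ablation_experiment,
    generate_scene,
    kfold_cv,
    make_quadratic_svm,
    metrics,
    run_evaluation,
    scene_feature_table,
    stratified_split,
)
from maizephen.exceptions import MetricError, ParameterError, SplitError
from maizephen.features import representative_schema


def _table(X, y):
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    df.insert(0, "stage", y)
    df.insert(0, "plot_id", [str(i) for i in range(len(y))])
    df.insert(0, "date", "20190601")
    df.insert(0, "sample_id", [f"s{i}" for i in range(len(y))])
    return df


# -- LDA ---------------------------------------------------------------------

def test_lda_with_identity_covariance_is_nearest_centroid():
    rng = np.random.default_rng(0)
    model = LDAClassifier()
    model.classes_ = np.array([1, 2, 3])
    model.priors_ = np.full(3, 1 / 3)
    model.means_ = rng.normal(size=(3, 4))
    model._precision = np.eye(4)
    X = rng.normal(size=(120, 4))
    pred = model.predict(X)
    dists = ((X[:, None, :] - model.means_[None]) ** 2).sum(axis=2)
    nearest = model.classes_[dists.argmin(axis=1)]
    np.testing.assert_array_equal(pred, nearest)


def test_lda_single_point_per_class_boundary_at_midpoint():
    model = LDAClassifier().fit(np.array([[0.0], [2.0]]), np.array([1, 2]))
    assert model.predict(np.array([[0.9]]))[0] == 1
    assert model.predict(np.array([[1.1]]))[0] == 2


def test_lda_priors_follow_class_imbalance():
    X = np.random.default_rng(1).normal(size=(40, 3))
    y = np.array([1] * 30 + [2] * 10)
    model = LDAClassifier().fit(X, y)
    np.testing.assert_allclose(model.priors_, [0.75, 0.25])


def test_lda_ridge_handles_singular_covariance():
    rng = np.random.default_rng(2)
    base = rng.normal(size=(60, 2)) + np.repeat([[0, 0], [4, 4]], 30, axis=0)
    X = np.hstack([base, base[:, :1]])  # duplicated column -> singular pooled cov
    y = np.repeat([1, 2], 30)
    model = LDAClassifier().fit(X, y)
    assert (model.predict(X) == y).mean() > 0.9


def test_lda_agrees_with_reference_implementation():
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    rng = np.random.default_rng(3)
    X = rng.normal(size=(200, 5))
    y = rng.integers(1, 4, size=200)
    X += y[:, None] * 1.5
    ours = LDAClassifier().fit(X, y)
    ref = LinearDiscriminantAnalysis().fit(X, y)
    Xq = rng.normal(size=(100, 5)) + 3.0
    np.testing.assert_array_equal(ours.predict(Xq), ref.predict(Xq))


# -- kNN ---------------------------------------------------------------------

def test_knn_k1_training_accuracy_is_one():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(30, 3))
    y = rng.integers(1, 4, size=30)
    model = KNNClassifier(k=1).fit(X, y)
    assert (model.predict(X) == y).all()


def test_knn_majority_vote_on_the_line():
    X = np.array([[0.0], [1.0], [10.0]])
    y = np.array(["A", "A", "B"])
    model = KNNClassifier(k=3).fit(X, y)
    assert model.predict(np.array([[0.4]]))[0] == "A"


def test_knn_tie_breaks_by_lowest_class_label():
    X = np.array([[0.0], [2.0]])
    y = np.array([2, 1])
    model = KNNClassifier(k=2).fit(X, y)
    # equidistant single votes with equal aggregate distance -> class 1
    assert model.predict(np.array([[1.0]]))[0] == 1


def test_knn_tie_breaks_by_aggregate_distance_first():
    X = np.array([[0.0], [2.1], [-1.0], [3.0]])
    y = np.array([1, 2, 1, 2])
    model = KNNClassifier(k=4).fit(X, y)
    # votes 2:2; class 2 has smaller total distance from the query at 1.5
    assert model.predict(np.array([[1.5]]))[0] == 2


def test_knn_k_larger_than_training_rejected():
    with pytest.raises(ParameterError):
        KNNClassifier(k=5).fit(np.zeros((3, 2)), np.array([1, 1, 2]))


def test_knn_manhattan_metric_runs():
    X = np.array([[0.0, 0.0], [5.0, 5.0]])
    model = KNNClassifier(k=1, metric="manhattan").fit(X, np.array([1, 2]))
    assert model.predict(np.array([[4.0, 4.0]]))[0] == 2


# -- quadratic SVM -----------------------------------------------------------

def test_quadratic_kernel_separates_xor():
    X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
    y = np.array([1, 1, 2, 2])
    quad = make_quadratic_svm(box_constraint=1e6, standardize=False).fit(X, y)
    assert (quad.predict(X) == y).all()
    from sklearn.svm import SVC

    linear = SVC(kernel="linear", C=1e6).fit(X, y)
    assert (linear.predict(X) != y).any()


def test_linearly_separable_training_accuracy():
    rng = np.random.default_rng(5)
    X = np.vstack([rng.normal(0, 0.3, (20, 2)), rng.normal(5, 0.3, (20, 2))])
    y = np.repeat([1, 2], 20)
    model = make_quadratic_svm().fit(X, y)
    assert (model.predict(X) == y).all()


def test_standardization_makes_predictions_scale_invariant():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(60, 3)) + np.repeat([[0, 0, 0], [2, 2, 2]], 30, axis=0)
    y = np.repeat([1, 2], 30)
    scale = np.array([1.0, 100.0, 0.01])
    a = make_quadratic_svm(standardize=True).fit(X, y).predict(X)
    b = make_quadratic_svm(standardize=True).fit(X * scale, y).predict(X * scale)
    np.testing.assert_array_equal(a, b)


def test_nonfinite_features_rejected():
    X = np.array([[0.0, np.nan], [1.0, 2.0]])
    with pytest.raises(ValueError):
        make_quadratic_svm().fit(X, np.array([1, 2]))


# -- splits and CV -----------------------------------------------------------

def test_stratified_split_preserves_class_proportions():
    X = np.zeros((100, 2))
    y = np.repeat([1, 2], 50)
    train, hold = stratified_split(_table(X, y), train_fraction=0.9, seed=0)
    assert len(train) == 90 and len(hold) == 10
    assert (train.stage == 1).sum() == 45 and (hold.stage == 1).sum() == 5


def test_stratified_split_is_a_deterministic_partition():
    table = _table(np.random.default_rng(7).normal(size=(40, 2)),
                   np.repeat([1, 2], 20))
    t1, h1 = stratified_split(table, seed=3)
    t2, h2 = stratified_split(table, seed=3)
    pd.testing.assert_frame_equal(t1, t2)
    ids = set(t1.sample_id) | set(h1.sample_id)
    assert ids == set(table.sample_id)
    assert not set(t1.sample_id) & set(h1.sample_id)


def test_split_rejects_singleton_class():
    table = _table(np.zeros((3, 1)), np.array([1, 1, 2]))
    with pytest.raises(SplitError):
        stratified_split(table)


def test_kfold_folds_partition_the_data():
    table = _table(np.random.default_rng(8).normal(size=(53, 3)),
                   np.tile([1, 2], 27)[:53])
    report = kfold_cv(table, ClassifierSpec("lda"), k=10, seed=1)
    sizes = np.array(report.fold_sizes)
    assert sizes.sum() == 53
    assert sizes.max() - sizes.min() <= 1
    assert report.confusion.total == 53


def test_kfold_rejects_k_below_two():
    table = _table(np.zeros((10, 1)), np.repeat([1, 2], 5))
    with pytest.raises(ParameterError):
        kfold_cv(table, ClassifierSpec("lda"), k=1)


def test_overall_precision_equals_weighted_fold_mean(small_table):
    report = kfold_cv(small_table, ClassifierSpec("lda"), k=5, seed=2)
    pooled = np.average(report.fold_accuracies, weights=report.fold_sizes)
    assert abs(report.overall - pooled) < 1e-12


def test_zero_noise_scene_is_perfectly_classified(zero_noise_scene):
    table = scene_feature_table(zero_noise_scene)
    report = kfold_cv(table, ClassifierSpec("knn", {"k": 1}), k=3, seed=0)
    assert report.overall == 1.0


def test_run_evaluation_reports_cv_and_holdout(small_table):
    out = run_evaluation(small_table, ClassifierSpec("lda"), k=3,
                         train_fraction=0.75, seed=0)
    assert set(out) == {"cv", "holdout"}
    assert out["holdout"].confusion.total == len(small_table) - out[
        "cv"
    ].confusion.total


def test_vanishing_separation_drives_classifiers_to_chance():
    """With one shared profile and uniform texture for every stage, no
    classifier can beat guessing: accuracy ~ 1/K within 3 SE over seeds."""
    profiles = {s: (0.05, 0.10, 0.07, 0.38) for s in range(1, 7)}
    uniform = {s: 1.0 for s in range(1, 7)}
    accs = {kind: [] for kind in ("lda", "knn", "svm_quadratic")}
    for seed in range(12):
        cfg = SceneConfig(
            grid_height=60, grid_width=130, n_plots=24, plot_height=8,
            plot_width=8, stage_profiles=profiles, stage_noise_scale=uniform,
            stage_autocorrelation={s: 1.5 for s in range(1, 7)}, seed=seed,
        )
        table = scene_feature_table(generate_scene(cfg))
        for kind in accs:
            accs[kind].append(
                kfold_cv(table, ClassifierSpec(kind), k=4, seed=seed).overall
            )
    for kind, values in accs.items():
        mean = np.mean(values)
        se = np.std(values, ddof=1) / np.sqrt(len(values))
        assert abs(mean - 1 / 6) <= 3 * se + 0.05, (kind, mean, se)


# -- metrics -----------------------------------------------------------------

def test_metrics_direct_arithmetic():
    cm = ConfusionMatrix(np.array([[8, 2], [1, 9]]), labels=(1, 2))
    m = metrics(cm)
    assert m.overall == 17 / 20
    assert m.per_class_recall[1] == 0.8
    assert m.per_class_precision[1] == 8 / 9


def test_metrics_perfect_matrix():
    cm = ConfusionMatrix(np.diag([5, 7, 3]), labels=(1, 2, 3))
    m = metrics(cm)
    assert m.overall == 1.0
    assert all(v == 1.0 for v in m.per_class_recall.values())


def test_metrics_uniform_matrix():
    cm = ConfusionMatrix(np.full((2, 2), 5), labels=(1, 2))
    m = metrics(cm)
    assert m.overall == 0.5
    assert all(v == 0.5 for v in m.per_class_recall.values())


def test_metrics_flag_zero_denominator_classes():
    cm = ConfusionMatrix(np.array([[4, 0], [0, 0]]), labels=(1, 2))
    m = metrics(cm)
    assert 2 in m.undefined
    assert np.isnan(m.per_class_recall[2])


def test_metrics_reject_empty_matrix():
    with pytest.raises(MetricError):
        metrics(ConfusionMatrix(np.zeros((2, 2), int), labels=(1, 2)))


# -- ablation ----------------------------------------------------------------

def test_ablation_returns_seven_reports(small_table):
    out = ablation_experiment(small_table, ClassifierSpec("lda"), k=5, seed=4)
    assert set(out) == {"full", "LISA", "LBP", "LAI", "RATIO", "RGB_NIR", "LAB"}
    assert out["full"].n_features == 45
    assert out["LISA"].n_features == 34
    direct = kfold_cv(small_table, ClassifierSpec("lda"), k=5, seed=4,
                      feature_names=list(representative_schema().names))
    assert out["full"].report.overall == direct.overall


def test_ablation_hurts_most_where_the_signal_lives():
    """A table whose class signal sits only in the RGB/NIR means loses the
    most accuracy when the RGB/NIR group is removed (averaged over seeds)."""
    names = list(representative_schema().names)
    drops = {g: [] for g in ("LISA", "LBP", "LAI", "RATIO", "RGB_NIR", "LAB")}
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n = 120
        y = np.repeat([1, 2, 3], n // 3)
        data = {name: rng.normal(size=n) for name in names}
        for name in ("red_m", "green_m", "blue_m", "nir_m"):
            data[name] = y * 2.0 + rng.normal(scale=0.5, size=n)
        table = pd.DataFrame(data)
        table.insert(0, "stage", y)
        table.insert(0, "plot_id", "1")
        table.insert(0, "date", "20190601")
        table.insert(0, "sample_id", [f"s{i}" for i in range(n)])
        out = ablation_experiment(table, ClassifierSpec("svm_quadratic"),
                                  k=5, seed=seed)
        for g in drops:
            drops[g].append(out[g].delta_vs_full)
    mean_drop = {g: np.mean(v) for g, v in drops.items()}
    assert min(mean_drop, key=mean_drop.get) == "RGB_NIR"
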