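"""Classifier training and evaluation for phenological-stage recognition.

Three supervised models are compared, mirroring the study design:

* **LDA** — Gaussian classes with a pooled covariance.  The fit uses the
  closed-form estimators (priors N_k/N, class means, pooled covariance with
  the N - K denominator) and predicts by the linear discriminant score
  ``delta_k(x) = x' S^-1 mu_k - 1/2 mu_k' S^-1 mu_k + log pi_k``.  A
  singular pooled covariance is ridge-regularised with
  ``eps = 1e-6 * trace(S)/p`` on the diagonal.
* **kNN** — majority vote among the k nearest training points (Euclidean,
  Manhattan or Minkowski distance); ties broken by the smallest aggregate
  distance of the tied classes, then by the lowest class label.
* **Quadratic SVM** — one-vs-one soft-margin SVMs with the polynomial
  kernel ``(gamma <xi,xj> + c)^2`` (libsvm via scikit-learn), features
  standardised to zero mean / unit variance by default.

Evaluation follows the protocol of a stratified 90/10 holdout combined
with stratified 10-fold cross-validation: `kfold_cv` pools the
out-of-fold predictions into one confusion matrix; `run_evaluation`
additionally reports the held-out 10%.  Overall precision is the trace of
the confusion matrix over the total; per-class precision is reported both
row-normalised (samples of a stage classified correctly — the convention
of the published per-stage tables) and column-normalised (precision of
the predictions for a stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import MetricError, ParameterError, SplitError
from .features import META_COLUMNS, table_schema_names

# -- models ------------------------------------------------------------------


@dataclass
class LDAClassifier:
    """Linear discriminant classifier with closed-form Gaussian estimators."""

    ridge: float | None = None  # None: auto eps = 1e-6 tr(S)/p when singular
    classes_: np.ndarray | None = None
    priors_: np.ndarray | None = None
    means_: np.ndarray | None = None
    covariance_: np.ndarray | None = None
    _precision: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LDAClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        n, p = X.shape
        k = classes.size
        if k < 2:
            raise ParameterError("LDA needs >= 2 classes")
        self.classes_ = classes
        self.priors_ = counts / n
        self.means_ = np.stack([X[y == c].mean(axis=0) for c in classes])
        pooled = np.zeros((p, p))
        for c, mu in zip(classes, self.means_):
            d = X[y == c] - mu
            pooled += d.T @ d
        if n > k:
            pooled /= n - k
        # n == k (one point per class): zero scatter, ridge handles inversion
        self.covariance_ = pooled
        self._precision = self._invert(pooled)
        return self

    def _invert(self, cov: np.ndarray) -> np.ndarray:
        p = cov.shape[0]
        try:
            np.linalg.cholesky(cov + 0.0)
            return np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            eps = self.ridge
            if eps is None:
                eps = 1e-6 * np.trace(cov) / p
                if eps <= 0:
                    eps = 1e-6
            return np.linalg.inv(cov + eps * np.eye(p))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        pm = self.means_ @ self._precision          # (k, p)
        const = -0.5 * np.einsum("kp,kp->k", pm, self.means_) + np.log(self.priors_)
        return X @ pm.T + const

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


@dataclass
class KNNClassifier:
    """k-nearest-neighbours with the documented deterministic tie-break."""

    k: int = 10
    metric: str = "euclidean"  # euclidean | manhattan | minkowski
    minkowski_p: float = 3.0
    _nn: NearestNeighbors | None = None
    _y: np.ndarray | None = None
    classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KNNClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.k < 1 or self.k > X.shape[0]:
            raise ParameterError(f"k={self.k} outside 1..{X.shape[0]}")
        kwargs = {"metric": self.metric}
        if self.metric == "minkowski":
            kwargs["p"] = self.minkowski_p
        self._nn = NearestNeighbors(n_neighbors=self.k, **kwargs).fit(X)
        self._y = y
        self.classes_ = np.unique(y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        dist, idx = self._nn.kneighbors(np.asarray(X, dtype=float))
        out = []
        for drow, irow in zip(dist, idx):
            labels = self._y[irow]
            votes: dict = {}
            agg: dict = {}
            for lab, d in zip(labels, drow):
                votes[lab] = votes.get(lab, 0) + 1
                agg[lab] = agg.get(lab, 0.0) + d
            top = max(votes.values())
            tied = [lab for lab, v in votes.items() if v == top]
            # tie-break: smallest aggregate distance, then lowest class label
            tied.sort(key=lambda lab: (agg[lab], lab))
            out.append(tied[0])
        return np.asarray(out)


def make_quadratic_svm(
    box_constraint: float = 1.0,
    gamma: float | str = "auto",  # "auto" = 1/n_features
    coef0: float = 1.0,
    standardize: bool = True,
) -> Pipeline:
    """One-vs-one quadratic-kernel SVM pipeline (optional standardisation)."""
    steps = []
    if standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("svm", SVC(C=box_constraint, kernel="poly", degree=2,
                             gamma=gamma, coef0=coef0)))
    return Pipeline(steps)


@dataclass(frozen=True)
class ClassifierSpec:
    """Declarative classifier choice: kind 'lda' | 'knn' | 'svm_quadratic'."""

    kind: str
    params: Mapping = field(default_factory=dict)

    def build(self):
        if self.kind == "lda":
            return LDAClassifier(**self.params)
        if self.kind == "knn":
            return KNNClassifier(**self.params)
        if self.kind == "svm_quadratic":
            return make_quadratic_svm(**self.params)
        raise ParameterError(f"unknown classifier kind {self.kind!r}")


# -- confusion matrices and metrics -----------------------------------------


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true stages, columns predicted stages."""

    counts: np.ndarray
    labels: tuple

    @classmethod
    def from_predictions(cls, y_true, y_pred, labels=None) -> "ConfusionMatrix":
        if labels is None:
            labels = np.unique(np.concatenate([np.asarray(y_true),
                                               np.asarray(y_pred)]))
        labels = tuple(labels)
        pos = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[pos[t], pos[p]] += 1
        return cls(counts=counts, labels=labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class Metrics:
    """Overall precision plus both per-class normalisations.

    ``per_class_recall`` divides the diagonal by row sums (share of each
    true stage classified correctly); ``per_class_precision`` divides by
    column sums.  Classes with a zero denominator are NaN and listed in
    ``undefined``.
    """

    overall: float
    per_class_recall: dict
    per_class_precision: dict
    undefined: set


def metrics(cm: ConfusionMatrix) -> Metrics:
    if cm.total == 0:
        raise MetricError("empty confusion matrix")
    counts = cm.counts.astype(float)
    diag = np.diag(counts)
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    undefined = set()
    recall, precision = {}, {}
    for i, lab in enumerate(cm.labels):
        recall[lab] = diag[i] / rows[i] if rows[i] > 0 else float("nan")
        precision[lab] = diag[i] / cols[i] if cols[i] > 0 else float("nan")
        if rows[i] == 0 or cols[i] == 0:
            undefined.add(lab)
    return Metrics(
        overall=float(diag.sum() / counts.sum()),
        per_class_recall=recall,
        per_class_precision=precision,
        undefined=undefined,
    )


@dataclass
class EvalReport:
    """Pooled confusion matrix and metrics of one evaluation run."""

    confusion: ConfusionMatrix
    overall: float
    per_class_recall: dict
    per_class_precision: dict
    fold_sizes: tuple[int, ...]
    fold_accuracies: tuple[float, ...]
    seed: int
    classifier: str


# -- data plumbing -----------------------------------------------------------


def split_xy(table: pd.DataFrame, feature_names: Sequence[str] | None = None):
    """Feature matrix and stage labels from a feature table."""
    if feature_names is None:
        feature_names = table_schema_names(table)
    X = table[list(feature_names)].to_numpy(dtype=float)
    y = table["stage"].to_numpy()
    return X, y


def stratified_split(
    table: pd.DataFrame, train_fraction: float = 0.9, seed: int = 0
):
    """Disjoint, exhaustive stratified split preserving class proportions."""
    y = table["stage"].to_numpy()
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise SplitError("every class needs >= 2 samples for a stratified split")
    idx = np.arange(len(table))
    train_idx, hold_idx = train_test_split(
        idx, train_size=train_fraction, stratify=y, random_state=seed
    )
    return (table.iloc[np.sort(train_idx)].reset_index(drop=True),
            table.iloc[np.sort(hold_idx)].reset_index(drop=True))


def kfold_cv(
    table: pd.DataFrame,
    spec: ClassifierSpec,
    k: int = 10,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> EvalReport:
    """Stratified k-fold CV; pooled out-of-fold confusion matrix + metrics."""
    if k < 2:
        raise ParameterError("k-fold CV needs k >= 2")
    X, y = split_xy(table, feature_names)
    labels = tuple(np.unique(y))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    fold_sizes, fold_accs = [], []
    for train_idx, test_idx in skf.split(X, y):
        model = spec.build()
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        y_pred[test_idx] = pred
        fold_sizes.append(len(test_idx))
        fold_accs.append(float(np.mean(pred == y[test_idx])))
    cm = ConfusionMatrix.from_predictions(y, y_pred, labels=labels)
    m = metrics(cm)
    return EvalReport(
        confusion=cm, overall=m.overall,
        per_class_recall=m.per_class_recall,
        per_class_precision=m.per_class_precision,
        fold_sizes=tuple(fold_sizes), fold_accuracies=tuple(fold_accs),
        seed=seed, classifier=spec.kind,
    )


def holdout_report(
    train: pd.DataFrame,
    holdout: pd.DataFrame,
    spec: ClassifierSpec,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> EvalReport:
    """Fit on the training table, report the held-out confusion matrix."""
    Xtr, ytr = split_xy(train, feature_names)
    Xte, yte = split_xy(holdout, feature_names)
    model = spec.build()
    model.fit(Xtr, ytr)
    pred = model.predict(Xte)
    cm = ConfusionMatrix.from_predictions(yte, pred, labels=tuple(np.unique(ytr)))
    m = metrics(cm)
    return EvalReport(
        confusion=cm, overall=m.overall,
        per_class_recall=m.per_class_recall,
        per_class_precision=m.per_class_precision,
        fold_sizes=(len(holdout),),
        fold_accuracies=(m.overall,),
        seed=seed, classifier=spec.kind,
    )


def run_evaluation(
    table: pd.DataFrame,
    spec: ClassifierSpec,
    k: int = 10,
    train_fraction: float = 0.9,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> dict[str, EvalReport]:
    """The full protocol: stratified 90/10 split, k-fold CV on the 90%,
    plus the held-out 10% confusion matrix.  Returns {'cv': ..., 'holdout': ...}."""
    train, hold = stratified_split(table, train_fraction=train_fraction, seed=seed)
    return {
        "cv": kfold_cv(train, spec, k=k, seed=seed, feature_names=feature_names),
        "holdout": holdout_report(train, hold, spec, seed=seed,
                                  feature_names=feature_names),
    }


# -- ablation ----------------------------------------------------------------


@dataclass
class AblationResult:
    report: EvalReport
    n_features: int
    delta_vs_full: float  # overall precision minus the full 45-feature run


def ablation_experiment(
    table: pd.DataFrame,
    spec: ClassifierSpec | None = None,
    k: int = 10,
    seed: int = 0,
) -> dict[str, AblationResult]:
    """CV once per ablation subset of the 45-feature schema, plus the full set.

    Keys: 'full' and the removed indicator groups ('LISA', 'LBP', 'LAI',
    'RATIO', 'RGB_NIR', 'LAB').
    """
    from .exceptions import SchemaError
    from .features import ablation_sets, representative_schema

    if spec is None:
        spec = ClassifierSpec("svm_quadratic")
    base = representative_schema()
    missing = set(base.names) - set(table.columns)
    if missing:
        raise SchemaError(f"table lacks main-schema columns: {sorted(missing)}")
    results: dict[str, AblationResult] = {}
    full_report = kfold_cv(table, spec, k=k, seed=seed,
                           feature_names=list(base.names))
    results["full"] = AblationResult(full_report, len(base), 0.0)
    for label, schema in ablation_sets().items():
        rep = kfold_cv(table, spec, k=k, seed=seed,
                       feature_names=list(schema.names))
        results[label] = AblationResult(rep, len(schema),
                                        rep.overall - full_report.overall)
    return results
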