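"""Two-layer stacked classification of preprocessed spectra.

Six base learners — k-nearest neighbours, PCA-LDA, PLS-DA, linear-kernel SVM,
RBF-kernel SVM and random forest — are tuned by repeated stratified k-fold
cross-validation on the training set.  Their out-of-fold class probabilities
(averaged over CV repeats) form the meta-features on which a gradient
boosting machine is fitted as the second layer.  Evaluation follows the
prediction-by-reference convention: confusion-matrix rows are model
predictions, columns are reference labels, and per-class sensitivity,
specificity and overall accuracy are pure functions of that matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from . import __version__
from .chemometrics import fit_lda, project
from .datatypes import SpectraSet

LEARNER_ORDER = ("knn", "lda", "pls_da", "svm_linear", "svm_rbf", "random_forest")


# ---------------------------------------------------------------------------
# specs

@dataclass
class SplitSpec:
    """Train/test partition: default 75/25, stratified, seed-controlled."""

    train_fraction: float = 0.75
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class CVSpec:
    """Repeated stratified k-fold CV used for tuning and meta-features."""

    folds: int = 10
    repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class BaseLearnerSpec:
    """One base learner: its kind, hyperparameter grid, and tuned values."""

    kind: str
    grid: list[dict] = field(default_factory=list)
    tuned_params: dict | None = None

    def __post_init__(self) -> None:
        if self.kind not in LEARNER_ORDER:
            raise ValueError(f"unknown learner kind {self.kind!r}")
        if not self.grid:
            raise ValueError(f"{self.kind}: hyperparameter grid must be non-empty")


def default_specs() -> list[BaseLearnerSpec]:
    """The six default learners with their tuning grids."""
    return [
        BaseLearnerSpec("knn", [{"n_neighbors": k} for k in (3, 5, 7, 9, 11)]),
        BaseLearnerSpec("lda", [{"pca_variance_target": 0.99}]),
        BaseLearnerSpec("pls_da", [{"n_components": c} for c in (2, 5, 10, 15, 20)]),
        BaseLearnerSpec("svm_linear", [{"C": c} for c in (0.01, 0.1, 1.0, 10.0)]),
        BaseLearnerSpec(
            "svm_rbf",
            [{"C": c, "gamma_factor": g} for c in (0.1, 1.0, 10.0) for g in (0.1, 1.0, 10.0)],
        ),
        BaseLearnerSpec("random_forest", [{"max_features": "sqrt"}]),
    ]


# ---------------------------------------------------------------------------
# estimator wrappers

class PCALDAClassifier(BaseEstimator, ClassifierMixin):
    """PCA-LDA with a Gaussian shared-covariance posterior in LD space."""

    def __init__(self, pca_variance_target: float = 0.99):
        self.pca_variance_target = pca_variance_target

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.model_ = fit_lda(X, y, pca_variance_target=self.pca_variance_target)
        self.classes_ = self.model_.classes_
        scores = project(self.model_, X)
        resid = scores - self.model_.class_means_ld_[
            np.searchsorted(self.classes_, y)
        ]
        cov = (resid.T @ resid) / max(len(y) - len(self.classes_), 1)
        cov += 1e-9 * np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])
        self._cov_inv = np.linalg.inv(cov)
        self._log_prior = np.log(
            np.array([(y == c).mean() for c in self.classes_])
        )
        return self

    def predict_proba(self, X):
        scores = project(self.model_, np.asarray(X, dtype=float))
        diff = scores[:, None, :] - self.model_.class_means_ld_[None, :, :]
        maha = np.einsum("nkd,de,nke->nk", diff, self._cov_inv, diff)
        logp = -0.5 * maha + self._log_prior
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """Partial least squares on a one-hot response with argmax decision.

    Pseudo-probabilities are the predicted responses shifted nonnegative and
    renormalized per row (argmax-preserving).
    """

    def __init__(self, n_components: int = 10):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        Y = (y[:, None] == self.classes_[None, :]).astype(float)
        k = min(self.n_components, X.shape[0] - 1, X.shape[1])
        self._pls = PLSRegression(n_components=max(k, 1), scale=False)
        self._pls.fit(X, Y)
        return self

    def decision_function(self, X):
        return self._pls.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        yhat = self.decision_function(X)
        p = yhat - yhat.min(axis=1, keepdims=True) + 1e-9
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


class SoftmaxSVC(BaseEstimator, ClassifierMixin):
    """Standardized SVC emitting softmax pseudo-probabilities.

    Features are standardized internally; ``gamma_factor`` multiplies the
    1 / (n_features * var) scale heuristic for the RBF kernel.  Probabilities
    are a softmax over the one-vs-rest decision values — deterministic and
    argmax-consistent, unlike Platt scaling.
    """

    def __init__(self, kernel: str = "linear", C: float = 1.0, gamma_factor: float = 1.0):
        self.kernel = kernel
        self.C = C
        self.gamma_factor = gamma_factor

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self._mean = X.mean(axis=0)
        self._std = X.std(axis=0)
        self._std[self._std < 1e-12] = 1.0
        Xs = (X - self._mean) / self._std
        gamma = "scale" if self.kernel == "linear" else self.gamma_factor / (
            Xs.shape[1] * max(Xs.var(), 1e-300)
        )
        self._svc = SVC(kernel=self.kernel, C=self.C, gamma=gamma,
                        decision_function_shape="ovr")
        self._svc.fit(Xs, y)
        self.classes_ = self._svc.classes_
        return self

    def decision_function(self, X):
        Xs = (np.asarray(X, dtype=float) - self._mean) / self._std
        d = self._svc.decision_function(Xs)
        if d.ndim == 1:  # binary: one margin for classes_[1]
            d = np.column_stack([-d, d])
        return d

    def predict_proba(self, X):
        d = self.decision_function(X)
        d = d - d.max(axis=1, keepdims=True)
        p = np.exp(d)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def make_estimator(kind: str, params: dict, seed: int = 0):
    """Instantiate one (unfitted) base learner."""
    params = dict(params)
    if kind == "knn":
        return KNeighborsClassifier(**params)
    if kind == "lda":
        return PCALDAClassifier(**params)
    if kind == "pls_da":
        return PLSDAClassifier(**params)
    if kind == "svm_linear":
        return SoftmaxSVC(kernel="linear", **params)
    if kind == "svm_rbf":
        return SoftmaxSVC(kernel="rbf", **params)
    if kind == "random_forest":
        params.setdefault("n_estimators", 300)
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    raise ValueError(f"unknown learner kind {kind!r}")


# ---------------------------------------------------------------------------
# splitting

def split_train_test(spectra_set: SpectraSet, spec: SplitSpec | None = None):
    """Disjoint, exhaustive, seed-deterministic train/test split.

    Stratified (default): per-class test counts are round((1 - f) * n_class).
    Unstratified: round((1 - f) * n) spectra drawn at random overall.  Raises
    if any class ends up absent from either side.
    """
    spec = spec or SplitSpec()
    labels = spectra_set.labels
    if any(l is None or (isinstance(l, float) and np.isnan(l)) for l in labels):
        raise ValueError("split requires a fully labelled set")
    labels = labels.astype(str)
    classes = np.unique(labels)
    rng = np.random.default_rng(spec.seed)
    n = len(spectra_set)
    test_frac = 1.0 - spec.train_fraction

    if spec.stratified:
        test_idx: list[int] = []
        for c in classes:
            idx = np.flatnonzero(labels == c)
            n_test_c = int(np.round(test_frac * idx.size))
            perm = rng.permutation(idx)
            test_idx.extend(perm[:n_test_c].tolist())
        test_idx = np.sort(np.array(test_idx, dtype=int))
    else:
        n_test = int(np.round(test_frac * n))
        perm = rng.permutation(n)
        test_idx = np.sort(perm[:n_test])

    mask = np.zeros(n, dtype=bool)
    mask[test_idx] = True
    train, test = spectra_set.subset(~mask), spectra_set.subset(mask)
    for side, name in ((train, "train"), (test, "test")):
        present = set(np.unique(side.labels.astype(str)))
        missing = set(classes) - present
        if missing:
            raise ValueError(f"classes {sorted(missing)} absent from the {name} set")
    return train, test


# ---------------------------------------------------------------------------
# tuning + stacking

@dataclass
class TunedLearner:
    kind: str
    estimator: object  # fitted on the full training set
    params: dict
    cv_accuracy: float  # mean over repeats of out-of-fold accuracy
    oof_proba: np.ndarray  # (n_train, n_classes), averaged over repeats


def _aligned_proba(estimator, X, class_order: np.ndarray) -> np.ndarray:
    p = estimator.predict_proba(X)
    cols = {c: j for j, c in enumerate(estimator.classes_)}
    out = np.zeros((p.shape[0], class_order.size))
    for j, c in enumerate(class_order):
        if c in cols:
            out[:, j] = p[:, cols[c]]
    return out


def _proba_to_meta(proba: np.ndarray, mode: str) -> np.ndarray:
    if mode == "proba":
        return proba
    if mode == "label":  # hard-label one-hot
        out = np.zeros_like(proba)
        out[np.arange(proba.shape[0]), np.argmax(proba, axis=1)] = 1.0
        return out
    raise ValueError(f"unknown meta-feature mode {mode!r}")


def _tune_learner(kind, grid, X, y, class_order, cv: CVSpec, seed: int) -> TunedLearner:
    folds = list(
        RepeatedStratifiedKFold(
            n_splits=cv.folds, n_repeats=cv.repeats, random_state=cv.seed
        ).split(X, y)
    )
    n, n_cls = len(y), class_order.size
    best = None
    for gi, params in enumerate(grid):
        oof = np.zeros((cv.repeats, n, n_cls))
        for fi, (tr, va) in enumerate(folds):
            est = make_estimator(kind, params, seed)
            est.fit(X[tr], y[tr])
            oof[fi // cv.folds, va] = _aligned_proba(est, X[va], class_order)
        accs = [
            float(np.mean(class_order[np.argmax(oof[r], axis=1)] == y))
            for r in range(cv.repeats)
        ]
        score = float(np.mean(accs))
        if best is None or score > best[0]:
            best = (score, gi, params, oof)
    score, _, params, oof = best
    final = make_estimator(kind, params, seed)
    final.fit(X, y)
    return TunedLearner(
        kind=kind,
        estimator=final,
        params=dict(params),
        cv_accuracy=score,
        oof_proba=oof.mean(axis=0),
    )


def fit_base_learners(
    train: SpectraSet | np.ndarray,
    labels=None,
    specs: list[BaseLearnerSpec] | None = None,
    cv: CVSpec | None = None,
    seed: int = 0,
    meta_mode: str = "proba",
):
    """Tune and fit the six base learners; return (learners, meta_features).

    ``train`` may be a labelled SpectraSet (labels taken from metadata) or a
    raw matrix with ``labels``.  Meta-features are the out-of-fold class
    probabilities of each learner, averaged over CV repeats, laid out as
    learner-major blocks of ``n_classes`` columns in :data:`LEARNER_ORDER`.
    """
    if isinstance(train, SpectraSet):
        X = train.intensities
        y = train.labels.astype(str)
    else:
        X = np.asarray(train, dtype=float)
        if labels is None:
            raise ValueError("labels required when passing a raw matrix")
        y = np.asarray(labels).astype(str)
    cv = cv or CVSpec()
    specs = specs if specs is not None else default_specs()
    class_order = np.unique(y)
    smallest = min(int((y == c).sum()) for c in class_order)
    if cv.folds > smallest:
        raise ValueError(
            f"fold count {cv.folds} exceeds the smallest class size {smallest}"
        )

    learners: dict[str, TunedLearner] = {}
    blocks = []
    by_kind = {s.kind: s for s in specs}
    for kind in LEARNER_ORDER:
        if kind not in by_kind:
            continue
        tuned = _tune_learner(kind, by_kind[kind].grid, X, y, class_order, cv, seed)
        by_kind[kind].tuned_params = tuned.params
        learners[kind] = tuned
        blocks.append(_proba_to_meta(tuned.oof_proba, meta_mode))
    meta_features = np.hstack(blocks)
    return learners, meta_features, class_order


GBM_GRID = [
    {"n_estimators": t, "max_depth": d} for t in (50, 100, 150) for d in (1, 2)
]


@dataclass
class StackedClassifierBundle:
    """Six fitted base learners + GBM meta-learner + full provenance."""

    base_learners: dict[str, TunedLearner]
    meta_learner: object
    meta_params: dict
    meta_cv_accuracy: float
    class_order: np.ndarray
    cv: CVSpec
    seed: int
    wavenumbers: np.ndarray
    meta_mode: str = "proba"

    @property
    def meta_layout(self) -> list[tuple[str, str]]:
        """(learner, class) per meta-feature column."""
        return [
            (kind, str(c))
            for kind in LEARNER_ORDER
            if kind in self.base_learners
            for c in self.class_order
        ]


def fit_stacked(
    meta_features: np.ndarray,
    labels,
    cv: CVSpec | None = None,
    base_learners: dict[str, TunedLearner] | None = None,
    class_order: np.ndarray | None = None,
    seed: int = 0,
    wavenumbers: np.ndarray | None = None,
    meta_mode: str = "proba",
) -> StackedClassifierBundle:
    """Tune and fit the GBM meta-learner on out-of-fold meta-features."""
    meta_features = np.asarray(meta_features, dtype=float)
    y = np.asarray(labels).astype(str)
    if meta_features.shape[0] != y.size:
        raise ValueError(
            f"meta-feature rows ({meta_features.shape[0]}) != labels ({y.size})"
        )
    cv = cv or CVSpec()
    if class_order is None:
        class_order = np.unique(y)

    folds = list(
        RepeatedStratifiedKFold(
            n_splits=cv.folds, n_repeats=cv.repeats, random_state=cv.seed
        ).split(meta_features, y)
    )
    best = None
    for gi, params in enumerate(GBM_GRID):
        correct = np.zeros(cv.repeats)
        for fi, (tr, va) in enumerate(folds):
            gbm = GradientBoostingClassifier(
                learning_rate=0.1, random_state=seed, **params
            )
            gbm.fit(meta_features[tr], y[tr])
            correct[fi // cv.folds] += (gbm.predict(meta_features[va]) == y[va]).sum()
        score = float(np.mean(correct / y.size))
        if best is None or score > best[0]:
            best = (score, gi, params)
    score, _, params = best
    meta = GradientBoostingClassifier(learning_rate=0.1, random_state=seed, **params)
    meta.fit(meta_features, y)
    return StackedClassifierBundle(
        base_learners=base_learners or {},
        meta_learner=meta,
        meta_params=dict(params),
        meta_cv_accuracy=score,
        class_order=np.asarray(class_order),
        cv=cv,
        seed=seed,
        wavenumbers=np.asarray(wavenumbers) if wavenumbers is not None else np.array([]),
        meta_mode=meta_mode,
    )


def train_stacked(
    train: SpectraSet,
    specs: list[BaseLearnerSpec] | None = None,
    cv: CVSpec | None = None,
    seed: int = 0,
    meta_mode: str = "proba",
) -> StackedClassifierBundle:
    """Convenience: fit base learners then the stacked meta-learner."""
    learners, meta_features, class_order = fit_base_learners(
        train, specs=specs, cv=cv, seed=seed, meta_mode=meta_mode
    )
    return fit_stacked(
        meta_features,
        train.labels.astype(str),
        cv=cv,
        base_learners=learners,
        class_order=class_order,
        seed=seed,
        wavenumbers=train.wavenumbers,
        meta_mode=meta_mode,
    )


def _bundle_meta_row(bundle: StackedClassifierBundle, X: np.ndarray) -> np.ndarray:
    blocks = []
    for kind in LEARNER_ORDER:
        if kind not in bundle.base_learners:
            continue
        proba = _aligned_proba(bundle.base_learners[kind].estimator, X, bundle.class_order)
        blocks.append(_proba_to_meta(proba, bundle.meta_mode))
    return np.hstack(blocks)


def predict_stacked(bundle: StackedClassifierBundle, data) -> np.ndarray:
    """Predict labels for a SpectraSet or matrix with the stacked model.

    Ties in meta-learner probability break toward the earlier class in the
    bundle's recorded class order.
    """
    X = data.intensities if isinstance(data, SpectraSet) else np.atleast_2d(np.asarray(data, float))
    if bundle.wavenumbers.size and X.shape[1] != bundle.wavenumbers.size:
        raise ValueError(
            f"input has {X.shape[1]} channels, bundle expects {bundle.wavenumbers.size}"
        )
    meta_X = _bundle_meta_row(bundle, X)
    proba = _aligned_proba(bundle.meta_learner, meta_X, bundle.class_order)
    return bundle.class_order[np.argmax(proba, axis=1)]


# ---------------------------------------------------------------------------
# evaluation

def confusion(predicted, reference, class_order) -> pd.DataFrame:
    """Prediction-by-reference count matrix: entry (i, j) counts spectra
    predicted class i whose reference is class j."""
    predicted = np.asarray(predicted).astype(str)
    reference = np.asarray(reference).astype(str)
    if predicted.size == 0:
        raise ValueError("empty label vectors")
    if predicted.size != reference.size:
        raise ValueError("predicted and reference lengths differ")
    class_order = [str(c) for c in class_order]
    known = set(class_order)
    stray = (set(predicted) | set(reference)) - known
    if stray:
        raise ValueError(f"labels outside class_order: {sorted(stray)}")
    matrix = pd.DataFrame(
        0,
        index=pd.Index(class_order, name="predicted"),
        columns=pd.Index(class_order, name="reference"),
        dtype=int,
    )
    for p, r in zip(predicted, reference):
        matrix.loc[p, r] += 1
    return matrix


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix
    arr = np.asarray(matrix)
    names = [str(i) for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=pd.Index(names, name="predicted"),
                        columns=pd.Index(names, name="reference"))


def sensitivity(matrix, cls) -> float:
    """100 * correctly-predicted / reference total for the class, 1 decimal."""
    m = _as_frame(matrix)
    cls = str(cls)
    total = int(m[cls].sum())
    if total == 0:
        raise ValueError(f"class {cls!r} has no reference spectra")
    return round(100.0 * int(m.loc[cls, cls]) / total, 1)


def specificity(matrix, cls) -> float:
    """100 * other-class spectra not predicted as the class / other-class total."""
    m = _as_frame(matrix)
    cls = str(cls)
    negatives = int(m.to_numpy().sum()) - int(m[cls].sum())
    if negatives == 0:
        raise ValueError(f"class {cls!r} has no negatives")
    false_pos = int(m.loc[cls].sum()) - int(m.loc[cls, cls])
    return round(100.0 * (negatives - false_pos) / negatives, 1)


def overall_accuracy(matrix) -> float:
    """100 * trace / total, 1 decimal."""
    m = _as_frame(matrix)
    total = int(m.to_numpy().sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    return round(100.0 * np.trace(m.to_numpy()) / total, 1)


@dataclass
class EvaluationReport:
    """Confusion matrix + per-class metrics + provenance."""

    confusion: pd.DataFrame
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    overall_accuracy: float
    n_test: int
    provenance: dict = field(default_factory=dict)


def report_from_confusion(matrix: pd.DataFrame, provenance: dict | None = None) -> EvaluationReport:
    """Compute every metric from a prediction-by-reference count matrix."""
    m = _as_frame(matrix)
    return EvaluationReport(
        confusion=m,
        sensitivity={c: sensitivity(m, c) for c in m.columns},
        specificity={c: specificity(m, c) for c in m.index},
        overall_accuracy=overall_accuracy(m),
        n_test=int(m.to_numpy().sum()),
        provenance=provenance or {},
    )


def evaluate(bundle: StackedClassifierBundle, test: SpectraSet) -> EvaluationReport:
    """Predict the test set and derive the full evaluation report."""
    reference = test.labels
    if any(l is None or (isinstance(l, float) and np.isnan(l)) for l in reference):
        raise ValueError("evaluate requires a labelled test set")
    predicted = predict_stacked(bundle, test)
    matrix = confusion(predicted, reference.astype(str), bundle.class_order)
    provenance = {
        "seed": int(bundle.seed),
        "cv": {"folds": bundle.cv.folds, "repeats": bundle.cv.repeats, "seed": bundle.cv.seed},
        "meta_mode": bundle.meta_mode,
        "meta_params": bundle.meta_params,
        "base_params": {k: v.params for k, v in bundle.base_learners.items()},
        "base_cv_accuracy": {k: v.cv_accuracy for k, v in bundle.base_learners.items()},
    }
    return report_from_confusion(matrix, provenance)


# ---------------------------------------------------------------------------
# persistence

def save_bundle(bundle: StackedClassifierBundle, directory) -> None:
    """Persist a bundle as a directory: JSON manifest + joblib'd learners."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "class_order": [str(c) for c in bundle.class_order],
        "cv": {"folds": bundle.cv.folds, "repeats": bundle.cv.repeats, "seed": bundle.cv.seed},
        "seed": int(bundle.seed),
        "meta_mode": bundle.meta_mode,
        "meta_params": bundle.meta_params,
        "meta_cv_accuracy": bundle.meta_cv_accuracy,
        "base_params": {k: v.params for k, v in bundle.base_learners.items()},
        "base_cv_accuracy": {k: v.cv_accuracy for k, v in bundle.base_learners.items()},
        "n_channels": int(bundle.wavenumbers.size),
        "software_version": __version__,
    }
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
        fh.write("\n")
    joblib.dump(
        {
            "base_estimators": {k: v.estimator for k, v in bundle.base_learners.items()},
            "meta_learner": bundle.meta_learner,
            "wavenumbers": bundle.wavenumbers,
        },
        directory / "learners.joblib",
    )


def load_bundle(directory) -> StackedClassifierBundle:
    directory = Path(directory)
    with open(directory / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    payload = joblib.load(directory / "learners.joblib")
    learners = {
        kind: TunedLearner(
            kind=kind,
            estimator=est,
            params=manifest["base_params"][kind],
            cv_accuracy=manifest["base_cv_accuracy"][kind],
            oof_proba=np.array([]),
        )
        for kind, est in payload["base_estimators"].items()
    }
    return StackedClassifierBundle(
        base_learners=learners,
        meta_learner=payload["meta_learner"],
        meta_params=manifest["meta_params"],
        meta_cv_accuracy=manifest["meta_cv_accuracy"],
        class_order=np.array(manifest["class_order"]),
        cv=CVSpec(**manifest["cv"]),
        seed=manifest["seed"],
        wavenumbers=np.asarray(payload["wavenumbers"]),
        meta_mode=manifest["meta_mode"],
    )
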