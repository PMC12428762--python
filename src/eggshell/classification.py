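"""Classifiers mapping (L*, a*, b*) to visual-score categories.

The centerpiece is a from-first-principles multi-class linear discriminant
analysis whose discriminant functions are extractable: the analysis uses the
LD1 coefficient ratios to motivate the simplified color indices, so the
scalings themselves (not just predictions) are part of the contract.  The
scalings solve the generalized eigenproblem of between-class versus pooled
within-class scatter and sphere the within-class covariance (the convention
of standard statistical software), making coefficients comparable across
fits up to the sign of each column.

Comparator models (random forest, RBF-kernel SVM, single-hidden-layer
neural network) wrap scikit-learn estimators with the study's fixed
hyperparameters; no hyperparameter search is performed.

The classification target is the AveObs value treated as a categorical
label: 4 categories for unanimous ("consistent") eggs, up to 13 for the
full or inconsistent scenarios.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .data_model import Dataset, ValidationError


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.70
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValidationError("train_fraction must lie in (0, 1)")


def _allocate(counts: np.ndarray, total_target: int, frac: float) -> np.ndarray:
    """Largest-remainder allocation of per-class train counts.

    Keeps every class represented on both sides where possible
    (1 <= take_c <= n_c - 1 for classes with n_c >= 2).
    """
    quota = counts * frac
    take = np.floor(quota).astype(int)
    hi = np.maximum(counts - 1, 1)
    take = np.clip(take, 1, hi)
    order = np.argsort(-(quota - np.floor(quota)))
    i = 0
    while take.sum() < total_target and i < 10 * len(counts):
        c = order[i % len(counts)]
        if take[c] < hi[c]:
            take[c] += 1
        i += 1
    while take.sum() > total_target:
        c = int(np.argmax(take - quota))
        if take[c] > 1:
            take[c] -= 1
        else:
            break
    return take


def split_dataset(ds: Dataset, spec: SplitSpec) -> tuple[Dataset, Dataset]:
    """Deterministic train/test split, stratified by AveObs category."""
    rng = np.random.default_rng(spec.seed)
    n = len(ds)
    target = int(round(spec.train_fraction * n))
    train_mask = np.zeros(n, dtype=bool)
    if spec.stratified:
        ave = ds.aveobs
        classes, inverse = np.unique(ave, return_inverse=True)
        counts = np.bincount(inverse)
        singles = classes[counts < 2]
        if len(singles):
            raise ValidationError(
                f"class {singles[0]} has a single record; cannot stratify"
            )
        take = _allocate(counts, target, spec.train_fraction)
        for c in range(len(classes)):
            rows = np.flatnonzero(inverse == c)
            chosen = rng.permutation(rows)[: take[c]]
            train_mask[chosen] = True
    else:
        chosen = rng.permutation(n)[:target]
        train_mask[chosen] = True
    return ds.subset(train_mask), ds.subset(~train_mask)


# ---------------------------------------------------------------------------
# Linear discriminant analysis
# ---------------------------------------------------------------------------


@dataclass
class LDAModel:
    """Fitted LDA with extractable discriminant functions.

    scalings columns (LD1..LDd) sphere the pooled within-class covariance:
    the within-class covariance of the transformed training data is the
    identity.  proportion_of_trace gives each discriminant's share of the
    between-class variance.
    """

    classes: np.ndarray
    priors: np.ndarray
    means: np.ndarray  # n_classes x p
    pooled_cov: np.ndarray  # p x p, divisor n - g
    scalings: np.ndarray  # p x d
    eigenvalues: np.ndarray  # length d, non-increasing
    proportion_of_trace: np.ndarray  # length d, sums to 1


def fit_lda(X: np.ndarray, y: np.ndarray) -> LDAModel:
    """Fit multi-class LDA by the generalized eigenproblem B v = l W v.

    W is the pooled within-class covariance (divisor n - g); B is the
    prior-weighted between-class scatter.  Eigenvectors are normalized so
    v' W v = 1 and oriented so each column's largest-magnitude coefficient
    is positive.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValidationError("X must be n x p with matching labels")
    classes, inverse = np.unique(y, return_inverse=True)
    g = len(classes)
    n, p = X.shape
    if g < 2:
        raise ValidationError("need at least 2 classes")
    counts = np.bincount(inverse)
    if counts.min() < 2:
        raise ValidationError(
            f"class {classes[np.argmin(counts)]} has fewer than 2 samples"
        )
    means = np.vstack([X[inverse == c].mean(axis=0) for c in range(g)])
    W = np.zeros((p, p))
    for c in range(g):
        d = X[inverse == c] - means[c]
        W += d.T @ d
    W /= n - g
    priors = counts / n
    grand = priors @ means
    dm = means - grand
    B = (dm * counts[:, None]).T @ dm / (g - 1)

    try:
        evals, evecs = scipy.linalg.eigh(B, W)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValidationError(
            "singular pooled within-class covariance; jitter the features "
            "or merge sparse classes"
        ) from exc
    if not np.isfinite(evals).all():
        raise ValidationError(
            "singular pooled within-class covariance; jitter the features "
            "or merge sparse classes"
        )
    order = np.argsort(evals)[::-1]
    d = min(p, g - 1)
    evals = np.clip(evals[order][:d], 0, None)
    scalings = evecs[:, order][:, :d]
    # eigh(B, W) already gives v' W v = 1; fix each column's sign
    for j in range(scalings.shape[1]):
        i = np.argmax(np.abs(scalings[:, j]))
        if scalings[i, j] < 0:
            scalings[:, j] = -scalings[:, j]
    total = evals.sum()
    prop = evals / total if total > 0 else np.full(d, np.nan)
    return LDAModel(
        classes=classes,
        priors=priors,
        means=means,
        pooled_cov=W,
        scalings=scalings,
        eigenvalues=evals,
        proportion_of_trace=prop,
    )


def predict_lda(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Gaussian equal-covariance Bayes rule with the training priors."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.means.shape[1]:
        raise ValidationError(
            f"expected n x {model.means.shape[1]} feature matrix"
        )
    Winv_mu = np.linalg.solve(model.pooled_cov, model.means.T)  # p x g
    const = -0.5 * np.einsum("ij,ji->i", model.means, Winv_mu) + np.log(
        model.priors
    )
    scores = X @ Winv_mu + const[None, :]
    return model.classes[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# Comparator classifiers
# ---------------------------------------------------------------------------


class Algorithm(str, enum.Enum):
    LDA = "LDA"
    RF = "RF"
    SVM_RBF = "SVM_RBF"
    NNET = "NNET"


@dataclass(frozen=True)
class ComparatorSpec:
    algorithm: Algorithm = Algorithm.LDA
    cv_folds: int = 10

    def __post_init__(self):
        object.__setattr__(self, "algorithm", Algorithm(self.algorithm))
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")


class _LDAEstimator(ClassifierMixin, BaseEstimator):
    """sklearn-compatible wrapper around the in-house LDA (for k-fold CV)."""

    def fit(self, X, y):
        self.model_ = fit_lda(X, y)
        self.classes_ = self.model_.classes
        return self

    def predict(self, X):
        return predict_lda(self.model_, X)

    @property
    def model(self) -> LDAModel | None:
        return getattr(self, "model_", None)


@dataclass
class FittedClassifier:
    """A trained classifier with a uniform predict contract."""

    spec: ComparatorSpec
    estimator: object
    classes: np.ndarray
    cv_accuracy: float
    lda: LDAModel | None = None  # populated for the LDA algorithm

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(np.asarray(X, dtype=float)))


def _build_estimator(spec: ComparatorSpec, seed: int):
    alg = Algorithm(spec.algorithm)
    if alg is Algorithm.LDA:
        return _LDAEstimator()
    if alg is Algorithm.RF:
        # 500 trees, sqrt(p) candidate features per split
        return RandomForestClassifier(
            n_estimators=500, max_features="sqrt", random_state=seed
        )
    if alg is Algorithm.SVM_RBF:
        # radial basis kernel with automatic feature scaling
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed))
    if alg is Algorithm.NNET:
        # one hidden layer of 10 sigmoid units; inputs standardized to keep
        # the sigmoid out of saturation
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(10,),
                activation="logistic",
                max_iter=2000,
                random_state=seed,
            ),
        )
    raise ValidationError(f"unknown algorithm {spec.algorithm!r}")


def fit_comparator(
    spec: ComparatorSpec, train: Dataset, seed: int = 0
) -> FittedClassifier:
    """Train one of the four algorithms on a dataset's colors vs AveObs.

    Labels are the AveObs categories of the training set.  k-fold CV
    accuracy is recorded with the fold count reduced to the smallest class
    size when a class is rarer than the requested folds.
    """
    X = train.colors
    y = train.aveobs.astype(str)  # categorical labels
    est = _build_estimator(spec, seed)
    _, counts = np.unique(y, return_counts=True)
    folds = int(min(spec.cv_folds, counts.min()))
    if folds >= 2:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        cv_acc = float(np.mean(cross_val_score(est, X, y, cv=skf)))
    else:
        cv_acc = float("nan")
    est.fit(X, y)
    return FittedClassifier(
        spec=spec,
        estimator=est,
        classes=np.unique(y),
        cv_accuracy=cv_acc,
        lda=getattr(est, "model", None),
    )
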