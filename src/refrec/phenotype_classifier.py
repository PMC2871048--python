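"""Growth-phenotype prediction from knockout damage profiles.

A strain's damage profile (which merged variables its knockout blocks)
is used to predict viability.  The pipeline per training round is:

1. *feature selection* — compute essentiality scores on the training rows
   only and keep the variables whose score is strictly greater than a
   threshold (default 0.5);
2. *training* — fit a maximum-margin (linear soft-margin SVM) classifier
   on the blocked-indicator vectors of the training strains;
3. *prediction* — a test strain is labeled by the side of the hyperplane
   its vector falls on; a vector exactly on the boundary is conservatively
   predicted viable (the majority class).

Evaluation uses repeated randomized hold-out with class-count-controlled
training sets (a fixed number of inviable and viable training strains
drawn without replacement, the remainder held out), reporting the true
positive rate (inviable correctly predicted) and false positive rate
(viable predicted inviable) per repeat with mean and standard deviation.

:class:`ViabilityClassifier` is a scikit-learn compatible estimator and
composes with sklearn model selection; the module-level functions are
thin wrappers over it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .essentiality import (INVIABLE, VIABLE, FeasibilityMatrix,
                           _phenotype_vector)


class SingleClassError(ValueError):
    """Training data contained only one phenotype class."""


class FeatureMismatchError(ValueError):
    """Prediction input does not match the fitted feature space."""


@dataclass
class SplitConfig:
    """Hold-out design: class counts, repetitions and seed."""

    n_train: int
    n_train_inviable: int
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_train_inviable > self.n_train:
            raise ValueError("n_train_inviable exceeds n_train")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class EvalResult:
    """Per-repeat and aggregate TPR/FPR of a hold-out evaluation."""

    tpr: np.ndarray
    fpr: np.ndarray
    n_features: np.ndarray

    @property
    def mean_tpr(self) -> float:
        return float(np.mean(self.tpr))

    @property
    def sd_tpr(self) -> float:
        return float(np.std(self.tpr, ddof=0))

    @property
    def mean_fpr(self) -> float:
        return float(np.mean(self.fpr))

    @property
    def sd_fpr(self) -> float:
        return float(np.std(self.fpr, ddof=0))


class ViabilityClassifier(BaseEstimator, ClassifierMixin):
    """Essentiality-score feature selection + linear soft-margin SVM.

    Parameters
    ----------
    score_threshold : float, default=0.5
        A variable becomes a feature when its training essentiality score
        is strictly greater than this; variables never blocked in training
        (undefined score) are excluded.
    C : float, default=1.0
        Soft-margin constant of the SVM.  The margin is maximal subject to
        hinge penalties; a soft margin absorbs label noise in real data.

    Attributes
    ----------
    feature_indices_ : ndarray
        Column indices selected as features.  May be empty, in which case
        the classifier predicts the training majority class.
    svm_ : sklearn.svm.SVC
        The fitted linear-kernel SVM (absent when no feature passed).
    classes_ : ndarray of shape (2,)
        ``[False, True]`` with ``True`` = inviable.

    Notes
    -----
    ``X`` is the binary feasibility matrix (``True`` = feasible); ``y``
    is boolean with ``True`` = inviable.  Internally features are blocked
    indicators, so an all-feasible strain maps to the zero vector.
    """

    def __init__(self, score_threshold: float = 0.5, C: float = 1.0):
        self.score_threshold = score_threshold
        self.C = C

    def fit(self, X, y):
        X = np.asarray(X, dtype=bool)
        y = np.asarray(y, dtype=bool)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2D with one label per row")
        if y.all() or not y.any():
            raise SingleClassError(
                "training set needs both viable and inviable samples")
        blocked = ~X
        n_blocking = blocked.sum(axis=0)
        n_lethal = blocked[y].sum(axis=0)
        with np.errstate(invalid="ignore"):
            scores = n_lethal / np.maximum(n_blocking, 1)
        selected = (n_blocking > 0) & (scores > self.score_threshold)
        self.feature_indices_ = np.flatnonzero(selected)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([False, True])
        self.majority_ = bool(y.sum() * 2 > y.size)
        if self.feature_indices_.size == 0:
            warnings.warn("no variable passed feature selection; "
                          "predicting the majority class", stacklevel=2)
            self.svm_ = None
            return self
        self.svm_ = SVC(kernel="linear", C=self.C)
        self.svm_.fit(blocked[:, self.feature_indices_].astype(float), y)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "feature_indices_")
        X = np.asarray(X, dtype=bool)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise FeatureMismatchError(
                f"expected {self.n_features_in_} columns, got "
                f"{X.shape[1] if X.ndim == 2 else 'non-2D'}")
        if self.svm_ is None:
            return np.full(X.shape[0], -1.0 if not self.majority_ else 1.0)
        blocked = (~X)[:, self.feature_indices_].astype(float)
        return self.svm_.decision_function(blocked)

    def predict(self, X):
        # strictly positive decision -> inviable; the boundary itself is
        # resolved toward the (majority) viable class
        return self.decision_function(X) > 0


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def select_features(train_matrix: FeasibilityMatrix, train_phenotypes,
                    score_threshold: float = 0.5):
    """Variable ids whose training essentiality score is > threshold."""
    from .essentiality import essentiality_scores

    scores = essentiality_scores(train_matrix, train_phenotypes)
    mask = scores["score"] > score_threshold  # NaN compares False
    return list(scores.index[mask])


def train_classifier(X, y, C: float = 1.0,
                     score_threshold: float = 0.5) -> ViabilityClassifier:
    """Fit a :class:`ViabilityClassifier` on feasibility rows X and
    boolean inviable labels y."""
    return ViabilityClassifier(score_threshold=score_threshold, C=C).fit(X, y)


def predict(model: ViabilityClassifier, samples):
    """Predict phenotype labels ('viable'/'inviable') for feasibility rows."""
    pred = model.predict(samples)
    return [INVIABLE if p else VIABLE for p in pred]


def evaluate_holdout(matrix: FeasibilityMatrix, phenotypes,
                     config: SplitConfig,
                     score_threshold: float = 0.5,
                     C: float = 1.0) -> EvalResult:
    """Repeated randomized hold-out evaluation.

    Each repeat draws ``config.n_train_inviable`` inviable and
    ``config.n_train - config.n_train_inviable`` viable strains without
    replacement into the training set; the remaining strains form the
    test set.  Features are selected and the SVM trained on the training
    rows only, then TPR and FPR are measured on the held-out rows.
    Fully reproducible from ``config.seed``.
    """
    y = _phenotype_vector(matrix, phenotypes)
    X = matrix.values
    inviable_idx = np.flatnonzero(y)
    viable_idx = np.flatnonzero(~y)
    n_v = config.n_train - config.n_train_inviable
    if len(inviable_idx) <= config.n_train_inviable:
        raise ValueError(
            f"need > {config.n_train_inviable} inviable strains, "
            f"have {len(inviable_idx)}")
    if len(viable_idx) <= n_v:
        raise ValueError(
            f"need > {n_v} viable strains, have {len(viable_idx)}")

    rng = np.random.default_rng(config.seed)
    tpr, fpr, nfeat = [], [], []
    for _ in range(config.n_repeats):
        train = np.concatenate([
            rng.choice(inviable_idx, config.n_train_inviable, replace=False),
            rng.choice(viable_idx, n_v, replace=False)])
        test_mask = np.ones(len(y), dtype=bool)
        test_mask[train] = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty-feature fallback is valid
            clf = ViabilityClassifier(
                score_threshold=score_threshold, C=C).fit(X[train], y[train])
        pred = clf.predict(X[test_mask])
        truth = y[test_mask]
        tpr.append(pred[truth].mean() if truth.any() else np.nan)
        fpr.append(pred[~truth].mean() if (~truth).any() else np.nan)
        nfeat.append(clf.feature_indices_.size)
    return EvalResult(tpr=np.array(tpr), fpr=np.array(fpr),
                      n_features=np.array(nfeat))
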