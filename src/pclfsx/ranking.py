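"""Feature orderings: principal-component-loading ranking, classifier
importances, and a recursive-feature-elimination baseline.

The PCLFS ranking scores each feature by the sum of the absolute values of
its loadings on the first two principal components of the (column-standardised)
training matrix. Loadings are the coefficients of the original variables in
the principal components' linear combinations, so a feature that contributes
heavily to the dominant axes of variation ranks high. Because absolute values
are taken, the sign indeterminacy of eigenvectors is irrelevant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import RFECV
from sklearn.model_selection import StratifiedKFold

from ._classifiers import make_classifier
from .datagen import Dataset

logger = logging.getLogger(__name__)

__all__ = [
    "RankedFeatures",
    "ImportanceScores",
    "pc_loadings",
    "pclfs_rank",
    "classifier_importance",
    "rfe_select",
]


@dataclass
class RankedFeatures:
    """A permutation of feature indices, most informative first, with the
    per-feature ranking score (sum of absolute first-two PC loadings)."""

    order: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        n = self.order.shape[0]
        if sorted(self.order.tolist()) != list(range(n)):
            raise ValueError("order must be a permutation of 0..n-1")
        if self.scores.shape[0] != n:
            raise ValueError("scores length must match order")

    @property
    def n_features(self) -> int:
        return self.order.shape[0]


@dataclass
class ImportanceScores:
    """Non-negative importances aligned to an active (PCLFS-ordered) feature
    prefix, plus the id of the classifier they came from."""

    values: np.ndarray
    classifier_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("importances must be non-negative")


def _standardize(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant column(s) during standardisation; dividing by 1", constant.sum()
        )
        sd = np.where(constant, 1.0, sd)
    return Xc / sd


def pc_loadings(X: np.ndarray, standardize: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """First two principal axes of X as unit-norm loading vectors.

    Columns are z-scored first by default (correlation-matrix PCA), so the
    ranking is invariant to per-feature scale. With a single feature the
    second vector is all zeros.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("X must be a 2-D matrix with at least 2 rows and 1 column")
    Z = _standardize(X) if standardize else X - X.mean(axis=0)
    n = Z.shape[1]
    if n == 1:
        return np.array([1.0]), np.array([0.0])
    cov = np.cov(Z, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    # eigh returns ascending order
    return eigvecs[:, -1].copy(), eigvecs[:, -2].copy()


def pclfs_rank(X: np.ndarray, standardize: bool = True) -> RankedFeatures:
    """Rank features by |L1| + |L2| over the first two PC loading vectors,
    descending; ties break toward the lower original column index."""
    l1, l2 = pc_loadings(X, standardize=standardize)
    scores = np.abs(l1) + np.abs(l2)
    # round before ordering so numerically-equal scores (e.g. duplicated
    # columns) tie-break by column index instead of eigensolver noise
    order = np.lexsort((np.arange(scores.size), -np.round(scores, 10)))
    return RankedFeatures(order=order, scores=scores)


def classifier_importance(model, n_active: int, classifier_id: str = "") -> ImportanceScores:
    """Extract per-feature importances from a fitted classifier.

    Linear models yield |coefficients|; trees and ensembles yield
    impurity-based importances. Only the relative order matters downstream.
    """
    if hasattr(model, "coef_"):
        values = np.abs(np.asarray(model.coef_)).reshape(-1)
    elif hasattr(model, "feature_importances_"):
        values = np.asarray(model.feature_importances_, dtype=float)
    else:
        raise TypeError(
            f"classifier {type(model).__name__} exposes neither coef_ nor feature_importances_"
        )
    if values.shape[0] != n_active:
        raise ValueError(
            f"model was fitted on {values.shape[0]} features, expected {n_active}"
        )
    return ImportanceScores(values=values, classifier_id=classifier_id or type(model).__name__)


def rfe_select(
    train: Dataset,
    classifier_id: str | BaseEstimator = "logit",
    step: int = 1,
    cv_folds: int = 5,
    scoring: str = "f1",
    seed: int = 0,
) -> np.ndarray:
    """Recursive feature elimination with the subset size chosen by
    cross-validated F1: drop the `step` least-important features per round,
    score every stage with stratified CV, keep the best-scoring stage.

    Returns the selected feature indices. Per-size CV scores are logged.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    est = make_classifier(classifier_id, seed=seed)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    selector = RFECV(est, step=step, cv=cv, scoring=scoring, min_features_to_select=1)
    selector.fit(train.X, train.y)
    sizes = selector.cv_results_["n_features"]
    means = selector.cv_results_["mean_test_score"]
    for size, score in zip(sizes, means):
        logger.info("RFE cv %s at %d features: %.4f", scoring, size, score)
    return np.flatnonzero(selector.support_)
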