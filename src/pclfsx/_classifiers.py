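"""Classifier registry shared by the ranking, selection and simulation modules.

String ids keep configuration files and CLI flags readable; every entry
provides an importance notion (|coefficients| for linear models,
impurity-based importances for trees/ensembles).
"""

from __future__ import annotations

import warnings

from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

__all__ = ["make_classifier", "available_classifiers", "CLASSIFIER_IDS"]

CLASSIFIER_IDS = ("logit", "svm_linear", "decision_tree", "random_forest", "gbm")


def _make_gbm(seed: int):
    try:
        from lightgbm import LGBMClassifier
    except ImportError:  # pragma: no cover - depends on install extras
        return None
    return LGBMClassifier(random_state=seed, verbose=-1, n_estimators=100)


def make_classifier(classifier_id: str | BaseEstimator, seed: int = 0) -> BaseEstimator:
    """Instantiate a fresh, seed-controlled classifier.

    An estimator instance is cloned (so repeated fits start fresh) and given
    the seed where it accepts one.
    """
    if isinstance(classifier_id, BaseEstimator):
        est = clone(classifier_id)
        if "random_state" in est.get_params():
            est.set_params(random_state=seed)
        return est
    if classifier_id == "logit":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if classifier_id == "svm_linear":
        return LinearSVC(max_iter=5000, random_state=seed)
    if classifier_id == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if classifier_id == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if classifier_id == "gbm":
        est = _make_gbm(seed)
        if est is None:
            raise ImportError(
                "classifier 'gbm' requires lightgbm; install pclfsx[gbm]"
            )
        return est
    raise ValueError(f"unknown classifier_id {classifier_id!r}; known: {CLASSIFIER_IDS}")


def available_classifiers() -> tuple[str, ...]:
    """The registry ids usable in this installation (drops gbm with a warning
    when lightgbm is absent)."""
    ids = list(CLASSIFIER_IDS)
    if _make_gbm(0) is None:  # pragma: no cover
        warnings.warn("lightgbm not installed; dropping 'gbm' from the classifier set")
        ids.remove("gbm")
    return tuple(ids)
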