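"""Core of the method: sequential F1 grid scoring, PCLFS maximum selection,
and the PCLFS-ext gradient-threshold rule.

PCLFS fits a nested sequence of models — the first i features of the
PC-loading order, for i = 1..n — scores each on held-out data with the
minority-class F1, and keeps the smallest subset attaining the maximum grid
score, n_pclfs. The extension inspects the local maxima of the grid below
n_pclfs, joins each to the maximum point, and accepts the smallest subset
whose per-feature F1-loss gradient toward the maximum,

    gradient_j = (g_{n_pclfs} - g_j) / (n_pclfs - j),

is strictly below the threshold t = T/n, where T is the user's maximum
tolerable total F1 reduction and n the dataset's total feature count. The
threshold therefore reads as the tolerable F1 loss per removed feature. When
no local maximum qualifies, the PCLFS selection is returned unchanged
(fallback). The final subset takes the n_proposed features with the highest
classifier importance among the n_pclfs active ones.

Grid indices are 1-based subset sizes in all public values (matching the
g_j notation); arrays are stored 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from ._classifiers import make_classifier
from .datagen import Dataset, SmoteConfig
from .datagen import smote as _smote
from .datagen import split as _split
from .metrics import f1_score
from .ranking import ImportanceScores, RankedFeatures, classifier_importance, pclfs_rank

__all__ = [
    "GridScores",
    "PclfsResult",
    "ExtSelection",
    "grid_scores",
    "pclfs_select",
    "local_maxima",
    "threshold",
    "ext_select",
    "ext_subset",
    "run_pclfs_ext",
    "PCLFS",
    "PCLFSExt",
]


@dataclass
class GridScores:
    """F1 grid: g[i-1] is the held-out F1 of the model trained on the first i
    features of the ranking order."""

    g: np.ndarray
    order_ref: RankedFeatures

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        if self.g.ndim != 1 or self.g.size == 0:
            raise ValueError("g must be a non-empty vector")
        if ((self.g < 0) | (self.g > 1)).any():
            raise ValueError("grid scores must lie in [0, 1]")

    def __len__(self) -> int:
        return self.g.size

    def score_at(self, j: int) -> float:
        """g_j for a 1-based subset size j."""
        return float(self.g[j - 1])


@dataclass
class PclfsResult:
    grid: GridScores
    n_pclfs: int
    importances: ImportanceScores

    def __post_init__(self) -> None:
        if not 1 <= self.n_pclfs <= len(self.grid):
            raise ValueError("n_pclfs out of range")
        if self.importances.values.shape[0] != self.n_pclfs:
            raise ValueError("importances must align to the first n_pclfs features")

    @property
    def selected(self) -> np.ndarray:
        """Original feature indices of the PCLFS selection."""
        return self.grid.order_ref.order[: self.n_pclfs]

    @property
    def f1(self) -> float:
        return self.grid.score_at(self.n_pclfs)


@dataclass
class ExtSelection:
    T: float
    t: float
    candidates: list[tuple[int, float, float]]  # (j, g_j, gradient_j), 1-based j
    n_proposed: int
    subset: np.ndarray
    fallback: bool
    f1_at_proposed: float | None = None

    def __post_init__(self) -> None:
        self.subset = np.asarray(self.subset, dtype=int)
        if self.subset.shape[0] != self.n_proposed:
            raise ValueError("subset size must equal n_proposed")


def grid_scores(
    train: Dataset,
    test: Dataset,
    ranking: RankedFeatures,
    classifier_id="logit",
    seed: int = 0,
) -> GridScores:
    """Fit a fresh classifier per nested subset and record held-out minority-class F1."""
    n = ranking.n_features
    g = np.empty(n)
    for i in range(1, n + 1):
        cols = ranking.order[:i]
        model = make_classifier(classifier_id, seed=seed)
        try:
            model.fit(train.X[:, cols], train.y)
            pred = model.predict(test.X[:, cols])
        except Exception as exc:  # noqa: BLE001 - re-raised with subset context
            raise RuntimeError(f"classifier failed at subset size {i}") from exc
        g[i - 1] = f1_score(test.y, pred)
    return GridScores(g=g, order_ref=ranking)


def pclfs_select(grid: GridScores) -> int:
    """Smallest subset size attaining the maximum grid score."""
    return int(np.argmax(grid.g)) + 1


def local_maxima(grid: GridScores, n_pclfs: int) -> list[int]:
    """1-based sizes j < n_pclfs with g_j strictly above both neighbours.

    The missing left neighbour of j = 1 counts as -inf, so an initial peak
    qualifies; j = n_pclfs - 1 compares against the maximum itself and can
    never qualify.
    """
    g = grid.g
    out = []
    for j in range(1, n_pclfs):  # j is a 1-based size; g[j-1] its score
        left = g[j - 2] if j >= 2 else -np.inf
        right = g[j]  # j < n_pclfs <= len(g), so g[j] always exists
        if g[j - 1] > max(left, right):
            out.append(j)
    return out


def threshold(T: float, n: int) -> float:
    """t = T/n: the tolerable F1 loss per removed feature. `n` is the TOTAL
    feature count of the dataset, not the PCLFS subset size."""
    if T < 0:
        raise ValueError("T must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    return T / n


def ext_select(grid: GridScores, n_pclfs: int, t: float) -> tuple[int, bool]:
    """Smallest local-maximum size whose gradient toward the maximum is
    strictly below t; falls back to the PCLFS size when none qualifies."""
    if t < 0:
        raise ValueError("t must be >= 0")
    g_max = grid.score_at(n_pclfs)
    for j in local_maxima(grid, n_pclfs):
        gradient = (g_max - grid.score_at(j)) / (n_pclfs - j)
        if gradient < t:
            return j, False
    return n_pclfs, True


def candidate_gradients(grid: GridScores, n_pclfs: int) -> list[tuple[int, float, float]]:
    """(j, g_j, gradient_j) for every local-maximum candidate."""
    g_max = grid.score_at(n_pclfs)
    return [
        (j, grid.score_at(j), (g_max - grid.score_at(j)) / (n_pclfs - j))
        for j in local_maxima(grid, n_pclfs)
    ]


def ext_subset(
    importances: ImportanceScores,
    ranking: RankedFeatures,
    n_proposed: int,
) -> np.ndarray:
    """The n_proposed original feature indices with highest importance among
    the active (first len(importances)) ordered features; ties break by
    PCLFS rank."""
    n_active = importances.values.shape[0]
    if n_proposed > n_active:
        raise ValueError("n_proposed exceeds the number of active features")
    # stable sort on descending importance keeps PCLFS order among ties
    pick = np.argsort(-importances.values, kind="stable")[:n_proposed]
    return ranking.order[:n_active][pick]


def run_pclfs_ext(
    train: Dataset,
    test: Dataset,
    classifier_id="logit",
    T: float = 0.05,
    seed: int = 0,
    standardize: bool = True,
) -> tuple[PclfsResult, ExtSelection]:
    """End-to-end composition: rank on train, grid-score against test, select
    the PCLFS maximum, refit for importances, then apply the gradient rule.

    The realised F1 loss never exceeds the tolerance:
    g_{n_pclfs} - g_{n_proposed} <= t·(n_pclfs - n_proposed) <= T.
    """
    ranking = pclfs_rank(train.X, standardize=standardize)
    grid = grid_scores(train, test, ranking, classifier_id, seed=seed)
    n_pclfs = pclfs_select(grid)

    active = ranking.order[:n_pclfs]
    model = make_classifier(classifier_id, seed=seed)
    model.fit(train.X[:, active], train.y)
    cid = classifier_id if isinstance(classifier_id, str) else type(classifier_id).__name__
    imp = classifier_importance(model, n_pclfs, classifier_id=cid)

    t = threshold(T, ranking.n_features)
    n_proposed, fallback = ext_select(grid, n_pclfs, t)
    subset = ext_subset(imp, ranking, n_proposed)

    loss = grid.score_at(n_pclfs) - grid.score_at(n_proposed)
    assert loss <= t * (n_pclfs - n_proposed) + 1e-12 and loss <= T + 1e-12

    final = make_classifier(classifier_id, seed=seed)
    final.fit(train.X[:, subset], train.y)
    f1_prop = f1_score(test.y, final.predict(test.X[:, subset]))

    pclfs_res = PclfsResult(grid=grid, n_pclfs=n_pclfs, importances=imp)
    ext_res = ExtSelection(
        T=T,
        t=t,
        candidates=candidate_gradients(grid, n_pclfs),
        n_proposed=n_proposed,
        subset=subset,
        fallback=fallback,
        f1_at_proposed=f1_prop,
    )
    return pclfs_res, ext_res


class PCLFS(SelectorMixin, BaseEstimator):
    """Principal-component-loading feature selector.

    Ranks features by the sum of absolute first-two PC loadings of the
    training matrix, scores every nested prefix of the ranking with
    minority-class F1 on an internal stratified validation split, and keeps
    the smallest prefix attaining the maximum.

    Parameters
    ----------
    estimator : str or sklearn classifier, default "logit"
        Registry id ("logit", "svm_linear", "decision_tree", "random_forest",
        "gbm") or an estimator instance exposing coef_ or feature_importances_.
    validation_fraction : float, default 0.25
        Held-out fraction used for the F1 grid.
    smote : bool, default False
        Rebalance the training part of the internal split by synthetic
        minority oversampling before ranking and fitting. The validation part
        is never resampled.
    standardize : bool, default True
        Z-score columns before PCA (correlation-matrix loadings).
    random_state : int, default 0
        Seeds the split, the oversampler and every classifier fit.

    Attributes
    ----------
    ranking_ : RankedFeatures
    grid_scores_ : ndarray of shape (n_features,)
    n_selected_ : int
        The PCLFS subset size (smallest argmax of the grid).
    support_ : ndarray of bool
    importances_ : ImportanceScores
    f1_selected_ : float
        Validation F1 at the selected size.
    """

    _selection_name = "pclfs"

    def __init__(
        self,
        estimator="logit",
        *,
        validation_fraction: float = 0.25,
        smote: bool = False,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.estimator = estimator
        self.validation_fraction = validation_fraction
        self.smote = smote
        self.standardize = standardize
        self.random_state = random_state

    def _prepare(self, X, y) -> tuple[Dataset, Dataset]:
        X, y = check_X_y(X, y, dtype=float)
        self.n_features_in_ = X.shape[1]
        ds = Dataset(X, y, [f"f{j}" for j in range(X.shape[1])])
        train, val = _split(
            ds, test_fraction=self.validation_fraction, stratify=True, seed=self.random_state
        )
        if self.smote:
            train = _smote(train, SmoteConfig(seed=self.random_state))
        return train, val

    def fit(self, X, y):
        train, val = self._prepare(X, y)
        self.ranking_ = pclfs_rank(train.X, standardize=self.standardize)
        grid = grid_scores(train, val, self.ranking_, self.estimator, seed=self.random_state)
        self.grid_scores_ = grid.g
        self._grid = grid
        self.n_selected_ = pclfs_select(grid)
        active = self.ranking_.order[: self.n_selected_]
        model = make_classifier(self.estimator, seed=self.random_state)
        model.fit(train.X[:, active], train.y)
        cid = self.estimator if isinstance(self.estimator, str) else type(self.estimator).__name__
        self.importances_ = classifier_importance(model, self.n_selected_, classifier_id=cid)
        self.f1_selected_ = grid.score_at(self.n_selected_)
        self._set_support(active)
        return self

    def _set_support(self, indices) -> None:
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[np.asarray(indices, dtype=int)] = True
        self.support_ = mask
        self.selected_indices_ = np.sort(np.asarray(indices, dtype=int))

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


class PCLFSExt(PCLFS):
    """PCLFS with the gradient-threshold extension.

    After the PCLFS grid is computed, the local maxima below the PCLFS size
    are tested against the threshold t = T/n; the smallest qualifying size
    becomes n_proposed and the final subset keeps the n_proposed
    highest-importance features among the active ones. Without a qualifying
    candidate the selector falls back to the plain PCLFS result.

    Parameters
    ----------
    T : float, default 0.05
        Maximum tolerable total F1 reduction (user-defined); the realised
        validation-F1 loss of the reduced subset is guaranteed <= T.

    Attributes (beyond PCLFS)
    ----------
    n_pclfs_ : int
    threshold_ : float
    candidates_ : list of (j, g_j, gradient_j)
    fallback_ : bool
    f1_selected_ : float
        Validation F1 of the refitted model on the final subset.
    """

    _selection_name = "pclfs-ext"

    def __init__(
        self,
        estimator="logit",
        *,
        T: float = 0.05,
        validation_fraction: float = 0.25,
        smote: bool = False,
        standardize: bool = True,
        random_state: int = 0,
    ):
        super().__init__(
            estimator,
            validation_fraction=validation_fraction,
            smote=smote,
            standardize=standardize,
            random_state=random_state,
        )
        self.T = T

    def fit(self, X, y):
        train, val = self._prepare(X, y)
        pclfs_res, ext_res = run_pclfs_ext(
            train,
            val,
            classifier_id=self.estimator,
            T=self.T,
            seed=self.random_state,
            standardize=self.standardize,
        )
        self.ranking_ = pclfs_res.grid.order_ref
        self.grid_scores_ = pclfs_res.grid.g
        self._grid = pclfs_res.grid
        self.n_pclfs_ = pclfs_res.n_pclfs
        self.importances_ = pclfs_res.importances
        self.threshold_ = ext_res.t
        self.candidates_ = ext_res.candidates
        self.n_selected_ = ext_res.n_proposed
        self.fallback_ = ext_res.fallback
        self.f1_selected_ = ext_res.f1_at_proposed
        self._set_support(ext_res.subset)
        return self
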