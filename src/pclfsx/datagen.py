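"""Synthetic imbalanced binary-classification data, CSV I/O, splitting and SMOTE.

The generator draws one Gaussian cluster per class. A chosen subset of
``n_informative`` features carries class signal: latent class-dependent
factors with heterogeneous variances are mixed by a random rotation, so the
informative block has a non-spherical within-class covariance and uneven
per-feature signal — the structure real informative blocks (and the usual
library generators) have. The remaining features are standard-normal noise
independent of the label. No redundant (exact linear-combination) or
repeated features are created. The minority class is coded 1 throughout and
is the positive class for F1 scoring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "SynthSpec",
    "SmoteConfig",
    "generate_dataset",
    "split",
    "smote",
    "read_csv",
    "write_csv",
]


@dataclass
class Dataset:
    """A feature matrix with binary labels.

    Parameters
    ----------
    X : ndarray of shape (l, n)
        Numeric feature matrix, no missing values.
    y : ndarray of shape (l,)
        Binary labels; 0 = majority/normal, 1 = minority/abnormal.
    feature_names : list of str
        One name per column of ``X``.
    informative_mask : ndarray of bool, optional
        True where the column carries class signal. Only available for
        simulated data, where the ground truth is known.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    informative_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts disagree")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("y must contain only {0, 1}")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must equal number of columns")
        if self.informative_mask is not None:
            self.informative_mask = np.asarray(self.informative_mask, dtype=bool)
            if self.informative_mask.shape[0] != self.X.shape[1]:
                raise ValueError("informative_mask length must equal number of columns")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def informative_indices(self) -> np.ndarray:
        if self.informative_mask is None:
            raise ValueError("dataset has no informative_mask (real data?)")
        return np.flatnonzero(self.informative_mask)


@dataclass
class SynthSpec:
    """Parameters of the synthetic two-class generator.

    ``class_sep`` is the Euclidean distance from each class centroid to the
    shared midpoint, measured across the whole informative subspace: per
    latent informative axis the centroids sit at ±class_sep/√n_informative,
    so the total centroid distance is 2·class_sep regardless of how many
    informative features there are. The latent axes get variances drawn from
    Uniform(0.5, 2) and are mixed by a random rotation before becoming the
    informative columns. This keeps individual features weakly and unevenly
    informative while the joint informative set separates the classes well —
    the regime in which sequential forward-selection curves rise over the
    informative features and then flatten.

    ``flip_y`` is the fraction of labels flipped at random after generation
    (label noise); 0 by default.
    """

    n_samples: int = 1000
    n_features: int = 30
    n_informative: int = 10
    class_weights: tuple[float, float] = (0.5, 0.5)
    class_sep: float = 1.0
    flip_y: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must lie in [0, n_features]")
        w0, w1 = self.class_weights
        if not (0 < w0 < 1 and 0 < w1 < 1) or abs(w0 + w1 - 1) > 1e-9:
            raise ValueError("class_weights must be in (0,1) and sum to 1")
        if self.class_sep <= 0:
            raise ValueError("class_sep must be positive")
        if not 0 <= self.flip_y < 1:
            raise ValueError("flip_y must be in [0, 1)")


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def generate_dataset(spec: SynthSpec) -> Dataset:
    """Draw a synthetic dataset from `spec`.

    Label counts are deterministic: the majority count is round(l * w_major)
    and the minority gets the remainder. Informative columns are permuted into
    random positions; ``informative_mask`` records where they landed.
    """
    rng = np.random.default_rng(spec.seed)
    l, n, k = spec.n_samples, spec.n_features, spec.n_informative

    w_major = max(spec.class_weights)
    n_major = int(round(l * w_major))
    n_minor = l - n_major
    if n_minor < 1 or n_major < 1:
        raise ValueError("class_weights leave a class empty at this sample size")
    y = np.concatenate([np.zeros(n_major, dtype=int), np.ones(n_minor, dtype=int)])

    X = rng.standard_normal((l, n))
    if k > 0:
        delta = spec.class_sep / np.sqrt(k)  # per-latent-axis centroid offset
        latent_sd = np.sqrt(rng.uniform(0.5, 2.0, k))
        z = X[:, :k] * latent_sd + np.where(y[:, None] == 1, delta, -delta)
        rotation = np.linalg.qr(rng.standard_normal((k, k)))[0]
        X[:, :k] = z @ rotation

    if spec.flip_y > 0:
        flip = rng.random(l) < spec.flip_y
        y = np.where(flip, 1 - y, y)

    perm = rng.permutation(n)
    X = X[:, perm]
    mask = np.zeros(n, dtype=bool)
    mask[np.flatnonzero(perm < k)] = True

    # shuffle rows so class blocks are not contiguous
    order = rng.permutation(l)
    names = [f"f{j}" for j in range(n)]
    return Dataset(X[order], y[order], names, informative_mask=mask)


def split(
    ds: Dataset,
    test_fraction: float = 0.25,
    stratify: bool = True,
    seed: int = 0,
) -> tuple[Dataset, Dataset]:
    """Disjoint train/test row partition; stratified by class when requested."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    idx = np.arange(ds.n_samples)
    tr, te = train_test_split(
        idx,
        test_size=test_fraction,
        stratify=ds.y if stratify else None,
        random_state=seed,
    )
    parts = []
    for rows in (tr, te):
        part = Dataset(
            ds.X[rows], ds.y[rows], ds.feature_names, informative_mask=ds.informative_mask
        )
        if len(np.unique(part.y)) < 2:
            raise ValueError("a class is absent from one side of the split")
        parts.append(part)
    return parts[0], parts[1]


def smote(train: Dataset, cfg: SmoteConfig | None = None) -> Dataset:
    """Rebalance classes exactly by synthetic minority oversampling.

    Each synthetic row is x + u * (x_nn - x) for a minority row x, one of its
    k nearest minority neighbours x_nn (Euclidean) and u ~ Uniform(0, 1).
    Original rows are kept verbatim; only the training partition should ever
    be passed here.
    """
    cfg = cfg or SmoteConfig()
    classes, counts = np.unique(train.y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("smote requires both classes present")
    minority = classes[np.argmin(counts)]
    n_minor, n_major = counts.min(), counts.max()
    deficit = n_major - n_minor
    if deficit == 0:
        return train

    k = cfg.k_neighbors
    if n_minor <= k:
        k = n_minor - 1
        logger.warning("minority count %d <= k_neighbors; reducing k to %d", n_minor, k)
    if k < 1:
        raise ValueError("minority class too small for SMOTE (needs >= 2 rows)")

    rng = np.random.default_rng(cfg.seed)
    Xm = train.X[train.y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    # first neighbour is the point itself
    neigh = nn.kneighbors(Xm, return_distance=False)[:, 1:]

    base = rng.integers(0, n_minor, size=deficit)
    pick = rng.integers(0, k, size=deficit)
    u = rng.random(deficit)
    x = Xm[base]
    x_nn = Xm[neigh[base, pick]]
    synth = x + u[:, None] * (x_nn - x)

    X = np.vstack([train.X, synth])
    y = np.concatenate([train.y, np.full(deficit, minority, dtype=int)])
    return Dataset(X, y, train.feature_names, informative_mask=train.informative_mask)


def read_csv(path: str | Path, label: str = "class") -> Dataset:
    """Read a dataset from CSV; the label column (default "class", else the
    last column if "class" is absent) must be binary, all others numeric."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty or unreadable CSV") from exc
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise ValueError(f"{path}: need at least one row and two columns")
    label_col = label if label in df.columns else df.columns[-1]
    y_raw = df[label_col]
    feats = df.drop(columns=[label_col])
    for col in feats.columns:
        coerced = pd.to_numeric(feats[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise ValueError(f"{path}: non-numeric value in column '{col}', row {row}")
        feats[col] = coerced
    uniq = set(pd.unique(y_raw))
    if not uniq <= {0, 1}:
        raise ValueError(f"{path}: label column '{label_col}' is not binary 0/1 (saw {sorted(uniq)})")
    return Dataset(feats.to_numpy(dtype=float), y_raw.to_numpy(dtype=int), list(feats.columns))


def write_csv(ds: Dataset, path: str | Path, label: str = "class") -> None:
    df = pd.DataFrame(ds.X, columns=ds.feature_names)
    df[label] = ds.y
    df.to_csv(path, index=False)
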