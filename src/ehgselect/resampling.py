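"""Resampling methods for imbalanced preterm/term feature tables.

Three families, all parameterised by a post-resampling minority:majority
target ratio (1.0 = fully balanced):

* oversampling ``RO``: SMOTE — synthetic minority rows interpolated
  between a minority row and one of its k nearest minority neighbours;
* undersampling ``RU``: the Neighborhood Cleaning Rule (Wilson's edited
  nearest-neighbour removal of noisy majority rows) followed by seeded
  random majority undersampling down to the target ratio (NCL alone
  cannot reach an arbitrary ratio);
* hybrid ``RH``: SMOTE to the target ratio, then NCL;
* ``RN``: identity.

Distances are Euclidean on the features as given; callers are expected to
z-score with training-fold statistics first so no feature dominates.
Minority rows are never removed and majority rows never fabricated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger("ehgselect")

METHODS = ("none", "smote", "ncl_undersample", "hybrid")
_ALIASES = {"RN": "none", "RO": "smote", "RU": "ncl_undersample", "RH": "hybrid"}


@dataclass
class ResamplingSpec:
    """Method + neighbour counts + target minority/majority ratio."""

    method: str = "none"
    k_smote: int = 5
    k_ncl: int = 3
    target_ratio: float = 1.0
    seed: int = 0
    ncl_before_smote: bool = False  # hybrid order flag (default SMOTE -> NCL)

    def __post_init__(self):
        self.method = _ALIASES.get(self.method, self.method)
        if self.method not in METHODS:
            raise ValueError(f"unknown resampling method {self.method!r}")
        if not (0 < self.target_ratio <= 1):
            raise ValueError("target_ratio must lie in (0, 1]")
        if self.k_smote < 1 or self.k_ncl < 1:
            raise ValueError("neighbour counts must be >= 1")


def _class_split(labels: np.ndarray) -> tuple[int, int]:
    """(minority_label, majority_label).

    The minority class is the preterm class, label 1, by convention —
    oversampling fabricates preterm rows and undersampling removes term
    rows regardless of momentary counts in a fold.
    """
    return 1, 0


def smote(
    X: np.ndarray, y: np.ndarray, spec: ResamplingSpec,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE oversampling of the minority class up to the target ratio.

    Each synthetic row is x_i + u (x_nn - x_i) with u ~ U(0,1) and x_nn
    one of the ``k_smote`` nearest minority neighbours of a random
    minority row x_i. Original rows are returned unchanged, synthetic rows
    appended. Deterministic under ``spec.seed`` (or a caller-provided rng).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    minority, _ = _class_split(y)
    Xmin = X[y == minority]
    n_min, n_maj = Xmin.shape[0], X.shape[0] - Xmin.shape[0]
    n_target = ceil(spec.target_ratio * n_maj)
    n_syn = n_target - n_min
    if n_syn <= 0:
        return X, y
    if n_min < spec.k_smote + 1:
        raise ValueError(
            f"SMOTE needs at least k+1 = {spec.k_smote + 1} minority rows, "
            f"got {n_min} (short by {spec.k_smote + 1 - n_min})")
    d = cdist(Xmin, Xmin)
    np.fill_diagonal(d, np.inf)
    nn = np.argsort(d, axis=1)[:, :spec.k_smote]
    base = rng.integers(0, n_min, size=n_syn)
    pick = rng.integers(0, spec.k_smote, size=n_syn)
    u = rng.random(size=n_syn)
    neigh = nn[base, pick]
    synth = Xmin[base] + u[:, None] * (Xmin[neigh] - Xmin[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_syn, minority, dtype=int)])
    return X_out, y_out


def ncl(
    X: np.ndarray, y: np.ndarray, spec: ResamplingSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Neighborhood Cleaning Rule: remove noisy majority rows.

    (i) Wilson editing — drop majority rows misclassified by their
    ``k_ncl`` nearest neighbours; (ii) drop the majority rows that appear
    among the ``k_ncl`` neighbours of misclassified minority rows.
    Minority rows are never removed. Deterministic (no randomness).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    if n < spec.k_ncl + 1:
        raise ValueError(f"NCL needs at least k+1 = {spec.k_ncl + 1} rows")
    minority, majority = _class_split(y)
    d = cdist(X, X)
    np.fill_diagonal(d, np.inf)
    nn = np.argsort(d, axis=1)[:, :spec.k_ncl]
    votes_min = (y[nn] == minority).sum(axis=1)
    # ties (k even) count as majority vote: conservative, removes less
    pred_min = votes_min > spec.k_ncl / 2

    drop = np.zeros(n, dtype=bool)
    # (i) majority rows whose neighbourhood votes minority
    drop |= (y == majority) & pred_min
    # (ii) majority neighbours of misclassified minority rows
    misclassified_min = np.flatnonzero((y == minority) & ~pred_min)
    for i in misclassified_min:
        for j in nn[i]:
            if y[j] == majority:
                drop[j] = True
    keep = ~drop
    return X[keep], y[keep]


def random_undersample(
    X: np.ndarray, y: np.ndarray, target_ratio: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random removal of majority rows down to the target ratio."""
    y = np.asarray(y, dtype=int)
    minority, majority = _class_split(y)
    n_min = int((y == minority).sum())
    maj_idx = np.flatnonzero(y == majority)
    n_keep = ceil(n_min / target_ratio)
    if maj_idx.size <= n_keep:
        return X, y
    kept_maj = rng.choice(maj_idx, size=n_keep, replace=False)
    keep = np.zeros(y.size, dtype=bool)
    keep[y == minority] = True
    keep[kept_maj] = True
    return X[keep], y[keep]


def resample(
    X: np.ndarray, y: np.ndarray, spec: ResamplingSpec,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Dispatch one of the four resampling families (RN/RO/RU/RH)."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if spec.method == "none":
        return np.asarray(X, dtype=float), np.asarray(y, dtype=int)
    if spec.method == "smote":
        return smote(X, y, spec, rng=rng)
    if spec.method == "ncl_undersample":
        Xc, yc = ncl(X, y, spec)
        return random_undersample(Xc, yc, spec.target_ratio, rng)
    # hybrid
    if spec.ncl_before_smote:
        Xc, yc = ncl(X, y, spec)
        return smote(Xc, yc, spec, rng=rng)
    Xo, yo = smote(X, y, spec, rng=rng)
    return ncl(Xo, yo, spec)


def export_resampled(X: np.ndarray, y: np.ndarray, n_original: int,
                     feature_names: list[str], path) -> None:
    """Write a resampled table to CSV with an original/synthetic
    provenance column (SMOTE appends synthetic rows after the originals)."""
    import pandas as pd

    df = pd.DataFrame(np.asarray(X, float), columns=feature_names)
    df["label"] = np.asarray(y, int)
    df["provenance"] = ["original"] * n_original + \
        ["synthetic"] * (df.shape[0] - n_original)
    df.to_csv(path, index=False)


def class_ratio(y: np.ndarray) -> float:
    """Minority/majority count ratio of a label vector."""
    y = np.asarray(y, dtype=int)
    minority, majority = _class_split(y)
    n_maj = int((y == majority).sum())
    return float((y == minority).sum() / n_maj) if n_maj else float("inf")
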