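"""Personalized feature selection with two-class ReliefF.

The subject's per-beat feature rows (class 1) are paired with an equal
number of control rows sampled from the population database (class 0);
classic ReliefF weights rank the 29 features and the top 10 become the
subject's personal feature index set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .types import N_FEATURES, FeatureIndexSet

TOP_K = 10  # size of the personalized index set


@dataclass
class LabeledFeatureData:
    """Combined subject/control feature rows for ReliefF."""

    X: np.ndarray  # (2n, 29)
    y: np.ndarray  # (2n,) 1 = subject, 0 = control
    n_per_class: int

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if set(np.unique(self.y)) != {0, 1}:
            raise ParameterError("both classes must be present")
        if (self.y == 0).sum() != (self.y == 1).sum():
            raise ParameterError("class counts must be equal")


def build_relief_input(subject_rows: np.ndarray, population: np.ndarray,
                       rng_seed: int = 0) -> LabeledFeatureData:
    """Label subject rows 1 and an equal-size random control sample 0.

    Control rows are drawn without replacement from the population pool.
    """
    M = np.atleast_2d(np.asarray(subject_rows, dtype=float))
    pool = np.atleast_2d(np.asarray(population, dtype=float))
    n = M.shape[0]
    if pool.shape[0] < n:
        raise ParameterError(
            f"population pool ({pool.shape[0]} rows) smaller than n={n}")
    rng = np.random.default_rng(int(rng_seed) % (2**31))
    pick = rng.choice(pool.shape[0], size=n, replace=False)
    N = pool[pick]
    X = np.vstack([M, N])
    y = np.concatenate([np.ones(n, dtype=int), np.zeros(n, dtype=int)])
    return LabeledFeatureData(X=X, y=y, n_per_class=n)


def relieff_weights(data: LabeledFeatureData, k_neighbors: int = 10,
                    rng_seed: int = 0) -> np.ndarray:
    """Classic two-class ReliefF weights, one per feature, in [-1, 1].

    Every instance is used once (m = all). Features are min-max scaled to
    [0, 1]; neighbor search uses Manhattan distance on the scaled features;
    per instance the k nearest hits and k nearest misses contribute
    mean miss-difference minus mean hit-difference, averaged over instances.
    Constant features receive weight 0 (with a warning). ``rng_seed`` is
    accepted for interface stability; with m = all the procedure is
    deterministic and the seed is unused.
    """
    X, y = data.X, data.y
    m, p = X.shape
    n_class = min((y == 0).sum(), (y == 1).sum())
    if not 1 <= k_neighbors < n_class:
        raise ParameterError(
            f"k_neighbors={k_neighbors} must be in [1, per-class count)")

    lo = X.min(axis=0)
    rng_ = X.max(axis=0) - lo
    const = rng_ == 0
    if const.any():
        warnings.warn("constant feature(s) receive ReliefF weight 0",
                      stacklevel=2)
    scale = np.where(const, 1.0, rng_)
    Z = (X - lo) / scale

    w = np.zeros(p)
    idx = np.arange(m)
    for i in range(m):
        d = np.abs(Z - Z[i]).sum(axis=1)
        same = idx[(y == y[i]) & (idx != i)]
        other = idx[y != y[i]]
        hits = same[np.argsort(d[same], kind="stable")[:k_neighbors]]
        misses = other[np.argsort(d[other], kind="stable")[:k_neighbors]]
        w += np.abs(Z[misses] - Z[i]).mean(axis=0)
        w -= np.abs(Z[hits] - Z[i]).mean(axis=0)
    w /= m
    w[const] = 0.0
    return w


def top_features(weights: np.ndarray, k: int = TOP_K) -> FeatureIndexSet:
    """Indices (1-based) of the k largest weights, ties to the lower index."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (N_FEATURES,):
        raise ParameterError(f"expected {N_FEATURES} weights")
    order = np.argsort(-weights, kind="stable")[:k]
    return FeatureIndexSet(indices=tuple(int(i) + 1 for i in order),
                           weights=tuple(float(weights[i]) for i in order))


def select_features(subject_rows: np.ndarray, population: np.ndarray,
                    k_neighbors: int = 10, rng_seed: int = 0) -> FeatureIndexSet:
    """Full personalized selection: build input, weight, take the top 10."""
    data = build_relief_input(subject_rows, population, rng_seed)
    k = min(k_neighbors, data.n_per_class - 1)
    if k < k_neighbors:
        warnings.warn(f"k_neighbors reduced to {k} (class size)", stacklevel=2)
    w = relieff_weights(data, k_neighbors=k, rng_seed=rng_seed)
    return top_features(w)
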