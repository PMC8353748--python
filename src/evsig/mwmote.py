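"""Majority-weighted minority oversampling (MWMOTE) for imbalanced cohorts.

MWMOTE balances a two-class training set by generating synthetic minority
samples.  It proceeds in three stages:

1. *Informative sets.*  Minority points whose ``k1`` nearest neighbors (over
   the whole set) contain no minority are treated as noise and filtered out.
   The ``k2`` nearest majority neighbors of each remaining minority point
   form the borderline majority set; the ``k3`` nearest minority neighbors of
   those majority points form the informative minority set.
2. *Selection weights.*  Each informative minority point receives a weight
   summing, over the borderline majority points, a closeness factor (large
   near the decision border, capped via ``c_th``/``c_max``) times a density
   factor (large in sparse clusters).  Normalized weights are the sampling
   probabilities.
3. *Generation.*  Filtered minority points are grouped by average-linkage
   clustering with a data-driven distance threshold; each synthetic sample is
   ``x + alpha * (y - x)`` with ``x`` drawn by the selection weights, ``y``
   uniform within ``x``'s cluster and ``alpha ~ U(0, 1)``, so every synthetic
   point is a convex combination of two original minority points.

Distances are Euclidean on z-standardized features (statistics of the input
set), since curve coefficients and biomarker units are incommensurable.
Synthetic rows carry their two parent indices, which the classification
pipeline uses to enforce its leakage guard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist

from .exceptions import ValidationError

__all__ = ["MWMOTEParams", "ImbalancedSet", "informative_sets", "selection_weights", "oversample"]


@dataclass(frozen=True)
class MWMOTEParams:
    """MWMOTE tuning parameters.

    Defaults follow the algorithm's published reference settings: ``k1=5``
    (noise-filter neighborhood), ``k2=3`` (majority neighbors per minority
    point), ``k3=None`` meaning half the minority size, closeness threshold
    ``c_th=5``, closeness cap ``c_max=2``, clustering threshold multiplier
    ``cluster_proportion=3``.  ``n_synthetic=None`` balances the classes.
    """

    k1: int = 5
    k2: int = 3
    k3: int | None = None
    c_th: float = 5.0
    c_max: float = 2.0
    cluster_proportion: float = 3.0
    n_synthetic: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k1 < 1 or self.k2 < 1 or (self.k3 is not None and self.k3 < 1):
            raise ValidationError("neighborhood sizes k1, k2, k3 must be >= 1")
        if self.c_th <= 0 or self.c_max <= 0 or self.cluster_proportion <= 0:
            raise ValidationError("c_th, c_max and cluster_proportion must be positive")
        if self.n_synthetic is not None and self.n_synthetic < 0:
            raise ValidationError("n_synthetic must be >= 0")


@dataclass(frozen=True)
class ImbalancedSet:
    """A binary-labelled feature matrix with per-row synthetic provenance.

    ``labels`` holds arbitrary class values; the minority class is the one
    with fewer *original* rows (or ``minority_label`` when given).  Synthetic
    rows carry the integer indices of their two minority parents; original
    rows carry -1.
    """

    features: np.ndarray
    labels: np.ndarray
    minority_label: object = None
    parent_a: np.ndarray = field(default=None)  # type: ignore[assignment]
    parent_b: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels)
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y)
        if X.ndim != 2 or y.shape != (X.shape[0],):
            raise ValidationError("features must be n x p with one label per row")
        if not np.all(np.isfinite(X)):
            raise ValidationError("features must be finite (impute before oversampling)")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValidationError(f"need exactly 2 classes, got {classes.size}")
        if self.minority_label is None:
            counts = {c: int(np.sum(y == c)) for c in classes}
            # deterministic tie-break: the lexicographically smaller label
            minority = min(sorted(counts, key=str), key=lambda c: counts[c])
            object.__setattr__(self, "minority_label", minority)
        elif self.minority_label not in classes:
            raise ValidationError(f"minority_label {self.minority_label!r} not present")
        n = X.shape[0]
        for name in ("parent_a", "parent_b"):
            p = getattr(self, name)
            p = np.full(n, -1, dtype=int) if p is None else np.asarray(p, dtype=int)
            if p.shape != (n,):
                raise ValidationError(f"{name} must have one entry per row")
            object.__setattr__(self, name, p)
        if int(np.sum((y == self.minority_label) & (self.parent_a < 0))) < 1:
            raise ValidationError("minority class has no original members")

    @property
    def is_synthetic(self) -> np.ndarray:
        return self.parent_a >= 0

    @property
    def minority_mask(self) -> np.ndarray:
        return self.labels == self.minority_label

    def counts(self) -> tuple[int, int]:
        """(minority, majority) row counts, synthetic rows included."""
        n_min = int(np.sum(self.minority_mask))
        return n_min, int(self.labels.size - n_min)


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _knn_indices(dist_row: np.ndarray, self_idx: int | None, k: int) -> np.ndarray:
    """Indices of the k nearest points by distance, ties to the lowest index."""
    d = dist_row.copy()
    if self_idx is not None:
        d[self_idx] = np.inf
    order = np.argsort(d, kind="stable")
    return order[: min(k, np.sum(np.isfinite(d)))]


def informative_sets(
    data: ImbalancedSet, params: MWMOTEParams = MWMOTEParams()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The (filtered minority, borderline majority, informative minority)
    index sets of the MWMOTE construction, as sorted arrays of row indices."""
    X = _standardize(data.features)
    y_min = data.minority_mask
    min_idx = np.flatnonzero(y_min)
    maj_idx = np.flatnonzero(~y_min)
    if min_idx.size == 0:
        raise ValidationError("minority class is empty")
    n = X.shape[0]
    if n < params.k1 + 1:
        raise ValidationError(f"need at least k1+1 = {params.k1 + 1} samples")
    D = cdist(X, X)

    filtered = [
        i for i in min_idx if np.any(y_min[_knn_indices(D[i], i, params.k1)])
    ]
    filtered = np.asarray(sorted(filtered), dtype=int)

    borderline: set[int] = set()
    for i in filtered:
        d = np.where(~y_min, D[i], np.inf)
        borderline.update(int(j) for j in _knn_indices(d, None, params.k2) if np.isfinite(d[j]))
    borderline_arr = np.asarray(sorted(borderline), dtype=int)

    k3 = params.k3 if params.k3 is not None else max(1, min_idx.size // 2)
    informative: set[int] = set()
    for j in borderline_arr:
        d = np.where(y_min, D[j], np.inf)
        informative.update(int(i) for i in _knn_indices(d, None, k3) if np.isfinite(d[i]))
    informative_arr = np.asarray(sorted(informative), dtype=int)
    return filtered, borderline_arr, informative_arr


def selection_weights(
    data: ImbalancedSet,
    sets: tuple[np.ndarray, np.ndarray, np.ndarray],
    params: MWMOTEParams = MWMOTEParams(),
) -> np.ndarray:
    """Selection probabilities over the informative minority set.

    For borderline majority y and informative minority x, the closeness
    factor is ``min(p / d(y, x), c_th) / c_th * c_max`` with p the feature
    dimension; the density factor normalizes closeness within each y; their
    product summed over y gives the selection weight of x, normalized to a
    probability vector.
    """
    _, borderline, informative = sets
    if informative.size == 0:
        raise ValidationError("informative minority set is empty")
    X = _standardize(data.features)
    p = X.shape[1]
    if borderline.size == 0:
        warnings.warn("no borderline majority points; falling back to uniform weights")
        return np.full(informative.size, 1.0 / informative.size)
    D = cdist(X[borderline], X[informative])
    with np.errstate(divide="ignore"):
        closeness = np.minimum(p / D, params.c_th) / params.c_th * params.c_max
    closeness[D == 0] = params.c_max  # coincident points: maximal closeness
    row_sums = closeness.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    density = closeness / row_sums
    weights = (closeness * density).sum(axis=0)
    total = weights.sum()
    if total <= 0:
        warnings.warn("degenerate all-zero selection weights; using uniform fallback")
        return np.full(informative.size, 1.0 / informative.size)
    return weights / total


def _cluster_filtered(X_std: np.ndarray, filtered: np.ndarray, cp: float) -> dict[int, np.ndarray]:
    """Average-linkage clusters of the filtered minority points.

    Threshold = cp x (mean nearest-neighbor distance among the filtered
    points).  Returns a map from row index to the cluster's row indices.
    """
    if filtered.size == 1:
        return {int(filtered[0]): filtered}
    sub = X_std[filtered]
    D = cdist(sub, sub)
    np.fill_diagonal(D, np.inf)
    d_avg = float(np.mean(D.min(axis=1)))
    Z = linkage(pdist(sub), method="average")
    labels = fcluster(Z, t=cp * d_avg, criterion="distance")
    return {
        int(row): filtered[labels == labels[k]] for k, row in enumerate(filtered)
    }


def oversample(
    data: ImbalancedSet,
    params: MWMOTEParams = MWMOTEParams(),
    seed: int | None = None,
) -> ImbalancedSet:
    """Append MWMOTE synthetic minority rows to an imbalanced set.

    ``n_synthetic`` defaults to the majority/minority count difference, so the
    returned set is exactly balanced.  Original rows are unchanged; synthetic
    rows record their two parent row indices.  Deterministic under the seed
    (``params.seed`` unless overridden here).
    """
    n_min, n_maj = data.counts()
    n_syn = params.n_synthetic if params.n_synthetic is not None else max(0, n_maj - n_min)
    if n_syn == 0:
        return data
    orig_min = np.flatnonzero(data.minority_mask & ~data.is_synthetic)
    if orig_min.size < 2:
        raise ValidationError(
            "minority class has a single original member; interpolation is impossible "
            "(duplicate the point explicitly if oversampling is still wanted)"
        )
    sets = informative_sets(data, params)
    filtered, _, informative = sets
    if filtered.size == 0:
        # every minority point was noise-filtered; fall back to the full
        # original minority so generation remains possible
        warnings.warn("all minority points filtered as noise; using them all")
        filtered = orig_min
        informative = orig_min
        probs = np.full(informative.size, 1.0 / informative.size)
    else:
        probs = selection_weights(data, sets, params)

    X_std = _standardize(data.features)
    clusters = _cluster_filtered(X_std, filtered, params.cluster_proportion)
    nearest_cache: dict[int, int] = {}

    rng = np.random.default_rng(params.seed if seed is None else seed)
    new_rows = np.empty((n_syn, data.features.shape[1]))
    pa = np.empty(n_syn, dtype=int)
    pb = np.empty(n_syn, dtype=int)
    for s in range(n_syn):
        x = int(rng.choice(informative, p=probs))
        if x in clusters:
            members = clusters[x]
        else:  # informative point that was noise-filtered: use nearest cluster
            if x not in nearest_cache:
                d = np.linalg.norm(X_std[filtered] - X_std[x], axis=1)
                nearest_cache[x] = int(filtered[int(np.argmin(d))])
            members = clusters[nearest_cache[x]]
        y = int(rng.choice(members))
        alpha = float(rng.uniform())
        new_rows[s] = data.features[x] + alpha * (data.features[y] - data.features[x])
        pa[s], pb[s] = x, y

    return ImbalancedSet(
        features=np.vstack([data.features, new_rows]),
        labels=np.concatenate(
            [data.labels, np.full(n_syn, data.minority_label, dtype=data.labels.dtype)]
        ),
        minority_label=data.minority_label,
        parent_a=np.concatenate([data.parent_a, pa]),
        parent_b=np.concatenate([data.parent_b, pb]),
    )
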