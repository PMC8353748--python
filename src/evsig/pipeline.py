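"""Leakage-safe Random-Forest classification of EV feature tables.

Two frameworks are provided for binary comparisons (ALS vs HC/MD/SBMA, fast
vs slow progressors), both with three stages: data handling, stratified
5-fold cross-validated model selection, and evaluation on an untouched test
cohort with precision-recall curves.

*basic*
    Train-set preprocessing (per-feature mean imputation fit on the training
    rows only) and Random-Forest training on the raw training data.
*advanced*
    As basic, but the training data are balanced with MWMOTE oversampling.
    Oversampling is re-run inside every cross-validation fold on that fold's
    training part only — never on validation or test rows — and a provenance
    check (:func:`assert_no_leakage`) turns any violation into a hard error.
    This is what makes the oversampled performance estimates honest: applying
    oversampling before the split leaks interpolated copies of evaluation
    minority points into training and inflates the measured PR-AUC.

PR-AUC is trapezoidal area under the precision-recall curve with tied scores
grouped; the baseline for an uninformative classifier is the positive-class
prevalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import mwmote
from .exceptions import LeakageError, ValidationError

__all__ = [
    "CohortTable",
    "PRResult",
    "impute_feature_mean",
    "split_cohort",
    "stratified_kfold",
    "pr_curve",
    "oversample_table",
    "assert_no_leakage",
    "run_framework",
    "FrameworkResult",
    "DEFAULT_GRID",
]

logger = logging.getLogger(__name__)

#: Default Random-Forest hyperparameter grid for CV model selection.
DEFAULT_GRID: tuple[dict, ...] = (
    {"n_estimators": 200, "max_depth": None, "max_features": "sqrt"},
    {"n_estimators": 200, "max_depth": 5, "max_features": "sqrt"},
)


@dataclass(frozen=True)
class CohortTable:
    """Per-sample feature rows with binary labels and synthetic provenance.

    ``features`` is indexed by unique sample id; ``labels`` is aligned and
    holds exactly two classes; ``positive_label`` names the target class.
    ``parent_a``/``parent_b`` (aligned Series of sample ids, empty string for
    original rows) record the parents of oversampled rows.
    """

    features: pd.DataFrame
    labels: pd.Series
    positive_label: object
    parent_a: pd.Series = None  # type: ignore[assignment]
    parent_b: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.features.index.is_unique:
            raise ValidationError("sample ids must be unique")
        if not self.labels.index.equals(self.features.index):
            raise ValidationError("labels must align with the feature index")
        classes = set(self.labels.unique())
        if len(classes) != 2:
            raise ValidationError(f"need exactly 2 classes, got {sorted(map(str, classes))}")
        if self.positive_label not in classes:
            raise ValidationError(f"positive label {self.positive_label!r} absent")
        for name in ("parent_a", "parent_b"):
            s = getattr(self, name)
            if s is None:
                s = pd.Series("", index=self.features.index)
            elif not s.index.equals(self.features.index):
                raise ValidationError(f"{name} must align with the feature index")
            object.__setattr__(self, name, s)

    @property
    def is_synthetic(self) -> pd.Series:
        return self.parent_a != ""

    def loc(self, ids: Sequence) -> "CohortTable":
        return CohortTable(
            self.features.loc[ids],
            self.labels.loc[ids],
            self.positive_label,
            self.parent_a.loc[ids],
            self.parent_b.loc[ids],
        )

    def __len__(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class PRResult:
    """Precision-recall points (per distinct score threshold, descending)
    and the trapezoidal area under them."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auc: float
    positive_class: object

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0 + 1e-12:
            raise ValidationError("PR-AUC must lie in [0, 1]")
        if np.any(np.diff(self.recall) < -1e-12):
            raise ValidationError("recall must be nondecreasing as threshold falls")


def impute_feature_mean(
    train: pd.DataFrame, test: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Fill missing cells with the train-set per-feature mean.

    The test table is filled with the *train* means (the test rows never
    contribute — leakage control).  A feature entirely missing in train is an
    error.
    """
    means = train.mean(axis=0, skipna=True)
    dead = means.index[means.isna()].tolist()
    if dead:
        raise ValidationError(f"features entirely missing in train: {dead}")
    train_f = train.fillna(means)
    test_f = None if test is None else test.fillna(means)
    return train_f, test_f


def split_cohort(
    cohort: CohortTable, test_fraction: float = 0.25, seed: int = 0
) -> tuple[CohortTable, CohortTable]:
    """Stratified train/test split with disjoint sample ids."""
    if not 0.0 < test_fraction < 1.0:
        raise ValidationError("test_fraction must lie in (0, 1)")
    counts = cohort.labels.value_counts()
    if counts.min() < 2:
        raise ValidationError("each class needs at least 2 samples to split")
    train_ids, test_ids = train_test_split(
        cohort.features.index.to_numpy(),
        test_size=test_fraction,
        stratify=cohort.labels.to_numpy(),
        random_state=seed,
    )
    logger.info("split: %d train / %d test (seed %d)", len(train_ids), len(test_ids), seed)
    return cohort.loc(sorted(train_ids)), cohort.loc(sorted(test_ids))


def stratified_kfold(
    labels: pd.Series, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold assignment over the given labels; per-fold class
    counts deviate from exact proportionality by at most one sample."""
    counts = labels.value_counts()
    if counts.min() < k:
        raise ValidationError(
            f"smallest class has {counts.min()} members; needs >= k = {k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    ids = labels.index.to_numpy()
    return [
        (ids[tr], ids[va])
        for tr, va in skf.split(np.zeros(len(labels)), labels.to_numpy())
    ]


def pr_curve(scores: Sequence[float], labels: Sequence, positive_label=1) -> PRResult:
    """Precision-recall curve and AUC from per-sample positive-class scores.

    Points are computed at every distinct score threshold (ties grouped);
    the area is trapezoidal over recall, with the curve anchored at recall 0
    using the precision of the highest-score group.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray([1 if lbl == positive_label else 0 for lbl in labels])
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be equal-length vectors")
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise ValidationError("both classes must be present to draw a PR curve")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    n_retrieved = np.arange(1, y.size + 1)
    # last index of each tie group = the point where the threshold drops
    group_end = np.r_[np.flatnonzero(np.diff(s_sorted) != 0), y.size - 1]
    precision = tp[group_end] / n_retrieved[group_end]
    recall = tp[group_end] / n_pos
    thresholds = s_sorted[group_end]
    rec = np.r_[0.0, recall]
    prec = np.r_[precision[0], precision]
    auc = float(np.trapezoid(prec, rec))
    return PRResult(
        thresholds=thresholds,
        precision=precision,
        recall=recall,
        auc=auc,
        positive_class=positive_label,
    )


def oversample_table(
    table: CohortTable, params: mwmote.MWMOTEParams, seed: int
) -> CohortTable:
    """MWMOTE-oversample a (training) cohort table, tracking provenance by
    sample id.  The minority class is the rarer label in the table."""
    data = mwmote.ImbalancedSet(
        features=table.features.to_numpy(dtype=float),
        labels=table.labels.to_numpy(),
    )
    out = mwmote.oversample(data, params, seed=seed)
    n_orig = len(table)
    n_syn = out.features.shape[0] - n_orig
    ids = list(table.features.index)
    syn_ids = [f"synthetic-{i:04d}" for i in range(n_syn)]
    index = pd.Index(ids + syn_ids, name=table.features.index.name)
    parent_a = list(table.parent_a) + [ids[j] for j in out.parent_a[n_orig:]]
    parent_b = list(table.parent_b) + [ids[j] for j in out.parent_b[n_orig:]]
    logger.info("oversampled %d -> %d rows (%d synthetic)", n_orig, len(index), n_syn)
    return CohortTable(
        features=pd.DataFrame(out.features, index=index, columns=table.features.columns),
        labels=pd.Series(out.labels, index=index),
        positive_label=table.positive_label,
        parent_a=pd.Series(parent_a, index=index),
        parent_b=pd.Series(parent_b, index=index),
    )


def assert_no_leakage(train: CohortTable, eval_ids: Iterable) -> None:
    """Enforce the oversampling contract for an evaluation partition.

    Raises :class:`LeakageError` if any evaluation row is synthetic, or if
    any synthetic training row has a parent inside the evaluation partition.
    """
    eval_ids = set(eval_ids)
    syn_in_eval = [i for i in eval_ids if i in train.features.index and train.is_synthetic.get(i, False)]
    synthetic = train.is_synthetic
    parents = set(train.parent_a[synthetic]) | set(train.parent_b[synthetic])
    contaminated = parents & eval_ids
    if syn_in_eval or contaminated:
        raise LeakageError(
            "oversampling leakage detected: "
            f"synthetic rows in evaluation set: {sorted(map(str, syn_in_eval))[:5]}; "
            f"synthetic parents inside evaluation set: {sorted(map(str, contaminated))[:5]}"
        )


def _check_eval_rows_original(table: CohortTable) -> None:
    if bool(table.is_synthetic.any()):
        raise LeakageError("evaluation partition contains synthetic rows")


@dataclass(frozen=True)
class FrameworkResult:
    """Outcome of one framework run: the refit model, the test-set PR curve,
    the per-fold CV table and the bookkeeping needed to reproduce the run."""

    framework: str
    model: RandomForestClassifier
    test_pr: PRResult
    cv_results: pd.DataFrame
    best_params: dict
    train_ids: tuple
    test_ids: tuple
    prevalence: float
    seed: int


def _fit_rf(X: pd.DataFrame, y: pd.Series, positive, params: dict, seed: int):
    clf = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    clf.fit(X.to_numpy(dtype=float), (y == positive).astype(int).to_numpy())
    return clf


def _score(clf, X: pd.DataFrame) -> np.ndarray:
    proba = clf.predict_proba(X.to_numpy(dtype=float))
    return proba[:, list(clf.classes_).index(1)]


def run_framework(
    cohort: CohortTable,
    framework: str = "basic",
    model_grid: Sequence[Mapping] | None = None,
    mwmote_params: mwmote.MWMOTEParams | None = None,
    test_fraction: float = 0.25,
    k: int = 5,
    seed: int = 0,
) -> FrameworkResult:
    """Run one ML framework end to end on a binary cohort table.

    Splits the cohort (stratified holdout), selects Random-Forest
    hyperparameters by mean stratified-k-fold CV PR-AUC (oversampling re-run
    inside each fold for the advanced framework), refits on the full
    (oversampled) training set and evaluates on the untouched test set.
    Deterministic for fixed (cohort, grid, seed).
    """
    if framework not in ("basic", "advanced"):
        raise ValidationError(f"unknown framework {framework!r}")
    if framework == "advanced" and mwmote_params is None:
        mwmote_params = mwmote.MWMOTEParams()
    grid = [dict(g) for g in (model_grid if model_grid is not None else DEFAULT_GRID)]
    if not grid:
        raise ValidationError("model grid must contain at least one setting")
    if bool(cohort.is_synthetic.any()):
        raise LeakageError("input cohort already contains synthetic rows; "
                           "oversampling must happen after splitting")

    rng_seeds = np.random.SeedSequence(seed).generate_state(4 + len(grid) * k)
    train, test = split_cohort(cohort, test_fraction=test_fraction, seed=int(rng_seeds[0] % 2**31))
    folds = stratified_kfold(train.labels, k=k, seed=int(rng_seeds[1] % 2**31))

    cv_rows = []
    for gi, params in enumerate(grid):
        for fi, (tr_ids, va_ids) in enumerate(folds):
            fold_train = train.loc(list(tr_ids))
            fold_val = train.loc(list(va_ids))
            _check_eval_rows_original(fold_val)
            Xtr, Xva = impute_feature_mean(fold_train.features, fold_val.features)
            fold_train = CohortTable(
                Xtr, fold_train.labels, cohort.positive_label,
                fold_train.parent_a, fold_train.parent_b,
            )
            if framework == "advanced":
                fold_train = oversample_table(
                    fold_train, mwmote_params, seed=int(rng_seeds[4 + gi * k + fi] % 2**31)
                )
            assert_no_leakage(fold_train, va_ids)
            clf = _fit_rf(
                fold_train.features, fold_train.labels, cohort.positive_label,
                params, seed=int(rng_seeds[2] % 2**31),
            )
            auc = pr_curve(
                _score(clf, Xva),
                (fold_val.labels == cohort.positive_label).astype(int),
            ).auc
            cv_rows.append({"grid_index": gi, "fold": fi, "pr_auc": auc, **params})
    cv_results = pd.DataFrame(cv_rows)
    mean_auc = cv_results.groupby("grid_index")["pr_auc"].mean()
    best_gi = int(mean_auc.idxmax())  # ties: first (lowest) grid index
    best_params = grid[best_gi]
    logger.info("selected grid entry %d (%s), mean CV PR-AUC %.3f",
                best_gi, best_params, mean_auc[best_gi])

    _check_eval_rows_original(test)
    Xtr, Xte = impute_feature_mean(train.features, test.features)
    final_train = CohortTable(Xtr, train.labels, cohort.positive_label,
                              train.parent_a, train.parent_b)
    if framework == "advanced":
        final_train = oversample_table(
            final_train, mwmote_params, seed=int(rng_seeds[3] % 2**31)
        )
    assert_no_leakage(final_train, test.features.index)
    clf = _fit_rf(final_train.features, final_train.labels, cohort.positive_label,
                  best_params, seed=int(rng_seeds[2] % 2**31))
    test_binary = (test.labels == cohort.positive_label).astype(int)
    result = pr_curve(_score(clf, Xte), test_binary)
    prevalence = float(test_binary.mean())
    return FrameworkResult(
        framework=framework,
        model=clf,
        test_pr=result,
        cv_results=cv_results,
        best_params=best_params,
        train_ids=tuple(train.features.index),
        test_ids=tuple(test.features.index),
        prevalence=prevalence,
        seed=seed,
    )
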