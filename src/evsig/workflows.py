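"""End-to-end helpers: from a cohort (curves + biomarkers + clinical) to a
binary classification run.

The feature vector of one sample is the 30 RBF coefficients of its
area-normalized size-distribution curve, optionally concatenated with one or
both protein-cargo biomarkers (``hsp90`` for diagnostic comparisons, ``ppia``
for progression).  Curves of a cohort share one RBF center grid so that
coefficient positions are comparable across samples.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .cohort import SyntheticCohort
from .exceptions import ValidationError
from .nta import SizeDistributionCurve
from .pipeline import CohortTable, FrameworkResult, run_framework
from .rbf import DEFAULT_N_RBF, compress_cohort

__all__ = ["build_feature_table", "binary_cohort_table", "run_comparison", "FEATURE_SETS"]

#: Supported feature sets, by name.
FEATURE_SETS = ("curve", "curve+hsp90", "curve+ppia", "curve+hsp90+ppia")


def build_feature_table(
    curves: Sequence[SizeDistributionCurve],
    biomarkers: pd.DataFrame | None = None,
    feature_set: str = "curve",
    n_rbf: int = DEFAULT_N_RBF,
) -> pd.DataFrame:
    """Per-sample feature rows for the requested feature set.

    Biomarker columns may contain missing values; imputation happens later,
    inside the pipeline, from training rows only.
    """
    if feature_set not in FEATURE_SETS:
        raise ValidationError(f"unknown feature set {feature_set!r}; choose from {FEATURE_SETS}")
    table = compress_cohort(curves, n_rbf=n_rbf)
    for marker in ("hsp90", "ppia"):
        if marker in feature_set:
            if biomarkers is None or marker not in biomarkers.columns:
                raise ValidationError(f"feature set {feature_set!r} needs biomarker {marker!r}")
            table[marker] = biomarkers[marker].reindex(table.index)
    return table


def binary_cohort_table(
    cohort: SyntheticCohort,
    positive: str,
    negative: str,
    feature_set: str = "curve",
    n_rbf: int = DEFAULT_N_RBF,
) -> CohortTable:
    """Restrict a cohort to two classes and build its feature table."""
    labels = cohort.clinical["label"]
    keep = labels.isin([positive, negative])
    if (labels == positive).sum() == 0 or (labels == negative).sum() == 0:
        raise ValidationError(f"comparison {positive} vs {negative}: a class is empty")
    curves = [c for c in cohort.curves if keep.get(c.sample_id, False)]
    features = build_feature_table(
        curves, biomarkers=cohort.biomarkers, feature_set=feature_set, n_rbf=n_rbf
    )
    return CohortTable(
        features=features,
        labels=labels[keep].reindex(features.index),
        positive_label=positive,
    )


def run_comparison(
    cohort: SyntheticCohort,
    positive: str,
    negative: str,
    feature_set: str = "curve",
    framework: str = "basic",
    seed: int = 0,
    **framework_kwargs,
) -> FrameworkResult:
    """Build the binary cohort table and run one framework on it."""
    table = binary_cohort_table(cohort, positive, negative, feature_set=feature_set)
    return run_framework(table, framework=framework, seed=seed, **framework_kwargs)
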