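"""Clinical and biochemical scalar metrics for the EV biomarker analysis.

Covers the ALSFRS-R-based progression rate and its fast/slow stratification,
the detection-limit censoring rule, the particles-per-microgram purity index,
label-free-quantification (LFQ) fold changes between isolation methods, the
aggregate apolipoprotein-reduction index, and protein-overlap percentages.

The progression rate is

    dALSFRS-R = (48 - ALSFRS-R at sampling) / months from onset to sampling,

in points/month; 0.96 points/month (the cohort median) separates slow from
fast progressors.  The stratification is defined only by strict inequalities,
so a rate exactly at the cutoff is flagged indeterminate rather than silently
assigned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "ClinicalRecord",
    "FoldChange",
    "delta_alsfrs",
    "stratify_progression",
    "replace_censored",
    "purity_index",
    "lfq_fold_change",
    "apolipoprotein_reduction",
    "overlap_fraction",
    "PROGRESSION_CUTOFF",
]

#: Cohort-median progression rate (points/month) splitting slow from fast ALS.
PROGRESSION_CUTOFF = 0.96


@dataclass(frozen=True)
class ClinicalRecord:
    """Minimal clinical state of one subject at plasma sampling."""

    alsfrs_r: int
    duration_months: float
    label: str = "ALS"

    def __post_init__(self) -> None:
        if not 0 <= self.alsfrs_r <= 48:
            raise ValidationError("ALSFRS-R must lie in [0, 48]")
        if not self.duration_months > 0:
            raise ValidationError("disease duration must be positive")


def delta_alsfrs(record: ClinicalRecord) -> float:
    """Progression rate (48 - ALSFRS-R) / duration, in points per month."""
    return (48.0 - record.alsfrs_r) / record.duration_months


def stratify_progression(rate: float, cutoff: float = PROGRESSION_CUTOFF) -> str:
    """Classify a progression rate as ``"slow"``, ``"fast"`` or, exactly at
    the cutoff, ``"indeterminate"`` (the strata are defined by strict
    inequalities only)."""
    if rate < 0:
        raise ValidationError("progression rate cannot be negative")
    if rate < cutoff:
        return "slow"
    if rate > cutoff:
        return "fast"
    return "indeterminate"


def replace_censored(
    values: Sequence[float], limit: float, censored: Sequence[bool] | None = None
) -> np.ndarray:
    """Replace censored measurements with L/sqrt(2), L the detection limit.

    Entries are censored where ``censored`` is True, or — when no mask is
    given — where the value is NaN (the usual encoding of a below-detection
    readout).  Other entries pass through unchanged; the substitution is
    idempotent.
    """
    if not limit > 0:
        raise ValidationError("detection limit must be positive")
    arr = np.asarray(values, dtype=float).copy()
    mask = np.isnan(arr) if censored is None else np.asarray(censored, dtype=bool)
    if mask.shape != arr.shape:
        raise ValidationError("censoring mask must match the value vector")
    arr[mask] = limit / math.sqrt(2.0)
    return arr


def purity_index(
    particles_per_ml: float, protein_micrograms: float, scale: float = 1e8
) -> float:
    """Particles-to-protein ratio (particles per microgram / ``scale``).

    A higher index means less co-isolated free protein.  The reporting scale
    is configurable because published purity indices are conventionally
    plotted in instrument-dependent units.
    """
    if protein_micrograms <= 0:
        raise ValidationError("protein mass must be positive")
    if particles_per_ml < 0:
        raise ValidationError("particle count cannot be negative")
    return particles_per_ml / protein_micrograms / scale


@dataclass(frozen=True)
class FoldChange:
    """Ratio of group-mean LFQ intensities; ``determined`` is False when the
    denominator group did not detect the protein (reported as "ND")."""

    value: float | None
    numerator_group: str
    denominator_group: str

    @property
    def determined(self) -> bool:
        return self.value is not None

    @property
    def rounded(self) -> float | None:
        """The conventional two-decimal report of the ratio."""
        return None if self.value is None else round(self.value, 2)

    def __str__(self) -> str:
        return "ND" if self.value is None else f"{self.value:.2f}"


def _group_mean(table: pd.DataFrame, accession: str, group: str) -> float | None:
    rows = table[(table["accession"] == accession) & (table["group"] == group)]
    if rows.empty:
        raise ValidationError(f"no LFQ rows for {accession!r} in group {group!r}")
    if "detected" in rows and not rows["detected"].all():
        return None
    return float(rows["mean_lfq"].mean())


def lfq_fold_change(
    table: pd.DataFrame, accession: str, numerator_group: str, denominator_group: str
) -> FoldChange:
    """Fold change of a protein between two isolation-method groups.

    ``table`` is long-format with columns ``accession``, ``group``,
    ``mean_lfq`` and optionally ``detected``.  A protein undetected in either
    group yields a not-determined result rather than infinity or zero.
    """
    num = _group_mean(table, accession, numerator_group)
    den = _group_mean(table, accession, denominator_group)
    if num is None or den is None or den == 0:
        return FoldChange(None, numerator_group, denominator_group)
    return FoldChange(num / den, numerator_group, denominator_group)


def apolipoprotein_reduction(
    table: pd.DataFrame,
    accessions: Iterable[str],
    method_a: str,
    method_b: str,
) -> tuple[float, int]:
    """Percent reduction of summed apolipoprotein LFQ from method A to B.

    Undetected entries count as zero intensity.  Returns the exact percentage
    and its integer part (table-derived sums carry the rounding of the
    printed two-significant-figure cells, so both are reported).
    """
    accessions = set(accessions)
    sub = table[table["accession"].isin(accessions)]
    if sub.empty:
        raise ValidationError("none of the requested accessions are in the table")

    def _sum(method: str) -> float:
        rows = sub[sub["group"] == method]
        vals = rows["mean_lfq"].to_numpy(dtype=float)
        if "detected" in rows:
            vals = np.where(rows["detected"].to_numpy(dtype=bool), vals, 0.0)
        return float(np.nansum(vals))

    total_a = _sum(method_a)
    total_b = _sum(method_b)
    if total_a <= 0:
        raise ValidationError(f"method {method_a!r} has zero summed intensity")
    exact = 100.0 * (1.0 - total_b / total_a)
    return exact, int(exact)


def overlap_fraction(shared: int, total: int) -> int:
    """Percent of proteins shared between two methods, rounded to an integer."""
    if total <= 0:
        raise ValidationError("total protein count must be positive")
    if not 0 <= shared <= total:
        raise ValidationError("shared count must lie in [0, total]")
    return int(round(100.0 * shared / total))
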