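"""Nanoparticle-tracking-analysis (NTA) size-distribution curves and summaries.

An NTA instrument reports, for one plasma sample, the particle concentration
(particles/mL) in each diameter bin of a size-distribution curve.  This module
parses such exports, normalizes curves to unit area, and computes the standard
size summaries used for extracellular-vesicle (EV) characterization: the
concentration-weighted mean diameter, the modal diameter, the D10/D50/D90
quantiles, the total particle concentration, and the split of curve area below
and above a small/big-EV cutoff (130 nm by default, the cohort median D50).

Areas are obtained by direct trapezoidal integration of the binned data.
Quantiles use the midpoint weighted-percentile convention on the trapezoidal
bin masses, restricted to bins with positive mass: for fine grids this
converges to the quantiles of the underlying continuous density, and for a
single-bin (delta-like) curve every D-value collapses onto that bin, as it
should for a point mass.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import DegenerateInputError, FormatError, ValidationError

__all__ = [
    "SizeDistributionCurve",
    "SizeSummary",
    "read_curve",
    "write_curve",
    "normalize_curve",
    "summarize",
    "derive_cutoff",
    "DEFAULT_CUTOFF_NM",
]

#: Small/big EV boundary used when no cohort is supplied: the median D50 of
#: the reference cohort this analysis was developed on.
DEFAULT_CUTOFF_NM = 130.0


@dataclass(frozen=True)
class SizeDistributionCurve:
    """One sample's binned size-distribution curve.

    Parameters
    ----------
    sizes
        Strictly increasing particle diameters in nm (bin centers).
    values
        Nonnegative particle concentration per bin (particles/mL per nm for
        raw exports; density per nm after normalization).
    sample_id
        Identifier of the sample the curve belongs to.
    normalized
        True when the trapezoidal integral of ``values`` over ``sizes`` is 1.
    total_concentration
        Original total concentration (particles/mL, the trapezoidal area of
        the raw curve), retained as metadata across normalization.
    """

    sizes: np.ndarray
    values: np.ndarray
    sample_id: str = ""
    normalized: bool = False
    total_concentration: float | None = None

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "values", values)
        if sizes.ndim != 1 or values.ndim != 1 or sizes.shape != values.shape:
            raise ValidationError("sizes and values must be 1-D arrays of equal length")
        if sizes.size < 2:
            raise ValidationError("a curve needs at least 2 bins")
        if not np.all(np.isfinite(sizes)) or not np.all(np.isfinite(values)):
            raise ValidationError("sizes and values must be finite")
        if np.any(np.diff(sizes) <= 0):
            raise ValidationError("sizes must be strictly increasing")
        if np.any(values < 0):
            raise ValidationError("concentration values must be nonnegative")
        if self.normalized:
            area = float(np.trapezoid(values, sizes))
            if abs(area - 1.0) > 1e-6:
                raise ValidationError(
                    f"curve flagged normalized but integrates to {area!r}"
                )

    @property
    def area(self) -> float:
        """Trapezoidal integral of the curve over its support."""
        return float(np.trapezoid(self.values, self.sizes))

    def __len__(self) -> int:
        return int(self.sizes.size)


@dataclass(frozen=True)
class SizeSummary:
    """Scalar size-distribution summaries for one curve."""

    sample_id: str
    mean_nm: float
    mode_nm: float
    d10_nm: float
    d50_nm: float
    d90_nm: float
    total_particles_per_ml: float
    fraction_below_cutoff: float
    auc_below: float
    auc_above: float
    cutoff_nm: float = DEFAULT_CUTOFF_NM

    def __post_init__(self) -> None:
        if not (self.d10_nm <= self.d50_nm <= self.d90_nm):
            raise ValidationError("quantiles must satisfy D10 <= D50 <= D90")
        if self.total_particles_per_ml < 0:
            raise ValidationError("total concentration must be nonnegative")


_NUMBER_SPLIT = re.compile(r"[;\t,]+|\s+")


def _parse_number(token: str, decimal: str) -> float:
    if decimal != ".":
        token = token.replace(decimal, ".")
    return float(token)


def read_curve(
    path: str | Path,
    sample_id: str | None = None,
    delimiter: str | None = None,
    decimal: str = ".",
) -> SizeDistributionCurve:
    """Read a two-column (size_nm, concentration) delimited text export.

    Header or comment lines before the first numeric row are skipped.  After
    numeric rows begin, an unparseable or negative row is an error reported
    with its 1-based line number.  ``delimiter=None`` splits on any of
    semicolon, tab, comma or whitespace; a decimal comma is tolerated via
    ``decimal=","`` together with a non-comma delimiter.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such curve file: {path}")
    sizes: list[float] = []
    values: list[float] = []
    started = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = (
            [t for t in line.split(delimiter) if t.strip()]
            if delimiter is not None
            else [t for t in _NUMBER_SPLIT.split(line) if t]
        )
        try:
            if len(tokens) < 2:
                raise ValueError("fewer than two columns")
            s = _parse_number(tokens[0], decimal)
            v = _parse_number(tokens[1], decimal)
        except ValueError:
            if started:
                raise FormatError(f"{path}: unparseable row at line {lineno}: {line!r}")
            continue  # header junk before the numeric block
        started = True
        if v < 0:
            raise ValidationError(
                f"{path}: negative concentration at line {lineno}: {line!r}"
            )
        sizes.append(s)
        values.append(v)
    if not started:
        raise FormatError(f"{path}: no numeric (size, concentration) rows found")
    return SizeDistributionCurve(
        np.asarray(sizes), np.asarray(values), sample_id=sample_id or path.stem
    )


def write_curve(curve: SizeDistributionCurve, path: str | Path, delimiter: str = ",") -> None:
    """Write a curve as two-column delimited text with a header line."""
    path = Path(path)
    lines = ["size_nm" + delimiter + "concentration_particles_per_ml"]
    lines += [f"{s:.6g}{delimiter}{v:.10g}" for s, v in zip(curve.sizes, curve.values)]
    path.write_text("\n".join(lines) + "\n")


def normalize_curve(curve: SizeDistributionCurve) -> SizeDistributionCurve:
    """Rescale a curve to unit trapezoidal area, keeping its shape.

    The original total concentration (the raw area) is retained on the
    returned curve as metadata; normalizing an already-normalized curve is
    the identity.
    """
    area = curve.area
    if area <= 0:
        raise DegenerateInputError(
            f"curve {curve.sample_id!r} has nonpositive area; cannot normalize"
        )
    if curve.normalized:
        return curve
    return replace(
        curve,
        values=curve.values / area,
        normalized=True,
        total_concentration=(
            curve.total_concentration if curve.total_concentration is not None else area
        ),
    )


def _trapezoid_bin_masses(curve: SizeDistributionCurve) -> np.ndarray:
    """Per-bin masses whose sum equals the trapezoidal integral."""
    widths = np.diff(curve.sizes)
    w = np.zeros_like(curve.sizes)
    w[:-1] += widths / 2.0
    w[1:] += widths / 2.0
    return curve.values * w


def _weighted_quantiles(
    sizes: np.ndarray, masses: np.ndarray, qs: Sequence[float]
) -> np.ndarray:
    # midpoint weighted-percentile convention; clamp to the positive-mass
    # support so a point mass yields its own location for every quantile
    keep = masses > 0
    s = sizes[keep]
    m = masses[keep]
    cum = (np.cumsum(m) - 0.5 * m) / m.sum()
    return np.interp(qs, cum, s)


def summarize(
    curve: SizeDistributionCurve, cutoff_nm: float = DEFAULT_CUTOFF_NM
) -> SizeSummary:
    """Compute the size summaries of one curve at a small/big-EV cutoff.

    The mean is the concentration-weighted mean diameter; the mode is the bin
    center of the maximum value (ties resolved to the smallest diameter);
    D10/D50/D90 are weighted quantiles of the binned distribution; and the
    curve area is split at the cutoff with the cutoff ordinate linearly
    interpolated, so ``auc_below + auc_above`` equals the full integral.
    """
    if not (curve.sizes[0] <= cutoff_nm <= curve.sizes[-1]):
        raise ValidationError(
            f"cutoff {cutoff_nm} nm outside curve support "
            f"[{curve.sizes[0]}, {curve.sizes[-1]}]"
        )
    masses = _trapezoid_bin_masses(curve)
    total_mass = float(masses.sum())
    if total_mass <= 0:
        raise DegenerateInputError(f"curve {curve.sample_id!r} carries no mass")

    mean = float(np.sum(curve.sizes * masses) / total_mass)
    mode = float(curve.sizes[int(np.argmax(curve.values))])
    d10, d50, d90 = (
        float(q) for q in _weighted_quantiles(curve.sizes, masses, [0.1, 0.5, 0.9])
    )

    cut_value = float(np.interp(cutoff_nm, curve.sizes, curve.values))
    below_mask = curve.sizes <= cutoff_nm
    xs = np.r_[curve.sizes[below_mask], cutoff_nm]
    ys = np.r_[curve.values[below_mask], cut_value]
    if xs.size >= 2:
        auc_below = float(np.trapezoid(ys, xs))
    else:  # cutoff at the very first grid point
        auc_below = 0.0
    area = curve.area
    auc_above = area - auc_below

    if curve.normalized and curve.total_concentration is not None:
        total = float(curve.total_concentration)
    else:
        total = area
    return SizeSummary(
        sample_id=curve.sample_id,
        mean_nm=mean,
        mode_nm=mode,
        d10_nm=d10,
        d50_nm=d50,
        d90_nm=d90,
        total_particles_per_ml=total,
        fraction_below_cutoff=auc_below / area,
        auc_below=auc_below,
        auc_above=auc_above,
        cutoff_nm=float(cutoff_nm),
    )


def derive_cutoff(cohort_curves: Sequence[SizeDistributionCurve]) -> float:
    """Median of the per-sample D50 values of a cohort (the data-driven
    small/big-EV cutoff; with an even count, the mean of the middle two)."""
    if len(cohort_curves) == 0:
        raise ValidationError("need at least one curve to derive a cutoff")
    d50s = []
    for c in cohort_curves:
        masses = _trapezoid_bin_masses(c)
        if masses.sum() <= 0:
            raise DegenerateInputError(f"curve {c.sample_id!r} carries no mass")
        d50s.append(float(_weighted_quantiles(c.sizes, masses, [0.5])[0]))
    return float(np.median(d50s))
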