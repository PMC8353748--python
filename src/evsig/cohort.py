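"""Synthetic plasma-EV cohorts: size-distribution curves, protein cargo
biomarkers and clinical metadata.

Real patient material cannot ship with the package, so this module generates
cohorts with the statistical structure the downstream analysis assumes.  One
sample's size-distribution curve is a truncated lognormal mixture on
[0, 400] nm: lognormal modes match the right-skewed shapes NTA instruments
record, and a two-mode mixture reproduces the bimodal curves of healthy
plasma.  Per-sample biological variability enters through jitter of the mode
medians, Dirichlet resampling of the mode weights and a lognormal total
concentration; per-bin multiplicative lognormal noise emulates the
heteroscedastic scatter of NTA replicates.

Default class profiles encode the qualitative orderings reported for plasma
EVs in motor-neuron-disease cohorts: muscular dystrophy (MD) the largest mean
diameter and spinal-bulbar muscular atrophy (SBMA) the smallest; ALS shifted
toward small diameters with a larger sub-130-nm particle fraction than
healthy controls (HC); HSP90 cargo about half as abundant in ALS as in HC;
and, within ALS, slow progressors with more particles (especially below
130 nm) and fast progressors with about one-third less PPIA.  Absolute curve
parameters are free choices; only these orderings are calibrated.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .nta import SizeDistributionCurve, write_curve

__all__ = [
    "ClassProfile",
    "SyntheticCohort",
    "default_profiles",
    "generate_curve",
    "generate_cohort",
    "inject_missing",
    "write_cohort",
    "SUPPORT_NM",
]

#: Size support of the generated curves (nm), matching the NTA export range.
SUPPORT_NM = (0.0, 400.0)


@dataclass(frozen=True)
class ClassProfile:
    """Generative parameters for one diagnostic class or progression stratum.

    ``mode_locations`` are the medians (nm) of the lognormal modes,
    ``mode_sds`` their shape parameters, ``mode_weights`` the mixing
    proportions (sum to 1).  ``total_concentration_mean``/``_cv`` set the
    scale and relative spread of the per-sample particle concentration
    (particles/mL).  Biomarker locations are in arbitrary densitometry units
    with common relative noise ``biomarker_cv``.  ``mode_jitter_sd`` (log-sd
    of the per-sample mode-median jitter), ``weight_concentration``
    (Dirichlet concentration of per-sample weights; ``None`` = no
    resampling) and ``noise_sd`` (per-bin multiplicative log-sd) control the
    sample-to-sample and bin-to-bin variability.
    """

    label: str
    mode_locations: tuple[float, ...]
    mode_sds: tuple[float, ...]
    mode_weights: tuple[float, ...]
    total_concentration_mean: float
    total_concentration_cv: float = 0.35
    hsp90_mean: float = 1.0
    ppia_mean: float = 1.0
    pnfh_mean: float = 0.3
    biomarker_cv: float = 0.3
    mode_jitter_sd: float = 0.08
    weight_concentration: float | None = 60.0
    # per-bin noise of an export averaged over ~5 captures; raw single-video
    # traces are far noisier, but the analysis only ever sees the average
    noise_sd: float = 0.04
    progression_rate_median: float | None = None
    progression_rate_sigma: float = 0.8

    def __post_init__(self) -> None:
        locs = tuple(float(x) for x in self.mode_locations)
        sds = tuple(float(x) for x in self.mode_sds)
        w = tuple(float(x) for x in self.mode_weights)
        object.__setattr__(self, "mode_locations", locs)
        object.__setattr__(self, "mode_sds", sds)
        object.__setattr__(self, "mode_weights", w)
        if not (len(locs) == len(sds) == len(w)) or len(locs) == 0:
            raise ValidationError("mode lists must be nonempty and equally long")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValidationError(f"mode_weights must sum to 1, got {sum(w)!r}")
        if any(wi < 0 for wi in w):
            raise ValidationError("mode_weights must be nonnegative")
        if any(not (SUPPORT_NM[0] < m < SUPPORT_NM[1]) for m in locs):
            raise ValidationError("mode_locations must lie in (0, 400) nm")
        if any(s <= 0 for s in sds):
            raise ValidationError("mode_sds must be positive")
        if self.total_concentration_mean <= 0:
            raise ValidationError("total_concentration_mean must be positive")

    def density(self, x: np.ndarray, locations=None, weights=None) -> np.ndarray:
        """Truncated-renormalized mixture density on the support."""
        locations = self.mode_locations if locations is None else locations
        weights = self.mode_weights if weights is None else weights
        dens = np.zeros_like(x, dtype=float)
        mass = 0.0
        for med, sd, w in zip(locations, self.mode_sds, weights):
            dens += w * stats.lognorm.pdf(x, s=sd, scale=med)
            mass += w * (
                stats.lognorm.cdf(SUPPORT_NM[1], s=sd, scale=med)
                - stats.lognorm.cdf(SUPPORT_NM[0], s=sd, scale=med)
            )
        return dens / mass


@dataclass(frozen=True)
class SyntheticCohort:
    """Curves, biomarker and clinical tables for one simulated cohort.

    All three tables are indexed/aligned by unique sample ids; biomarker
    cells may be missing (NaN) after :func:`inject_missing`.
    """

    curves: tuple[SizeDistributionCurve, ...]
    biomarkers: pd.DataFrame
    clinical: pd.DataFrame
    seed: int
    profile_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [c.sample_id for c in self.curves]
        if len(set(ids)) != len(ids):
            raise ValidationError("sample ids must be unique")
        if not (
            list(self.biomarkers.index) == ids and list(self.clinical.index) == ids
        ):
            raise ValidationError("curves, biomarkers and clinical must align by id")

    def __len__(self) -> int:
        return len(self.curves)


def default_profiles() -> dict[str, ClassProfile]:
    """The default class profiles (diagnostic classes and ALS progression
    strata).  See the module docstring for the orderings they encode."""
    profiles = [
        ClassProfile(
            label="ALS",
            mode_locations=(78.0, 165.0),
            mode_sds=(0.28, 0.30),
            mode_weights=(0.62, 0.38),
            total_concentration_mean=1.6e10,
            hsp90_mean=0.48,  # ~52% below control
            ppia_mean=1.0,
            pnfh_mean=1.1,
            progression_rate_median=0.86,
        ),
        ClassProfile(
            label="HC",
            mode_locations=(95.0, 170.0),
            mode_sds=(0.22, 0.22),
            mode_weights=(0.50, 0.50),
            total_concentration_mean=1.3e10,
            hsp90_mean=1.0,
            ppia_mean=1.0,
            pnfh_mean=0.3,
        ),
        ClassProfile(
            label="MD",
            mode_locations=(105.0, 210.0),
            mode_sds=(0.30, 0.28),
            mode_weights=(0.45, 0.55),
            total_concentration_mean=1.2e10,
            hsp90_mean=0.90,
            ppia_mean=1.0,
            pnfh_mean=0.35,
        ),
        ClassProfile(
            label="SBMA",
            mode_locations=(75.0, 140.0),
            mode_sds=(0.25, 0.25),
            mode_weights=(0.70, 0.30),
            total_concentration_mean=1.9e10,
            hsp90_mean=0.95,
            ppia_mean=1.0,
            pnfh_mean=0.45,
        ),
        # ALS progression strata: slow progressors carry ~1.3x the particle
        # concentration and a larger small-mode weight (~1.5x the sub-130-nm
        # count); fast progressors ~32% less PPIA.
        ClassProfile(
            label="slow",
            mode_locations=(78.0, 165.0),
            mode_sds=(0.28, 0.30),
            mode_weights=(0.66, 0.34),
            total_concentration_mean=1.8e10,
            hsp90_mean=0.48,
            ppia_mean=1.0,
            pnfh_mean=1.0,
            progression_rate_median=0.54,
        ),
        ClassProfile(
            label="fast",
            mode_locations=(78.0, 165.0),
            mode_sds=(0.28, 0.30),
            mode_weights=(0.55, 0.45),
            total_concentration_mean=1.35e10,
            hsp90_mean=0.48,
            ppia_mean=0.68,
            pnfh_mean=1.3,
            progression_rate_median=1.48,
        ),
    ]
    return {p.label: p for p in profiles}


def _bin_centers(n_bins: int) -> np.ndarray:
    edges = np.linspace(SUPPORT_NM[0], SUPPORT_NM[1], n_bins + 1)
    return (edges[:-1] + edges[1:]) / 2.0


def generate_curve(
    profile: ClassProfile,
    n_bins: int = 400,
    seed: int = 0,
    sample_id: str | None = None,
) -> SizeDistributionCurve:
    """Draw one sample's raw size-distribution curve from a class profile.

    The curve is sampled on a uniform grid of ``n_bins`` bin centers over
    [0, 400] nm; bin values are the sample's total concentration times the
    (per-sample jittered) mixture density at the centers, times per-bin
    multiplicative lognormal noise, clamped to be nonnegative.
    """
    if n_bins < 50:
        raise ValidationError("need at least 50 bins for an NTA-like curve")
    rng = np.random.default_rng(seed)
    locations = np.asarray(profile.mode_locations, dtype=float)
    if profile.mode_jitter_sd > 0:
        locations = locations * np.exp(
            rng.normal(0.0, profile.mode_jitter_sd, size=locations.size)
        )
        locations = np.clip(locations, 1.0, SUPPORT_NM[1] - 1.0)
    weights = np.asarray(profile.mode_weights, dtype=float)
    if profile.weight_concentration is not None and weights.size > 1:
        positive = weights > 0
        alpha = weights[positive] * profile.weight_concentration
        drawn = np.zeros_like(weights)
        drawn[positive] = rng.dirichlet(alpha)
        weights = drawn
    cv = profile.total_concentration_cv
    sigma_c = np.sqrt(np.log1p(cv * cv))
    total = profile.total_concentration_mean * np.exp(
        rng.normal(-0.5 * sigma_c * sigma_c, sigma_c)
    )
    x = _bin_centers(n_bins)
    values = total * profile.density(x, locations=locations, weights=weights)
    if profile.noise_sd > 0:
        values = values * np.exp(rng.normal(0.0, profile.noise_sd, size=x.size))
    return SizeDistributionCurve(
        sizes=x,
        values=np.clip(values, 0.0, None),
        sample_id=sample_id or f"{profile.label}-{seed}",
    )


def _draw_clinical(profile: ClassProfile, rng: np.random.Generator) -> dict:
    age = float(np.clip(rng.normal(64.0, 10.0), 25.0, 90.0))
    sex = "M" if (profile.label == "SBMA" or rng.uniform() < 0.58) else "F"
    row = {
        "label": profile.label,
        "age": round(age, 1),
        "sex": sex,
        "alsfrs_r": np.nan,
        "duration_months": np.nan,
        "onset_site": "",
    }
    if profile.progression_rate_median is None:
        return row
    # Draw a progression rate, then a duration, and back out the ALSFRS-R
    # score; the induced rate distribution straddles the 0.96 cutoff for the
    # pooled ALS profile, and sits on the correct side for fast/slow strata.
    for _ in range(200):
        rate = profile.progression_rate_median * np.exp(
            rng.normal(0.0, profile.progression_rate_sigma)
        )
        if profile.label == "slow" and rate >= 0.96:
            continue
        if profile.label == "fast" and rate <= 0.96:
            continue
        duration = float(np.clip(14.0 * np.exp(rng.normal(0.0, 0.6)), 3.0, 179.0))
        score = int(round(48.0 - rate * duration))
        if 0 <= score <= 47:
            row["alsfrs_r"] = score
            row["duration_months"] = round(duration, 1)
            row["onset_site"] = "bulbar" if rng.uniform() < 0.26 else "spinal"
            return row
    raise RuntimeError("could not draw a consistent clinical record")  # pragma: no cover


def generate_cohort(
    profiles: Mapping[str, ClassProfile] | Sequence[ClassProfile] | None = None,
    n_per_class: Mapping[str, int] | None = None,
    seed: int = 0,
    n_bins: int = 400,
) -> SyntheticCohort:
    """Generate a cohort with the given per-class sizes.

    ``profiles`` defaults to :func:`default_profiles`; ``n_per_class`` maps
    profile labels to sample counts (unknown labels are an error, zero counts
    are allowed).  Identical arguments and seed reproduce the cohort
    bitwise.
    """
    if profiles is None:
        profiles = default_profiles()
    if not isinstance(profiles, Mapping):
        profiles = {p.label: p for p in profiles}
    if n_per_class is None:
        n_per_class = {"ALS": 106, "HC": 36, "MD": 28, "SBMA": 32}
    unknown = set(n_per_class) - set(profiles)
    if unknown:
        raise ValidationError(f"unknown class labels: {sorted(unknown)}")

    ss = np.random.SeedSequence(seed)
    curves: list[SizeDistributionCurve] = []
    bio_rows: list[dict] = []
    clin_rows: list[dict] = []
    ids: list[str] = []
    for label in n_per_class:  # caller-declared order
        profile = profiles[label]
        n = int(n_per_class[label])
        if n < 0:
            raise ValidationError("class sizes must be nonnegative")
        label_key = zlib.crc32(label.encode()) % (2**31)  # stable across runs
        child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(label_key,))
        seeds = child.generate_state(max(n, 1) * 2)
        for i in range(n):
            sid = f"{label}-{i:03d}"
            ids.append(sid)
            curves.append(
                generate_curve(profile, n_bins=n_bins, seed=int(seeds[2 * i]), sample_id=sid)
            )
            rng = np.random.default_rng(int(seeds[2 * i + 1]))
            sigma_b = np.sqrt(np.log1p(profile.biomarker_cv**2))
            draw = lambda mean: float(
                mean * np.exp(rng.normal(-0.5 * sigma_b**2, sigma_b))
            )
            bio_rows.append(
                {
                    "hsp90": draw(profile.hsp90_mean),
                    "ppia": draw(profile.ppia_mean),
                    "pnfh": draw(profile.pnfh_mean),
                }
            )
            clin_rows.append(_draw_clinical(profile, rng))
    biomarkers = pd.DataFrame(bio_rows, index=pd.Index(ids, name="sample_id"))
    clinical = pd.DataFrame(clin_rows, index=pd.Index(ids, name="sample_id"))
    return SyntheticCohort(
        curves=tuple(curves),
        biomarkers=biomarkers,
        clinical=clinical,
        seed=seed,
        profile_labels=tuple(profiles),
    )


def inject_missing(cohort: SyntheticCohort, rate: float, seed: int = 0) -> SyntheticCohort:
    """Set approximately ``rate`` of the biomarker cells to missing,
    uniformly at random; curves and clinical data are untouched."""
    if not 0.0 <= rate < 1.0:
        raise ValidationError("missing rate must lie in [0, 1)")
    if rate == 0.0:
        return cohort
    rng = np.random.default_rng(seed)
    bio = cohort.biomarkers.copy()
    mask = rng.uniform(size=bio.shape) < rate
    bio = bio.mask(pd.DataFrame(mask, index=bio.index, columns=bio.columns))
    return replace(cohort, biomarkers=bio)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write one curve file per sample plus biomarkers.csv, clinical.csv and
    a JSON manifest (labels and seed) under ``outdir``."""
    outdir = Path(outdir)
    (outdir / "curves").mkdir(parents=True, exist_ok=True)
    for c in cohort.curves:
        write_curve(c, outdir / "curves" / f"{c.sample_id}.csv")
    cohort.biomarkers.to_csv(outdir / "biomarkers.csv")
    cohort.clinical.to_csv(outdir / "clinical.csv")
    manifest = {
        "seed": cohort.seed,
        "n_samples": len(cohort),
        "profiles": list(cohort.profile_labels),
        "classes": cohort.clinical["label"].value_counts().to_dict(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
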