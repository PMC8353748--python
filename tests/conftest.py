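"""Shared fixtures: analytic mixture curves and small cohorts."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from evsig.nta import SizeDistributionCurve


def lognormal_mixture_curve(
    medians, sds, weights, n_bins=400, support=(0.0, 400.0), sample_id="mix",
    total=1.0,
) -> SizeDistributionCurve:
    """Noise-free curve sampled from a truncated lognormal mixture density."""
    edges = np.linspace(*support, n_bins + 1)
    x = (edges[:-1] + edges[1:]) / 2
    dens = np.zeros_like(x)
    mass = 0.0
    for med, sd, w in zip(medians, sds, weights):
        dens += w * stats.lognorm.pdf(x, s=sd, scale=med)
        mass += w * (
            stats.lognorm.cdf(support[1], s=sd, scale=med)
            - stats.lognorm.cdf(support[0], s=sd, scale=med)
        )
    return SizeDistributionCurve(x, total * dens / mass, sample_id=sample_id)


@pytest.fixture
def bimodal_curve() -> SizeDistributionCurve:
    return lognormal_mixture_curve([90.0, 170.0], [0.2, 0.2], [0.5, 0.5])


@pytest.fixture
def uniform_curve() -> SizeDistributionCurve:
    sizes = np.linspace(30.0, 230.0, 201)
    return SizeDistributionCurve(sizes, np.full(201, 2.0), sample_id="uniform")


@pytest.fixture
def delta_curve() -> SizeDistributionCurve:
    sizes = np.array([98.0, 99.0, 100.0, 101.0, 102.0])
    values = np.array([0.0, 0.0, 5.0, 0.0, 0.0])
    return SizeDistributionCurve(sizes, values, sample_id="delta")
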