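"""Size-distribution parsing, normalization and summary statistics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from evsig.exceptions import DegenerateInputError, FormatError, ValidationError
from evsig.nta import (
    SizeDistributionCurve,
    derive_cutoff,
    normalize_curve,
    read_curve,
    summarize,
    write_curve,
)

from conftest import lognormal_mixture_curve


class TestReadCurve:
    def test_two_column_file_roundtrip(self, tmp_path, bimodal_curve):
        path = tmp_path / "c.csv"
        write_curve(bimodal_curve, path)
        back = read_curve(path)
        assert len(back) == len(bimodal_curve)
        np.testing.assert_allclose(back.sizes, bimodal_curve.sizes)
        np.testing.assert_allclose(back.values, bimodal_curve.values, rtol=1e-9)

    def test_header_junk_is_skipped(self, tmp_path):
        path = tmp_path / "c.txt"
        path.write_text(
            "NanoSight export\nSample: foo\nsize,conc\n10,1.0\n20,2.0\n30,1.0\n"
        )
        curve = read_curve(path)
        assert len(curve) == 3
        np.testing.assert_allclose(curve.sizes, [10, 20, 30])

    def test_decimal_comma_dialect(self, tmp_path):
        path = tmp_path / "c.txt"
        path.write_text("10;1,5\n20;2,5\n")
        curve = read_curve(path, delimiter=";", decimal=",")
        np.testing.assert_allclose(curve.values, [1.5, 2.5])

    def test_negative_row_reported_with_line_number(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("10,1.0\n20,-3.0\n30,1.0\n")
        with pytest.raises(ValidationError, match="line 2"):
            read_curve(path)

    def test_garbage_after_data_reported_with_line_number(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("10,1.0\n20,2.0\nnot a row\n")
        with pytest.raises(FormatError, match="line 3"):
            read_curve(path)

    def test_nonmonotone_sizes_rejected(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("10,1.0\n10,2.0\n")
        with pytest.raises(ValidationError, match="increasing"):
            read_curve(path)


class TestNormalize:
    def test_constant_curve_becomes_density(self):
        sizes = np.linspace(0, 400, 401)
        curve = SizeDistributionCurve(sizes, np.full(401, 7.0))
        normed = normalize_curve(curve)
        np.testing.assert_allclose(normed.values, 1.0 / 400.0)
        assert normed.total_concentration == pytest.approx(7.0 * 400.0)

    def test_idempotent(self, bimodal_curve):
        once = normalize_curve(bimodal_curve)
        twice = normalize_curve(once)
        np.testing.assert_array_equal(once.values, twice.values)
        assert twice.total_concentration == once.total_concentration

    def test_unit_integral_by_independent_quadrature(self):
        # fine grid so that an independent quadrature rule (Simpson) agrees
        # with the trapezoidal normalization target to 1e-6
        curve = lognormal_mixture_curve([90, 170], [0.25, 0.2], [0.6, 0.4], n_bins=8000)
        normed = normalize_curve(curve)
        from scipy.integrate import simpson

        assert simpson(normed.values, x=normed.sizes) == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_curve_is_degenerate(self):
        curve = SizeDistributionCurve(np.array([1.0, 2.0]), np.array([0.0, 0.0]))
        with pytest.raises(DegenerateInputError):
            normalize_curve(curve)


class TestSummarize:
    def test_uniform_curve_symmetry(self, uniform_curve):
        s = summarize(uniform_curve, cutoff_nm=130.0)
        assert s.fraction_below_cutoff == pytest.approx(0.5)
        assert s.d50_nm == pytest.approx(130.0)
        assert s.mean_nm == pytest.approx(130.0)

    def test_delta_mass_collapses_all_statistics(self, delta_curve):
        s = summarize(delta_curve, cutoff_nm=100.0)
        assert s.mean_nm == pytest.approx(100.0)
        assert s.mode_nm == 100.0
        assert (s.d10_nm, s.d50_nm, s.d90_nm) == (100.0, 100.0, 100.0)

    def test_quantiles_match_monte_carlo_oracle(self):
        medians, sds, weights = [90.0, 170.0], [0.25, 0.2], [0.6, 0.4]
        curve = lognormal_mixture_curve(medians, sds, weights, n_bins=2000)
        s = summarize(curve)
        rng = np.random.default_rng(12345)
        comp = rng.choice(2, size=10**6, p=weights)
        draws = np.where(
            comp == 0,
            stats.lognorm.rvs(sds[0], scale=medians[0], size=10**6, random_state=rng),
            stats.lognorm.rvs(sds[1], scale=medians[1], size=10**6, random_state=rng),
        )
        draws = draws[(draws >= 0) & (draws <= 400)]  # truncation by rejection
        q10, q50, q90 = np.quantile(draws, [0.1, 0.5, 0.9])
        assert s.d10_nm == pytest.approx(q10, abs=1.0)
        assert s.d50_nm == pytest.approx(q50, abs=1.0)
        assert s.d90_nm == pytest.approx(q90, abs=1.0)

    def test_mode_tie_breaks_to_smallest_diameter(self):
        curve = SizeDistributionCurve(
            np.array([50.0, 100.0, 150.0]), np.array([2.0, 1.0, 2.0])
        )
        assert summarize(curve, cutoff_nm=100.0).mode_nm == 50.0

    def test_cutoff_outside_support_rejected(self, uniform_curve):
        with pytest.raises(ValidationError, match="support"):
            summarize(uniform_curve, cutoff_nm=300.0)


class TestDeriveCutoff:
    def test_three_known_d50s(self):
        curves = []
        for d50 in (120.0, 130.0, 140.0):
            sizes = np.array([d50 - 2, d50 - 1, d50, d50 + 1, d50 + 2])
            values = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
            curves.append(SizeDistributionCurve(sizes, values))
        assert derive_cutoff(curves) == pytest.approx(130.0)

    def test_matches_sort_based_median_oracle(self):
        rng = np.random.default_rng(7)
        curves = [
            lognormal_mixture_curve(
                [rng.uniform(60, 120), rng.uniform(140, 220)],
                [0.25, 0.25],
                [0.5, 0.5],
                sample_id=f"s{i}",
            )
            for i in range(8)  # even count: mean of the middle two
        ]
        d50s = sorted(summarize(c).d50_nm for c in curves)
        oracle = (d50s[3] + d50s[4]) / 2.0
        assert derive_cutoff(curves) == pytest.approx(oracle)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            derive_cutoff([])


@st.composite
def random_mixture_curves(draw):
    n_modes = draw(st.integers(1, 3))
    medians = [draw(st.floats(40, 250)) for _ in range(n_modes)]
    sds = [draw(st.floats(0.1, 0.5)) for _ in range(n_modes)]
    raw_w = [draw(st.floats(0.1, 1.0)) for _ in range(n_modes)]
    weights = [w / sum(raw_w) for w in raw_w]
    return lognormal_mixture_curve(medians, sds, weights, n_bins=300)


class TestCurveProperties:
    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(random_mixture_curves())
    def test_quantile_monotonicity(self, curve):
        s = summarize(curve)
        assert s.d10_nm <= s.d50_nm <= s.d90_nm

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(random_mixture_curves(), st.floats(20, 380))
    def test_area_split_conservation(self, curve, cutoff):
        s = summarize(curve, cutoff_nm=cutoff)
        assert s.auc_below + s.auc_above == pytest.approx(curve.area, rel=1e-9)
        assert s.fraction_below_cutoff == pytest.approx(
            s.auc_below / (s.auc_below + s.auc_above)
        )

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(random_mixture_curves(), st.floats(0.01, 1e6))
    def test_scaling_invariance(self, curve, scale):
        scaled = SizeDistributionCurve(curve.sizes, curve.values * scale)
        a, b = summarize(curve), summarize(scaled)
        assert b.fraction_below_cutoff == pytest.approx(a.fraction_below_cutoff)
        assert b.mode_nm == a.mode_nm
        assert (b.d10_nm, b.d50_nm, b.d90_nm) == pytest.approx(
            (a.d10_nm, a.d50_nm, a.d90_nm)
        )
        assert b.total_particles_per_ml == pytest.approx(
            scale * a.total_particles_per_ml, rel=1e-9
        )
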