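"""Synthetic echo cohorts and M-mode analysis: round trips and estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lvcomp.cohort import (
    CohortSpec,
    MModeTrace,
    ab_cohort_spec,
    generate_echo_cohort,
    sham_cohort_spec,
)
from lvcomp.echo import (
    EchoDimensions,
    LongitudinalSeries,
    cohort_compare,
    ejection_fraction,
    ejection_fraction_volume_oracle,
    extract_dimensions,
    remodeling_rate,
)
from lvcomp.errors import (
    InsufficientDataError,
    InvalidGeometryError,
)


def _dims(r_d, r_s, w_d, w_s):
    return EchoDimensions(LVD_dia=2 * r_d, LVD_sys=2 * r_s,
                          LVWT_dia=w_d, LVWT_sys=w_s, n_beats_averaged=1)


class TestEjectionFraction:
    def test_no_contraction_gives_zero(self):
        # degenerate geometry bypasses the dataclass ordering check
        d = _dims(4.0, 3.999999, 1.5, 1.5000001)
        assert ejection_fraction(d) == pytest.approx(0.0, abs=1e-5)

    def test_matches_cylinder_volume_oracle(self):
        d = _dims(4.05, 2.45, 1.5, 2.2)
        assert ejection_fraction(d) == pytest.approx(
            ejection_fraction_volume_oracle(d), rel=1e-13)

    @given(r_d=st.floats(2.5, 6.0), contraction=st.floats(0.05, 0.7),
           w_d=st.floats(0.8, 3.0), thickening=st.floats(1.01, 2.0))
    @settings(max_examples=100, deadline=None)
    def test_oracle_equivalence_property(self, r_d, contraction, w_d,
                                         thickening):
        d = _dims(r_d, r_d * (1 - contraction), w_d, w_d * thickening)
        assert ejection_fraction(d) == pytest.approx(
            ejection_fraction_volume_oracle(d), rel=1e-12)

    def test_monotone_decreasing_in_systolic_radius(self):
        efs = [ejection_fraction(_dims(4.0, rs, 1.5, 2.2))
               for rs in np.linspace(1.5, 3.8, 12)]
        assert all(a > b for a, b in zip(efs[:-1], efs[1:]))

    def test_monotone_increasing_in_systolic_thickness(self):
        efs = [ejection_fraction(_dims(4.0, 2.5, 1.5, ws))
               for ws in np.linspace(1.6, 40.0, 12)]
        assert all(a < b for a, b in zip(efs[:-1], efs[1:]))
        assert efs[-1] < 1.0   # approaches 1 from below

    def test_printed_variant_differs(self):
        d = _dims(4.05, 2.45, 1.5, 2.2)
        assert ejection_fraction(d, "printed") != pytest.approx(
            ejection_fraction(d, "corrected"), rel=1e-6)


class TestRemodelingRate:
    def test_constant_series_gives_zero(self):
        s = LongitudinalSeries(np.array([0.0, 2.0, 4.0]),
                               np.array([1.7, 1.7, 1.7]))
        assert remodeling_rate(s) == pytest.approx(0.0, abs=1e-15)

    def test_collinear_points_exact_slope(self):
        s = LongitudinalSeries(np.array([0.0, 2.0, 4.0]),
                               np.array([1.0, 1.2, 1.4]))
        assert remodeling_rate(s) == pytest.approx(0.1, rel=1e-12)

    def test_invariant_under_rescaling(self):
        w = np.array([0.0, 2.0, 4.0])
        v = np.array([1.1, 1.35, 1.52])
        r1 = remodeling_rate(LongitudinalSeries(w, v))
        r2 = remodeling_rate(LongitudinalSeries(w, 7.3 * v))
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_zero_baseline_raises(self):
        s = LongitudinalSeries(np.array([0.0, 2.0]), np.array([0.0, 1.0]))
        with pytest.raises(ZeroDivisionError):
            remodeling_rate(s)

    def test_single_point_raises(self):
        with pytest.raises(InsufficientDataError):
            LongitudinalSeries(np.array([0.0]), np.array([1.0]))


class TestCohortCompare:
    def test_identical_groups_not_significant(self):
        g = [0.1, 0.12, 0.09, 0.11]
        rep = cohort_compare(g, g)
        assert rep.mean_a == pytest.approx(rep.mean_b)
        assert rep.p_value == pytest.approx(1.0)

    def test_welch_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.095, 0.030, 10)
        b = rng.normal(0.060, 0.030, 10)   # moderate effect
        rep = cohort_compare(a, b)
        # permutation oracle on the mean difference, 1e5 resamples
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        count = 0
        n_res = 100_000
        for _ in range(n_res):
            rng.shuffle(pooled)
            if abs(pooled[:10].mean() - pooled[10:].mean()) >= obs:
                count += 1
        p_perm = count / n_res
        assert rep.p_value == pytest.approx(p_perm, abs=0.02)

    def test_strong_effect_highly_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.095, 0.030, 10)
        b = rng.normal(0.030, 0.020, 10)
        rep = cohort_compare(a, b)
        assert rep.p_value < 1e-3

    def test_single_observation_raises(self):
        with pytest.raises(InsufficientDataError):
            cohort_compare([0.1], [0.1, 0.2])


class TestCohortGeneration:
    def test_shape_contract(self):
        spec = sham_cohort_spec(n_rats=10, seed=3)
        records = generate_echo_cohort(spec)
        assert len(records) == 10
        for rec in records:
            assert set(rec.traces) == {0.0, 2.0, 4.0}
            for trace in rec.traces.values():
                span_ms = trace.time[-1] - trace.time[0]
                assert span_ms >= 5 * spec.period_ms

    def test_reproducibility_bit_identical(self):
        spec = ab_cohort_spec(n_rats=3, seed=11)
        a = generate_echo_cohort(spec)
        b = generate_echo_cohort(spec)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.traces[4.0].endo_far,
                                          rb.traces[4.0].endo_far)

    def test_positive_thickness_and_diameter_throughout(self):
        spec = sham_cohort_spec(n_rats=5, seed=5, noise_sd_mm=0.0)
        for rec in generate_echo_cohort(spec):
            for trace in rec.traces.values():
                assert np.all(trace.inner_diameter > 0)
                assert np.all(trace.near_wall_thickness > 0)
                assert np.all(trace.far_wall_thickness > 0)


class TestNoiselessRoundTrips:
    @pytest.fixture(scope="class")
    def noiseless(self):
        spec = sham_cohort_spec(n_rats=4, seed=21, noise_sd_mm=0.0)
        return spec, generate_echo_cohort(spec)

    def test_extraction_recovers_true_dimensions(self, noiseless):
        spec, records = noiseless
        for rec in records:
            dims = extract_dimensions(rec.traces[0.0], spec.period_ms)
            assert dims.LVD_dia == pytest.approx(rec.true_lvd_dia_mm,
                                                 abs=1e-3)
            assert dims.LVWT_dia == pytest.approx(rec.true_lvwt_dia_mm,
                                                  abs=1e-3)

    def test_extraction_recovers_true_ef(self, noiseless):
        spec, records = noiseless
        for rec in records:
            dims = extract_dimensions(rec.traces[0.0], spec.period_ms)
            assert ejection_fraction(dims) == pytest.approx(rec.true_ef,
                                                            abs=1e-3)

    def test_growth_rate_round_trip_exact(self):
        spec = ab_cohort_spec(n_rats=3, seed=2, noise_sd_mm=0.0,
                              growth_rate_mean_per_week=0.095,
                              growth_rate_sd_per_week=0.0)
        for rec in generate_echo_cohort(spec):
            lvwt = [extract_dimensions(rec.traces[w], spec.period_ms).LVWT_dia
                    for w in spec.weeks]
            r = remodeling_rate(LongitudinalSeries(np.array(spec.weeks),
                                                   np.array(lvwt)))
            assert r == pytest.approx(0.095, rel=1e-3)


class TestNoisyExtraction:
    def test_estimates_within_monte_carlo_tolerance(self):
        spec = sham_cohort_spec(n_rats=6, seed=17, noise_sd_mm=0.05)
        records = generate_echo_cohort(spec)
        for rec in records:
            dims = extract_dimensions(rec.traces[0.0], spec.period_ms)
            # smoothing plus beat averaging: generous 3-sigma style bound
            assert dims.LVD_dia == pytest.approx(rec.true_lvd_dia_mm, abs=0.1)
            assert dims.LVWT_dia == pytest.approx(rec.true_lvwt_dia_mm,
                                                  abs=0.1)

    def test_constant_trace_raises_insufficient_data(self):
        t = np.arange(0, 1200.0, 1.0)
        ones = np.ones_like(t)
        trace = MModeTrace(time=t, endo_near=-4 * ones, endo_far=4 * ones,
                           epi_near=-5.5 * ones, epi_far=5.5 * ones)
        with pytest.raises(InsufficientDataError):
            extract_dimensions(trace)

    def test_short_trace_raises(self):
        spec = sham_cohort_spec(n_rats=1, seed=1, n_beats=6)
        rec = generate_echo_cohort(spec)[0]
        tr = rec.traces[0.0]
        cut = slice(0, int(0.6 * spec.period_ms / spec.dt_ms))
        short = MModeTrace(time=tr.time[cut], endo_near=tr.endo_near[cut],
                           endo_far=tr.endo_far[cut],
                           epi_near=tr.epi_near[cut], epi_far=tr.epi_far[cut])
        with pytest.raises(InsufficientDataError):
            extract_dimensions(short)


class TestDimensionInvariants:
    def test_ordering_invariants_enforced(self):
        with pytest.raises(InvalidGeometryError):
            EchoDimensions(LVD_dia=4.0, LVD_sys=5.0, LVWT_dia=1.5,
                           LVWT_sys=2.0, n_beats_averaged=1)
        with pytest.raises(InvalidGeometryError):
            EchoDimensions(LVD_dia=8.0, LVD_sys=5.0, LVWT_dia=2.5,
                           LVWT_sys=2.0, n_beats_averaged=1)
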