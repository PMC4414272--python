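"""Rate estimation and activity-summary tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cleavekit import (
    ApparentRate,
    KineticParameters,
    NoiseModel,
    ProgressCurveModel,
    RateLowerBound,
    TimeCourse,
    TitrationSeries,
    compare_activity,
    fold_excess,
    fraction_cleaved,
    gen_timecourse,
    kapp_fit,
    kapp_single_point,
    min_complete_conc,
    overdigestion_fold,
)
from cleavekit.errors import (
    ComparisonError,
    DataError,
    DomainError,
    UnidentifiableError,
)


class TestSinglePoint:
    def test_half_cleaved_at_15_min(self):
        rate = kapp_single_point(0.50, 15.0)
        assert rate.k_app == pytest.approx(math.log(2) / 15.0)
        assert rate.provenance == "single-point"

    def test_zero_fraction_gives_zero_rate(self):
        assert kapp_single_point(0.0, 30.0).k_app == 0.0

    @given(f=st.floats(1e-6, 1 - 1e-6), t=st.floats(0.01, 1e4))
    @settings(max_examples=300, derandomize=True)
    def test_round_trips_with_forward_model(self, f, t):
        rate = kapp_single_point(f, t)
        assert fraction_cleaved(rate, t) == pytest.approx(f, rel=1e-10)

    def test_saturated_point_returns_lower_bound(self):
        res = kapp_single_point(1.0, 20.0)
        assert isinstance(res, RateLowerBound)
        assert res.min_k_app == pytest.approx(-math.log(0.01) / 20.0)

    @pytest.mark.parametrize("f,t", [(-0.1, 10), (1.5, 10), (0.5, 0.0), (0.5, -5)])
    def test_domain_errors(self, f, t):
        with pytest.raises(DomainError):
            kapp_single_point(f, t)


class TestProgressCurveFit:
    def test_noiseless_recovery_to_six_digits(self):
        k_true = 0.0462
        t = np.array([5.0, 15.0, 30.0, 60.0])
        course = TimeCourse(t, 1.0 - np.exp(-k_true * t))
        res = ProgressCurveModel(course).fit()
        assert res.k_app == pytest.approx(k_true, rel=1e-6)
        assert res.rate.provenance == "fitted"

    def test_on_column_release_pair(self):
        # 80% at 15 min / 96% at 30 min lie on one exponential with
        # k = ln(5)/15, which exceeds the 90%-at-30-min release bound
        course = TimeCourse([15.0, 30.0], [0.80, 0.96])
        res = ProgressCurveModel(course).fit()
        assert res.k_app == pytest.approx(math.log(5) / 15.0, rel=1e-4)
        assert res.predict(30.0) >= 0.90

    def test_noisy_recovery_median_error(self, equal_affinity_params):
        # 50 seeded courses at sigma=0.02: median |rel err| well under 10%
        k_true = math.log(2) / 15.0
        p = KineticParameters(kcat=1.0, K_M=10.0, K_P=10.0,
                              E0=k_true * 110.0, S0=100.0)
        t = np.array([0.0, 5, 10, 15, 20, 30, 40, 50, 60])
        noise = NoiseModel(intensity_cv=0.0, fraction_sigma=0.02)
        errs = []
        for seed in range(50):
            course = gen_timecourse(p, t, noise, seed=seed)
            errs.append(abs(kapp_fit(course).k_app - k_true) / k_true)
        assert np.median(errs) < 0.10

    def test_saturated_points_excluded_when_enough_remain(self):
        k = 0.1
        t = np.array([5.0, 10.0, 20.0, 80.0])
        f = 1.0 - np.exp(-k * t)
        f[-1] = 1.0  # gel reads "complete"
        model = ProgressCurveModel(TimeCourse(t, f))
        assert model.n_saturated == 1 and model.t_fit.size == 3
        assert model.fit().k_app == pytest.approx(k, rel=1e-6)

    def test_all_saturated_is_unidentifiable(self):
        with pytest.raises(UnidentifiableError):
            ProgressCurveModel(TimeCourse([10.0, 20.0], [1.0, 1.0])).fit()

    def test_too_few_points(self):
        with pytest.raises(DataError):
            ProgressCurveModel(TimeCourse([10.0], [0.5])).fit()

    def test_standard_error_covers_truth(self):
        k_true = 0.05
        p = KineticParameters(kcat=1.0, K_M=10.0, K_P=10.0,
                              E0=k_true * 110.0, S0=100.0)
        t = np.linspace(5, 60, 8)
        t = np.concatenate(([0.0], t))
        noise = NoiseModel(intensity_cv=0.0, fraction_sigma=0.02)
        hits = 0
        for seed in range(40):
            res = ProgressCurveModel(gen_timecourse(p, t, noise, seed=seed)).fit()
            if abs(res.k_app - k_true) <= 3.0 * res.bse:
                hits += 1
        assert hits >= 0.9 * 40

    def test_summary_mentions_rate(self):
        course = TimeCourse([15.0, 30.0], [0.5, 0.75], {"substrate": "xLC3B"})
        text = ProgressCurveModel(course).fit().summary()
        assert "k_app" in text and "substrate=xLC3B" in text


class TestFoldExcess:
    def test_values(self):
        assert fold_excess(100.0, 0.001) == pytest.approx(100_000)
        assert fold_excess(5.0, 5.0) == 1.0
        assert fold_excess(100.0, 0.3) == pytest.approx(333.333, rel=1e-3)

    def test_zero_enzyme_rejected(self):
        with pytest.raises(DomainError):
            fold_excess(100.0, 0.0)


class TestMinCompleteConc:
    concs = np.array([0.01, 0.03, 0.1, 0.3, 1.0, 3.0])

    def make(self, fractions):
        return TitrationSeries(self.concs, np.asarray(fractions))

    def test_threshold_crossing(self):
        series = self.make([0.10, 0.30, 0.70, 0.94, 0.97, 1.0])
        ep = min_complete_conc(series, 0.95)
        assert ep.conc == 1.0 and not ep.censored and not ep.upper_bound_only

    def test_all_below_threshold_is_censored(self):
        ep = min_complete_conc(self.make([0.1] * 6), 0.95)
        assert ep.censored and ep.conc is None and ep.max_tested == 3.0

    def test_lowest_lane_already_complete_is_upper_bound(self):
        ep = min_complete_conc(self.make([0.96, 0.97, 0.98, 0.99, 1.0, 1.0]), 0.95)
        assert ep.conc == 0.01 and ep.upper_bound_only

    def test_non_monotone_series_flagged(self):
        ep = min_complete_conc(self.make([0.1, 0.3, 0.96, 0.90, 0.99, 1.0]), 0.95)
        assert ep.conc == 0.1 and ep.non_monotone

    def test_monotone_in_threshold(self):
        series = self.make([0.10, 0.30, 0.70, 0.94, 0.97, 1.0])
        concs = [min_complete_conc(series, th).conc for th in (0.5, 0.9, 0.95, 1.0)]
        assert concs == sorted(concs)

    def test_empty_series_rejected(self):
        with pytest.raises(DataError):
            TitrationSeries(np.array([]), np.array([]))

    def test_bad_threshold(self):
        with pytest.raises(DomainError):
            min_complete_conc(self.make([0.5] * 6), 0.0)


class TestCompareActivity:
    def test_rate_fold(self):
        cmp = compare_activity(ApparentRate(0.04, "fitted"),
                               ApparentRate(0.01, "fitted"))
        assert cmp.fold == pytest.approx(4.0) and cmp.faster == "a"

    def test_min_conc_inverted(self):
        a = min_complete_conc(
            TitrationSeries([0.25, 1.0, 4.0], [0.5, 0.96, 1.0]), 0.95)
        b = min_complete_conc(
            TitrationSeries([0.25, 1.0, 4.0], [0.96, 0.99, 1.0]), 0.95)
        cmp = compare_activity(a, b)
        assert cmp.fold == pytest.approx(4.0) and cmp.faster == "b"
        assert cmp.is_bound  # b is only an upper bound

    def test_lower_bound_rate_is_qualitative(self):
        bound = kapp_single_point(1.0, 10.0)
        cmp = compare_activity(bound, ApparentRate(0.01, "fitted"))
        assert cmp.is_bound and cmp.faster == "a"

    def test_condition_mismatch_lists_fields(self):
        with pytest.raises(ComparisonError, match="temp_C"):
            compare_activity(
                ApparentRate(0.04, "fitted"), ApparentRate(0.01, "fitted"),
                conditions_a={"substrate": "xLC3B", "temp_C": 0},
                conditions_b={"substrate": "xLC3B", "temp_C": 25},
            )

    def test_mixed_kinds_rejected(self):
        ep = min_complete_conc(TitrationSeries([1.0, 2.0], [0.96, 1.0]), 0.95)
        with pytest.raises(ComparisonError):
            compare_activity(ApparentRate(0.1, "fitted"), ep)


class TestOverdigestion:
    def test_values(self):
        assert overdigestion_fold(20.0, 0.001).fold == pytest.approx(20_000)
        assert overdigestion_fold(1.0, 1.0).fold == 1.0

    def test_upper_bound_min_gives_lower_bound_fold(self):
        ep = min_complete_conc(TitrationSeries([0.01, 0.1], [0.99, 1.0]), 0.95)
        res = overdigestion_fold(20.0, ep)
        assert res.is_lower_bound and res.fold == pytest.approx(2000.0)

    def test_censored_min_rejected(self):
        ep = min_complete_conc(TitrationSeries([0.01, 0.1], [0.1, 0.2]), 0.95)
        with pytest.raises(DataError):
            overdigestion_fold(20.0, ep)
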