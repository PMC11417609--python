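"""Agreement statistics: hand-computed examples, symmetries, test calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from xcal.agreement import (
    CorrelationStrength,
    bland_altman,
    classify_correlation,
    compare_methods,
    percent_error_from_values,
)


def series(values, prefix="S"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))],
                     dtype=float)


class TestPercentError:
    def test_ten_percent(self):
        s = percent_error_from_values(series([110.0, 110.0]), series([100.0, 100.0]))
        assert s.mean == pytest.approx(10.0)

    def test_exact_estimates_give_zero_with_degenerate_ci(self):
        m = series([3.0, 4.0, 5.0])
        s = percent_error_from_values(m, m)
        assert (s.mean, s.ci_low, s.ci_high) == (0.0, 0.0, 0.0)

    def test_hand_computed_t_interval(self):
        # errors 2,4,6,8%: mean 5, SE = 2.582/2, t(0.975, 3) = 3.1824
        measured = series([100.0] * 4)
        estimated = series([102.0, 104.0, 106.0, 108.0])
        s = percent_error_from_values(estimated, measured)
        assert s.mean == pytest.approx(5.0)
        half = stats.t.ppf(0.975, 3) * np.std([2, 4, 6, 8], ddof=1) / 2.0
        assert s.ci_high - s.mean == pytest.approx(half)
        assert s.ci_high - s.mean == pytest.approx(4.1086, abs=1e-3)

    def test_zero_measured_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="measured value 0"):
            s = percent_error_from_values(series([1.0, 2.0, 3.0]),
                                          series([0.0, 2.0, 3.0]))
        assert s.n == 2 and s.n_excluded == 1

    def test_scale_invariance(self):
        est, meas = series([11.0, 13.0, 9.0]), series([10.0, 12.0, 10.0])
        a = percent_error_from_values(est, meas)
        b = percent_error_from_values(7.3 * est, 7.3 * meas)
        assert a.mean == pytest.approx(b.mean)
        assert a.errors.to_numpy() == pytest.approx(b.errors.to_numpy())


class TestBlandAltman:
    def test_identical_series(self):
        r = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r.mean_difference, r.loa_low, r.loa_high) == (0.0, 0.0, 0.0)
        assert r.prop_bias_slope == 0.0

    def test_constant_offset(self):
        r = bland_altman([6.0, 7.0, 8.0], [1.0, 2.0, 3.0])
        assert r.mean_difference == pytest.approx(5.0)
        assert r.sd_difference == 0.0
        assert r.prop_bias_slope == 0.0

    def test_hand_computed_example(self):
        r = bland_altman([1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 2.0, 2.0])
        assert r.mean_difference == pytest.approx(0.5)
        assert r.sd_difference == pytest.approx(1.2910, abs=1e-4)
        assert r.loa_low == pytest.approx(-2.0303, abs=1e-3)
        assert r.loa_high == pytest.approx(3.0303, abs=1e-3)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(10, 2, 20), rng.normal(10, 2, 20)
        assert bland_altman(a, b).mean_difference == pytest.approx(
            -bland_altman(b, a).mean_difference)

    def test_constant_means_flag_undefined_bias(self):
        # a + b constant => means constant while differences vary
        a = np.array([1.0, 2.0, 3.0])
        r = bland_altman(a, 4.0 - a)
        assert np.isnan(r.prop_bias_slope) and np.isnan(r.prop_bias_p)

    def test_proportional_bias_detected(self):
        rng = np.random.default_rng(1)
        b = rng.normal(10, 3, 40)
        a = 1.5 * b + rng.normal(0, 0.1, 40)  # difference grows with level
        r = bland_altman(a, b)
        assert r.prop_bias_flagged and r.prop_bias_slope > 0

    def test_loa_coverage_for_gaussian_differences(self):
        rng = np.random.default_rng(2)
        b = rng.normal(50, 5, 10_000)
        a = b + rng.normal(1.0, 2.0, 10_000)
        r = bland_altman(a, b)
        d = a - b
        coverage = np.mean((d >= r.loa_low) & (d <= r.loa_high))
        assert coverage == pytest.approx(0.95, abs=0.02)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            bland_altman([1.0, 2.0], [1.0, 2.0])


class TestClassification:
    @pytest.mark.parametrize("r2, expected", [
        (0.95, CorrelationStrength.strong),
        (0.31, CorrelationStrength.weak),
        (0.80, CorrelationStrength.moderate),
        (0.69, CorrelationStrength.weak),
        (0.91, CorrelationStrength.strong),
    ])
    def test_bands(self, r2, expected):
        assert classify_correlation(r2) is expected

    @pytest.mark.parametrize("boundary, expected", [
        (0.9, CorrelationStrength.moderate),
        (0.7, CorrelationStrength.weak),
    ])
    def test_open_boundaries_fall_to_lower_class_with_warning(self, boundary,
                                                              expected):
        with pytest.warns(UserWarning, match="boundary"):
            assert classify_correlation(boundary) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_correlation(1.2)


finite_pairs = hnp.arrays(
    np.float64, st.integers(3, 25),
    elements=st.floats(-1e3, 1e3, allow_nan=False, width=32),
)


class TestBlandAltmanProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=finite_pairs, b=finite_pairs)
    def test_loa_bracket_mean_and_antisymmetry(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        if n < 3:
            return
        r = bland_altman(a, b)
        assert r.loa_low <= r.mean_difference <= r.loa_high
        assert r.mean_difference == pytest.approx(
            -bland_altman(b, a).mean_difference, abs=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(values=finite_pairs, scale=st.floats(0.01, 100.0))
    def test_percent_error_scale_invariance(self, values, scale):
        measured = np.abs(values) + 1.0  # strictly positive
        estimated = measured * 1.07
        a = percent_error_from_values(series(estimated), series(measured))
        b = percent_error_from_values(series(estimated * scale),
                                      series(measured * scale))
        assert a.mean == pytest.approx(b.mean, rel=1e-9)


def summary_of(errors):
    return percent_error_from_values(series(100.0 + np.asarray(errors)),
                                     series([100.0] * len(errors)))


class TestCompareMethods:
    def test_identical_errors_give_p_one(self):
        s = summary_of([2.0, 4.0, 6.0])
        assert compare_methods(s, s) == 1.0

    def test_constant_shift_with_zero_variance_gives_p_zero(self):
        a = summary_of([5.0] * 12)
        b = summary_of([2.0] * 12)
        assert compare_methods(a, b) == 0.0

    def test_matches_scipy_paired_t(self):
        rng = np.random.default_rng(3)
        e1, e2 = rng.uniform(1, 8, 12), rng.uniform(1, 8, 12)
        p = compare_methods(summary_of(e1), summary_of(e2))
        assert p == pytest.approx(stats.ttest_rel(e1, e2).pvalue)

    def test_unpaired_inputs_rejected(self):
        a = summary_of([1.0, 2.0, 3.0])
        b = percent_error_from_values(series([101.0, 102.0], prefix="T"),
                                      series([100.0, 100.0], prefix="T"))
        with pytest.raises(ValueError, match="paired"):
            compare_methods(a, b)

    def test_power_matches_analytic_paired_t(self):
        """Rejection rate under a known 2% mean shift (SD 2%, n=12) matches
        the noncentral-t power of the paired t-test within 5%."""
        n, shift, sd = 12, 2.0, 2.0
        ncp = shift / (sd / np.sqrt(n))
        tcrit = stats.t.ppf(0.975, n - 1)
        power = 1 - stats.nct.cdf(tcrit, n - 1, ncp) + stats.nct.cdf(-tcrit,
                                                                     n - 1, ncp)
        rng = np.random.default_rng(4)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            base = rng.uniform(8, 15, n)
            d = rng.normal(shift, sd, n)
            p = compare_methods(summary_of(base + d), summary_of(base))
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(power, abs=0.05)
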