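"""Bland-Altman, paired t, correlation and calibration regression.

The brute-force oracle in this file evaluates every statistic from the
textbook definitions with plain Python loops; the implementation under test
must agree with it to 1e-10 on random samples.
"""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from bodycomp3c.errors import InsufficientDataError
from bodycomp3c.method_agreement import (
    PairedSample,
    bland_altman,
    calibration_regression,
    mean_difference,
    paired_t_test,
    pearson,
    summarize_agreement,
)


def sample(test, ref, variable="bf_pct"):
    return PairedSample(variable, np.asarray(test, float), np.asarray(ref, float))


finite_series = st.lists(
    st.floats(-100.0, 100.0), min_size=4, max_size=30
).filter(lambda xs: np.ptp(xs) > 1e-6)


class TestBlandAltman:
    def test_hand_computed_example(self):
        ba = bland_altman(sample([19, 20, 21], [25, 24, 26]))
        assert ba["mean_diff"] == pytest.approx(-5.0)
        assert ba["sd_diff"] == pytest.approx(1.0)
        assert ba["loa_lower"] == pytest.approx(-7.0)
        assert ba["loa_upper"] == pytest.approx(-3.0)
        assert ba["loa_half_width"] == pytest.approx(2.0)

    def test_identical_methods(self):
        ba = bland_altman(sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert ba["mean_diff"] == 0.0
        assert ba["sd_diff"] == 0.0
        assert ba["loa_lower"] == ba["loa_upper"] == 0.0

    def test_constant_offset(self):
        ba = bland_altman(sample([3.0, 4.0, 5.0], [1.0, 2.0, 3.0]))
        assert ba["mean_diff"] == pytest.approx(2.0)
        assert ba["sd_diff"] == 0.0
        assert ba["trend_slope"] == 0.0

    def test_zero_variance_averages_flagged(self):
        ba = bland_altman(sample([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]))
        assert math.isnan(ba["trend_slope"])
        assert "trend_undefined" in ba["flags"]

    def test_too_few_subjects(self):
        with pytest.raises(InsufficientDataError):
            sample([1.0, 2.0], [1.0, 2.0])

    def test_printed_method_means_reproduce_bias(self):
        # bias between method means equals the mean per-subject difference
        assert mean_difference(19.4, 25.1) == pytest.approx(-5.7)
        assert mean_difference(4.1, 5.3) == pytest.approx(-1.2)
        assert mean_difference(16.4, 15.2) == pytest.approx(1.2)


class TestPairedT:
    def test_hand_computed_example(self):
        # diffs -6, -4, -5: t = -5/(1/sqrt(3)), p = 1 - |t|/sqrt(t^2+2) for df=2
        t, p = paired_t_test(sample([19, 20, 21], [25, 24, 26]))
        assert t == pytest.approx(-5 * math.sqrt(3), rel=1e-12)
        assert p == pytest.approx(0.013072, abs=1e-6)

    def test_degenerate_zero_variance(self):
        t, p = paired_t_test(sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert math.isnan(t) and math.isnan(p)

    def test_calibrated_simulation_direction(self, medium_cohort):
        """BIA sits far below the criterion: a decisive negative paired t."""
        truth = medium_cohort.truth
        s = sample(medium_cohort.records["bia_bf_pct"], truth["true_bf3c"])
        t, p = paired_t_test(s)
        assert t < 0
        assert p < 1e-10


class TestPearson:
    def test_affine_invariance(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0])
        r, _ = pearson(sample(2 * ref + 1, ref))
        assert r == pytest.approx(1.0, rel=1e-12)

    def test_hand_computed_example(self):
        r, _ = pearson(sample([1, 2, 3], [2, 1, 3]))
        assert r == pytest.approx(0.5, rel=1e-12)

    def test_zero_variance_undefined(self):
        r, p = pearson(sample([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))
        assert math.isnan(r) and math.isnan(p)


class TestCalibrationRegression:
    def test_exact_proportionality(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0])
        intercept, slope, r2, see = calibration_regression(sample(ref, 3 * ref))
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert slope == pytest.approx(3.0, rel=1e-12)
        assert r2 == pytest.approx(1.0, rel=1e-12)
        assert see == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_ols(self):
        intercept, slope, _, _ = calibration_regression(sample([1, 2, 3], [2, 1, 3]))
        assert slope == pytest.approx(0.5, rel=1e-12)
        assert intercept == pytest.approx(1.0, rel=1e-12)


class TestProperties:
    @given(data=st.data())
    def test_antisymmetry_under_method_swap(self, data):
        xs = np.array(data.draw(finite_series))
        ys = np.array(data.draw(st.lists(
            st.floats(-100.0, 100.0), min_size=len(xs), max_size=len(xs))))
        a = bland_altman(sample(xs, ys))
        b = bland_altman(sample(ys, xs))
        assert b["mean_diff"] == pytest.approx(-a["mean_diff"], abs=1e-9)
        assert b["sd_diff"] == pytest.approx(a["sd_diff"], abs=1e-9)
        assert b["loa_lower"] == pytest.approx(-a["loa_upper"], abs=1e-9)
        assert b["loa_upper"] == pytest.approx(-a["loa_lower"], abs=1e-9)

    @given(data=st.data(), c=st.floats(0.1, 50.0))
    def test_scale_equivariance(self, data, c):
        xs = np.array(data.draw(finite_series))
        ys = xs + np.arange(len(xs))  # guarantees varying diffs
        a = bland_altman(sample(xs, ys))
        b = bland_altman(sample(c * xs, c * ys))
        assert b["mean_diff"] == pytest.approx(c * a["mean_diff"], rel=1e-9)
        assert b["sd_diff"] == pytest.approx(c * a["sd_diff"], rel=1e-9)
        r_a, _ = pearson(sample(xs, ys))
        r_b, _ = pearson(sample(c * xs, c * ys))
        assert r_b == pytest.approx(r_a, abs=1e-9)


def oracle_statistics(test, ref):
    """Direct-definition reference implementation (independent of scipy)."""
    n = len(test)
    diffs = [t - r for t, r in zip(test, ref)]
    avgs = [(t + r) / 2 for t, r in zip(test, ref)]

    def mean(xs):
        return sum(xs) / len(xs)

    def sd(xs):
        m = mean(xs)
        return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))

    def ols(x, y):
        mx, my = mean(x), mean(y)
        sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
        sxx = sum((a - mx) ** 2 for a in x)
        slope = sxy / sxx
        return my - slope * mx, slope

    def corr(x, y):
        mx, my = mean(x), mean(y)
        sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
        sxx = sum((a - mx) ** 2 for a in x)
        syy = sum((b - my) ** 2 for b in y)
        return sxy / math.sqrt(sxx * syy)

    md, sdd = mean(diffs), sd(diffs)
    t_stat = md / (sdd / math.sqrt(n))
    r = corr(test, ref)
    t_r = r * math.sqrt((n - 2) / (1 - r * r))
    b0, b1 = ols(test, ref)
    ss_res = sum((y - (b0 + b1 * x)) ** 2 for x, y in zip(test, ref))
    trend_b0, trend_b1 = ols(avgs, diffs)
    return {
        "mean_diff": md,
        "sd_diff": sdd,
        "loa_lower": md - 2 * sdd,
        "loa_upper": md + 2 * sdd,
        "trend_slope": trend_b1,
        "trend_intercept": trend_b0,
        "trend_r": corr(avgs, diffs),
        "paired_t": t_stat,
        "paired_p": 2 * sps.t.sf(abs(t_stat), n - 1),
        "pearson_r": r,
        "pearson_p": 2 * sps.t.sf(abs(t_r), n - 2),
        "reg_intercept": b0,
        "reg_slope": b1,
        "reg_r2": corr(test, ref) ** 2,
        "reg_see": math.sqrt(ss_res / (n - 2)),
    }


def test_oracle_equivalence_on_random_samples(rng):
    """All statistics match the direct-formula oracle on 100 random samples."""
    for _ in range(100):
        n = int(rng.integers(4, 25))
        test = rng.normal(20, 4, n)
        ref = 3 + 1.1 * test + rng.normal(0, 3, n)
        got = summarize_agreement(sample(test, ref))
        want = oracle_statistics(list(test), list(ref))
        for key, expected in want.items():
            assert getattr(got, key) == pytest.approx(expected, abs=1e-10), key
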