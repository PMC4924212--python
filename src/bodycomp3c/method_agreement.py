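"""Paired-method agreement statistics: Bland-Altman, t-test, correlation, calibration.

For a test method (BIA) and a reference/criterion method (3C model) measured
on the same subjects, the comparison comprises:

* Bland-Altman: per-subject differences (test - ref) against per-subject
  averages; mean difference (bias), SD of differences, and limits of
  agreement at mean +/- 2*SD.  A trend (proportional bias) is assessed by
  OLS of difference on average, with significance from the Pearson
  correlation of (average, difference).
* a paired Student t-test on the differences;
* Pearson correlation between the raw series;
* a calibration regression of the criterion on the test method, with R^2 and
  the standard error of the estimate SEE = sqrt(SS_res / (n - 2)).

Conventions: sample SDs use the n-1 denominator; limits of agreement use
exactly +/- 2 SD (not 1.96); degenerate cases (zero-variance differences or
averages) are reported as NaN with a flag rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, SchemaError


@dataclass(frozen=True)
class PairedSample:
    """Aligned per-subject values from the test (BIA) and reference (3C) methods."""

    variable: str
    test_values: np.ndarray
    ref_values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.test_values, dtype=float)
        r = np.asarray(self.ref_values, dtype=float)
        object.__setattr__(self, "test_values", t)
        object.__setattr__(self, "ref_values", r)
        if t.ndim != 1 or t.shape != r.shape:
            raise SchemaError("test and reference series must be 1-D and equal length")
        if len(t) < 3:
            raise InsufficientDataError("paired agreement needs at least 3 subjects")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
            raise SchemaError("paired values must be finite")

    @property
    def n(self) -> int:
        return len(self.test_values)


@dataclass(frozen=True)
class AgreementSummary:
    """All agreement statistics for one variable across a cohort."""

    variable: str
    units: str
    n: int
    mean_test: float
    mean_ref: float
    # Bland-Altman difference block
    mean_diff: float
    sd_diff: float
    loa_half_width: float  # 2 * sd_diff
    loa_lower: float
    loa_upper: float
    # trend of difference on average
    trend_slope: float
    trend_intercept: float
    trend_r: float
    trend_p: float
    # paired t-test
    paired_t: float
    paired_p: float
    # correlation between the raw series
    pearson_r: float
    pearson_p: float
    # calibration regression: reference on test
    reg_intercept: float
    reg_slope: float
    reg_r2: float
    reg_see: float
    flags: tuple[str, ...] = ()


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1))


def bland_altman(sample: PairedSample) -> dict:
    """Difference block: bias, SD of differences, +/-2SD limits, trend.

    Returns a dict with keys ``n, mean_test, mean_ref, mean_diff, sd_diff,
    loa_half_width, loa_lower, loa_upper, trend_slope, trend_intercept,
    trend_r, trend_p, flags``.  The trend is undefined (NaN, flagged) when the
    averages have zero variance.
    """
    diffs = sample.test_values - sample.ref_values
    avgs = (sample.test_values + sample.ref_values) / 2.0
    mean_diff = float(np.mean(diffs))
    sd_diff = _sd(diffs)
    flags: list[str] = []
    if np.ptp(avgs) == 0:
        slope = intercept = r = p = float("nan")
        flags.append("trend_undefined")
    elif np.ptp(diffs) == 0:
        # constant offset: flat trend with an exactly zero slope
        slope, r = 0.0, 0.0
        intercept = mean_diff
        p = 1.0
    else:
        fit = stats.linregress(avgs, diffs)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r, p = float(fit.rvalue), float(fit.pvalue)
    return {
        "n": sample.n,
        "mean_test": float(np.mean(sample.test_values)),
        "mean_ref": float(np.mean(sample.ref_values)),
        "mean_diff": mean_diff,
        "sd_diff": sd_diff,
        "loa_half_width": 2.0 * sd_diff,
        "loa_lower": mean_diff - 2.0 * sd_diff,
        "loa_upper": mean_diff + 2.0 * sd_diff,
        "trend_slope": slope,
        "trend_intercept": intercept,
        "trend_r": r,
        "trend_p": p,
        "flags": tuple(flags),
    }


def mean_difference(mean_test: float, mean_ref: float) -> float:
    """Bias between method means (test - ref); linearity of the mean makes this
    identical to the mean of per-subject differences."""
    return mean_test - mean_ref


def paired_t_test(sample: PairedSample) -> tuple[float, float]:
    """Paired Student t-test on the differences.

    ``t = mean_diff / (sd_diff / sqrt(n))`` with n-1 df, two-sided p.  When
    the differences have zero variance the statistic is undefined and
    ``(nan, nan)`` is returned.
    """
    diffs = sample.test_values - sample.ref_values
    sd = _sd(diffs)
    if sd == 0:
        return float("nan"), float("nan")
    n = sample.n
    t = float(np.mean(diffs)) / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return t, p


def pearson(sample: PairedSample) -> tuple[float, float]:
    """Product-moment correlation of the two series with its two-sided p.

    Undefined (NaN, NaN) when either series has zero variance.
    """
    if np.ptp(sample.test_values) == 0 or np.ptp(sample.ref_values) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(sample.test_values, sample.ref_values)
    return float(res.statistic), float(res.pvalue)


def calibration_regression(sample: PairedSample) -> tuple[float, float, float, float]:
    """OLS of the reference (3C) on the test (BIA) values.

    Returns ``(intercept, slope, r2, see)``.  Undefined (NaNs) when the test
    series has zero variance.
    """
    x, y = sample.test_values, sample.ref_values
    if np.ptp(x) == 0:
        return (float("nan"),) * 4
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    see = math.sqrt(float(np.sum(resid**2)) / (sample.n - 2))
    return float(fit.intercept), float(fit.slope), float(fit.rvalue) ** 2, see


def summarize_agreement(sample: PairedSample) -> AgreementSummary:
    """Full agreement summary for one variable: all four statistic blocks."""
    ba = bland_altman(sample)
    t, p_t = paired_t_test(sample)
    r, p_r = pearson(sample)
    intercept, slope, r2, see = calibration_regression(sample)
    flags = list(ba.pop("flags"))
    if math.isnan(t):
        flags.append("paired_t_undefined")
    if math.isnan(r):
        flags.append("pearson_undefined")
    return AgreementSummary(
        variable=sample.variable,
        units=sample.units,
        paired_t=t,
        paired_p=p_t,
        pearson_r=r,
        pearson_p=p_r,
        reg_intercept=intercept,
        reg_slope=slope,
        reg_r2=r2,
        reg_see=see,
        flags=tuple(flags),
        **ba,
    )
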