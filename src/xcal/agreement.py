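"""Validation statistics: percent error, Bland-Altman agreement, correlation
strength classification, and paired comparison of segmentation methods.

Percent-error summaries report the mean absolute percent error between
estimated (XCTII*) and measured (XCTII) values with a t-based 95%
confidence interval.  Bland-Altman analysis reports the mean difference,
the 95% limits of agreement (mean +/- 1.96 SD of the differences), and a
proportional-bias test (OLS slope of differences on means, two-sided p).
The standard-vs-LH comparison is a paired two-sided t-test on per-subject
absolute percent errors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import EstimateSet
from .tables import OutcomeTable

__all__ = [
    "PercentErrorSummary",
    "BlandAltmanResult",
    "CorrelationStrength",
    "percent_error",
    "percent_error_from_values",
    "bland_altman",
    "classify_correlation",
    "compare_methods",
]

logger = logging.getLogger(__name__)


@dataclass
class PercentErrorSummary:
    """Mean absolute percent error with t-based 95% CI."""

    parameter: str
    errors: pd.Series  # per-subject absolute percent errors
    mean: float
    ci_low: float
    ci_high: float
    n: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not self.ci_low <= self.mean <= self.ci_high:
            raise ValueError("CI must bracket the mean")


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    mean = float(values.mean())
    n = values.size
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    if sd == 0.0:
        return mean, mean, mean
    half = float(stats.t.ppf(0.5 + level / 2.0, n - 1)) * sd / np.sqrt(n)
    return mean, mean - half, mean + half


def percent_error_from_values(estimated: pd.Series, measured: pd.Series,
                              parameter: str = "") -> PercentErrorSummary:
    """Per-subject |estimated - measured| / measured x 100 with 95% CI.

    Subjects with a measured value of zero are excluded with a warning;
    incomplete pairs are dropped.
    """
    est = pd.Series(estimated, dtype=np.float64)
    meas = pd.Series(measured, dtype=np.float64)
    joined = pd.concat([est.rename("est"), meas.rename("meas")], axis=1,
                       join="inner").dropna()
    zero = joined["meas"] == 0.0
    if zero.any():
        warnings.warn(
            f"{parameter or 'percent_error'}: excluded {int(zero.sum())} "
            "subject(s) with measured value 0", stacklevel=2,
        )
    joined = joined[~zero]
    if len(joined) < 2:
        raise ValueError("need at least 2 valid pairs for percent error")
    errors = (joined["est"] - joined["meas"]).abs() / joined["meas"].abs() * 100.0
    mean, lo, hi = _t_ci(errors.to_numpy())
    return PercentErrorSummary(
        parameter=parameter, errors=errors, mean=mean, ci_low=lo, ci_high=hi,
        n=len(errors), n_excluded=int(zero.sum()),
    )


def percent_error(estimates: EstimateSet, measured: OutcomeTable,
                  method: str | None = None) -> PercentErrorSummary:
    """Percent error of an estimate set against measured XCTII values."""
    meas = measured.values_for(estimates.parameter, scanner="XCTII", method=method)
    return percent_error_from_values(estimates.estimates, meas,
                                     parameter=estimates.parameter)


@dataclass
class BlandAltmanResult:
    """Agreement between two paired measurement series."""

    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    prop_bias_slope: float
    prop_bias_p: float
    prop_bias_flagged: bool
    n: int

    def __post_init__(self) -> None:
        if not self.loa_low <= self.mean_difference <= self.loa_high:
            raise ValueError("limits of agreement must bracket the mean difference")


def bland_altman(a, b, alpha: float = 0.05) -> BlandAltmanResult:
    """Bland-Altman statistics for paired series ``a`` and ``b``.

    Differences are a - b, plotted against pair means; the limits of
    agreement are mean +/- 1.96 SD.  Proportional bias is the OLS slope of
    differences on means with its two-sided p-value; a constant-mean input
    leaves the proportional bias undefined (NaN, flagged).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1D arrays of equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("need at least 3 pairs for Bland-Altman analysis")
    diffs = a - b
    means = (a + b) / 2.0
    md = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    loa_low, loa_high = md - 1.96 * sd, md + 1.96 * sd
    if np.ptp(means) == 0.0:
        logger.warning("constant pair means: proportional bias undefined")
        slope, p = float("nan"), float("nan")
        flagged = False
    elif sd == 0.0:
        # differences constant: zero slope, no bias
        slope, p = 0.0, 1.0
        flagged = False
    else:
        reg = stats.linregress(means, diffs)
        slope, p = float(reg.slope), float(reg.pvalue)
        flagged = p < alpha
    return BlandAltmanResult(
        mean_difference=md, sd_difference=sd, loa_low=loa_low, loa_high=loa_high,
        prop_bias_slope=slope, prop_bias_p=p, prop_bias_flagged=flagged, n=a.size,
    )


class CorrelationStrength(str, Enum):
    strong = "strong"
    moderate = "moderate"
    weak = "weak"


def classify_correlation(r_squared: float) -> CorrelationStrength:
    """strong if R^2 > 0.9, moderate if 0.7 < R^2 < 0.9, weak if R^2 < 0.7.

    The class intervals are open; boundary values fall to the lower class
    and are flagged with a warning.
    """
    if not 0.0 <= r_squared <= 1.0:
        raise ValueError("R^2 must lie in [0, 1]")
    if r_squared in (0.7, 0.9):
        warnings.warn(
            f"R^2 = {r_squared} sits on an open class boundary; assigned to "
            "the lower class", stacklevel=2,
        )
    if r_squared > 0.9:
        return CorrelationStrength.strong
    if r_squared > 0.7:
        return CorrelationStrength.moderate
    return CorrelationStrength.weak


def compare_methods(errors_standard: PercentErrorSummary,
                    errors_lh: PercentErrorSummary) -> float:
    """Paired two-sided t-test on per-subject absolute percent errors.

    Returns the p-value; inputs must share their subjects.  Degenerate
    zero-variance differences give p = 1 (identical) or p = 0 (constant
    nonzero shift).
    """
    e1 = errors_standard.errors
    e2 = errors_lh.errors
    joined = pd.concat([e1.rename("a"), e2.rename("b")], axis=1, join="inner")
    if len(joined) != len(e1) or len(joined) != len(e2):
        raise ValueError("error summaries are not paired by subject")
    if len(joined) < 2:
        raise ValueError("need at least 2 paired subjects")
    d = (joined["a"] - joined["b"]).to_numpy()
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        return 1.0 if d.mean() == 0.0 else 0.0
    t = d.mean() / (sd / np.sqrt(n))
    return float(2.0 * stats.t.sf(abs(t), n - 1))
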