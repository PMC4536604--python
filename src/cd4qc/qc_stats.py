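"""Pure statistical kernel for CD4 internal quality control.

Every statistic used by the duplicate-analysis and stabilized-control
monitors lives here, with no I/O and no state:

* percent variation of a re-tested sample against its previous-day value,
* mean absolute percent variation (signs ignored),
* coefficient of variation (%CV) of repeated control measurements,
* Pearson r / r-squared of day-1 vs day-2 counts,
* Bland-Altman bias and limits of agreement,
* QC failure rate per laboratory-year,
* per-day mean and standard error of percent variation across laboratories.

Conventions: standard deviations are sample standard deviations (n-1
denominator, the clinical-lab convention for small-n QC series); the
Bland-Altman difference direction is day2 - day1 (observed - expected),
matching the sign of percent variation; limits of agreement use exactly
2 standard deviations by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

__all__ = [
    "DomainError",
    "InsufficientDataError",
    "PercentVariation",
    "BlandAltmanResult",
    "RegressionResult",
    "PrecisionStats",
    "FailureRate",
    "percent_variation",
    "mean_abs_percent_variation",
    "coefficient_of_variation",
    "regression_r2",
    "bland_altman",
    "failure_rate",
    "daily_mean_se",
]

#: Acceptance limit for percent variation, in percent. Values with
#: |%V| strictly greater than this are unacceptable (the boundary is in).
DEFAULT_PV_THRESHOLD = 20.0

#: Multiplier on the SD of paired differences for limits of agreement.
DEFAULT_K_SD = 2.0


class DomainError(ValueError):
    """An input is outside the statistic's domain (e.g. nonpositive baseline)."""


class InsufficientDataError(ValueError):
    """Too few observations to compute the statistic."""


@dataclass(frozen=True)
class PercentVariation:
    """Signed percent variation of a duplicate measurement.

    ``value`` is observed/expected x 100 - 100 in percent; ``acceptable``
    is True iff |value| <= threshold (inclusive).
    """

    value: float
    acceptable: bool
    threshold: float = DEFAULT_PV_THRESHOLD


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement between paired day-1 / day-2 counts.

    ``bias`` is the mean of (day2 - day1) differences in cells/uL;
    limits of agreement are bias +/- k_sd * sd_diff.
    """

    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n_pairs: int
    k_sd: float = DEFAULT_K_SD


@dataclass(frozen=True)
class RegressionResult:
    """Pearson correlation and simple-regression fit of paired counts."""

    pearson_r: float
    r_squared: float
    slope: float
    intercept: float
    n_pairs: int


@dataclass(frozen=True)
class PrecisionStats:
    """Bundle of the precision statistics reported per laboratory."""

    mean_abs_pv: float
    cv_percent: float | None
    r_squared: float
    pearson_r: float


@dataclass(frozen=True)
class FailureRate:
    """QC failures normalised by laboratory observation time.

    ``rate_per_lab_year`` divides failures by lab-months/12 (the primary
    quantity); ``rate_per_lab_month`` is the raw failures-per-month rate.
    """

    n_failures: float
    lab_months: float
    rate_per_lab_year: float

    @property
    def rate_per_lab_month(self) -> float:
        return self.n_failures / self.lab_months


def _as_finite_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise DomainError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} contains non-finite values")
    return arr


def percent_variation(
    expected_day1: float,
    observed_day2: float,
    threshold: float = DEFAULT_PV_THRESHOLD,
) -> PercentVariation:
    """Percent variation of a re-tested sample: observed/expected x 100 - 100.

    Parameters
    ----------
    expected_day1
        Day-1 (expected) CD4 count in cells/uL; must be positive.
    observed_day2
        Day-2 (observed) CD4 count in cells/uL; must be non-negative.
    threshold
        Acceptance limit in percent; |%V| <= threshold is acceptable.

    Raises
    ------
    DomainError
        If ``expected_day1 <= 0`` (the ratio is undefined or meaningless) or
        either count is non-finite. Callers must surface this as an invalid
        record, never skip it silently.
    """
    if not (math.isfinite(expected_day1) and math.isfinite(observed_day2)):
        raise DomainError("counts must be finite")
    if expected_day1 <= 0:
        raise DomainError(
            f"day-1 (expected) count must be positive, got {expected_day1}"
        )
    if observed_day2 < 0:
        raise DomainError(f"day-2 (observed) count must be >= 0, got {observed_day2}")
    value = observed_day2 / expected_day1 * 100.0 - 100.0
    return PercentVariation(
        value=value, acceptable=abs(value) <= threshold, threshold=threshold
    )


def mean_abs_percent_variation(pv_series: Sequence[float]) -> float:
    """Mean of daily percent variations with the minus sign ignored."""
    arr = _as_finite_array(pv_series, "pv_series")
    if arr.size == 0:
        raise InsufficientDataError("percent-variation series is empty")
    return float(np.mean(np.abs(arr)))


def coefficient_of_variation(values: Sequence[float]) -> float:
    """%CV of repeated measurements: sample sd / mean x 100.

    Requires at least two values and a positive mean (CD4 counts are
    positive; a nonpositive mean signals corrupted input).
    """
    arr = _as_finite_array(values, "values")
    if arr.size < 2:
        raise InsufficientDataError(
            f"coefficient of variation needs >= 2 values, got {arr.size}"
        )
    mean = float(np.mean(arr))
    if mean <= 0:
        raise DomainError(f"mean must be positive for %CV, got {mean}")
    sd = float(np.std(arr, ddof=1))
    return sd / mean * 100.0


def regression_r2(
    day1_counts: Sequence[float], day2_counts: Sequence[float]
) -> RegressionResult:
    """Pearson correlation and r-squared of paired day-1 / day-2 counts.

    The long-term-precision statistic: duplicate pairs accumulated over a
    period (typically >= 3 months) are regressed day-2 on day-1; r^2 above
    ~0.8 indicates good long-term precision.
    """
    x = _as_finite_array(day1_counts, "day1_counts")
    y = _as_finite_array(day2_counts, "day2_counts")
    if x.size != y.size:
        raise DomainError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise InsufficientDataError(f"regression needs >= 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation undefined: a series has zero variance")
    fit = _scipy_stats.linregress(x, y)
    r = float(fit.rvalue)
    return RegressionResult(
        pearson_r=r,
        r_squared=r * r,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_pairs=int(x.size),
    )


def bland_altman(
    day1_counts: Sequence[float],
    day2_counts: Sequence[float],
    k_sd: float = DEFAULT_K_SD,
) -> BlandAltmanResult:
    """Bland-Altman agreement of paired counts.

    Differences are day2 - day1; bias is their mean and the limits of
    agreement are bias +/- ``k_sd`` sample standard deviations (default 2).
    """
    x = _as_finite_array(day1_counts, "day1_counts")
    y = _as_finite_array(day2_counts, "day2_counts")
    if x.size != y.size:
        raise DomainError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise InsufficientDataError(f"Bland-Altman needs >= 2 pairs, got {x.size}")
    diffs = y - x
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - k_sd * sd,
        loa_upper=bias + k_sd * sd,
        n_pairs=int(x.size),
        k_sd=k_sd,
    )


def failure_rate(n_failures: float, lab_months: float) -> FailureRate:
    """QC failures per laboratory-year.

    ``n_failures`` QC failures observed over ``lab_months`` total months
    contributed by all laboratories; the per-year rate divides by
    lab-months/12. The raw per-month rate is available on the result.
    """
    if not math.isfinite(lab_months) or lab_months <= 0:
        raise DomainError(f"lab_months must be positive, got {lab_months}")
    if not math.isfinite(n_failures) or n_failures < 0:
        raise DomainError(f"n_failures must be >= 0, got {n_failures}")
    return FailureRate(
        n_failures=n_failures,
        lab_months=lab_months,
        rate_per_lab_year=n_failures / (lab_months / 12.0),
    )


def daily_mean_se(
    pv_table: pd.DataFrame,
    value_col: str = "pv",
    day_col: str = "date",
    lab_col: str = "lab_id",
) -> pd.DataFrame:
    """Per-day mean and standard error of %V across laboratories.

    One row per calendar day present in the input (days with no
    observations are omitted, never zero-filled). The SE is the sample
    sd / sqrt(n_labs); it is NaN when only one laboratory reported.

    Returns a DataFrame with columns ``date``, ``mean_pv``, ``se_pv``,
    ``n_labs``, sorted by date.
    """
    required = {value_col, day_col, lab_col}
    missing = required - set(pv_table.columns)
    if missing:
        raise DomainError(f"missing columns: {sorted(missing)}")
    if pv_table.empty:
        return pd.DataFrame(columns=["date", "mean_pv", "se_pv", "n_labs"])

    grouped = pv_table.groupby(day_col)[value_col]
    out = pd.DataFrame(
        {
            "mean_pv": grouped.mean(),
            "se_pv": grouped.apply(
                lambda v: v.std(ddof=1) / math.sqrt(len(v)) if len(v) > 1 else np.nan
            ),
            "n_labs": grouped.size(),
        }
    )
    out.index.name = "date"
    return out.reset_index().sort_values("date").reset_index(drop=True)
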