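"""Duplicate-analysis internal quality control.

The duplicate-analysis method re-tests two of the previous day's patient
samples — one with a low CD4 count (200-400 cells/uL) and one with a
normal count (>500 cells/uL) — and compares the day-2 result against the
day-1 result via percent variation. A run whose |%V| exceeds 20% is a QC
failure. This module turns raw duplicate-pair records into daily
verdicts, long-term precision summaries (mean |%V|, r-squared,
Bland-Altman) per laboratory and QC level, and trend series per
laboratory and across laboratories.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import qc_stats
from .qc_stats import (
    BlandAltmanResult,
    DomainError,
    FailureRate,
    PercentVariation,
    RegressionResult,
)

__all__ = [
    "LEVELS",
    "LOW_WINDOW",
    "NORMAL_FLOOR",
    "DuplicatePair",
    "QCVerdict",
    "LabSummary",
    "check_eligibility",
    "evaluate_pairs",
    "long_term_precision",
    "pv_trend_series",
    "cross_lab_trend",
    "duplicate_failure_rate",
    "verdicts_to_frame",
]

LEVELS = ("low", "normal")
INSTRUMENTS = ("FACSCount", "FACSCalibur", "Cyflow", "other")

#: Eligibility window for the low-level QC sample, cells/uL, closed interval.
LOW_WINDOW = (200.0, 400.0)
#: A normal-level QC sample must have a day-1 count strictly above this.
NORMAL_FLOOR = 500.0

PASS, FAIL, INVALID = "pass", "fail", "invalid"


@dataclass(frozen=True)
class DuplicatePair:
    """One previous-day sample re-tested: day-1 (expected) vs day-2 (observed)."""

    lab_id: str
    instrument: str
    date: dt.date
    level: str  # "low" | "normal"
    day1_count: float
    day2_count: float


@dataclass(frozen=True)
class QCVerdict:
    """Accept/fail decision for one duplicate pair.

    ``status`` is "pass", "fail" or "invalid"; ``pv`` is present unless the
    record was invalid, in which case ``reason`` says why. Invalid records
    are flagged, never dropped.
    """

    pair: DuplicatePair
    pv: PercentVariation | None
    status: str
    reason: str | None = None


@dataclass(frozen=True)
class LabSummary:
    """Per-laboratory, per-level precision summary over a period.

    ``mean_abs_pv`` is the mean |%V| over the whole period; ``pv_range`` is
    the (min, max) of per-calendar-month mean |%V| within it, the
    "mean, min-max" figure reported per laboratory. ``available`` is False
    when the level had too few valid pairs (< 3) to summarise.
    """

    lab_id: str
    level: str
    period: tuple[dt.date, dt.date] | None
    available: bool
    n_pairs: int
    n_failures: int
    mean_abs_pv: float | None = None
    pv_range: tuple[float, float] | None = None
    regression: RegressionResult | None = None
    bland_altman: BlandAltmanResult | None = None
    failure_rate: FailureRate | None = None
    monthly_mean_abs_pv: dict[str, float] = field(default_factory=dict)

    @property
    def r_squared(self) -> float | None:
        return None if self.regression is None else self.regression.r_squared


def check_eligibility(
    level: str,
    day1_count: float,
    low_window: tuple[float, float] = LOW_WINDOW,
    normal_floor: float = NORMAL_FLOOR,
) -> bool:
    """Whether a day-1 count qualifies the sample for a QC level.

    Low: count inside the closed interval ``low_window`` (default
    [200, 400] cells/uL). Normal: count strictly above ``normal_floor``
    (default 500). Counts in the gap (400, 500] are eligible for neither.
    """
    if day1_count <= 0:
        raise DomainError(f"day-1 count must be positive, got {day1_count}")
    if level == "low":
        return low_window[0] <= day1_count <= low_window[1]
    if level == "normal":
        return day1_count > normal_floor
    raise DomainError(f"unknown QC level {level!r}; expected one of {LEVELS}")


def evaluate_pairs(
    pairs: Sequence[DuplicatePair],
    threshold: float = qc_stats.DEFAULT_PV_THRESHOLD,
    enforce_eligibility: bool = False,
) -> list[QCVerdict]:
    """One verdict per pair, order-preserving.

    Records that cannot be scored (nonpositive day-1 count, negative or
    non-finite counts, unknown level, duplicate same-day record for a
    lab/level, or — when ``enforce_eligibility`` — a day-1 count outside
    the level's window) get status "invalid" with a reason; they are never
    silently dropped or averaged.
    """
    verdicts: list[QCVerdict] = []
    seen: set[tuple[str, dt.date, str]] = set()
    for pair in pairs:
        reason: str | None = None
        if pair.level not in LEVELS:
            reason = f"unknown level {pair.level!r}"
        else:
            key = (pair.lab_id, pair.date, pair.level)
            if key in seen:
                reason = "duplicate record for this lab/date/level"
            else:
                seen.add(key)
        if reason is None:
            try:
                pv = qc_stats.percent_variation(
                    pair.day1_count, pair.day2_count, threshold=threshold
                )
            except DomainError as exc:
                reason = str(exc)
            else:
                if enforce_eligibility and not check_eligibility(
                    pair.level, pair.day1_count
                ):
                    reason = (
                        f"day-1 count {pair.day1_count} ineligible for level "
                        f"{pair.level!r}"
                    )
        if reason is not None:
            verdicts.append(QCVerdict(pair=pair, pv=None, status=INVALID, reason=reason))
        else:
            verdicts.append(
                QCVerdict(pair=pair, pv=pv, status=PASS if pv.acceptable else FAIL)
            )
    return verdicts


def _month_key(d: dt.date) -> str:
    return f"{d.year:04d}-{d.month:02d}"


def long_term_precision(
    pairs: Sequence[DuplicatePair],
    threshold: float = qc_stats.DEFAULT_PV_THRESHOLD,
    contributed_months: float | None = None,
) -> dict[str, LabSummary]:
    """Long-term precision summary for one laboratory, per QC level.

    For each level, computes mean |%V| over the period, the (min, max) of
    per-calendar-month mean |%V|, r-squared of day-1 vs day-2 counts,
    Bland-Altman bias and limits of agreement, and the failure rate per
    laboratory-year. A level with fewer than 3 valid pairs is returned
    with ``available=False`` rather than omitted.

    ``contributed_months`` defaults to the number of distinct calendar
    months covered by the laboratory's records.
    """
    labs = {p.lab_id for p in pairs}
    if len(labs) > 1:
        raise DomainError(f"pairs must come from one laboratory, got {sorted(labs)}")
    verdicts = evaluate_pairs(pairs, threshold=threshold)
    lab_id = next(iter(labs)) if labs else ""
    if contributed_months is None:
        contributed_months = len({_month_key(p.date) for p in pairs})

    out: dict[str, LabSummary] = {}
    for level in LEVELS:
        vlevel = [v for v in verdicts if v.pair.level == level]
        valid = [v for v in vlevel if v.pv is not None]
        n_failures = sum(1 for v in vlevel if v.status == FAIL)
        if len(valid) < 3:
            out[level] = LabSummary(
                lab_id=lab_id,
                level=level,
                period=None,
                available=False,
                n_pairs=len(vlevel),
                n_failures=n_failures,
            )
            continue
        dates = [v.pair.date for v in valid]
        pvs = [v.pv.value for v in valid]
        day1 = [v.pair.day1_count for v in valid]
        day2 = [v.pair.day2_count for v in valid]

        monthly: dict[str, float] = {}
        by_month: dict[str, list[float]] = {}
        for v in valid:
            by_month.setdefault(_month_key(v.pair.date), []).append(v.pv.value)
        for month, series in sorted(by_month.items()):
            monthly[month] = qc_stats.mean_abs_percent_variation(series)

        try:
            regression = qc_stats.regression_r2(day1, day2)
        except (DomainError, qc_stats.InsufficientDataError):
            regression = None  # degenerate series (e.g. zero variance)
        rate = (
            qc_stats.failure_rate(n_failures, contributed_months)
            if contributed_months > 0
            else None
        )
        out[level] = LabSummary(
            lab_id=lab_id,
            level=level,
            period=(min(dates), max(dates)),
            available=True,
            n_pairs=len(vlevel),
            n_failures=n_failures,
            mean_abs_pv=qc_stats.mean_abs_percent_variation(pvs),
            pv_range=(min(monthly.values()), max(monthly.values())),
            regression=regression,
            bland_altman=qc_stats.bland_altman(day1, day2),
            failure_rate=rate,
            monthly_mean_abs_pv=monthly,
        )
    return out


def verdicts_to_frame(verdicts: Iterable[QCVerdict]) -> pd.DataFrame:
    """Flatten verdicts into a DataFrame (one row per pair, input order)."""
    rows = []
    for v in verdicts:
        rows.append(
            {
                "lab_id": v.pair.lab_id,
                "instrument": v.pair.instrument,
                "date": v.pair.date,
                "level": v.pair.level,
                "day1_count": v.pair.day1_count,
                "day2_count": v.pair.day2_count,
                "pv": np.nan if v.pv is None else v.pv.value,
                "status": v.status,
                "reason": v.reason or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "lab_id",
            "instrument",
            "date",
            "level",
            "day1_count",
            "day2_count",
            "pv",
            "status",
            "reason",
        ],
    )


def pv_trend_series(
    verdicts: Sequence[QCVerdict],
    threshold: float = qc_stats.DEFAULT_PV_THRESHOLD,
) -> pd.DataFrame:
    """Chronological %V series for one laboratory with reference lines.

    Returns a DataFrame sorted by date with columns ``date``, ``level``,
    ``pv``, ``status`` plus constant reference columns ``ref_zero`` (0),
    ``ref_upper`` (+threshold) and ``ref_lower`` (-threshold), ready for a
    trend chart. Gaps (missed days) are preserved, not interpolated.
    """
    labs = {v.pair.lab_id for v in verdicts}
    if len(labs) > 1:
        raise DomainError(
            f"trend series is per laboratory, got labs {sorted(labs)}"
        )
    frame = verdicts_to_frame(verdicts)
    frame = frame.sort_values(["date", "level"], kind="stable").reset_index(drop=True)
    frame["ref_zero"] = 0.0
    frame["ref_upper"] = float(threshold)
    frame["ref_lower"] = -float(threshold)
    return frame[
        ["date", "level", "pv", "status", "ref_zero", "ref_upper", "ref_lower"]
    ]


def cross_lab_trend(verdicts: Sequence[QCVerdict]) -> pd.DataFrame:
    """Per-day mean and SE of %V across laboratories, per QC level.

    Only valid verdicts contribute. The SE is NaN on days where a single
    laboratory reported. Returns columns ``level``, ``date``, ``mean_pv``,
    ``se_pv``, ``n_labs``.
    """
    frame = verdicts_to_frame(v for v in verdicts if v.pv is not None)
    pieces = []
    for level in LEVELS:
        sub = frame[frame["level"] == level]
        if sub.empty:
            continue
        daily = qc_stats.daily_mean_se(sub, value_col="pv")
        daily.insert(0, "level", level)
        pieces.append(daily)
    if not pieces:
        return pd.DataFrame(columns=["level", "date", "mean_pv", "se_pv", "n_labs"])
    return pd.concat(pieces, ignore_index=True)


def duplicate_failure_rate(
    verdicts: Sequence[QCVerdict],
    contributed_months: Mapping[str, float],
) -> FailureRate:
    """Pooled duplicate-analysis QC failure rate per laboratory-year.

    Counts failing verdicts across all laboratories and divides by the
    summed months each laboratory contributed. Every laboratory with
    verdicts must appear in ``contributed_months``.
    """
    labs = {v.pair.lab_id for v in verdicts}
    missing = labs - set(contributed_months)
    if missing:
        raise DomainError(
            f"no contributed months for laboratories: {sorted(missing)}"
        )
    for lab, months in contributed_months.items():
        if months <= 0:
            raise DomainError(f"contributed months must be > 0 for lab {lab!r}")
    n_failures = sum(1 for v in verdicts if v.status == FAIL)
    total_months = float(sum(contributed_months.values()))
    return qc_stats.failure_rate(n_failures, total_months)
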