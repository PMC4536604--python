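"""Stabilized commercial-control internal quality control.

Commercial control materials (e.g. IMMUNO-TROL, Multi-Check) come with a
manufacturer-assigned mean and range. Laboratories preferably establish
their own range — mean +/- 2 SD of their runs of the lot, provisional
after 10 runs and final after 20 — and plot daily measurements on a
Levey-Jennings chart, judging each run against the Westgard multirules.
A lot with only a manufacturer range (typical for short-shelf-life
products) is judged against that range, without z-scores.

This module establishes ranges, evaluates runs against the active range,
applies the classic six Westgard rules (1_2s warning; 1_3s, 2_2s, R_4s,
4_1s, 10_x rejection), computes monthly %CV, and counts out-of-range
failures for the failure-rate comparison. Rules never span lots: a lot
changeover resets the evaluation history.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import qc_stats
from .qc_stats import DomainError, FailureRate, InsufficientDataError

__all__ = [
    "ControlLot",
    "ControlRun",
    "LJEvaluation",
    "RangeComparison",
    "WESTGARD_RULES",
    "establish_range",
    "evaluate_run",
    "westgard_flags",
    "westgard_evaluate",
    "analyze_lot_history",
    "monthly_cv",
    "monthly_cv_series",
    "range_comparison",
    "control_failure_rate",
    "evaluations_to_frame",
]

PRODUCTS = ("IMMUNO-TROL", "Multi-Check", "other")
RANGE_STATUSES = ("none", "provisional", "final")

#: Minimum establishment runs per range status.
MIN_RUNS = {"provisional": 10, "final": 20}

#: The classic six multirules. 1_2s is a warning; the rest reject.
WESTGARD_RULES = ("1_2s", "1_3s", "2_2s", "R_4s", "4_1s", "10_x")
REJECTION_RULES = frozenset({"1_3s", "2_2s", "R_4s", "4_1s", "10_x"})


@dataclass(frozen=True)
class ControlLot:
    """A control material lot with manufacturer and (optional) lab range.

    The laboratory range is lab_mean +/- k_sd * lab_sd (k_sd = 2 by
    convention), provisional after >= 10 establishment runs and final
    after >= 20.
    """

    lot_id: str
    product: str
    level: str  # "low" | "normal"
    manufacturer_mean: float
    manufacturer_low: float
    manufacturer_high: float
    expiry: dt.date | None = None
    lab_mean: float | None = None
    lab_sd: float | None = None
    lab_low: float | None = None
    lab_high: float | None = None
    range_status: str = "none"
    n_establishment_runs: int = 0

    def __post_init__(self) -> None:
        if not (
            self.manufacturer_low <= self.manufacturer_mean <= self.manufacturer_high
        ):
            raise DomainError(
                f"lot {self.lot_id}: manufacturer range "
                f"[{self.manufacturer_low}, {self.manufacturer_high}] does not "
                f"bracket mean {self.manufacturer_mean}"
            )
        if self.range_status not in RANGE_STATUSES:
            raise DomainError(f"unknown range status {self.range_status!r}")


@dataclass(frozen=True)
class ControlRun:
    """One daily measurement of a control lot."""

    lab_id: str
    date: dt.date
    lot_id: str
    measured_count: float

    def __post_init__(self) -> None:
        if self.measured_count < 0:
            raise DomainError(
                f"measured count must be >= 0, got {self.measured_count}"
            )


@dataclass(frozen=True)
class LJEvaluation:
    """One Levey-Jennings point: a run judged against its lot's active range.

    ``z_score`` is only defined when a laboratory range (with a nonzero SD)
    is active; ``in_range`` uses whichever range is active, with inclusive
    boundaries. ``violations`` holds Westgard rule identifiers once
    :func:`westgard_evaluate` has run over the history.
    """

    run: ControlRun
    active_range: str  # "manufacturer" | "laboratory"
    in_range: bool
    z_score: float | None = None
    violations: frozenset[str] = frozenset()


@dataclass(frozen=True)
class RangeComparison:
    """Manufacturer vs laboratory range widths and mean offset for one lot."""

    manufacturer_width: float
    laboratory_width: float
    mean_offset: float  # manufacturer_mean - lab_mean


def establish_range(
    runs: Sequence[ControlRun],
    lot: ControlLot,
    mode: str = "final",
    k_sd: float = 2.0,
) -> ControlLot:
    """Establish a laboratory range for a lot from its own runs.

    The range is mean +/- ``k_sd`` sample SD of the establishment runs:
    at least 10 for a provisional range, 20 for a final range. Returns an
    updated copy of the lot; a zero SD yields a degenerate range
    (lab_low == lab_high), which downstream z-scoring refuses.
    """
    if mode not in MIN_RUNS:
        raise DomainError(f"mode must be 'provisional' or 'final', got {mode!r}")
    lots = {r.lot_id for r in runs}
    if lots and lots != {lot.lot_id}:
        raise DomainError(
            f"establishment runs must come from lot {lot.lot_id!r}, got {sorted(lots)}"
        )
    required = MIN_RUNS[mode]
    if len(runs) < required:
        raise InsufficientDataError(
            f"{mode} range needs >= {required} runs, got {len(runs)}"
        )
    values = np.array([r.measured_count for r in runs], dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return replace(
        lot,
        lab_mean=mean,
        lab_sd=sd,
        lab_low=mean - k_sd * sd,
        lab_high=mean + k_sd * sd,
        range_status=mode,
        n_establishment_runs=len(runs),
    )


def _lab_range_active(lot: ControlLot, allow_provisional: bool) -> bool:
    if lot.range_status == "final":
        return True
    return lot.range_status == "provisional" and allow_provisional


def evaluate_run(
    run: ControlRun,
    lot: ControlLot,
    allow_provisional: bool = False,
) -> LJEvaluation:
    """Judge one control run against its lot's active range.

    The laboratory range is active when established (by default only a
    final, 20-run range; pass ``allow_provisional=True`` to let a 10-run
    provisional range govern QC decisions). Otherwise the manufacturer
    range applies and no z-score is available. Boundaries are inclusive.
    """
    if run.lot_id != lot.lot_id:
        raise DomainError(f"run lot {run.lot_id!r} does not match {lot.lot_id!r}")
    if _lab_range_active(lot, allow_provisional):
        low, high = lot.lab_low, lot.lab_high
        z = (
            (run.measured_count - lot.lab_mean) / lot.lab_sd
            if lot.lab_sd and lot.lab_sd > 0
            else None
        )
        active = "laboratory"
    else:
        low, high = lot.manufacturer_low, lot.manufacturer_high
        z = None
        active = "manufacturer"
    return LJEvaluation(
        run=run,
        active_range=active,
        in_range=low <= run.measured_count <= high,
        z_score=z,
    )


def westgard_flags(
    z_scores: Sequence[float],
    rules: Iterable[str] = WESTGARD_RULES,
) -> list[frozenset[str]]:
    """Apply the Westgard multirules to a chronological z-score series.

    Single pass over the series; each position gets the set of rules it
    violates, flagged on the run that completes the pattern:

    * ``1_2s`` — |z| > 2 (warning);
    * ``1_3s`` — |z| > 3;
    * ``2_2s`` — two consecutive runs beyond 2 SD on the same side;
    * ``R_4s`` — adjacent runs beyond 2 SD on opposite sides spanning >= 4 SD;
    * ``4_1s`` — four consecutive runs beyond 1 SD on the same side;
    * ``10_x`` — ten consecutive runs on the same side of the mean.
    """
    enabled = set(rules)
    unknown = enabled - set(WESTGARD_RULES)
    if unknown:
        raise DomainError(f"unknown Westgard rules: {sorted(unknown)}")
    z = np.asarray(z_scores, dtype=float)
    if z.ndim != 1:
        raise DomainError("z-scores must be one-dimensional")
    if not np.all(np.isfinite(z)):
        raise DomainError("z-scores contain non-finite values")

    out: list[set[str]] = [set() for _ in range(z.size)]
    run_beyond1 = 0  # consecutive same-side beyond 1 SD ending here
    run_side = 0  # consecutive same-side-of-mean streak ending here
    for i, zi in enumerate(z):
        if abs(zi) > 2 and "1_2s" in enabled:
            out[i].add("1_2s")
        if abs(zi) > 3 and "1_3s" in enabled:
            out[i].add("1_3s")
        if i > 0:
            zp = z[i - 1]
            if (
                "2_2s" in enabled
                and ((zi > 2 and zp > 2) or (zi < -2 and zp < -2))
            ):
                out[i].add("2_2s")
            if (
                "R_4s" in enabled
                and ((zi > 2 and zp < -2) or (zi < -2 and zp > 2))
                and abs(zi - zp) >= 4
            ):
                out[i].add("R_4s")
        # same-side streak counters (z == 0 sits on the mean: breaks both)
        if zi > 1:
            run_beyond1 = run_beyond1 + 1 if i > 0 and z[i - 1] > 1 else 1
        elif zi < -1:
            run_beyond1 = run_beyond1 + 1 if i > 0 and z[i - 1] < -1 else 1
        else:
            run_beyond1 = 0
        if zi > 0:
            run_side = run_side + 1 if i > 0 and z[i - 1] > 0 else 1
        elif zi < 0:
            run_side = run_side + 1 if i > 0 and z[i - 1] < 0 else 1
        else:
            run_side = 0
        if run_beyond1 >= 4 and "4_1s" in enabled:
            out[i].add("4_1s")
        if run_side >= 10 and "10_x" in enabled:
            out[i].add("10_x")
    return [frozenset(s) for s in out]


def westgard_evaluate(
    history: Sequence[LJEvaluation],
    rules: Iterable[str] = WESTGARD_RULES,
) -> list[LJEvaluation]:
    """Annotate a chronological lot history with Westgard violations.

    All evaluations must carry z-scores (i.e. a laboratory range with a
    positive SD was active) and come from one lot; the history must not
    span a lot changeover.
    """
    lots = {e.run.lot_id for e in history}
    if len(lots) > 1:
        raise DomainError(f"history spans multiple lots: {sorted(lots)}")
    if any(e.z_score is None for e in history):
        raise DomainError("Westgard rules need z-scores (laboratory range with SD)")
    dates = [e.run.date for e in history]
    if dates != sorted(dates):
        raise DomainError("history must be chronological")
    flags = westgard_flags([e.z_score for e in history], rules=rules)
    return [replace(e, violations=f) for e, f in zip(history, flags)]


def monthly_cv(runs: Sequence[ControlRun]) -> float:
    """%CV of a lot's runs within one calendar month.

    The end-of-month precision statistic for a commercial control.
    Requires at least two runs, all from one lot and one month.
    """
    lots = {r.lot_id for r in runs}
    if len(lots) > 1:
        raise DomainError(f"runs span multiple lots: {sorted(lots)}")
    months = {(r.date.year, r.date.month) for r in runs}
    if len(months) > 1:
        raise DomainError(f"runs span multiple calendar months: {sorted(months)}")
    return qc_stats.coefficient_of_variation([r.measured_count for r in runs])


def monthly_cv_series(runs: Sequence[ControlRun]) -> pd.DataFrame:
    """Monthly %CV per lot over a run stream.

    Groups by (lot, calendar month); months with fewer than two runs get
    a NaN %CV (unavailable, not zero). Columns: ``lot_id``, ``month``
    (YYYY-MM), ``cv_percent``, ``n_runs``.
    """
    rows = []
    by_key: dict[tuple[str, str], list[ControlRun]] = {}
    for r in runs:
        by_key.setdefault((r.lot_id, f"{r.date.year:04d}-{r.date.month:02d}"), []).append(r)
    for (lot_id, month), group in sorted(by_key.items()):
        cv = monthly_cv(group) if len(group) >= 2 else np.nan
        rows.append(
            {"lot_id": lot_id, "month": month, "cv_percent": cv, "n_runs": len(group)}
        )
    return pd.DataFrame(rows, columns=["lot_id", "month", "cv_percent", "n_runs"])


def range_comparison(lot: ControlLot) -> RangeComparison:
    """Manufacturer vs laboratory range widths and mean offset for one lot."""
    if lot.lab_low is None or lot.lab_high is None or lot.lab_mean is None:
        raise DomainError(f"lot {lot.lot_id} has no laboratory range")
    return RangeComparison(
        manufacturer_width=lot.manufacturer_high - lot.manufacturer_low,
        laboratory_width=lot.lab_high - lot.lab_low,
        mean_offset=lot.manufacturer_mean - lot.lab_mean,
    )


def control_failure_rate(
    evaluations: Sequence[LJEvaluation],
    contributed_months: Mapping[str, float],
) -> FailureRate:
    """Pooled control QC failure rate per laboratory-year.

    A failure is an out-of-active-range run. Westgard rejections are
    reported on the evaluations but a 1_2s warning — or any rule firing
    while the value stays inside the active range — does not enter the
    rate; only range violations do.
    """
    labs = {e.run.lab_id for e in evaluations}
    missing = labs - set(contributed_months)
    if missing:
        raise DomainError(f"no contributed months for laboratories: {sorted(missing)}")
    for lab, months in contributed_months.items():
        if months <= 0:
            raise DomainError(f"contributed months must be > 0 for lab {lab!r}")
    n_failures = sum(1 for e in evaluations if not e.in_range)
    total_months = float(sum(contributed_months.values()))
    return qc_stats.failure_rate(n_failures, total_months)


def analyze_lot_history(
    runs: Sequence[ControlRun],
    lot: ControlLot,
    allow_provisional: bool = False,
    rules: Iterable[str] = WESTGARD_RULES,
) -> tuple[ControlLot, list[LJEvaluation]]:
    """Run the full control workflow for one laboratory on one lot.

    Chronologically: the first runs establish the laboratory range (final
    at 20 runs; provisional at 10 when ``allow_provisional``) and are
    judged against the manufacturer range; subsequent runs are judged
    against the established range and annotated with Westgard violations.
    With too few runs to establish any usable range, every run is judged
    against the manufacturer range (the short-shelf-life situation).

    Returns the updated lot and one evaluation per run, in date order.
    """
    ordered = sorted(runs, key=lambda r: r.date)
    n_establish = 0
    updated = lot
    if len(ordered) >= MIN_RUNS["final"]:
        n_establish = MIN_RUNS["final"]
        updated = establish_range(ordered[:n_establish], lot, mode="final")
    elif allow_provisional and len(ordered) >= MIN_RUNS["provisional"]:
        n_establish = MIN_RUNS["provisional"]
        updated = establish_range(ordered[:n_establish], lot, mode="provisional")
    evaluations = [
        evaluate_run(r, lot, allow_provisional=False)  # manufacturer range phase
        for r in ordered[:n_establish]
    ]
    monitored = [
        evaluate_run(r, updated, allow_provisional=allow_provisional)
        for r in ordered[n_establish:]
    ]
    if monitored and all(e.z_score is not None for e in monitored):
        monitored = westgard_evaluate(monitored, rules=rules)
    return updated, evaluations + monitored


def evaluations_to_frame(evaluations: Iterable[LJEvaluation]) -> pd.DataFrame:
    """Flatten LJ evaluations to a DataFrame (semicolon-joined violations)."""
    rows = []
    for e in evaluations:
        rows.append(
            {
                "lab_id": e.run.lab_id,
                "date": e.run.date,
                "lot_id": e.run.lot_id,
                "measured_count": e.run.measured_count,
                "z_score": np.nan if e.z_score is None else e.z_score,
                "in_range": e.in_range,
                "violations": ";".join(sorted(e.violations)),
                "active_range": e.active_range,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "lab_id",
            "date",
            "lot_id",
            "measured_count",
            "z_score",
            "in_range",
            "violations",
            "active_range",
        ],
    )
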