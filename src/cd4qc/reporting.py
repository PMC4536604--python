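"""CSV I/O, per-study summaries and chart-data exports.

All files are comma-separated UTF-8 with a mandatory header, ISO-8601
dates and "." decimals. Readers validate row by row: a missing required
column is a hard error; a malformed row becomes a reject (with its file
line number and a reason), never a silent drop.

The study summary mirrors the per-laboratory IQC table a QC programme
publishes: one row per laboratory with instrument, duplicate-analysis
mean |%V| and its monthly range, commercial-control mean %CV and range,
r-squared, Bland-Altman bias and failure rates. Cells a laboratory
cannot supply (e.g. control columns for a duplicate-only laboratory) are
rendered with a "-" sentinel, never as 0. A full-precision machine-
readable frame is kept alongside the rounded display frame.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import controls as controls_mod
from . import duplicate as duplicate_mod
from . import qc_stats
from .controls import ControlLot, ControlRun, LJEvaluation
from .duplicate import DuplicatePair, LabSummary, QCVerdict

__all__ = [
    "SchemaError",
    "SENTINEL",
    "ReadResult",
    "StudySummary",
    "read_duplicate_pairs",
    "write_duplicate_pairs",
    "write_verdicts",
    "read_control_lots",
    "write_control_lots",
    "read_control_runs",
    "write_control_runs",
    "write_evaluations",
    "read_qc_logs",
    "summarize_study",
    "export_chart_data",
]

SENTINEL = "-"
FLOAT_FORMAT = "%.10g"  # deterministic, full-precision float rendering

DUPLICATE_COLUMNS = ["lab_id", "instrument", "date", "level", "day1_count", "day2_count"]
LOT_COLUMNS = [
    "lot_id",
    "product",
    "level",
    "manufacturer_mean",
    "manufacturer_low",
    "manufacturer_high",
    "expiry",
]
RUN_COLUMNS = ["lab_id", "date", "lot_id", "measured_count"]

#: cells/uL per declared input unit
UNIT_FACTORS = {"cells/uL": 1.0, "cells/µL": 1.0, "cells/mL": 1e-3}


class SchemaError(ValueError):
    """A required column is missing or the file cannot be parsed at all."""


@dataclass(frozen=True)
class ReadResult:
    """Validated records plus a reject report (file line number, reason)."""

    records: list
    rejects: pd.DataFrame

    def require_clean(self):
        if not self.rejects.empty:
            raise SchemaError(
                f"{len(self.rejects)} malformed rows; first: "
                f"line {self.rejects.iloc[0]['line']}: {self.rejects.iloc[0]['reason']}"
            )
        return self.records


@dataclass(frozen=True)
class StudySummary:
    """Per-laboratory study table: rounded display + full-precision frames."""

    formatted: pd.DataFrame
    machine: pd.DataFrame


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, header required") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return frame


def _rejects_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["line", "reason"])


def _parse_date(text: str) -> dt.date:
    return dt.date.fromisoformat(text.strip())


def read_duplicate_pairs(path, unit: str = "cells/uL") -> ReadResult:
    """Read a duplicate-pair CSV into typed records.

    Counts are converted to cells/uL according to the declared ``unit``.
    Rows with unparsable fields are collected as rejects with 1-based
    file line numbers (header is line 1).
    """
    if unit not in UNIT_FACTORS:
        raise SchemaError(f"unknown unit {unit!r}; known: {sorted(UNIT_FACTORS)}")
    factor = UNIT_FACTORS[unit]
    frame = _read_csv(path, DUPLICATE_COLUMNS)
    records: list[DuplicatePair] = []
    rejects: list[dict] = []
    for idx, row in frame.iterrows():
        line = int(idx) + 2  # header on line 1
        try:
            records.append(
                DuplicatePair(
                    lab_id=row["lab_id"].strip(),
                    instrument=row["instrument"].strip(),
                    date=_parse_date(row["date"]),
                    level=row["level"].strip(),
                    day1_count=float(row["day1_count"]) / factor,
                    day2_count=float(row["day2_count"]) / factor,
                )
            )
        except (ValueError, TypeError) as exc:
            rejects.append({"line": line, "reason": str(exc)})
    return ReadResult(records=records, rejects=_rejects_frame(rejects))


def write_duplicate_pairs(pairs: Sequence[DuplicatePair], path) -> None:
    rows = [
        {
            "lab_id": p.lab_id,
            "instrument": p.instrument,
            "date": p.date.isoformat(),
            "level": p.level,
            "day1_count": p.day1_count,
            "day2_count": p.day2_count,
        }
        for p in pairs
    ]
    pd.DataFrame(rows, columns=DUPLICATE_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def write_verdicts(verdicts: Sequence[QCVerdict], path) -> None:
    """Verdict CSV: the pair columns plus pv, status, reason."""
    frame = duplicate_mod.verdicts_to_frame(verdicts)
    frame["date"] = frame["date"].map(dt.date.isoformat)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_control_lots(path) -> ReadResult:
    frame = _read_csv(path, LOT_COLUMNS)
    records: list[ControlLot] = []
    rejects: list[dict] = []
    for idx, row in frame.iterrows():
        line = int(idx) + 2
        try:
            expiry = row["expiry"].strip()
            records.append(
                ControlLot(
                    lot_id=row["lot_id"].strip(),
                    product=row["product"].strip(),
                    level=row["level"].strip(),
                    manufacturer_mean=float(row["manufacturer_mean"]),
                    manufacturer_low=float(row["manufacturer_low"]),
                    manufacturer_high=float(row["manufacturer_high"]),
                    expiry=_parse_date(expiry) if expiry else None,
                )
            )
        except (ValueError, TypeError) as exc:
            rejects.append({"line": line, "reason": str(exc)})
    return ReadResult(records=records, rejects=_rejects_frame(rejects))


def write_control_lots(lots: Sequence[ControlLot], path) -> None:
    rows = [
        {
            "lot_id": lot.lot_id,
            "product": lot.product,
            "level": lot.level,
            "manufacturer_mean": lot.manufacturer_mean,
            "manufacturer_low": lot.manufacturer_low,
            "manufacturer_high": lot.manufacturer_high,
            "expiry": lot.expiry.isoformat() if lot.expiry else "",
        }
        for lot in lots
    ]
    pd.DataFrame(rows, columns=LOT_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_control_runs(path) -> ReadResult:
    frame = _read_csv(path, RUN_COLUMNS)
    records: list[ControlRun] = []
    rejects: list[dict] = []
    for idx, row in frame.iterrows():
        line = int(idx) + 2
        try:
            records.append(
                ControlRun(
                    lab_id=row["lab_id"].strip(),
                    date=_parse_date(row["date"]),
                    lot_id=row["lot_id"].strip(),
                    measured_count=float(row["measured_count"]),
                )
            )
        except (ValueError, TypeError) as exc:
            rejects.append({"line": line, "reason": str(exc)})
    return ReadResult(records=records, rejects=_rejects_frame(rejects))


def write_control_runs(runs: Sequence[ControlRun], path) -> None:
    rows = [
        {
            "lab_id": r.lab_id,
            "date": r.date.isoformat(),
            "lot_id": r.lot_id,
            "measured_count": r.measured_count,
        }
        for r in runs
    ]
    pd.DataFrame(rows, columns=RUN_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def write_evaluations(evaluations: Sequence[LJEvaluation], path) -> None:
    """Evaluation CSV: run columns plus z_score, in_range, violations, active_range."""
    frame = controls_mod.evaluations_to_frame(evaluations)
    frame["date"] = frame["date"].map(dt.date.isoformat)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_qc_logs(
    pairs_path=None, lots_path=None, runs_path=None, unit: str = "cells/uL"
) -> dict[str, ReadResult]:
    """Read whichever QC logs a study has; keys: pairs, lots, runs."""
    out: dict[str, ReadResult] = {}
    if pairs_path is not None:
        out["pairs"] = read_duplicate_pairs(pairs_path, unit=unit)
    if lots_path is not None:
        out["lots"] = read_control_lots(lots_path)
    if runs_path is not None:
        out["runs"] = read_control_runs(runs_path)
    return out


def _fmt_mean_range(mean: float | None, rng: tuple[float, float] | None) -> str:
    if mean is None:
        return SENTINEL
    if rng is None or rng[0] == rng[1]:
        return f"{mean:.1f}"
    return f"{mean:.1f}, {rng[0]:.1f}–{rng[1]:.1f}"


def _pooled_duplicate_stats(
    summaries: Mapping[str, LabSummary],
) -> tuple[float | None, tuple[float, float] | None, float | None]:
    """Pool both QC levels of one lab: mean |%V|, monthly range, weighted r^2."""
    available = [s for s in summaries.values() if s.available]
    if not available:
        return None, None, None
    mean_pv = (
        sum(s.mean_abs_pv * s.n_pairs for s in available)
        / sum(s.n_pairs for s in available)
    )
    monthly = [v for s in available for v in s.monthly_mean_abs_pv.values()]
    rng = (min(monthly), max(monthly)) if monthly else None
    with_r2 = [s for s in available if s.r_squared is not None]
    r2 = (
        sum(s.r_squared * s.n_pairs for s in with_r2) / sum(s.n_pairs for s in with_r2)
        if with_r2
        else None
    )
    return mean_pv, rng, r2


def summarize_study(
    duplicate_summaries: Mapping[str, Mapping[str, LabSummary]],
    instruments: Mapping[str, str],
    control_cv: Mapping[str, pd.DataFrame] | None = None,
    control_products: Mapping[str, str] | None = None,
    months_per_lab: Mapping[str, float] | None = None,
    duplicate_rate: qc_stats.FailureRate | None = None,
    control_rates: Mapping[str, qc_stats.FailureRate] | None = None,
) -> StudySummary:
    """Assemble the per-laboratory study table.

    ``duplicate_summaries`` maps lab -> level -> LabSummary (from
    :func:`cd4qc.duplicate.long_term_precision`); ``control_cv`` maps lab
    -> monthly %CV frame (from :func:`cd4qc.controls.monthly_cv_series`)
    for labs that ran commercial controls. Pooled failure rates, when
    given, are attached as frame attributes ``failure_rates``.
    """
    control_cv = control_cv or {}
    control_products = control_products or {}
    formatted_rows = []
    machine_rows = []
    for lab_id in sorted(duplicate_summaries):
        levels = duplicate_summaries[lab_id]
        mean_pv, pv_rng, r2 = _pooled_duplicate_stats(levels)
        cv_cell, cv_mean, cv_rng = SENTINEL, None, None
        if lab_id in control_cv:
            cvs = control_cv[lab_id]["cv_percent"].dropna()
            if len(cvs):
                cv_mean = float(cvs.mean())
                cv_rng = (float(cvs.min()), float(cvs.max()))
                cv_cell = _fmt_mean_range(cv_mean, cv_rng)
                product = control_products.get(lab_id)
                if product:
                    cv_cell = f"{cv_cell} ({product})"
        normal = levels.get("normal")
        ba = normal.bland_altman if normal and normal.available else None
        formatted_rows.append(
            {
                "lab_id": lab_id,
                "instrument": instruments.get(lab_id, SENTINEL),
                "duplicate_mean_pv": _fmt_mean_range(mean_pv, pv_rng),
                "control_mean_cv": cv_cell,
                "r_squared": SENTINEL if r2 is None else f"{r2:.2f}",
                "bland_altman_bias": (
                    SENTINEL if ba is None else f"{ba.bias:.2f} ± {ba.sd_diff:.2f}"
                ),
            }
        )
        machine_rows.append(
            {
                "lab_id": lab_id,
                "instrument": instruments.get(lab_id, None),
                "duplicate_mean_abs_pv": mean_pv,
                "duplicate_pv_min": None if pv_rng is None else pv_rng[0],
                "duplicate_pv_max": None if pv_rng is None else pv_rng[1],
                "control_mean_cv": cv_mean,
                "control_cv_min": None if cv_rng is None else cv_rng[0],
                "control_cv_max": None if cv_rng is None else cv_rng[1],
                "r_squared": r2,
                "bland_altman_bias": None if ba is None else ba.bias,
                "bland_altman_sd": None if ba is None else ba.sd_diff,
                "n_pairs": sum(s.n_pairs for s in levels.values()),
                "n_duplicate_failures": sum(s.n_failures for s in levels.values()),
                "contributed_months": (
                    None if months_per_lab is None else months_per_lab.get(lab_id)
                ),
            }
        )
    formatted = pd.DataFrame(formatted_rows)
    machine = pd.DataFrame(machine_rows)
    rates: dict[str, float] = {}
    if duplicate_rate is not None:
        rates["duplicate_per_lab_year"] = duplicate_rate.rate_per_lab_year
    for name, rate in (control_rates or {}).items():
        rates[f"{name}_per_lab_year"] = rate.rate_per_lab_year
    formatted.attrs["failure_rates"] = rates
    machine.attrs["failure_rates"] = rates
    return StudySummary(formatted=formatted, machine=machine)


CHART_KINDS = (
    "regression",
    "bland_altman",
    "lj",
    "pv_trend",
    "cross_lab_trend",
    "range_comparison",
)


def export_chart_data(kind: str, **inputs) -> pd.DataFrame:
    """Tabular data for one chart kind, reference lines included as columns.

    * ``regression`` — day-1 vs day-2 scatter plus fitted line
      (inputs: verdicts);
    * ``bland_altman`` — pair mean vs difference plus bias and limits of
      agreement (inputs: verdicts, optional k_sd);
    * ``lj`` — Levey-Jennings points with mean and +/-1/2/3 SD lines
      (inputs: evaluations, lot);
    * ``pv_trend`` — %V series with 0 and +/-threshold lines
      (inputs: verdicts, optional threshold);
    * ``cross_lab_trend`` — per-day mean/SE of %V (inputs: verdicts);
    * ``range_comparison`` — manufacturer vs laboratory range per lot
      (inputs: lots).
    """
    if kind == "regression":
        verdicts = [v for v in inputs["verdicts"] if v.pv is not None]
        rows = []
        for level in duplicate_mod.LEVELS:
            sub = [v for v in verdicts if v.pair.level == level]
            if len(sub) < 3:
                continue
            fit = qc_stats.regression_r2(
                [v.pair.day1_count for v in sub], [v.pair.day2_count for v in sub]
            )
            for v in sub:
                rows.append(
                    {
                        "level": level,
                        "lab_id": v.pair.lab_id,
                        "day1_count": v.pair.day1_count,
                        "day2_count": v.pair.day2_count,
                        "fit_value": fit.slope * v.pair.day1_count + fit.intercept,
                        "r_squared": fit.r_squared,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "level",
                "lab_id",
                "day1_count",
                "day2_count",
                "fit_value",
                "r_squared",
            ],
        )
    if kind == "bland_altman":
        verdicts = [v for v in inputs["verdicts"] if v.pv is not None]
        k_sd = inputs.get("k_sd", qc_stats.DEFAULT_K_SD)
        rows = []
        for level in duplicate_mod.LEVELS:
            sub = [v for v in verdicts if v.pair.level == level]
            if len(sub) < 2:
                continue
            ba = qc_stats.bland_altman(
                [v.pair.day1_count for v in sub],
                [v.pair.day2_count for v in sub],
                k_sd=k_sd,
            )
            for v in sub:
                rows.append(
                    {
                        "level": level,
                        "lab_id": v.pair.lab_id,
                        "pair_mean": (v.pair.day1_count + v.pair.day2_count) / 2.0,
                        "difference": v.pair.day2_count - v.pair.day1_count,
                        "bias": ba.bias,
                        "loa_lower": ba.loa_lower,
                        "loa_upper": ba.loa_upper,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "level",
                "lab_id",
                "pair_mean",
                "difference",
                "bias",
                "loa_lower",
                "loa_upper",
            ],
        )
    if kind == "lj":
        evaluations: Sequence[LJEvaluation] = inputs["evaluations"]
        lot: ControlLot = inputs["lot"]
        if lot.lab_mean is None or lot.lab_sd is None:
            raise qc_stats.DomainError(
                f"LJ chart needs a laboratory range for lot {lot.lot_id}"
            )
        rows = []
        for e in evaluations:
            rows.append(
                {
                    "date": e.run.date,
                    "measured_count": e.run.measured_count,
                    "mean": lot.lab_mean,
                    "sd_minus_3": lot.lab_mean - 3 * lot.lab_sd,
                    "sd_minus_2": lot.lab_mean - 2 * lot.lab_sd,
                    "sd_minus_1": lot.lab_mean - 1 * lot.lab_sd,
                    "sd_plus_1": lot.lab_mean + 1 * lot.lab_sd,
                    "sd_plus_2": lot.lab_mean + 2 * lot.lab_sd,
                    "sd_plus_3": lot.lab_mean + 3 * lot.lab_sd,
                    "violations": ";".join(sorted(e.violations)),
                }
            )
        return pd.DataFrame(rows)
    if kind == "pv_trend":
        return duplicate_mod.pv_trend_series(
            inputs["verdicts"],
            threshold=inputs.get("threshold", qc_stats.DEFAULT_PV_THRESHOLD),
        )
    if kind == "cross_lab_trend":
        return duplicate_mod.cross_lab_trend(inputs["verdicts"])
    if kind == "range_comparison":
        rows = []
        for lot in inputs["lots"]:
            cmp_ = controls_mod.range_comparison(lot)
            rows.append(
                {
                    "lot_id": lot.lot_id,
                    "product": lot.product,
                    "level": lot.level,
                    "manufacturer_low": lot.manufacturer_low,
                    "manufacturer_mean": lot.manufacturer_mean,
                    "manufacturer_high": lot.manufacturer_high,
                    "lab_low": lot.lab_low,
                    "lab_mean": lot.lab_mean,
                    "lab_high": lot.lab_high,
                    "manufacturer_width": cmp_.manufacturer_width,
                    "laboratory_width": cmp_.laboratory_width,
                    "mean_offset": cmp_.mean_offset,
                }
            )
        return pd.DataFrame(rows)
    raise qc_stats.DomainError(f"unknown chart kind {kind!r}; known: {CHART_KINDS}")
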