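"""Synthetic multi-laboratory CD4 QC data generator.

Emulates the data streams a national CD4 QC programme collects: per
laboratory, daily duplicate-analysis pairs (a low-level sample drawn from
200-400 cells/uL and a normal-level sample from >500 cells/uL, each
measured on two consecutive days with multiplicative analytical noise)
and daily runs of commercial control lots that rotate at shelf-life
expiry. Laboratory analytical CVs default to the 2-12% band seen across
real CD4 laboratories. Shift, drift and outlier events can be injected
to emulate reagent-lot changes, staff changes or instrument problems.

Everything is deterministic given the config seed: per-laboratory random
streams are derived with ``numpy.random.SeedSequence`` so the testing-day
schedule, duplicate noise and control noise are independent and
reproducible, and :func:`ground_truth` can restate the schedule and the
expected noise-free failure counts without regenerating measurements.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .controls import ControlLot, ControlRun
from .duplicate import DuplicatePair

__all__ = [
    "ConfigError",
    "LabProfile",
    "EventSpec",
    "ControlLotSpec",
    "SimulationConfig",
    "simulate_duplicate_stream",
    "simulate_control_stream",
    "inject_event",
    "ground_truth",
    "default_study_config",
    "config_to_yaml",
    "config_from_yaml",
]

logger = logging.getLogger(__name__)

_STREAM_SCHEDULE, _STREAM_DUPLICATE, _STREAM_CONTROL = 0, 1, 2


class ConfigError(ValueError):
    """Invalid simulation configuration; the message lists the bad fields."""


@dataclass(frozen=True)
class LabProfile:
    """Analytical characteristics of one simulated laboratory.

    ``analytical_cv`` is the within-laboratory relative SD of a single
    measurement (fraction, e.g. 0.035 for 3.5%); ``bias`` a systematic
    relative offset applied to every measurement; ``day2_bias`` an extra
    relative offset on day-2 duplicate measurements (overnight specimen
    effects, default 0 — stored samples are treated as stable).
    ``control_cv`` lets stabilized control material carry a different
    measurement CV than fresh blood (None: same as ``analytical_cv``);
    ``control_products`` restricts which control products the laboratory
    runs (None: every configured lot).
    """

    lab_id: str
    instrument: str = "FACSCount"
    analytical_cv: float = 0.035
    bias: float = 0.0
    day2_bias: float = 0.0
    testing_days_per_month: int = 20
    uses_duplicates: bool = True
    uses_controls: bool = False
    control_cv: float | None = None
    control_products: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.control_products is not None:
            object.__setattr__(
                self, "control_products", tuple(self.control_products)
            )


@dataclass(frozen=True)
class EventSpec:
    """An out-of-control episode injected into a laboratory's stream.

    ``kind`` is "shift" (multiply affected measurements by 1+magnitude for
    ``duration`` days), "drift" (multiplier 1 + magnitude*(d - onset + 1)
    on day d of the episode, magnitude in fraction/day), or "outlier"
    (single-day shift). ``level`` restricts the event to one QC level
    (None hits both). Events act on day-2 duplicate measurements and on
    control runs from ``onset_day`` (0-based day index from the
    simulation start).
    """

    kind: str  # "shift" | "drift" | "outlier"
    onset_day: int
    magnitude: float
    duration: int = 1
    level: str | None = None


@dataclass(frozen=True)
class ControlLotSpec:
    """Template for a rotating series of control lots of one product/level.

    ``manufacturer_halfwidth`` is the half-width of the assigned range as
    a fraction of the true mean (manufacturer ranges are wide; 0.25 is
    typical). Lots rotate every ``shelf_life_days`` (about 30 for
    short-shelf-life products, 90 for longer-lived ones).
    """

    product: str
    level: str  # "low" | "normal"
    true_mean: float
    manufacturer_halfwidth: float = 0.25
    shelf_life_days: int = 30


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a simulated multi-laboratory QC study."""

    labs: tuple[LabProfile, ...]
    n_days: int = 365
    seed: int = 0
    start_date: dt.date = dt.date(2013, 1, 1)
    low_window: tuple[float, float] = (200.0, 400.0)
    normal_window: tuple[float, float] = (500.0, 1200.0)
    control_lots: tuple[ControlLotSpec, ...] = ()
    events: dict[str, tuple[EventSpec, ...]] = field(default_factory=dict)
    noise_model: str = "gaussian"  # "gaussian" | "lognormal"
    round_counts: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "labs", tuple(self.labs))
        object.__setattr__(self, "control_lots", tuple(self.control_lots))
        object.__setattr__(
            self, "events", {k: tuple(v) for k, v in self.events.items()}
        )
        self.validate()

    def validate(self) -> None:
        problems: list[str] = []
        if not self.labs:
            problems.append("labs: at least one laboratory required")
        seen = set()
        for lab in self.labs:
            if lab.lab_id in seen:
                problems.append(f"labs: duplicate lab_id {lab.lab_id!r}")
            seen.add(lab.lab_id)
            if not 0 <= lab.analytical_cv < 0.5:
                problems.append(
                    f"labs[{lab.lab_id}].analytical_cv: must be in [0, 0.5), "
                    f"got {lab.analytical_cv}"
                )
            if not 1 <= lab.testing_days_per_month <= 31:
                problems.append(
                    f"labs[{lab.lab_id}].testing_days_per_month: must be in "
                    f"[1, 31], got {lab.testing_days_per_month}"
                )
            if lab.control_cv is not None and not 0 <= lab.control_cv < 0.5:
                problems.append(
                    f"labs[{lab.lab_id}].control_cv: must be in [0, 0.5), "
                    f"got {lab.control_cv}"
                )
            if lab.control_products is not None:
                known = {s.product for s in self.control_lots}
                for product in lab.control_products:
                    if product not in known:
                        problems.append(
                            f"labs[{lab.lab_id}].control_products: "
                            f"{product!r} has no configured lot"
                        )
        if self.n_days < 1:
            problems.append(f"n_days: must be >= 1, got {self.n_days}")
        if not 0 < self.low_window[0] < self.low_window[1]:
            problems.append(f"low_window: invalid {self.low_window}")
        if not self.low_window[1] < self.normal_window[0] < self.normal_window[1]:
            problems.append(f"normal_window: invalid {self.normal_window}")
        for lab_id, events in self.events.items():
            if lab_id not in seen:
                problems.append(f"events: unknown lab_id {lab_id!r}")
            for e in events:
                if e.kind not in ("shift", "drift", "outlier"):
                    problems.append(f"events[{lab_id}]: unknown kind {e.kind!r}")
                if not 0 <= e.onset_day < self.n_days:
                    problems.append(
                        f"events[{lab_id}]: onset_day {e.onset_day} outside "
                        f"horizon [0, {self.n_days})"
                    )
                if not math.isfinite(e.magnitude):
                    problems.append(f"events[{lab_id}]: non-finite magnitude")
                if e.duration < 1:
                    problems.append(f"events[{lab_id}]: duration must be >= 1")
                if e.level not in (None, "low", "normal"):
                    problems.append(f"events[{lab_id}]: unknown level {e.level!r}")
        for i, lot_spec in enumerate(self.control_lots):
            if lot_spec.true_mean <= 0:
                problems.append(f"control_lots[{i}].true_mean: must be > 0")
            if not 0 < lot_spec.manufacturer_halfwidth < 1:
                problems.append(
                    f"control_lots[{i}].manufacturer_halfwidth: must be in (0, 1)"
                )
            if lot_spec.shelf_life_days < 1:
                problems.append(f"control_lots[{i}].shelf_life_days: must be >= 1")
        if self.noise_model not in ("gaussian", "lognormal"):
            problems.append(f"noise_model: unknown {self.noise_model!r}")
        if problems:
            raise ConfigError("invalid simulation config:\n  " + "\n  ".join(problems))


def _lab_rng(config: SimulationConfig, lab_index: int, stream: int) -> np.random.Generator:
    # seeds are derived, never shared: schedule / duplicate / control draws
    # stay independent so ground_truth can replay the schedule alone
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), lab_index, stream])
    )


def _testing_day_indices(config: SimulationConfig, lab_index: int) -> list[int]:
    """0-based day indices (from start_date) on which the lab tests."""
    lab = config.labs[lab_index]
    rng = _lab_rng(config, lab_index, _STREAM_SCHEDULE)
    horizon_end = config.start_date + dt.timedelta(days=config.n_days)
    indices: list[int] = []
    month_start = config.start_date.replace(day=1)
    while month_start < horizon_end:
        if month_start.month == 12:
            next_month = month_start.replace(year=month_start.year + 1, month=1)
        else:
            next_month = month_start.replace(month=month_start.month + 1)
        first = max(month_start, config.start_date)
        last = min(next_month, horizon_end)
        days_in_window = (last - first).days
        if days_in_window > 0:
            k = min(lab.testing_days_per_month, days_in_window)
            offset = (first - config.start_date).days
            picks = rng.choice(days_in_window, size=k, replace=False)
            indices.extend(sorted(int(offset + p) for p in picks))
        month_start = next_month
    return indices


def _noise_factor(
    rng: np.random.Generator, bias: float, cv: float, model: str
) -> float:
    """One multiplicative measurement factor with mean 1+bias and sd cv."""
    if model == "gaussian":
        return 1.0 + bias + rng.normal(0.0, cv)
    # lognormal with matched first two moments
    m = 1.0 + bias
    sigma2 = math.log1p((cv / m) ** 2)
    mu = math.log(m) - sigma2 / 2.0
    return math.exp(rng.normal(mu, math.sqrt(sigma2)))


def _positive_factor(
    rng: np.random.Generator, bias: float, cv: float, model: str, counter: list[int]
) -> float:
    factor = _noise_factor(rng, bias, cv, model)
    while factor <= 0:  # resample, never clip: counts must stay positive
        counter[0] += 1
        factor = _noise_factor(rng, bias, cv, model)
    return factor


def _event_multiplier(
    events: Sequence[EventSpec], day_index: int, level: str | None
) -> float:
    mult = 1.0
    for e in events:
        if e.level is not None and level is not None and e.level != level:
            continue
        if e.kind == "outlier":
            if day_index == e.onset_day:
                mult *= 1.0 + e.magnitude
        elif e.onset_day <= day_index < e.onset_day + e.duration:
            if e.kind == "shift":
                mult *= 1.0 + e.magnitude
            else:  # drift: linearly growing multiplier
                mult *= 1.0 + e.magnitude * (day_index - e.onset_day + 1)
    return mult


def _round(value: float, round_counts: bool) -> float:
    return float(round(value)) if round_counts else float(value)


def simulate_duplicate_stream(config: SimulationConfig) -> list[DuplicatePair]:
    """Generate duplicate-analysis pairs for every laboratory.

    Per testing day and QC level, a true count is drawn uniformly from
    the level's eligibility window; day-1 and day-2 measurements are
    conditionally independent multiplicative-noise readings of that true
    count. Events modify day-2 measurements. Counts are rounded to
    integers on output unless ``round_counts`` is off.
    """
    pairs: list[DuplicatePair] = []
    resampled = [0]
    for i, lab in enumerate(config.labs):
        if not lab.uses_duplicates:
            continue
        rng = _lab_rng(config, i, _STREAM_DUPLICATE)
        events = config.events.get(lab.lab_id, ())
        for day_index in _testing_day_indices(config, i):
            date = config.start_date + dt.timedelta(days=day_index)
            for level, window in (
                ("low", config.low_window),
                ("normal", config.normal_window),
            ):
                true = rng.uniform(*window)
                f1 = _positive_factor(
                    rng, lab.bias, lab.analytical_cv, config.noise_model, resampled
                )
                f2 = _positive_factor(
                    rng,
                    lab.bias + lab.day2_bias,
                    lab.analytical_cv,
                    config.noise_model,
                    resampled,
                )
                day2 = true * f2 * _event_multiplier(events, day_index, level)
                pairs.append(
                    DuplicatePair(
                        lab_id=lab.lab_id,
                        instrument=lab.instrument,
                        date=date,
                        level=level,
                        day1_count=_round(true * f1, config.round_counts),
                        day2_count=_round(day2, config.round_counts),
                    )
                )
    if resampled[0]:
        logger.warning(
            "resampled %d nonpositive duplicate measurements", resampled[0]
        )
    return pairs


def _lot_series(config: SimulationConfig) -> list[tuple[ControlLotSpec, list[ControlLot]]]:
    series = []
    abbrev = {"IMMUNO-TROL": "IT", "Multi-Check": "MC"}
    for lot_spec in config.control_lots:
        n_lots = math.ceil(config.n_days / lot_spec.shelf_life_days)
        prefix = abbrev.get(lot_spec.product, "CT")
        lots = [
            ControlLot(
                lot_id=f"{prefix}-{lot_spec.level[0].upper()}{j + 1:02d}",
                product=lot_spec.product,
                level=lot_spec.level,
                manufacturer_mean=lot_spec.true_mean,
                manufacturer_low=lot_spec.true_mean * (1 - lot_spec.manufacturer_halfwidth),
                manufacturer_high=lot_spec.true_mean * (1 + lot_spec.manufacturer_halfwidth),
                expiry=config.start_date
                + dt.timedelta(days=(j + 1) * lot_spec.shelf_life_days - 1),
            )
            for j in range(n_lots)
        ]
        series.append((lot_spec, lots))
    return series


def simulate_control_stream(
    config: SimulationConfig,
) -> tuple[list[ControlLot], list[ControlRun]]:
    """Generate control lots and daily control runs.

    Lots rotate at shelf-life expiry (a 30-day shelf life over a 90-day
    horizon yields 3 lots). Each control-using laboratory runs every
    active lot on its testing days; measurements are true_mean times a
    multiplicative noise factor, modified by any events.
    """
    series = _lot_series(config)
    all_lots = [lot for _, lots in series for lot in lots]
    runs: list[ControlRun] = []
    resampled = [0]
    for i, lab in enumerate(config.labs):
        if not lab.uses_controls:
            continue
        rng = _lab_rng(config, i, _STREAM_CONTROL)
        events = config.events.get(lab.lab_id, ())
        cv = lab.control_cv if lab.control_cv is not None else lab.analytical_cv
        for day_index in _testing_day_indices(config, i):
            date = config.start_date + dt.timedelta(days=day_index)
            for lot_spec, lots in series:
                if (
                    lab.control_products is not None
                    and lot_spec.product not in lab.control_products
                ):
                    continue
                lot = lots[day_index // lot_spec.shelf_life_days]
                factor = _positive_factor(
                    rng, lab.bias, cv, config.noise_model, resampled
                )
                measured = (
                    lot_spec.true_mean
                    * factor
                    * _event_multiplier(events, day_index, lot_spec.level)
                )
                runs.append(
                    ControlRun(
                        lab_id=lab.lab_id,
                        date=date,
                        lot_id=lot.lot_id,
                        measured_count=_round(measured, config.round_counts),
                    )
                )
    if resampled[0]:
        logger.warning("resampled %d nonpositive control measurements", resampled[0])
    return all_lots, runs


def inject_event(
    stream: Sequence[DuplicatePair] | Sequence[ControlRun],
    event: EventSpec,
    start_date: dt.date | None = None,
    lot_levels: dict[str, str] | None = None,
) -> list[DuplicatePair] | list[ControlRun]:
    """Apply an event to an already-generated stream, returning a new list.

    Duplicate pairs have their day-2 measurement modified; control runs
    their measured count. ``start_date`` anchors the event's day index
    (defaults to the earliest date in the stream). For control runs,
    ``lot_levels`` (lot_id -> level) lets a level-restricted event skip
    other levels; without it such events apply to every run. Values are
    not re-rounded, so noise-free constructions stay exact.
    """
    if not stream:
        return []
    if start_date is None:
        start_date = min(r.date for r in stream)
    out: list = []
    for record in stream:
        day_index = (record.date - start_date).days
        if isinstance(record, DuplicatePair):
            level: str | None = record.level
        else:
            level = lot_levels.get(record.lot_id) if lot_levels else None
        mult = _event_multiplier([event], day_index, level)
        if mult == 1.0:
            out.append(record)
        elif isinstance(record, DuplicatePair):
            out.append(
                dataclasses.replace(record, day2_count=record.day2_count * mult)
            )
        else:
            out.append(
                dataclasses.replace(
                    record, measured_count=record.measured_count * mult
                )
            )
    return out


def ground_truth(
    config: SimulationConfig, threshold: float = 20.0
) -> dict:
    """Machine-readable truth for parameter-recovery tests.

    Restates each laboratory's configured CV, bias and event schedule,
    its testing-day indices, and the failure counts the pipeline must
    produce on a noise-free (cv=0) rerun of the same config: duplicate
    failures are testing-day/level slots whose deterministic |%V| exceeds
    ``threshold``; control failures are runs pushed outside the
    manufacturer range.
    """
    truth: dict = {"seed": config.seed, "n_days": config.n_days, "labs": {}}
    for i, lab in enumerate(config.labs):
        events = config.events.get(lab.lab_id, ())
        days = _testing_day_indices(config, i)
        dup_failures = 0
        if lab.uses_duplicates:
            base_day1 = 1.0 + lab.bias
            base_day2 = 1.0 + lab.bias + lab.day2_bias
            for d in days:
                for level in ("low", "normal"):
                    mult = _event_multiplier(events, d, level)
                    pv = (base_day2 * mult / base_day1 - 1.0) * 100.0
                    if abs(pv) > threshold:
                        dup_failures += 1
        ctrl_failures = 0
        if lab.uses_controls:
            for d in days:
                for lot_spec in config.control_lots:
                    if (
                        lab.control_products is not None
                        and lot_spec.product not in lab.control_products
                    ):
                        continue
                    mult = _event_multiplier(events, d, lot_spec.level)
                    measured = lot_spec.true_mean * (1.0 + lab.bias) * mult
                    low = lot_spec.true_mean * (1 - lot_spec.manufacturer_halfwidth)
                    high = lot_spec.true_mean * (1 + lot_spec.manufacturer_halfwidth)
                    if not low <= measured <= high:
                        ctrl_failures += 1
        truth["labs"][lab.lab_id] = {
            "analytical_cv": lab.analytical_cv,
            "bias": lab.bias,
            "day2_bias": lab.day2_bias,
            "instrument": lab.instrument,
            "testing_day_indices": days,
            "events": [dataclasses.asdict(e) for e in events],
            "expected_duplicate_failures_at_cv0": dup_failures,
            "expected_control_failures_at_cv0": ctrl_failures,
        }
    return truth


# (lab, instrument, duplicate cv, control cv, control products)
# Duplicate CVs are back-derived from per-laboratory mean |%V| values of
# 0.5-7.2 via E|%V| ~= (200/sqrt(pi)) * cv for independent Gaussian
# replicates; control CVs span the 2.2-12.5% band typical of stabilized
# material. Mix: 5 FACSCalibur, 3 FACSCount, 3 Cyflow; six laboratories
# run commercial controls, one of them a long-shelf-life product that
# permits laboratory range establishment.
_DEFAULT_STUDY_LABS = (
    ("lab01", "FACSCount", 0.022, 0.039, ("IMMUNO-TROL",)),
    ("lab02", "FACSCount", 0.064, 0.054, ("Multi-Check",)),
    ("lab03", "FACSCalibur", 0.051, 0.124, ("Multi-Check",)),
    ("lab04", "FACSCalibur", 0.045, None, None),
    ("lab05", "FACSCalibur", 0.039, 0.022, ("Multi-Check",)),
    ("lab06", "FACSCalibur", 0.052, 0.034, ("Multi-Check",)),
    ("lab07", "FACSCount", 0.023, 0.035, ("Multi-Check",)),
    ("lab08", "Cyflow", 0.026, None, None),
    ("lab09", "Cyflow", 0.004, None, None),
    ("lab10", "Cyflow", 0.031, None, None),
    ("lab11", "FACSCalibur", 0.043, None, None),
)


def default_study_config(
    seed: int = 0,
    n_days: int = 365,
    testing_days_per_month: int = 20,
) -> SimulationConfig:
    """A canonical eleven-laboratory, one-year QC study.

    The laboratory mix mirrors a national CD4 QC programme: eleven
    laboratories on three instrument platforms, all performing duplicate
    analysis, six also running commercial controls (five a short-shelf-
    life product judged against the manufacturer range, one a 90-day
    product with laboratory-established ranges). Per-laboratory
    analytical CVs span the observed 0.4-6.4% duplicate band and the
    2.2-12.5% stabilized-control band.
    """
    labs = tuple(
        LabProfile(
            lab_id=lab_id,
            instrument=instrument,
            analytical_cv=dup_cv,
            control_cv=ctrl_cv,
            testing_days_per_month=testing_days_per_month,
            uses_controls=products is not None,
            control_products=products,
        )
        for lab_id, instrument, dup_cv, ctrl_cv, products in _DEFAULT_STUDY_LABS
    )
    control_lots = (
        ControlLotSpec(product="IMMUNO-TROL", level="low", true_mean=280,
                       shelf_life_days=90),
        ControlLotSpec(product="IMMUNO-TROL", level="normal", true_mean=620,
                       shelf_life_days=90),
        ControlLotSpec(product="Multi-Check", level="low", true_mean=300,
                       shelf_life_days=30),
        ControlLotSpec(product="Multi-Check", level="normal", true_mean=650,
                       shelf_life_days=30),
    )
    return SimulationConfig(
        labs=labs, n_days=n_days, seed=seed, control_lots=control_lots
    )


def _plain(value):
    if isinstance(value, tuple):
        return [_plain(v) for v in value]
    if isinstance(value, list):
        return [_plain(v) for v in value]
    if isinstance(value, dict):
        return {k: _plain(v) for k, v in value.items()}
    if isinstance(value, dt.date):
        return value.isoformat()
    return value


def config_to_yaml(config: SimulationConfig) -> str:
    """Serialize a config to YAML (dates as ISO strings)."""
    return yaml.safe_dump(_plain(dataclasses.asdict(config)), sort_keys=False)


def config_from_yaml(text: str) -> SimulationConfig:
    """Parse a config from YAML produced by :func:`config_to_yaml`."""
    raw = yaml.safe_load(text)
    try:
        return SimulationConfig(
            labs=tuple(LabProfile(**lab) for lab in raw["labs"]),
            n_days=raw.get("n_days", 365),
            seed=raw.get("seed", 0),
            start_date=dt.date.fromisoformat(raw.get("start_date", "2013-01-01")),
            low_window=tuple(raw.get("low_window", (200.0, 400.0))),
            normal_window=tuple(raw.get("normal_window", (500.0, 1200.0))),
            control_lots=tuple(
                ControlLotSpec(**s) for s in raw.get("control_lots", ())
            ),
            events={
                lab: tuple(EventSpec(**e) for e in evs)
                for lab, evs in raw.get("events", {}).items()
            },
            noise_model=raw.get("noise_model", "gaussian"),
            round_counts=raw.get("round_counts", True),
        )
    except TypeError as exc:
        raise ConfigError(f"malformed config: {exc}") from exc
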