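# Methods

## The two monitors

**Duplicate analysis.** Each testing day a laboratory re-tests two of the
previous day's patient samples: a low-level sample whose day-1 CD4 count
lies in the closed window [200, 400] cells/µL and a normal-level sample
with a day-1 count strictly above 500 cells/µL. (Counts in (400, 500]
qualify for neither level; the windows deliberately leave that band
undefined and `check_eligibility` treats it as ineligible.) The decision
statistic is the signed percent variation

    %V = day2 / day1 × 100 − 100,

with |%V| ≤ 20 acceptable — the boundary is inclusive, since only
variation *more than* ±20% counts as a failure. A record that cannot be
scored (non-positive day-1 count, unknown level, a second same-day record
for the same laboratory/level) is returned as an explicit `invalid`
verdict with a reason, never dropped or averaged: duplicated same-day
records are treated as data errors because the design is one pair per
level per day.

Long-term precision per laboratory and level is summarised by the mean
|%V| over the period (minus signs ignored), the (min, max) of
per-calendar-month mean |%V| — monthly sub-windows, partial months
included — the Pearson r²/regression of day-2 on day-1 counts, and
Bland–Altman agreement. The Bland–Altman difference direction is
day2 − day1 (observed − expected), matching the %V sign convention, and
the limits of agreement use exactly 2 SD, not 1.96. All standard
deviations in the package are sample SDs (n − 1), the small-n clinical
laboratory convention.

**Commercial controls.** A control lot carries a manufacturer range; a
laboratory preferably establishes its own range as mean ± 2 SD of its
runs of that lot — provisional at 10 runs, final at 20. `evaluate_run`
judges a run against the *active* range (inclusive boundaries):
laboratory when a final range exists, manufacturer otherwise. Whether a
10-run provisional range may govern QC decisions is an explicit opt-in
(`allow_provisional`, default off): provisional ranges are advisory in
routine practice, and defaulting to final-range-only keeps decisions
conservative. z-scores exist only under a laboratory range with a
positive SD. The Westgard engine implements the classic six multirules
(1_2s as warning; 1_3s, 2_2s, R_4s, 4_1s, 10_x as rejections), each
rule individually switchable, evaluated within one control level; lot
changeover resets the history so no rule spans lots.
`analyze_lot_history` packages the whole workflow: the first 20 runs of
a (laboratory, lot) history establish the range and are themselves
judged against the manufacturer range; later runs are judged against
the established range and annotated with rule violations. Lots with
fewer than 20 runs — the short-shelf-life situation — stay on the
manufacturer range throughout.

**Failure rates.** A QC failure is |%V| > 20 for duplicate analysis and
an out-of-active-range run for controls (a 1_2s warning alone is not a
failure; rule rejections are reported but only range violations enter
the rate, matching how out-of-range readings are counted in practice).
The pooled rate divides failures by the total months contributed by all
laboratories; because the quantity is conventionally quoted *per
laboratory-year*, the primary rate divides by lab-months/12, and the raw
per-month rate is exposed alongside (`rate_per_lab_month`) since the
month-denominator recipe is sometimes quoted directly.

## Synthetic data generator

`cd4qc.synthetic` emulates the QC streams a national CD4 programme
collects. Per laboratory and testing day, a true count is drawn
uniformly from the level's eligibility window (low [200, 400]; normal
[500, 1200] — the ceiling chosen to span the range over which duplicate
scatter plots are typically displayed), and day-1/day-2 measurements are
conditionally independent multiplicative-noise readings:
measured = true × (1 + ε), ε ~ N(bias, cv²). Gaussian-on-relative-scale
matches the %CV framing of laboratory precision; a moment-matched
lognormal model is a config switch. Day-1 and day-2 draws are
conditionally independent given the truth — stored specimens are treated
as stable, with an optional `day2_bias` to model overnight degradation.
Control runs are true_mean × (1 + ε); `control_cv` lets stabilized
material carry a different (typically larger) measurement CV than fresh
blood. Lots rotate at shelf-life expiry (~30 days for the short-lived
product, 90 for the long-lived one).

Events operationalise out-of-control causes (reagent lots, staff,
instrument settings, environment): a *shift* multiplies affected
measurements by (1 + m) for its duration, a *drift* applies
1 + m·(d − onset + 1) on day d, an *outlier* is a one-day shift; an
optional level filter restricts an event to one QC level. Events act on
day-2 duplicate measurements and control runs from their onset day.

Counts are rounded to integers on output (instrument reports are
integral) and statistics are computed on the rounded values, mirroring
real logs; `round_counts=False` disables this for algebraically exact
constructions. Non-positive draws are rejected by resampling and logged,
never clipped. Determinism: every random stream is derived from the
config seed via `numpy.random.SeedSequence([seed, lab_index, stream])`,
with separate streams for the testing-day schedule, duplicate noise and
control noise, so `ground_truth` can restate the schedule and the
noise-free expected failure counts without regenerating measurements,
and identical configs produce byte-identical CSVs.

`default_study_config` is the canonical study: eleven laboratories
(5 FACSCalibur, 3 FACSCount, 3 Cyflow) over twelve months at 20 testing
days/month. Duplicate-side CVs (0.4–6.4%) are back-derived from
per-laboratory mean |%V| values between 0.5 and 7.2 via
E|%V| ≈ (200/√π)·cv for independent Gaussian replicates; control-side
CVs span 2.2–12.5%. Six laboratories run commercial controls, five a
short-shelf-life product judged against its manufacturer range and one
a 90-day product with laboratory-established ranges.

What the generator does *not* model: real patient-count distributions
(true counts are uniform in the windows), instrument-specific systematic
differences, specimen-quality artefacts of stabilized material (gating
difficulty, acquisition failures), and correlated day-to-day drift
outside explicit events. Passing tests therefore demonstrate that the
statistics and decision rules behave correctly under the stated error
model — not that any particular real laboratory attains these numbers.

## Numerical and design choices

* ±20% %V limit, ±2 SD ranges and k_sd for limits of agreement are all
  parameters with the conventional defaults; tests pin the defaults.
* Degenerate inputs fail loudly: zero-variance series make r undefined
  (`DomainError`), <2 values make %CV unavailable, a zero establishment
  SD yields a degenerate range that z-scoring refuses.
* Units are cells/µL throughout; CSV readers accept a declared input
  unit (e.g. cells/mL) and convert on read.
* A day with no observations is omitted from cross-laboratory trend
  series, never zero-filled; a single-laboratory day has mean but no SE.
* Report formatting rounds %V/%CV to 1 decimal, r² to 2, bias/LoA to 2;
  a full-precision machine-readable table is always written alongside,
  and CSV floats use a fixed `%.10g` format so reruns are byte-identical.

## Problem sizes

The acceptance experiments use sizes chosen to make sampling error small
relative to the quantities measured while keeping everything comfortably
interactive: the study pipeline runs 11 laboratories × 12 months
(5,280 pairs, 2,880 control runs); CV recovery uses ~500 runs per
configured CV; in-control exceedance rates use 100,000 runs against a
range established from a 2,000-run calibration series (so that range-
estimation noise, which inflates exceedance by ~2 percentage points for
a 20-run range, does not confound the check of the decision rule
itself); shift detection uses 1,000 series. Observed outcomes: the ±2 SD
out-of-range rate sits near the theoretical 4.6%, the 1_3s rate near
0.27%, and a +3 SD step shift is rejected within four runs in >99% of
series.

A consequence worth noting: a laboratory-established ±2 SD range fails
~5% of in-control runs *by construction*, so the simulated failure rate
for the long-shelf-life product (monitored against laboratory ranges) is
an order of magnitude above that of the short-shelf-life product
(monitored against wide manufacturer ranges). The comparison direction —
wider range, fewer flagged runs — is the robust finding; the absolute
rates depend on the range in force.

## Known limitations

* The Westgard set is the classic six rules; sigma-metric rule selection
  and across-level rule variants are out of scope.
* Range establishment uses the first 20 runs chronologically; no
  outlier-trimming of the establishment set is applied.
* The CLI analyses each (laboratory, lot) history independently;
  cross-laboratory pooling of control material is intentionally not
  performed.
* Multi-analyte panels are out of scope: the pipeline is CD4-only.
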