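# cd4qc

Internal quality control (IQC) statistics for CD4 T-cell count testing.

CD4 enumeration decides antiretroviral-therapy eligibility and monitors
treatment response, so laboratories must verify every day that their flow
cytometers are measuring consistently. Two IQC strategies exist:

* **Duplicate analysis** — re-test two of the previous day's patient
  samples, one with a low CD4 count (200–400 cells/µL) and one with a
  normal count (>500 cells/µL), and compare the day-2 result against the
  day-1 result. The statistic is the *percent variation*
  `%V = observed(day 2) / expected(day 1) × 100 − 100`, with runs beyond
  ±20% treated as QC failures. It costs nothing — the QC material is
  yesterday's fresh blood — which matters wherever commercial control
  material is unaffordable.
* **Stabilized commercial controls** — manufactured control material with
  an assigned mean and range, plotted daily on a Levey-Jennings (LJ)
  chart against a laboratory-established range (mean ± 2 SD; provisional
  after 10 runs, final after 20) and judged by the Westgard multirules
  (1_2s warning; 1_3s, 2_2s, R_4s, 4_1s, 10_x rejection).

`cd4qc` implements both monitors and every statistic used to compare
them: mean |%V| (signs ignored), monthly coefficient of variation
(%CV = sd/mean × 100), day-1 vs day-2 regression r², Bland–Altman bias
and limits of agreement (bias ± 2 SD of the paired differences), QC
failure rates per laboratory-year, and cross-laboratory daily mean ± SE
trend series. A deterministic synthetic generator produces multi-
laboratory QC streams (lab-specific analytical CV, rotating control
lots, injectable shift/drift/outlier events) so the whole pipeline is
testable end to end.

## Worked example

`python examples/duplicate_precision.py` simulates three months of daily
duplicate re-testing at a 3.5% analytical CV and prints:

```
124 duplicate pairs over 3 months

low level (62 pairs, 0 QC failures)
  mean |%V|      : 4.0  (monthly range 2.4-4.6)
  r^2 day1 vs day2: 0.93
  Bland-Altman    : bias -1.66 cells/uL, LoA [-32.6, 29.3]

normal level (62 pairs, 0 QC failures)
  mean |%V|      : 3.9  (monthly range 3.6-5.3)
  r^2 day1 vs day2: 0.96
  Bland-Altman    : bias +5.76 cells/uL, LoA [-75.4, 86.9]
```

A mean |%V| far below the 20% action limit shows good daily precision;
r² above 0.8 over a three-month window shows good *long-term* precision;
and a Bland–Altman bias near zero means day-2 re-tests agree with day-1
results with no systematic drift overnight.

The other examples cover LJ/Westgard monitoring of a control lot with an
injected +3 SD shift (`levey_jennings_westgard.py`), out-of-control
episodes in the %V trend (`event_detection.py`), and a full
eleven-laboratory, one-year study producing the per-laboratory summary
table and pooled failure rates (`multilab_study.py`).

## Command line

The same pipeline is scriptable from a shell:

```bash
cd4qc simulate --config study.yaml --seed 1 --out-dir data/
cd4qc analyze-duplicate --pairs data/duplicate_pairs.csv --out-dir out/
cd4qc analyze-control --lots data/control_lots.csv --runs data/control_runs.csv --out-dir out/
cd4qc summarize --pairs data/duplicate_pairs.csv --lots data/control_lots.csv \
      --runs data/control_runs.csv --out-dir out/
cd4qc export-chart --kind bland_altman --pairs data/duplicate_pairs.csv --out chart.csv
```

All inputs and outputs are plain CSV (schemas in
`cd4qc.reporting`); chart exports include every reference line (0 and
±20% for %V trends; mean and ±1/2/3 SD for LJ charts) as columns.

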