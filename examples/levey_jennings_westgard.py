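"""Levey-Jennings monitoring of a commercial control with Westgard rules.

Simulates daily runs of a long-shelf-life stabilized control, establishes
the laboratory range (mean ± 2 SD of the first 20 runs), then injects a
+3 SD step shift and shows which runs the Westgard multirules reject.
"""

import dataclasses

from cd4qc import controls, synthetic

config = synthetic.SimulationConfig(
    labs=(
        synthetic.LabProfile(
            lab_id="lab01", analytical_cv=0.035,
            uses_controls=True, uses_duplicates=False,
        ),
    ),
    n_days=60,
    seed=7,
    control_lots=(
        synthetic.ControlLotSpec(
            product="IMMUNO-TROL", level="normal", true_mean=600,
            shelf_life_days=60,
        ),
    ),
)
# step shift of ~+3 SD (analytical CV 3.5% -> shift 3 x 3.5% = 10.5%)
config = dataclasses.replace(
    config,
    events={"lab01": (synthetic.EventSpec(kind="shift", onset_day=45,
                                          magnitude=0.105, duration=15),)},
)

lots, runs = synthetic.simulate_control_stream(config)
lot, evaluations = controls.analyze_lot_history(runs, lots[0])

print(f"lot {lot.lot_id}: laboratory range established from 20 runs")
print(f"  mean {lot.lab_mean:.1f}, SD {lot.lab_sd:.1f} "
      f"-> range [{lot.lab_low:.1f}, {lot.lab_high:.1f}] cells/uL")
print(f"  manufacturer range [{lot.manufacturer_low:.0f}, "
      f"{lot.manufacturer_high:.0f}] (much wider)\n")

print("date        value   z     in-range  violations")
for e in evaluations:
    if e.z_score is None:
        continue
    flag = ";".join(sorted(e.violations)) or "-"
    marker = " " if e.in_range else "*"
    print(f"{e.run.date}  {e.run.measured_count:6.0f} {e.z_score:+5.2f}  "
          f"{str(e.in_range):8s}{marker} {flag}")

rejected = [e for e in evaluations if e.violations & controls.REJECTION_RULES]
print(f"\n{len(rejected)} runs rejected by Westgard multirules; the step shift")
print("from day 45 shows up as 1_3s/2_2s/4_1s flags within a few runs of onset,")
print("while the wide manufacturer range alone would have missed most of it.")
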