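#!/usr/bin/env python
"""Physiology endpoints: tear-wick summaries and sensitivity thresholds.

Reduces the simulated cohort's long-format physiology CSV to per-group/day
wick means ± SEM with percent change from baseline, per-animal sensitivity
thresholds from the >=3-of-6 blink rule, and day-wise normality-gated group
comparisons.
"""

import json
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

from nervebed import io, physiology as phys  # noqa: E402


def main() -> None:
    csv = RESULTS / "sim" / "physiology.csv"
    if not csv.exists():
        print("no cohort CSV found: run analysis/01_simulate.py first", file=sys.stderr)
        return 1
    wick, blink = io.physiology_from_long(pd.read_csv(csv))
    summary = phys.wick_summary(wick, baseline_day=0)
    summary.to_csv(RESULTS / "wick_summary.csv", index=False)
    thr = phys.blink_thresholds(blink)
    thr.to_csv(RESULTS / "sensitivity_thresholds.csv", index=False)

    desiccated = summary[summary["group"] == "vehicle"].set_index("day")
    print("tear production, desiccation+vehicle arm (change vs baseline):")
    for day in (5, 7, 14):
        row = desiccated.loc[day]
        print(f"  day {day:2d}: {row['mean_mm']:.2f} mm ({row['pct_change_vs_baseline']:+.0f}%)")
    t = thr.groupby(["group", "day"])["threshold_mm"].mean()
    print(f"sensitivity threshold, vehicle: day 0 {t[('vehicle', 0)]:.2f} mm -> day 7 {t[('vehicle', 7)]:.2f} mm")

    comparisons = {}
    for day in sorted(wick["day"].unique()):
        for frame, metric, label in ((wick, "wick_mm", "wick"), (thr, "threshold_mm", "sensitivity")):
            sub = frame[frame["day"] == day]
            if sub["group"].nunique() < 2:
                continue
            r = phys.group_compare(sub[metric], sub["group"])
            comparisons[f"{label}_day{day}"] = {
                "test": r.test_name,
                "p_value": round(r.p_value, 5),
                "means": r.summary.set_index("group")["mean"].round(2).to_dict(),
            }
    (RESULTS / "endpoint_comparisons.json").write_text(json.dumps(comparisons, indent=1))
    for key, c in comparisons.items():
        print(f"  {key}: p={c['p_value']} ({c['test']})")
    return 0


if __name__ == "__main__":
    sys.exit(main())
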