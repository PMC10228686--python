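#!/usr/bin/env python
"""Score epithelial integrity of every simulated DAPI field and compare groups.

Per image: 8-bit rescale + Gaussian smoothing, 5 row + 5 column intensity
profiles, first derivatives, and the three transition statistics (delta,
AUC, AUC per transition).  Groups are compared with the normality-gated
dispatch; one QC overlay per group is rendered to scratch/.
"""

import json
import sys
from pathlib import Path

import pandas as pd
import tifffile

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"

from nervebed import epithelium as epi  # noqa: E402
from nervebed import physiology as phys  # noqa: E402
from nervebed import pipeline  # noqa: E402


def main() -> None:
    images = sorted(SIM.glob("dapi_*.tif"))
    if not images:
        print("no DAPI images found: run analysis/01_simulate.py first", file=sys.stderr)
        return 1
    rows = []
    for path in images:
        tag = path.stem.removeprefix("dapi_")
        group = tag.split("_")[0]
        img = tifffile.imread(path)
        res = pipeline.analyze_epithelium_image(img)
        rows.append({"animal": tag, "group": group, **res["metrics"]})
        if tag.endswith("_00"):
            epi.qc_plot(res["preprocessed"], res["profiles"], str(ROOT / "scratch" / f"dapi_qc_{group}.png"))
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "epithelium_metrics.csv", index=False)

    comparisons = {}
    for metric in ("transition_delta", "auc", "auc_per_transition"):
        for pair in (("naive", "vehicle"), ("vehicle", "cmp")):
            sel = df[df["group"].isin(pair)]
            r = phys.group_compare(sel[metric], sel["group"])
            comparisons[f"{metric}.{pair[0]}_vs_{pair[1]}"] = {
                "test": r.test_name,
                "p_value": round(r.p_value, 5),
                "means": r.summary.set_index("group")["mean"].round(2).to_dict(),
            }
    (RESULTS / "epithelium_comparisons.json").write_text(json.dumps(comparisons, indent=1))
    print(df.groupby("group")[["transition_delta", "auc", "auc_per_transition"]].mean().round(2))
    for key, c in comparisons.items():
        print(f"  {key}: p={c['p_value']} ({c['test']})")
    return 0


if __name__ == "__main__":
    sys.exit(main())
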