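#!/usr/bin/env python
"""Count nerve fragments per animal and compare groups.

Flood-fills every stitched mask, renders pseudo-color fragment images for
one example animal per group, computes coverage and the coverage-normalized
fragmentation index, and runs normality-gated group comparisons
(vehicle vs naive: degeneration; vehicle vs CMP: protection).
"""

import json
import sys
from pathlib import Path

import imageio.v3 as iio
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
MASKS = ROOT / "scratch" / "masks"
RESULTS = ROOT / "results"

from nervebed import fragmentation as frag  # noqa: E402
from nervebed import io, physiology as phys  # noqa: E402


def main() -> None:
    masks = sorted(MASKS.glob("*_sub_basal.png")) + sorted(MASKS.glob("*_epithelial.png"))
    if not masks:
        print("no masks found: run analysis/02_project_stacks.py first", file=sys.stderr)
        return 1
    rows = []
    for path in masks:
        layer = "sub_basal" if path.stem.endswith("_sub_basal") else "epithelial"
        tag = path.stem.removesuffix(f"_{layer}")
        group = tag.split("_")[0]
        labeling = frag.label_fragments(io.read_mask(path), connectivity=8)
        m = frag.compute_metrics(labeling)
        rows.append(
            {
                "animal": tag, "group": group, "layer": layer,
                "fragment_count": m.fragment_count, "coverage_px": m.coverage_px,
                "coverage_fraction": m.coverage_fraction,
                "fragmentation_per_1000px": m.fragmentation_per_1000px,
            }
        )
        if tag.endswith("_00"):
            iio.imwrite(ROOT / "scratch" / f"fragments_{tag}_{layer}.png", frag.pseudo_color(labeling, seed=0))
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "fragmentation_metrics.csv", index=False)

    comparisons = {}
    for layer in ("sub_basal", "epithelial"):
        sub = df[df["layer"] == layer]
        for metric in ("fragmentation_per_1000px", "coverage_fraction"):
            for pair in (("naive", "vehicle"), ("vehicle", "cmp")):
                sel = sub[sub["group"].isin(pair)]
                r = phys.group_compare(sel[metric], sel["group"])
                means = r.summary.set_index("group")["mean"].round(4).to_dict()
                comparisons[f"{layer}.{metric}.{pair[0]}_vs_{pair[1]}"] = {
                    "test": r.test_name, "p_value": round(r.p_value, 5), "means": means,
                }
    (RESULTS / "fragmentation_comparisons.json").write_text(json.dumps(comparisons, indent=1))

    sb = df[df["layer"] == "sub_basal"].groupby("group")
    print(df.groupby(["layer", "group"])[["fragmentation_per_1000px", "coverage_fraction"]].mean().round(3))
    fold = (
        sb["fragmentation_per_1000px"].mean()["vehicle"] / sb["fragmentation_per_1000px"].mean()["naive"]
    )
    print(f"sub-basal fragmentation, vehicle vs naive: {fold:.1f}-fold")
    for key, c in comparisons.items():
        print(f"  {key}: p={c['p_value']} ({c['test']})")
    return 0


if __name__ == "__main__":
    sys.exit(main())
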