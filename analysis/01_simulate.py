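#!/usr/bin/env python
"""Simulate the three-arm desiccation study: nerve stacks, DAPI fields, physiology.

Generates, per group (naive / desiccation+vehicle / desiccation+CMP):
  * 6 per-animal confocal-like nerve z-stacks with group-specific degeneration
    (vehicle: heavy fiber breakage + coverage loss; CMP: partial protection),
  * 6 per-animal DAPI epithelium images (vehicle: blur + contrast flattening),
  * one 11-animal/group physiology cohort (wick + blink tables).

Image artifacts land in scratch/sim/ (binary, regenerable); the physiology
CSV and the planted-truth summaries land in results/sim/.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results" / "sim"

from nervebed import io, synthetic as syn  # noqa: E402

SEED = 20230516

NERVE_GROUPS = {
    "naive": dict(break_rate=0.05, coverage_loss=0.0, terminal_dropout=0.0),
    "vehicle": dict(break_rate=0.5, coverage_loss=0.5, terminal_dropout=0.5),
    "cmp": dict(break_rate=0.2, coverage_loss=0.15, terminal_dropout=0.15),
}
EPI_GROUPS = {
    "naive": dict(blur_sigma_px=0.0, intensity_flattening=0.0, dropout=0.0),
    "vehicle": dict(blur_sigma_px=3.0, intensity_flattening=0.4, dropout=0.15),
    "cmp": dict(blur_sigma_px=1.0, intensity_flattening=0.1, dropout=0.05),
}
N_ANIMALS = 6


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    truth_summary = {}
    for gi, (group, nerve_kw) in enumerate(NERVE_GROUPS.items()):
        for a in range(N_ANIMALS):
            tag = f"{group}_{a:02d}"
            stack, truth = syn.generate_nerve_stack(
                syn.SyntheticNerveParams(
                    image_size_px=(128, 128), n_planes=8, n_fibers=14,
                    curvature_tilt=2.0, seed=SEED + 100 * gi + a, **nerve_kw,
                )
            )
            io.write_stack(SCRATCH / f"nerve_{tag}.tif", stack)
            img, _ = syn.generate_epithelium_image(
                syn.SyntheticEpitheliumParams(seed=SEED + 500 + 100 * gi + a, **EPI_GROUPS[group])
            )
            import tifffile

            tifffile.imwrite(SCRATCH / f"dapi_{tag}.tif", img.astype("float32"))
            truth_summary[tag] = {
                "group": group,
                "true_fragment_count": truth.true_fragment_count,
                "true_coverage_px": int(truth.true_coverage_mask.sum()),
            }
    wick, blink, cohort_truth = syn.generate_cohort(syn.CohortSpec(seed=SEED))
    io.physiology_to_long(wick, blink).to_csv(RESULTS / "physiology.csv", index=False)
    (RESULTS / "planted_truth.json").write_text(json.dumps(truth_summary, indent=1))
    (RESULTS / "cohort_design.json").write_text(json.dumps(cohort_truth.cohort_effects, indent=1))
    print(f"simulated {len(truth_summary)} animals x (nerve stack + DAPI field) -> {SCRATCH}")
    print(f"physiology cohort: {wick['animal_id'].nunique()} animals x {wick['day'].nunique()} days -> {RESULTS}")


if __name__ == "__main__":
    sys.exit(main())
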