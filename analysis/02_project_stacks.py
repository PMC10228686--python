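#!/usr/bin/env python
"""Flatten every simulated nerve stack into per-layer binary masks.

Runs the tiled workflow per stack: 3x3 split, per-tile auto z-bounds
(brightest 3-plane window; the epithelial layer takes the brightest window
outside the sub-basal one), population-SD projection, Otsu binarization,
seam-free re-stitch.  Masks land in scratch/masks/, provenance in
results/projection_provenance.json.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
MASKS = ROOT / "scratch" / "masks"

from nervebed import io, pipeline  # noqa: E402


def main() -> None:
    stacks = sorted(SIM.glob("nerve_*.tif"))
    if not stacks:
        print("no simulated stacks found: run analysis/01_simulate.py first", file=sys.stderr)
        return 1
    MASKS.mkdir(parents=True, exist_ok=True)
    provenance = {}
    for path in stacks:
        tag = path.stem.removeprefix("nerve_")
        stack = io.read_stack(path)
        res = pipeline.analyze_nerve_stack(stack)
        for layer, layer_res in res["layers"].items():
            io.write_mask(MASKS / f"{tag}_{layer}.png", layer_res["mask"])
        provenance[tag] = {layer: r["provenance"] for layer, r in res["layers"].items()}
    out = ROOT / "results" / "projection_provenance.json"
    out.write_text(json.dumps(provenance, indent=1))
    print(f"projected {len(stacks)} stacks -> {MASKS} (provenance in {out.name})")
    return 0


if __name__ == "__main__":
    sys.exit(main())
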