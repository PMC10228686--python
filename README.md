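# nervebed

Quantification of corneal nerve-bed degeneration and epithelial integrity in
mouse models of ocular surface desiccation (dry eye).

The sub-basal nerve plexus of the cornea — a dense swirl of sensory fibers
running under the epithelium, ending in punctate intraepithelial terminals —
degrades under desiccation stress: fibers fragment, coverage shrinks, the
epithelial nucleus mosaic loses definition, tear production and corneal
sensitivity fall. `nervebed` implements the full measurement pipeline for
such studies, plus synthetic generators with planted ground truth so every
stage is testable without microscope data.

## What it computes

**Nerve fragmentation from confocal z-stacks.** A flattened whole-mount
cornea is curved, so the sub-basal plexus and epithelial terminals occupy
different z-planes in different parts of the field. The pipeline splits the
(y, x) plane into a 3×3 grid of tiles, selects a per-tile z-window per
anatomical layer (manually configured, or automatically as the brightest
window), flattens each tile sub-stack with a population standard-deviation
projection

&nbsp;&nbsp;&nbsp;&nbsp;SD(y, x) = √( Σ_z (I(z, y, x) − Ī(y, x))² / n ),

binarizes (manual threshold or Otsu), and re-stitches the tiles seam-free.
On the stitched mask, an iterative flood fill labels every contiguous
foreground region ("fragment"); with fragment count K and nerve coverage
A (foreground pixels), the fragmentation index is

&nbsp;&nbsp;&nbsp;&nbsp;F = K / A&nbsp;&nbsp;(reported per 1000 foreground px).

Healthy nerve beds are a few long fragments (low F); degenerating beds are
many short ones (high F). A pseudo-color rendering with one random RGB color
per fragment records K visually.

**Epithelial integrity from DAPI images.** Intensity profiles at 5 fixed x-
and 5 fixed y-coordinates (10 per image) oscillate across the nucleus
mosaic. On each profile's first derivative f′, a peak is a background→nucleus
transition and a trough a nucleus→background transition. Three statistics
fall as the epithelium degrades: the transition delta (mean |peak − trough|
amplitude), the AUC (combined unsigned area of the derivative's peak and
trough lobes), and the AUC per transition.

**Physiology endpoints.** Tear-wick lengths reduce to per-group/day
mean ± SEM and percent change from baseline. Cochet-Bonnet blink tables
(6 taps at each filament length 3.5 … 0.5 mm; longer filament = lower force)
reduce to a sensitivity threshold: the longest length with ≥ 3/6 positive
blinks, or 0 with no response anywhere. Group comparisons are
normality-gated: Shapiro–Wilk per group at α = 0.05, then Student's
t/one-way ANOVA, or Mann–Whitney/Kruskal–Wallis when any group fails.

## Worked example

```python
from nervebed import synthetic as syn, pipeline

healthy = syn.SyntheticNerveParams(seed=7)
degraded = syn.SyntheticNerveParams(seed=7, break_rate=0.5, coverage_loss=0.5)
for label, params in [("healthy", healthy), ("degraded", degraded)]:
    stack, truth = syn.generate_nerve_stack(params)
    res = pipeline.analyze_nerve_stack(stack)
    m = res["layers"]["sub_basal"]["metrics"]
    print(f"{label}: {m['fragment_count']} fragments, "
          f"coverage {m['coverage_fraction']:.2f}, "
          f"{m['fragmentation_per_1000px']:.2f} fragments / 1000 px "
          f"(planted components: {truth.sub_basal_fragment_count})")
```

prints

```
healthy: 10 fragments, coverage 0.25, 0.60 fragments / 1000 px (planted components: 1)
degraded: 54 fragments, coverage 0.15, 5.51 fragments / 1000 px (planted components: 49)
```

The healthy whorl is essentially one connected plexus (the imaging pipeline
splits it into a handful of pieces where thin strands fall below threshold);
severing half its candidate break points and removing half its fibers drops
coverage from 0.25 to 0.15 and raises the fragmentation index ninefold —
the degeneration signature the index is built to detect.

## Analysis drivers

`analysis/01_simulate.py` … `05_endpoints.py` run a complete three-arm
in-silico study (naïve / desiccation+vehicle / desiccation+CMP): simulate
per-animal nerve stacks, DAPI fields and a physiology cohort; project and
binarize; count fragments and compare groups; score epithelial integrity;
summarize tear and sensitivity endpoints. Text outputs land in `results/`,
regenerable image artifacts in `scratch/`. Each script prints what it found.

## Command line

`nervebed simulate|project|fragment|epithelium|endpoints --help` exposes the
same stages as thin CLI wrappers (YAML configs, TIFF/PNG/CSV in and out).

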