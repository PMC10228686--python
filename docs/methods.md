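# Methods

This note documents the models, conventions and design choices behind
`nervebed`, in the order the pipeline runs.

## Tiled z-stack flattening (`nervebed.zstack`)

**Why tiles.** A dissected cornea flattens imperfectly, so a single z-window
cannot capture the sub-basal plexus (or the terminal layer) across the whole
field: the anatomical bands drift in z from one corner of the image to the
other. Splitting the field into a 3×3 grid and choosing per-tile z-windows
approximates the curved surface piecewise. Tile rectangles are half-open,
0-based, and partition the plane exactly; when an axis is not divisible by
the grid, larger tiles come first (ceil before floor). Any fixed rule would
do — stitching restores the full extent, and the seam-freedom tests assert
that fragment counts after re-stitching equal counts on the never-split
mask.

**Z-windows.** The attended workflow supplies per-tile inclusive
`[z_lo, z_hi]` intervals per layer from a config. For unattended runs,
`auto_zbounds` picks the contiguous window of `window` planes (default 3)
maximizing total intensity; the epithelial layer takes the brightest window
disjoint from the sub-basal one. The two layers' windows may overlap in the
attended mode — nothing in the pipeline assumes disjointness.

**SD projection.** Each output pixel is the standard deviation of its
intensities over the window, population convention (divide by n, recorded in
provenance). The SD projection highlights structures that appear in few
planes (thin fibers) while suppressing uniform background. A single-plane
window is legal but yields zero everywhere, so it warns.

**Binarization.** `manual`/`fixed` thresholds reproduce an attended
workflow; Otsu (scikit-image) is the unattended default since manual
thresholding is not reproducible. The mask is `img > threshold`. A constant
image under Otsu returns an empty mask with a warning rather than failing.

## Fragment counting (`nervebed.fragmentation`)

Connected components are labeled by an iterative, explicit-stack flood fill
seeded in raster-scan order. Iteration is a contract, not a convenience: a
healthy plexus is one near-image-sized component, which recursion-based
fills cannot traverse. Connectivity defaults to 8 so 1-px diagonal fiber
runs stay contiguous (4 available by flag). No minimum-fragment filter is
applied by default; a `min_size` option exists for noisy masks.

The fragmentation index is stored as fragments per foreground pixel and
reported per 1000 foreground px for readability; the coverage denominator is
the foreground pixel count (a physical-area variant is a unit conversion via
`pixel_size_um`). The empty mask yields all-zero metrics with a flag.

The pseudo-color rendering assigns each label a distinct random RGB triple
(channels drawn in 32..255 to stay clear of the black background,
collision-checked), so the count of distinct non-black colors equals the
fragment count.

## Epithelial integrity (`nervebed.epithelium`)

Preprocessing rescales intensities linearly to [0, 255] (min→0, max→255;
constant image → zeros) and Gaussian-smooths with σ = 1 px by default —
enough to suppress speckle without erasing inter-nucleus valleys. Profiles
are taken at fractions 1/6 … 5/6 of each axis (borders excluded), 5 rows
plus 5 columns. Derivatives are central differences at interior points and
one-sided at the ends, so output length matches input length.

Transition detection finds strict local extrema of the derivative with
plateaus resolved to their leftmost index, keeps peaks above +p and troughs
below −p, and enforces alternation by dropping the lesser-magnitude of two
same-sign consecutive extrema. The prominence default is p = 5% of the
profile's maximum |f′|, making detection invariant to overall gain. The
delta pairs each peak with the next trough (a trailing unpaired extremum is
dropped); the AUC integrates |f′| trapezoidally over the maximal same-sign
runs containing the detected extrema (baseline 0), and equals
`auc_per_transition × n_transitions` exactly by construction.

Pooling is per-profile by default: each profile is differentiated
separately and the detected transitions pooled. An `average_first` mode
averages raw profiles per axis before differentiating, matching workflows
that average group line plots first; it assumes the profiles are spatially
aligned, which only controlled synthetic data guarantees, hence the
default.

## Physiology endpoints (`nervebed.physiology`)

The sensitivity threshold is the longest tested filament length (3.5, 2.5,
2, 1.5, 1, 0.5 mm) with ≥ 3 of 6 positive blinks, else 0. Longer
Cochet-Bonnet filaments exert lower force, so responding at a longer length
means higher sensitivity; scanning all lengths for the longest qualifying
one is equivalent to descending to the first positive whenever response is
monotone in force, and is what is implemented. All lengths are in mm.

Wick summaries report mean ± SEM (SEM = SD/√n with sample SD, n−1) per
group/day and percent change `100·(mean_day − mean_baseline)/mean_baseline`;
a zero or absent baseline flags the row instead of dividing by zero.

`group_compare` dispatches on per-group Shapiro–Wilk at α = 0.05: all pass →
Student's t (2 groups) or one-way ANOVA; any fail → Mann–Whitney U or
Kruskal–Wallis; paired data use paired t / Wilcoxon signed-rank. Groups with
n < 3 cannot be normality-tested and force the nonparametric branch with a
warning; a constant group is treated as failing normality; identical
constant groups short-circuit to a flagged degenerate result. No
multiple-testing correction is applied by default (day-wise pairwise
comparisons are reported unadjusted); the calibration tests assert the
dispatched pipeline's null rejection rate stays near nominal on both
branches.

## Synthetic generators (`nervebed.synthetic`)

All generators are pure functions of (params, seed) via a private
`numpy` Generator; identical seeds give bitwise-identical outputs.

**Nerve stacks.** Fibers follow logarithmic-spiral streamlines from the
image center (r = r₀·e^{bθ}, b set so a fiber makes `swirl_turns` windings
from r₀ = 3 px to 0.45·min(H, W)) — the whorl morphology with two
parameters. Strokes are rendered by stamping discs of radius
`fiber_width_px/2` at ~0.7 px arclength steps. Degradation: `coverage_loss`
removes ⌊fraction·n⌋ whole fibers; `break_rate` independently severs each
candidate break point (spaced ~3 gap-lengths along the path), deleting a gap
of 3× the fiber width so no later binarization can re-bridge it; terminals
are σ = 1 px Gaussian puncta (2–4 px above half-amplitude) thinned by
`terminal_dropout`. A `non_touching` layout instead confines one short
stroke per disjoint grid cell with a safety margin, so exactly `n_fibers`
components are planted — the basis of the planted-recovery tests. The
sub-basal band sits at 25% and the terminal band at 75% of the available
depth, both drifting by `curvature_tilt` planes along the image diagonal.
Noise is additive Gaussian clipped to [0, 255]; Poisson/photon statistics
and per-plane PSF blur are out of scope. Truth masks are the noiseless
foreground; their component counts are computed with `scipy.ndimage.label`
— deliberately independent of the package's own flood fill, which the tests
then compare against it and against a BFS oracle.

**Epithelium fields.** Nuclei are smooth Gaussian discs (amplitude 180 on
background 30, σ = radius/2) on a square lattice with per-nucleus jitter.
Defaults — spacing 14 px, radius 6 px, jitter 1 px, noise SD 5 — model a
densely packed epithelial mosaic (nucleus diameter comparable to spacing),
which matters: because preprocessing rescales each image to [0, 255],
degradation must *structurally* reduce transitions, not just dim them. With
packed nuclei, blur merges neighbors and fills inter-nucleus valleys, so
delta, AUC and AUC-per-transition decline monotonically with blur, as they
do with contrast flattening; with a sparse lattice those areas would be
nearly blur-invariant (lobes widen as they attenuate) — an artifact of
min–max renormalization, not of the tissue being emulated. Degradation
order is fixed and documented: dropout → blur → flattening (contrast toward
the image mean by the given fraction) → noise. Parameter validation rejects
geometrically impossible settings (2·radius ≥ spacing) and warns when
jitter merely could bring neighbors into contact.

**Cohorts.** Wick values are Normal(group×day mean, SD) truncated at 0;
blink positives are Binomial(6, p) with a logistic detection curve
p(length) = 1/(1 + e^{(length − m)/s}), s = 0.25 mm, midpoint m at that
group/day's threshold mean — monotone non-increasing in length, so
generated thresholds land on the tested-length grid around m. Default
effects mirror a two-week desiccation design: baseline wick ~5 mm falling
~43%/~60% by days 5/7 with partial CMP recovery; thresholds ~2.65 mm
falling to ~1.08 mm by day 7; n = 11 per group; days 0/5/7/10/14.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: optical PSF and depth attenuation, Poisson noise,
nonuniform illumination, real whorl branching topology (fibers here do not
branch), and terminal-branch fragmentation. The last is visible in the
bundled in-silico study: terminal degradation is modeled as dropout of
intact puncta, which lowers terminal coverage but leaves the terminal-layer
fragmentation index roughly unchanged, so the epithelial-layer fragmentation
contrast between arms is weaker than the sub-basal one. Real degenerating
terminals additionally shatter, which the sub-basal break model captures
but the punctum model does not.

## Problem sizes

The bundled study and the test suite run at desk scale, chosen to keep the
whole suite fast while leaving every algorithmic path exercised: 128–256 px
synthetic fields (vs 800 px acquisitions), 8–12 planes, 6–8 animals per arm
for imaging and 11 for physiology, 20 seeds per level for monotonicity
checks, 2000 simulations for dispatch calibration. The geometry rules
(tiling, stitching, connectivity, thresholds) are size-free, and the 800 px
tiling case is asserted explicitly.

## Known limitations

* Auto z-bounds assume the brightest window is the layer of interest; a
  stack dominated by debris would need manual bounds.
* Otsu assumes a bimodal histogram; near-empty masks should use manual
  thresholds or the `min_size` filter.
* The fragmentation index is resolution-dependent (per-pixel denominator);
  compare only images of equal scale, or convert via `pixel_size_um`.
* The dispatch tests calibrate the two-group path; many-group ANOVA-on-ranks
  calibration is asserted only indirectly.
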