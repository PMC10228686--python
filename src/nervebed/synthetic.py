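"""Synthetic corneal inputs with planted ground truth.

Three generators emulate everything the pipeline consumes, so every stage is
testable without microscope data:

* ``generate_nerve_stack`` — a confocal-like z-stack of the central cornea:
  thin bright curvilinear fibers following a logarithmic-spiral field (the
  sub-basal whorl) in a low-z band, punctate epithelial terminals in a
  higher band, both drifting in z across the image to mimic the curvature of
  a flattened cornea.  Degeneration is controllable: fiber breakage
  (severing short gaps), whole-fiber coverage loss, terminal dropout.
* ``generate_epithelium_image`` — a jittered lattice of bright nuclei on
  dark background (a DAPI field), degraded by dropout → blur → contrast
  flattening → noise, in that fixed order.
* ``generate_cohort`` — wick-test and blink-response tables for a
  naïve / desiccation+vehicle / desiccation+CMP design with configurable
  group×day effects.

Every generator is a pure function of its parameters (including the seed),
and returns a :class:`SyntheticTruth` carrying exactly what the pipeline is
supposed to recover (fragment counts on the noiseless foreground, surviving
nucleus centers, cohort effect sizes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .physiology import N_TAPS, TESTED_LENGTHS_MM
from .zstack import ImageStack

__all__ = [
    "SyntheticNerveParams",
    "SyntheticEpitheliumParams",
    "CohortSpec",
    "SyntheticTruth",
    "generate_nerve_stack",
    "generate_epithelium_image",
    "generate_cohort",
]

DEFAULT_CONNECTIVITY = 8
_STRUCTURES = {4: ndimage.generate_binary_structure(2, 1), 8: np.ones((3, 3), bool)}

FIBER_AMPLITUDE = 180.0
TERMINAL_AMPLITUDE = 220.0
INTENSITY_MAX = 255.0


@dataclass
class SyntheticTruth:
    """Planted ground truth carried alongside every generated input."""

    true_fragment_count: int = 0
    true_coverage_mask: np.ndarray | None = None  # union of all noiseless foreground
    nucleus_centers: list[tuple[float, float]] = field(default_factory=list)
    cohort_effects: dict | None = None
    # layer-wise detail for the nerve generator
    sub_basal_mask: np.ndarray | None = None
    terminal_mask: np.ndarray | None = None
    sub_basal_fragment_count: int = 0
    terminal_fragment_count: int = 0


def _count_components(mask: np.ndarray, connectivity: int = DEFAULT_CONNECTIVITY) -> int:
    return int(ndimage.label(mask, structure=_STRUCTURES[connectivity])[1])


# --------------------------------------------------------------------------
# nerve stack
# --------------------------------------------------------------------------


@dataclass
class SyntheticNerveParams:
    """Parameters for the nerve z-stack generator.

    ``break_rate`` is the per-candidate-point probability that a fiber is
    severed there; each cut removes a gap of at least 3× the fiber width so
    binarization cannot re-bridge it.  ``coverage_loss`` removes that
    fraction of fibers entirely.  ``curvature_tilt`` is the number of
    z-planes the anatomical bands drift between opposite image corners.
    ``non_touching`` lays fibers out as short strokes in disjoint grid cells
    (instead of the spiral field) so the planted fragment count is exactly
    ``n_fibers`` when nothing is severed.
    """

    image_size_px: tuple[int, int] = (256, 256)
    n_planes: int = 12
    n_fibers: int = 30
    swirl_turns: float = 1.5
    fiber_width_px: float = 2.0
    terminal_density: float = 2.0  # terminals per 1000 px²
    break_rate: float = 0.0
    terminal_dropout: float = 0.0
    coverage_loss: float = 0.0
    curvature_tilt: float = 3.0
    noise_sd: float = 4.0
    seed: int = 0
    non_touching: bool = False

    def __post_init__(self) -> None:
        h, w = self.image_size_px
        if h < 64 or w < 64:
            raise ValueError("image dimensions must be >= 64 px")
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if self.curvature_tilt >= self.n_planes:
            raise ValueError("curvature_tilt must be < n_planes")
        for name in ("break_rate", "terminal_dropout", "coverage_loss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_fibers < 0 or self.terminal_density < 0 or self.noise_sd < 0:
            raise ValueError("n_fibers, terminal_density and noise_sd must be >= 0")
        if self.swirl_turns <= 0 or self.fiber_width_px <= 0:
            raise ValueError("swirl_turns and fiber_width_px must be positive")


def _spiral_path(h: int, w: int, theta0: float, turns: float, step_px: float = 0.7) -> np.ndarray:
    """Polyline along a logarithmic spiral r = r0·e^{bθ} from near-center outward."""
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r0, rmax = 3.0, 0.45 * min(h, w)
    span = 2.0 * np.pi * turns
    b = np.log(rmax / r0) / span
    pts = []
    theta = 0.0
    while theta <= span:
        r = r0 * np.exp(b * theta)
        pts.append((cy + r * np.sin(theta0 + theta), cx + r * np.cos(theta0 + theta)))
        # advance by ~step_px of arclength: ds = r·sqrt(1+b²)·dθ
        theta += step_px / (r * np.sqrt(1.0 + b * b))
    return np.asarray(pts)


def _cell_stroke(rng: np.random.Generator, y0: int, x0: int, cell: int, margin: int) -> np.ndarray:
    """A short random stroke confined to one grid cell with a safety margin."""
    lo, hi = margin, cell - margin
    a = rng.uniform(lo, hi, size=2)
    b = rng.uniform(lo, hi, size=2)
    n = max(int(np.hypot(*(b - a)) / 0.7) + 2, 4)
    t = np.linspace(0.0, 1.0, n)[:, None]
    return np.array([y0, x0]) + a + t * (b - a)


def _apply_breaks(path: np.ndarray, break_rate: float, gap_px: float, rng: np.random.Generator) -> list[np.ndarray]:
    """Sever a polyline at candidate points, removing gaps of >= gap_px arclength."""
    if break_rate == 0.0 or len(path) < 3:
        return [path]
    seg = np.hypot(*np.diff(path, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])  # arclength per vertex
    total = s[-1]
    spacing = max(3.0 * gap_px, 8.0)
    candidates = np.arange(gap_px, total - gap_px, spacing)
    keep = np.ones(len(path), bool)
    for c in candidates:
        if rng.random() < break_rate:
            keep &= ~((s > c - gap_px / 2.0) & (s < c + gap_px / 2.0))
    pieces, start = [], None
    for i, k in enumerate(keep):
        if k and start is None:
            start = i
        elif not k and start is not None:
            pieces.append(path[start:i])
            start = None
    if start is not None:
        pieces.append(path[start:])
    return [p for p in pieces if len(p) >= 2]


def _disc_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = max(int(np.floor(radius)), 1)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    inside = dy * dy + dx * dx <= radius * radius + 1e-9
    return dy[inside], dx[inside]


def _stamp(mask: np.ndarray, pts: np.ndarray, radius: float) -> None:
    """Stamp a disc of given radius at every polyline vertex (stroke rendering)."""
    if len(pts) == 0:
        return
    h, w = mask.shape
    dy, dx = _disc_offsets(radius)
    yy = (np.round(pts[:, 0]).astype(int)[:, None] + dy[None, :]).ravel()
    xx = (np.round(pts[:, 1]).astype(int)[:, None] + dx[None, :]).ravel()
    ok = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
    mask[yy[ok], xx[ok]] = True


def generate_nerve_stack(params: SyntheticNerveParams) -> tuple[ImageStack, SyntheticTruth]:
    """Render a degraded nerve bed into a curvature-tilted z-stack.

    Sub-basal fibers land in a low-z band and terminals in a higher band;
    both band indices drift linearly by ``curvature_tilt`` planes along the
    image diagonal.  The truth records the noiseless foreground masks and
    their connected-component counts (8-connectivity, matching the
    pipeline's default).
    """
    p = params
    rng = np.random.default_rng(p.seed)
    h, w = p.image_size_px
    radius = max(p.fiber_width_px / 2.0, 1.0)
    gap_px = 3.0 * p.fiber_width_px

    # --- fiber paths ------------------------------------------------------
    if p.non_touching:
        g = int(np.ceil(np.sqrt(max(p.n_fibers, 1))))
        cell = min(h, w) // g
        margin = int(np.ceil(gap_px)) + 2
        if cell < 2 * margin + 4:
            raise ValueError(f"image too small for {p.n_fibers} non-touching fibers")
        cells = [(r * cell, c * cell) for r in range(g) for c in range(g)]
        order = rng.permutation(len(cells))[: p.n_fibers]
        paths = [_cell_stroke(rng, *cells[i], cell, margin) for i in order]
    else:
        thetas = rng.uniform(0.0, 2.0 * np.pi, size=p.n_fibers)
        paths = [_spiral_path(h, w, t, p.swirl_turns) for t in thetas]

    n_removed = int(round(p.coverage_loss * len(paths)))
    if n_removed:
        drop = set(rng.permutation(len(paths))[:n_removed].tolist())
        paths = [pa for i, pa in enumerate(paths) if i not in drop]

    fiber_mask = np.zeros((h, w), bool)
    for path in paths:
        for piece in _apply_breaks(path, p.break_rate, gap_px, rng):
            _stamp(fiber_mask, piece, radius)

    # --- terminals (punctate, 2-4 px) -------------------------------------
    n_term = rng.poisson(p.terminal_density * h * w / 1000.0)
    term_mask = np.zeros((h, w), bool)
    term_field = np.zeros((h, w), np.float64)
    centers = rng.uniform([2, 2], [h - 3, w - 3], size=(n_term, 2)) if n_term else np.empty((0, 2))
    kept = centers[rng.random(n_term) >= p.terminal_dropout] if n_term else centers
    dy, dx = np.mgrid[-2:3, -2:3]
    bump = TERMINAL_AMPLITUDE * np.exp(-(dy * dy + dx * dx) / 2.0)  # sigma = 1 px
    for cy, cx in kept:
        iy, ix = int(round(cy)), int(round(cx))
        ys, xs = (iy + dy).ravel(), (ix + dx).ravel()
        ok = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
        np.maximum.at(term_field, (ys[ok], xs[ok]), bump.ravel()[ok])
    term_mask = term_field > 0.5 * TERMINAL_AMPLITUDE  # ~2-4 px per punctum

    # --- z-placement with curvature tilt ----------------------------------
    yy, xx = np.mgrid[0:h, 0:w]
    frac = (yy + xx) / float((h - 1) + (w - 1))
    drift = p.curvature_tilt * frac
    span = max(p.n_planes - 1 - p.curvature_tilt, 0.0)
    z_sub = np.clip(np.round(0.25 * span + drift), 0, p.n_planes - 1).astype(int)
    z_epi = np.clip(np.round(0.75 * span + drift), 0, p.n_planes - 1).astype(int)

    voxels = np.zeros((p.n_planes, h, w), np.float32)
    fy, fx = np.nonzero(fiber_mask)
    voxels[z_sub[fy, fx], fy, fx] = FIBER_AMPLITUDE
    ty, tx = np.nonzero(term_field > 0)
    np.maximum.at(voxels, (z_epi[ty, tx], ty, tx), term_field[ty, tx].astype(np.float32))

    if p.noise_sd > 0:
        voxels += rng.normal(0.0, p.noise_sd, voxels.shape).astype(np.float32)
    voxels = np.clip(voxels, 0.0, INTENSITY_MAX)

    union = fiber_mask | term_mask
    truth = SyntheticTruth(
        true_fragment_count=_count_components(union),
        true_coverage_mask=union,
        nucleus_centers=[],
        sub_basal_mask=fiber_mask,
        terminal_mask=term_mask,
        sub_basal_fragment_count=_count_components(fiber_mask),
        terminal_fragment_count=_count_components(term_mask),
    )
    return ImageStack(voxels, pixel_size_um=0.31), truth


# --------------------------------------------------------------------------
# epithelium image
# --------------------------------------------------------------------------


@dataclass
class SyntheticEpitheliumParams:
    """Parameters for the DAPI-like nucleus field generator.

    Nuclei sit on a square lattice of period ``nucleus_spacing_px`` with
    per-nucleus positional jitter.  Degradation order is fixed:
    dropout → blur → contrast flattening → additive Gaussian noise.
    """

    image_size_px: tuple[int, int] = (200, 200)
    nucleus_spacing_px: float = 14.0
    nucleus_radius_px: float = 6.0
    position_jitter_px: float = 1.0
    dropout: float = 0.0
    blur_sigma_px: float = 0.0
    intensity_flattening: float = 0.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dropout", "intensity_flattening"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.image_size_px) < 16:
            raise ValueError("image too small")
        if self.nucleus_spacing_px <= 0 or self.nucleus_radius_px <= 0:
            raise ValueError("spacing and radius must be positive")
        if self.position_jitter_px < 0 or self.blur_sigma_px < 0 or self.noise_sd < 0:
            raise ValueError("jitter, blur and noise must be >= 0")
        if 2.0 * self.nucleus_radius_px >= self.nucleus_spacing_px:
            raise ValueError("nucleus_radius_px >= spacing/2 guarantees nucleus overlap")
        if 2.0 * (self.nucleus_radius_px + self.position_jitter_px) > self.nucleus_spacing_px:
            warnings.warn("jitter may bring neighboring nuclei into contact", stacklevel=2)


EPI_BACKGROUND = 30.0
EPI_AMPLITUDE = 180.0


def generate_epithelium_image(
    params: SyntheticEpitheliumParams,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Render a (possibly degraded) periodic nucleus field.

    Returns the float image (intensities in [0, 255]) and the truth listing
    the surviving (post-dropout) nucleus centers.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    h, w = p.image_size_px
    s = p.nucleus_spacing_px

    gy = np.arange(s / 2.0, h, s)
    gx = np.arange(s / 2.0, w, s)
    centers = np.array([(y, x) for y in gy for x in gx])
    if p.position_jitter_px > 0 and len(centers):
        centers = centers + rng.uniform(-p.position_jitter_px, p.position_jitter_px, centers.shape)
    # dropout (first degradation step)
    if len(centers):
        centers = centers[rng.random(len(centers)) >= p.dropout]
    centers = [(float(y), float(x)) for y, x in centers]

    img = np.full((h, w), EPI_BACKGROUND, np.float64)
    sigma_n = p.nucleus_radius_px / 2.0
    r_sup = int(np.ceil(3.0 * sigma_n))
    dy, dx = np.mgrid[-r_sup : r_sup + 1, -r_sup : r_sup + 1]
    bump = EPI_AMPLITUDE * np.exp(-(dy * dy + dx * dx) / (2.0 * sigma_n * sigma_n))
    for cy, cx in centers:
        iy, ix = int(round(cy)), int(round(cx))
        ys, xs = (iy + dy).ravel(), (ix + dx).ravel()
        ok = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
        np.maximum.at(img, (ys[ok], xs[ok]), EPI_BACKGROUND + bump.ravel()[ok])

    if p.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, p.blur_sigma_px)
    if p.intensity_flattening > 0:
        img = img.mean() + (img - img.mean()) * (1.0 - p.intensity_flattening)
    if p.noise_sd > 0:
        img = img + rng.normal(0.0, p.noise_sd, img.shape)
    img = np.clip(img, 0.0, INTENSITY_MAX)

    return img, SyntheticTruth(nucleus_centers=centers)


# --------------------------------------------------------------------------
# physiology cohort
# --------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Design of a synthetic physiology cohort.

    ``wick_means_mm`` and ``threshold_means_mm`` are group×day matrices of
    target means.  Blink responses at each filament length are Binomial(6,
    p) with a logistic detection model p(length) = 1/(1+exp((length − m)/s)),
    monotone non-increasing in length (longer filament = lower force), whose
    midpoint m is that group/day's threshold mean.  ``blink_prob_override``
    replaces the logistic with an arbitrary p(length_mm, group_idx,
    day_idx) for controlled tests.
    """

    groups: tuple[str, ...] = ("naive", "vehicle", "cmp")
    n_per_group: int = 11
    days: tuple[int, ...] = (0, 5, 7, 10, 14)
    wick_means_mm: np.ndarray | None = None
    wick_sd_mm: float = 0.8
    threshold_means_mm: np.ndarray | None = None
    blink_scale_mm: float = 0.25
    blink_prob_override: object | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 0:
            raise ValueError("n_per_group must be >= 0")
        if list(self.days) != sorted(self.days):
            raise ValueError("days must be sorted ascending")
        if self.wick_sd_mm < 0:
            raise ValueError("wick_sd_mm must be >= 0")
        g, d = len(self.groups), len(self.days)
        if self.wick_means_mm is None:
            # study-condition defaults: ~5 mm baseline; desiccation cuts tears
            # by ~43% at day 5 and ~60% at day 7; vehicle stays low; CMP recovers
            by_group = {
                "naive": [5.0, 5.0, 5.0, 5.0, 5.0],
                "vehicle": [5.0, 2.85, 2.0, 2.0, 2.2],
                "cmp": [5.0, 2.85, 2.0, 2.8, 3.6],
            }
            self.wick_means_mm = np.array([by_group[g_][:d] for g_ in self.groups])
        if self.threshold_means_mm is None:
            # sensitivity threshold ~2.65 mm at baseline, ~1.08 mm after 7 d
            by_group = {
                "naive": [2.65, 2.65, 2.65, 2.65, 2.65],
                "vehicle": [2.65, 1.6, 1.08, 0.7, 1.0],
                "cmp": [2.65, 1.6, 1.08, 1.1, 2.0],
            }
            self.threshold_means_mm = np.array([by_group[g_][:d] for g_ in self.groups])
        self.wick_means_mm = np.asarray(self.wick_means_mm, float)
        self.threshold_means_mm = np.asarray(self.threshold_means_mm, float)
        if self.wick_means_mm.shape != (g, d) or self.threshold_means_mm.shape != (g, d):
            raise ValueError(f"effect matrices must have shape {(g, d)}")
        if (self.wick_means_mm < 0).any():
            raise ValueError("wick means must be >= 0")


def _blink_p(spec: CohortSpec, length: float, gi: int, di: int) -> float:
    if spec.blink_prob_override is not None:
        return float(spec.blink_prob_override(length, gi, di))
    m = spec.threshold_means_mm[gi, di]
    return float(1.0 / (1.0 + np.exp((length - m) / spec.blink_scale_mm)))


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw per-animal wick and blink tables for the configured design.

    Wick lengths are Normal(mean, sd) truncated at 0; blink positives at
    each length are Binomial(6, p(length)).  Identical seeds give identical
    tables.
    """
    rng = np.random.default_rng(spec.seed)
    wick_rows, blink_rows = [], []
    for gi, group in enumerate(spec.groups):
        for ai in range(spec.n_per_group):
            animal = f"{group}_{ai:02d}"
            for di, day in enumerate(spec.days):
                wick = max(0.0, rng.normal(spec.wick_means_mm[gi, di], spec.wick_sd_mm))
                wick_rows.append(
                    {"animal_id": animal, "group": group, "day": day, "wick_mm": wick}
                )
                for length in TESTED_LENGTHS_MM:
                    pos = int(rng.binomial(N_TAPS, _blink_p(spec, length, gi, di)))
                    blink_rows.append(
                        {
                            "animal_id": animal,
                            "group": group,
                            "day": day,
                            "length_mm": length,
                            "positives": pos,
                        }
                    )
    cols_w = ["animal_id", "group", "day", "wick_mm"]
    cols_b = ["animal_id", "group", "day", "length_mm", "positives"]
    wick_df = pd.DataFrame(wick_rows, columns=cols_w)
    blink_df = pd.DataFrame(blink_rows, columns=cols_b)
    truth = SyntheticTruth(
        cohort_effects={
            "groups": list(spec.groups),
            "days": list(spec.days),
            "wick_means_mm": spec.wick_means_mm.tolist(),
            "threshold_means_mm": spec.threshold_means_mm.tolist(),
        }
    )
    return wick_df, blink_df, truth
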