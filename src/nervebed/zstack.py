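"""Tiled z-stack flattening for curved whole-mount cornea confocal images.

The cornea flattens imperfectly onto a slide, so the sub-basal nerve plexus
and the more superficial epithelial terminals sit in different z-planes in
different regions of the same field.  The pipeline therefore splits the
(y, x) plane into a small grid of tiles, selects a per-tile z-window for
each anatomical layer, flattens each tile sub-stack with a standard-
deviation projection, binarizes, and re-stitches the tiles into a single
seam-free binary mask per layer.

Conventions used throughout: coordinates are 0-based, tile rectangles are
half-open ``[y0, y1) x [x0, x1)``, z-windows are inclusive ``[z_lo, z_hi]``,
and the SD projection uses the population convention (divide by n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "ImageStack",
    "TileGrid",
    "BinaryMask",
    "ProjectedImage",
    "split_tiles",
    "auto_zbounds",
    "sd_project",
    "binarize",
    "stitch",
    "project_stack",
]

LAYERS = ("sub_basal", "epithelial")


@dataclass
class ImageStack:
    """A 3D intensity volume indexed (z, y, x) with optional pixel size."""

    voxels: np.ndarray
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a (z, y, x) volume, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)) or self.voxels.min() < 0:
            raise ValueError("stack intensities must be finite and non-negative")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def plane_count(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.voxels.shape[1], self.voxels.shape[2]


def _axis_edges(n: int, k: int) -> np.ndarray:
    """Partition ``n`` pixels into ``k`` contiguous runs, larger runs first.

    Sizes differ by at most one pixel; e.g. 800 into 3 gives (267, 267, 266)
    and 10 into 3 gives (4, 3, 3).  Returns k+1 edge coordinates.
    """
    if k <= 0:
        raise ValueError("grid dimensions must be positive")
    if n < k:
        raise ValueError(f"cannot split {n} pixels into {k} non-empty tiles")
    base, rem = divmod(n, k)
    sizes = [base + 1] * rem + [base] * (k - rem)
    return np.concatenate([[0], np.cumsum(sizes)])


@dataclass
class TileGrid:
    """A rows x cols partition of the (y, x) plane into half-open rectangles."""

    rows: int = 3
    cols: int = 3
    shape_yx: tuple[int, int] = (800, 800)
    tile_bounds: list[tuple[int, int, int, int]] = field(init=False)

    def __post_init__(self) -> None:
        ye = _axis_edges(self.shape_yx[0], self.rows)
        xe = _axis_edges(self.shape_yx[1], self.cols)
        # row-major tile order: tile (r, c) has flat index r * cols + c
        self.tile_bounds = [
            (int(ye[r]), int(ye[r + 1]), int(xe[c]), int(xe[c + 1]))
            for r in range(self.rows)
            for c in range(self.cols)
        ]

    @property
    def n_tiles(self) -> int:
        return self.rows * self.cols


def split_tiles(stack: ImageStack | np.ndarray, grid: TileGrid) -> list[np.ndarray]:
    """Split a stack (or 2D image) into row-major tile views per the grid."""
    arr = stack.voxels if isinstance(stack, ImageStack) else np.asarray(stack)
    if arr.shape[-2:] != tuple(grid.shape_yx):
        raise ValueError(f"stack extent {arr.shape[-2:]} does not match grid extent {grid.shape_yx}")
    return [arr[..., y0:y1, x0:x1] for (y0, y1, x0, x1) in grid.tile_bounds]


def auto_zbounds(substack: np.ndarray, window: int = 3) -> tuple[int, int]:
    """Choose the contiguous window of ``window`` planes maximizing total intensity.

    Stands in for the manual per-tile z-bound selection when running
    unattended; returns an inclusive (z_lo, z_hi) interval.
    """
    nz = substack.shape[0]
    window = min(window, nz)
    per_plane = substack.reshape(nz, -1).sum(axis=1, dtype=np.float64)
    sums = np.convolve(per_plane, np.ones(window), mode="valid")
    z_lo = int(np.argmax(sums))
    return z_lo, z_lo + window - 1


def sd_project(substack: np.ndarray, bounds: tuple[int, int]) -> np.ndarray:
    """Flatten planes ``z_lo..z_hi`` (inclusive) to their per-pixel population SD.

    A single-plane interval is legal but carries no variance information and
    yields an all-zero projection with a warning.
    """
    z_lo, z_hi = bounds
    nz = substack.shape[0]
    if not (0 <= z_lo <= z_hi < nz):
        raise ValueError(f"z-bounds ({z_lo}, {z_hi}) outside 0..{nz - 1}")
    if z_lo == z_hi:
        warnings.warn("single-plane z-interval: SD projection is identically zero", stacklevel=2)
    return np.std(substack[z_lo : z_hi + 1].astype(np.float64), axis=0)


@dataclass
class BinaryMask:
    """A thresholded projection plus the threshold provenance."""

    mask: np.ndarray
    threshold_used: float
    method: str  # manual | fixed | otsu

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class ProjectedImage:
    """A flattened 2D field with its provenance (layer, tile id or 'stitched')."""

    pixels: np.ndarray
    layer: str = "sub_basal"
    tile: str = "stitched"


def binarize(img: np.ndarray, method: str = "otsu", threshold: float | None = None) -> BinaryMask:
    """Threshold a projected image; ``mask = img > threshold``.

    ``manual``/``fixed`` require an explicit threshold (the attended
    workflow); ``otsu`` computes it from the histogram for unattended runs.
    A constant image under Otsu yields an empty mask with a warning rather
    than failing.
    """
    img = np.asarray(img, dtype=np.float64)
    if method in ("manual", "fixed"):
        if threshold is None:
            raise ValueError(f"method={method!r} requires an explicit threshold")
        thr = float(threshold)
    elif method == "otsu":
        if np.ptp(img) == 0:
            warnings.warn("constant image: Otsu undefined, returning empty mask", stacklevel=2)
            return BinaryMask(np.zeros(img.shape, bool), float(img.flat[0] if img.size else 0.0), method)
        thr = float(threshold_otsu(img))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return BinaryMask(img > thr, thr, method)


def stitch(tiles: list[BinaryMask | np.ndarray], grid: TileGrid) -> np.ndarray:
    """Reassemble per-tile masks into one full-extent mask (pure copy, no blending)."""
    if len(tiles) != grid.n_tiles:
        raise ValueError(f"expected {grid.n_tiles} tiles, got {len(tiles)}")
    out = np.zeros(grid.shape_yx, dtype=bool)
    for t, (y0, y1, x0, x1) in zip(tiles, grid.tile_bounds):
        m = t.mask if isinstance(t, BinaryMask) else np.asarray(t, bool)
        if m.shape != (y1 - y0, x1 - x0):
            raise ValueError(f"tile shape {m.shape} does not fit rectangle {(y0, y1, x0, x1)}")
        out[y0:y1, x0:x1] = m
    return out


def project_stack(
    stack: ImageStack,
    grid: TileGrid | None = None,
    zbounds: list[tuple[int, int]] | str = "auto",
    window: int = 3,
    threshold_mode: str = "otsu",
    thresholds: list[float] | None = None,
) -> tuple[np.ndarray, dict]:
    """Run split -> per-tile SD projection -> binarize -> stitch for one layer.

    ``zbounds`` is either a per-tile list of inclusive (z_lo, z_hi) intervals
    (the attended workflow) or ``"auto"`` to pick the brightest ``window``
    planes per tile.  Returns the stitched mask and a provenance record.
    """
    if grid is None:
        grid = TileGrid(shape_yx=stack.shape_yx)
    subs = split_tiles(stack, grid)
    if zbounds == "auto":
        bounds = [auto_zbounds(s, window) for s in subs]
    else:
        bounds = list(zbounds)
        if len(bounds) != grid.n_tiles:
            raise ValueError("need one z-bound interval per tile")
    masks = []
    for i, (s, b) in enumerate(zip(subs, bounds)):
        proj = sd_project(s, b)
        thr = thresholds[i] if thresholds is not None else None
        masks.append(binarize(proj, threshold_mode, thr))
    stitched = stitch(masks, grid)
    provenance = {
        "grid": {"rows": grid.rows, "cols": grid.cols, "tile_bounds": grid.tile_bounds},
        "zbounds": [list(map(int, b)) for b in bounds],
        "sd_convention": "population",
        "thresholds": [float(m.threshold_used) for m in masks],
        "threshold_mode": threshold_mode,
    }
    return stitched, provenance
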