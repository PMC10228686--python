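"""End-to-end convenience wrappers used by the analysis drivers and the CLI."""

from __future__ import annotations

import numpy as np

from . import epithelium, fragmentation, zstack

__all__ = ["analyze_nerve_stack", "analyze_mask", "analyze_epithelium_image"]


def analyze_mask(mask: np.ndarray, connectivity: int = 8, min_size: int = 0) -> dict:
    """Fragmentation metrics for one binary nerve mask."""
    labeling = fragmentation.label_fragments(mask, connectivity)
    if min_size > 0 and labeling.fragment_count:
        small = np.flatnonzero(labeling.fragment_sizes < min_size) + 1
        if len(small):
            cleaned = mask & ~np.isin(labeling.labels, small)
            labeling = fragmentation.label_fragments(cleaned, connectivity)
    m = fragmentation.compute_metrics(labeling)
    return {
        "fragment_count": m.fragment_count,
        "coverage_px": m.coverage_px,
        "coverage_fraction": m.coverage_fraction,
        "fragmentation_index": m.fragmentation_index,
        "fragmentation_per_1000px": m.fragmentation_per_1000px,
    }


def analyze_nerve_stack(
    stack: zstack.ImageStack,
    grid: zstack.TileGrid | None = None,
    window: int = 3,
    threshold_mode: str = "otsu",
    connectivity: int = 8,
) -> dict:
    """Project, binarize, stitch and fragment both anatomical layers.

    With auto z-bounds the sub-basal layer is the brightest window and the
    epithelial layer the brightest window in the remaining planes; returns
    per-layer masks, provenance and fragmentation metrics.
    """
    if grid is None:
        grid = zstack.TileGrid(shape_yx=stack.shape_yx)
    out: dict = {"layers": {}}
    subs = zstack.split_tiles(stack, grid)
    # per-tile: brightest window = sub-basal; brightest disjoint later window = epithelial
    for layer in ("sub_basal", "epithelial"):
        bounds = []
        for s in subs:
            b_sub = zstack.auto_zbounds(s, window)
            if layer == "sub_basal":
                bounds.append(b_sub)
            else:
                rest = s.copy()
                rest[b_sub[0] : b_sub[1] + 1] = 0
                bounds.append(zstack.auto_zbounds(rest, window))
        mask, prov = zstack.project_stack(stack, grid, bounds, window, threshold_mode)
        out["layers"][layer] = {
            "mask": mask,
            "provenance": prov,
            "metrics": analyze_mask(mask, connectivity),
        }
    return out


def analyze_epithelium_image(
    img: np.ndarray,
    n_per_axis: int = 5,
    sigma: float = 1.0,
    min_prominence: float | str = "auto",
    pool: str = "per_profile",
) -> dict:
    """Preprocess, profile and score one DAPI image."""
    pre = epithelium.preprocess(img, epithelium.PreprocessSpec(gaussian_sigma_px=sigma))
    profiles = epithelium.extract_profiles(pre, n_per_axis)
    m = epithelium.compute_metrics(profiles, min_prominence, pool)
    return {
        "preprocessed": pre,
        "profiles": profiles,
        "metrics": {
            "n_peaks": m.n_peaks,
            "n_troughs": m.n_troughs,
            "n_transitions": m.n_transitions,
            "transition_delta": m.transition_delta,
            "auc": m.auc,
            "auc_per_transition": m.auc_per_transition,
        },
    }
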