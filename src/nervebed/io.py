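"""File formats: multi-page TIFF stacks, PNG masks, CSV tables, JSON sidecars.

Physiology tables travel as a single long-format CSV with columns exactly
``animal_id, group, day, measure, value`` where ``measure`` is ``wick_mm``
or ``blink_pos_<length>mm``.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .synthetic import SyntheticTruth
from .zstack import ImageStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_mask",
    "read_mask",
    "write_labels",
    "write_truth",
    "read_truth",
    "physiology_to_long",
    "physiology_from_long",
]

PHYSIOLOGY_COLUMNS = ["animal_id", "group", "day", "measure", "value"]


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write one TIFF page per z-plane (float32)."""
    tifffile.imwrite(str(path), stack.voxels.astype(np.float32))


def read_stack(path: str | Path, pixel_size_um: float | None = None, channel: int | None = None) -> ImageStack:
    """Read a single- or multi-channel multi-page TIFF as a (z, y, x) stack.

    For a 4D (z, c, y, x) file, ``channel`` selects the channel of interest
    (e.g. the neuronal marker).
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 4:
        if channel is None:
            raise ValueError("multi-channel stack: a channel index is required")
        arr = arr[:, channel]
    return ImageStack(np.asarray(arr, np.float32), pixel_size_um=pixel_size_um)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(str(path), (np.asarray(mask, bool).astype(np.uint8) * 255))


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(str(path))) > 0


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    """16-bit label TIFF (caps at 65535 fragments)."""
    tifffile.imwrite(str(path), np.asarray(labels).astype(np.uint16))


def write_truth(path: str | Path, truth: SyntheticTruth, mask_path: str | None = None) -> None:
    """JSON sidecar for planted truth; the coverage mask goes to PNG separately."""
    payload = {
        "true_fragment_count": truth.true_fragment_count,
        "sub_basal_fragment_count": truth.sub_basal_fragment_count,
        "terminal_fragment_count": truth.terminal_fragment_count,
        "nucleus_centers": [list(c) for c in truth.nucleus_centers],
        "cohort_effects": truth.cohort_effects,
        "coverage_mask_file": mask_path,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def physiology_to_long(wick_df: pd.DataFrame, blink_df: pd.DataFrame) -> pd.DataFrame:
    wick = wick_df.assign(measure="wick_mm", value=wick_df["wick_mm"])[PHYSIOLOGY_COLUMNS]
    blink = blink_df.assign(
        measure=blink_df["length_mm"].map(lambda v: f"blink_pos_{v:g}mm"),
        value=blink_df["positives"].astype(float),
    )[PHYSIOLOGY_COLUMNS]
    return pd.concat([wick, blink], ignore_index=True)


def physiology_from_long(long_df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    if list(long_df.columns) != PHYSIOLOGY_COLUMNS:
        raise ValueError(f"expected columns {PHYSIOLOGY_COLUMNS}, got {list(long_df.columns)}")
    is_wick = long_df["measure"] == "wick_mm"
    wick = long_df[is_wick].rename(columns={"value": "wick_mm"})[
        ["animal_id", "group", "day", "wick_mm"]
    ].reset_index(drop=True)
    b = long_df[~is_wick].copy()
    b["length_mm"] = b["measure"].str.extract(r"blink_pos_([\d.]+)mm").astype(float)
    b["positives"] = b["value"].astype(int)
    blink = b[["animal_id", "group", "day", "length_mm", "positives"]].reset_index(drop=True)
    return wick, blink
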