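"""Biological readouts: per-frame counts, sickled fraction r(t), overlap rate.

The sickled fraction of a frame at time t is

    r(t) = n_sickled(t) / (n_healthy(t) + n_sickled(t)),

and the frame-wise overlap rate is

    R_overlap(t) = N_overlap(t) / N_total(t),

where N_overlap counts cells whose mask intersects, or 8-connectedly
touches, at least one other cell's mask. Both are carried as explicit
``None`` flags (never NaN) on empty frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "FrameQuant",
    "TimeSeries",
    "count_instances",
    "sickled_fraction",
    "overlap_rate",
    "overlap_flags_from_masks",
    "estimated_overlap_rate",
    "summarize_dataset",
    "assemble_time_series",
]

_TOUCH_STRUCT = np.ones((3, 3), dtype=bool)
_KNOWN_CLASSES = ("healthy", "sickled")


@dataclass(frozen=True)
class FrameQuant:
    """Counts and fractions for a single frame."""

    time_s: float
    n_healthy: int
    n_sickled: int
    r: float | None
    R_overlap: float | None = None
    R_overlap_is_estimate: bool = False
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_sickled < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class TimeSeries:
    """Time-ordered frame quantifications with provenance."""

    frames: list[FrameQuant]
    provenance: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": [f.frame_index for f in self.frames],
                "time_s": [f.time_s for f in self.frames],
                "n_healthy": [f.n_healthy for f in self.frames],
                "n_sickled": [f.n_sickled for f in self.frames],
                "r": [f.r for f in self.frames],
                "R_overlap": [f.R_overlap for f in self.frames],
                "R_overlap_is_estimate": [f.R_overlap_is_estimate for f in self.frames],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time_s for f in self.frames])

    @property
    def r_values(self) -> list[float | None]:
        return [f.r for f in self.frames]


def count_instances(inst) -> tuple[int, int]:
    """Exact (n_healthy, n_sickled) tallies of an InstanceLabelMap."""
    classes = list(inst.table["cls"]) if len(inst.table) else []
    return classes.count("healthy"), classes.count("sickled")


def sickled_fraction(n_healthy: int, n_sickled: int) -> float | None:
    """r = n_sickled / (n_healthy + n_sickled); None when both are zero."""
    if n_healthy < 0 or n_sickled < 0:
        raise ValueError("counts must be >= 0")
    total = n_healthy + n_sickled
    if total == 0:
        return None
    return n_sickled / total


def _bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.where(rows)[0][[0, -1]]
    c0, c1 = np.where(cols)[0][[0, -1]]
    return int(r0), int(r1) + 1, int(c0), int(c1) + 1


def overlap_flags_from_masks(masks: Sequence[np.ndarray]) -> list[bool]:
    """Brute-force pairwise involvement: a cell is involved in overlap iff
    its mask intersects or 8-connectedly touches another cell's mask."""
    n = len(masks)
    flags = [False] * n
    boxes = [_bbox(m) for m in masks]
    for i in range(n):
        for j in range(i + 1, n):
            if flags[i] and flags[j]:
                continue
            ri0, ri1, ci0, ci1 = boxes[i]
            rj0, rj1, cj0, cj1 = boxes[j]
            # expand by 1 px for the touch rule
            if ri1 + 1 <= rj0 or rj1 + 1 <= ri0 or ci1 + 1 <= cj0 or cj1 + 1 <= ci0:
                continue
            r0, r1 = min(ri0, rj0), max(ri1, rj1)
            c0, c1 = min(ci0, cj0), max(ci1, cj1)
            a = masks[i][r0:r1, c0:c1]
            b = masks[j][r0:r1, c0:c1]
            if np.any(ndi.binary_dilation(a, _TOUCH_STRUCT) & b):
                flags[i] = True
                flags[j] = True
    return flags


def overlap_rate(gt) -> float | None:
    """R_overlap = N_overlap / N_total on ground-truth masks (None if no
    cells). 0 means no cell overlaps; 1 means every cell is involved."""
    if gt.n_cells == 0:
        return None
    flags = overlap_flags_from_masks(gt.instance_masks)
    return sum(flags) / gt.n_cells


def estimated_overlap_rate(inst) -> float | None:
    """Prediction-only surrogate: fraction of instances whose parent region
    was split by the watershed. Labeled an estimate because true instance
    identities are unavailable at inference."""
    total = len(inst.table)
    if total == 0:
        return None
    return int(inst.table["split_flag"].sum()) / total


def _counts_from_manifest(m) -> tuple[dict[str, int], str]:
    """Accept a {class: count} mapping or a path to a JSON sidecar listing
    per-cell records with a 'class' field."""
    if isinstance(m, (str, Path)):
        records = json.loads(Path(m).read_text())
        counts: dict[str, int] = {}
        for rec in records:
            counts[rec["class"]] = counts.get(rec["class"], 0) + 1
        name = str(m)
    elif isinstance(m, Mapping):
        counts = {k: int(v) for k, v in m.items()}
        name = "<mapping>"
    else:
        raise TypeError(f"unsupported manifest type {type(m)!r}")
    for cls in counts:
        if cls not in _KNOWN_CLASSES:
            raise ValueError(f"manifest {name} contains unknown class {cls!r}")
    return counts, name


def summarize_dataset(manifests: Iterable) -> dict:
    """Aggregate per-class and total instance counts over many manifests.

    Returns ``{"per_class": {...}, "total": int, "per_frame": DataFrame}``;
    the total is exactly the sum of the per-class counts.
    """
    per_class = {cls: 0 for cls in _KNOWN_CLASSES}
    rows = []
    for m in manifests:
        counts, name = _counts_from_manifest(m)
        row = {"manifest": name}
        for cls in _KNOWN_CLASSES:
            c = counts.get(cls, 0)
            per_class[cls] += c
            row[cls] = c
        row["total"] = sum(counts.values())
        rows.append(row)
    return {
        "per_class": per_class,
        "total": sum(per_class.values()),
        "per_frame": pd.DataFrame(rows, columns=["manifest", *_KNOWN_CLASSES, "total"]),
    }


def assemble_time_series(
    frames: Iterable[FrameQuant], provenance: str = ""
) -> TimeSeries:
    """Sort frames by time and reject duplicate timestamps."""
    ordered = sorted(frames, key=lambda f: f.time_s)
    if not ordered:
        raise ValueError("at least one frame is required")
    times = [f.time_s for f in ordered]
    for a, b in zip(times, times[1:]):
        if a == b:
            raise ValueError(f"duplicate timestamp {a} s in time series")
    return TimeSeries(frames=ordered, provenance=provenance)
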