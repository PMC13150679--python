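"""Segmenter adapter contract plus a classical fallback segmenter.

The production segmenter is an external trained network (plugged in via
:func:`run_external_adapter`, exchanging PNG frames and {0,1,2} label maps
by basename). :func:`baseline_segment` is a download-free classical
stand-in — dark-object thresholding plus an elongation classifier — so the
end-to-end pipeline runs and is testable without trained weights. It is a
demo heuristic, not a replacement for a learned segmenter on real data.
"""

from __future__ import annotations

import logging
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.filters import threshold_otsu

from .frameio import FrameRecord, read_labelmap

__all__ = ["SegmenterAdapter", "baseline_segment", "run_external_adapter", "AdapterResult"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmenterAdapter:
    """A stateless mapping from a standardized frame to a {0,1,2} label map
    of identical shape."""

    name: str
    run: Callable[[FrameRecord], np.ndarray]

    def __call__(self, fr: FrameRecord) -> np.ndarray:
        out = np.asarray(self.run(fr))
        if out.shape != fr.image.shape[:2]:
            raise ValueError(
                f"adapter {self.name!r} returned shape {out.shape}, "
                f"expected {fr.image.shape[:2]}"
            )
        bad = set(np.unique(out)) - {0, 1, 2}
        if bad:
            raise ValueError(
                f"adapter {self.name!r} emitted invalid label values "
                f"{sorted(int(v) for v in bad)}"
            )
        return out.astype(np.uint8)


def _drop_small(mask, min_px):
    lbl, n = ndi.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return mask
    sizes = np.bincount(lbl.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[lbl]


def baseline_segment(
    fr: FrameRecord,
    fg_threshold_mode: str = "otsu",
    fixed_threshold: float | None = None,
    elong_threshold: float = 2.0,
    min_object_px: int = 30,
) -> np.ndarray:
    """Classify dark objects as healthy/sickled by elongation.

    Foreground is the below-threshold (dark) pixel set after small-object
    removal; each connected component is labeled sickled (2) if its
    major/minor axis ratio is >= ``elong_threshold``, else healthy (1).
    The default threshold of 2.0 separates crescents (aspect >= 2.5) from
    discs with margin.
    """
    img = np.asarray(fr.image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim != 2:
        raise ValueError("baseline_segment expects a preprocessed grayscale frame")
    out = np.zeros(img.shape, dtype=np.uint8)
    if np.ptp(img) == 0:
        return out
    if fg_threshold_mode == "otsu":
        thr = threshold_otsu(img)
    elif fg_threshold_mode == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed_threshold required when fg_threshold_mode='fixed'")
        thr = float(fixed_threshold)
    else:
        raise ValueError(f"unknown fg_threshold_mode {fg_threshold_mode!r}")
    fg = img < thr
    fg = _drop_small(fg, min_object_px)
    lbl = sk_label(fg, connectivity=2)
    for prop in regionprops(lbl):
        minor = max(prop.axis_minor_length, 1e-6)
        elong = prop.axis_major_length / minor
        out[lbl == prop.label] = 2 if elong >= elong_threshold else 1
    return out


@dataclass
class AdapterResult:
    """Per-frame outcome of an external-adapter run."""

    frame_name: str
    labels: np.ndarray | None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.labels is not None


def run_external_adapter(
    frames_dir: str | Path, adapter_command: str, out_dir: str | Path
) -> list[AdapterResult]:
    """Run an external segmenter over a directory of PNG frames.

    The command receives the input/output directories via ``{frames_dir}``
    and ``{out_dir}`` placeholders (appended as arguments when absent) and
    must write one {0,1,2} PNG per frame with a matching basename
    (ignoring a ``_0000`` channel suffix). Malformed or missing outputs are
    reported per frame without aborting the run.
    """
    frames_dir = Path(frames_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame_files = sorted(frames_dir.glob("*.png"))
    if not frame_files:
        log.warning("no frames found in %s; nothing to segment", frames_dir)
        return []

    if "{frames_dir}" in adapter_command or "{out_dir}" in adapter_command:
        cmd = adapter_command.format(frames_dir=frames_dir, out_dir=out_dir)
    else:
        cmd = f"{adapter_command} {frames_dir} {out_dir}"
    proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
    if proc.returncode != 0:
        raise EnvironmentError(
            f"adapter command failed (exit {proc.returncode}): {cmd}\n"
            f"{proc.stderr.strip()}\n"
            "Install the external segmenter and ensure the command is on PATH."
        )

    results: list[AdapterResult] = []
    for f in frame_files:
        base = f.stem.removesuffix("_0000")
        candidate = out_dir / f"{base}.png"
        if not candidate.exists():
            candidate = out_dir / f.name
        try:
            labels = read_labelmap(candidate)
            results.append(AdapterResult(frame_name=f.name, labels=labels))
        except (IOError, ValueError) as exc:
            log.error("adapter output invalid for %s: %s", f.name, exc)
            results.append(AdapterResult(frame_name=f.name, labels=None, error=str(exc)))
    return results
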