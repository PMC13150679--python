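"""Frame extraction, preprocessing, and integer-encoded label-map I/O.

Sources: a directory of image frames, a multi-page TIFF stack, or any
container ``imageio`` can open (fps is taken from container metadata when
available, otherwise it must be supplied). Preprocessing follows the
inference front-end of the counting pipeline: grayscale conversion, CLAHE
contrast normalization, then resize to the 1000x1000 working resolution.

Label maps are 8-bit single-channel PNGs with values background=0,
healthy=1, sickled=2, named ``frame_{index:06d}.png`` (an optional
``_0000`` channel suffix supports external-segmenter file conventions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.color import rgb2gray
from skimage.exposure import equalize_adapthist
from skimage.transform import resize

__all__ = [
    "FrameRecord",
    "extract_frames",
    "preprocess_frame",
    "write_labelmap",
    "read_labelmap",
    "labelmap_filename",
    "frame_filename",
]

_IMAGE_EXTS = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp")


@dataclass(frozen=True)
class FrameRecord:
    """One frame with its bookkeeping: index, timestamp, pixels, origin."""

    frame_index: int
    time_s: float
    image: np.ndarray
    source_path: str

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")


def frame_filename(index: int, channel_suffix: bool = False) -> str:
    """Per-frame naming convention; ``_0000`` marks the single input channel
    for external segmenters that expect per-channel files."""
    suffix = "_0000" if channel_suffix else ""
    return f"frame_{index:06d}{suffix}.png"


labelmap_filename = frame_filename


def _load_stack(source: str | Path, fps: float | None):
    """Return (list of frame arrays, fps). Raises IOError on unreadable
    input or missing frame-rate metadata."""
    source = Path(source)
    if source.is_dir():
        files = sorted(
            p for p in source.iterdir() if p.suffix.lower() in _IMAGE_EXTS
        )
        if not files:
            raise IOError(f"no image frames found in directory {source}")
        if fps is None:
            raise IOError(f"fps must be supplied for frame directory {source}")
        return [np.asarray(Image.open(p)) for p in files], float(fps)
    if not source.exists():
        raise IOError(f"video source not found: {source}")
    if source.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        frames = list(tifffile.imread(source))
        if fps is None:
            raise IOError(f"fps must be supplied for TIFF stack {source}")
        return frames, float(fps)
    # generic container via imageio (requires a suitable plugin)
    import imageio.v2 as imageio

    try:
        reader = imageio.get_reader(str(source))
    except Exception as exc:  # pragma: no cover - depends on local plugins
        raise IOError(f"cannot decode video container {source}: {exc}") from exc
    meta = reader.get_meta_data()
    container_fps = fps if fps is not None else meta.get("fps")
    if container_fps is None:
        raise IOError(f"missing fps metadata in {source}; pass fps explicitly")
    frames = [np.asarray(f) for f in reader]
    reader.close()
    return frames, float(container_fps)


def extract_frames(
    source: str | Path,
    *,
    every_n: int | None = None,
    every_sec: float | None = None,
    fps: float | None = None,
) -> list[FrameRecord]:
    """Decode a video source into timestamped frames.

    Exactly one sampling mode applies: all frames (default), every Nth
    frame (``every_n``), or the frame temporally nearest each t = 0, S,
    2S, ... up to the video duration inclusive (``every_sec``; ties go to
    the earlier frame). Frame 0 corresponds to t = 0, so a 120 s recording
    sampled every 10 s yields 13 frames.
    """
    if every_n is not None and every_sec is not None:
        raise ValueError("every_n and every_sec are mutually exclusive")
    if every_n is not None and every_n < 1:
        raise ValueError("every_n must be >= 1")
    if every_sec is not None and every_sec <= 0:
        raise ValueError("every_sec must be > 0")

    frames, fps_val = _load_stack(source, fps)
    n_frames = len(frames)
    if every_n is not None:
        indices = list(range(0, n_frames, every_n))
    elif every_sec is not None:
        duration = (n_frames - 1) / fps_val
        indices = []
        t = 0.0
        k = 0
        while t <= duration + 1e-9:
            # nearest frame, earlier frame on ties
            idx = int(math.ceil(t * fps_val - 0.5))
            idx = min(max(idx, 0), n_frames - 1)
            if not indices or idx != indices[-1]:
                indices.append(idx)
            k += 1
            t = k * every_sec
    else:
        indices = list(range(n_frames))

    return [
        FrameRecord(
            frame_index=i,
            time_s=i / fps_val,
            image=np.asarray(frames[i]),
            source_path=str(source),
        )
        for i in indices
    ]


def preprocess_frame(
    fr: FrameRecord,
    target_shape: tuple[int, int] = (1000, 1000),
    clahe_clip: float | None = 0.01,
    clahe_tiles: tuple[int, int] = (8, 8),
) -> FrameRecord:
    """Grayscale + CLAHE + resize to the working resolution.

    ``clahe_clip`` is the normalized clip limit of scikit-image's
    ``equalize_adapthist`` (default 0.01); ``None`` or 0 disables contrast
    normalization entirely. CLAHE is applied before resizing. Constant
    images pass through unchanged (a flat histogram needs no equalization).
    Output is a single-channel uint8 frame of ``target_shape``.
    """
    if len(target_shape) != 2 or min(target_shape) < 1:
        raise ValueError("target_shape must be a positive (H, W) pair")
    img = np.asarray(fr.image)
    if img.size == 0:
        raise ValueError("empty image")
    img = img.astype(float)
    if img.ndim == 3:
        img = rgb2gray(img[..., :3] / 255.0) * 255.0
    img = np.clip(img, 0, 255) / 255.0

    if clahe_clip and np.ptp(img) > 0:
        kernel = (
            max(img.shape[0] // clahe_tiles[0], 1),
            max(img.shape[1] // clahe_tiles[1], 1),
        )
        img = equalize_adapthist(img, kernel_size=kernel, clip_limit=clahe_clip)

    if img.shape != tuple(target_shape):
        downscale = (
            target_shape[0] < img.shape[0] or target_shape[1] < img.shape[1]
        )
        img = resize(
            img, target_shape, order=1, anti_aliasing=downscale, preserve_range=True
        )
    out = np.rint(np.clip(img, 0.0, 1.0) * 255).astype(np.uint8)
    return replace(fr, image=out)


def write_labelmap(labels: np.ndarray, path: str | Path) -> Path:
    """Write a {0,1,2} label map as an 8-bit single-channel PNG."""
    labels = np.asarray(labels)
    bad = set(np.unique(labels)) - {0, 1, 2}
    if bad:
        raise ValueError(
            f"label map contains invalid values {sorted(int(v) for v in bad)}"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(labels.astype(np.uint8), mode="L").save(path)
    return path


def read_labelmap(path: str | Path) -> np.ndarray:
    """Read a label-map PNG, enforcing the {0,1,2} integer encoding."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"label map not found: {path}")
    arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a single-channel label map")
    bad = set(np.unique(arr)) - {0, 1, 2}
    if bad:
        raise ValueError(
            f"{path} contains values outside {{0,1,2}}: {sorted(int(v) for v in bad)}"
        )
    return arr.astype(np.uint8)
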