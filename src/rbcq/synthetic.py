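"""Seeded synthetic fields of healthy and sickled red blood cells.

Every downstream stage of the pipeline (segmentation fallback, watershed
instance separation, counting, evaluation) is exercised against scenes
produced here, for which instance masks, classes, and overlap involvement
are known exactly.

Geometry conventions
--------------------
Healthy cells are rendered as near-circular discs (radius ~9-12 px at the
1000x1000-equivalent working scale, with mild low-order boundary jitter,
imitating biconcave discocytes seen in projection). Sickled cells are bent,
tapered capsules (half-length ~11-14 px, half-width ~3.5-4.5 px, aspect
ratio >= 2.5) imitating elongated crescent morphologies. Same-class cells
that touch or intersect merge into a single connected region of the
semantic label map, which is precisely the failure mode the watershed
post-processing exists to undo.

Overlap is controlled by construction: ``round(target_overlap_rate *
n_cells)`` cells are placed in touching clusters (pairs, plus one triple
when the count is odd) and all remaining cells are placed with a clearance
margin, so the achieved overlap rate equals the target up to rounding.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage as ndi

__all__ = [
    "CellSpec",
    "SceneSpec",
    "GroundTruth",
    "SicklingSchedule",
    "PlacementError",
    "generate_scene",
    "render_semantic_map",
    "render_brightfield",
    "simulate_sequence",
    "perturb_semantic_map",
    "logistic_schedule",
    "save_ground_truth",
    "scene_spec_from_yaml",
    "scene_spec_to_yaml",
]

HEALTHY = "healthy"
SICKLED = "sickled"

# Geometry defaults (pixels at the 1000x1000-equivalent working scale).
HEALTHY_RADIUS_RANGE = (9.0, 12.0)
SICKLED_HALF_LENGTH_RANGE = (11.0, 14.0)
SICKLED_HALF_WIDTH_RANGE = (3.2, 4.2)
SICKLED_BEND_RANGE = (0.4, 0.7)  # half-angle of the centerline arc, radians
_JITTER_AMP = 0.04  # relative radial boundary jitter for healthy discs
_MAX_ATTEMPTS = 10_000  # hard cap per cell during rejection sampling

_BG_LEVEL = 0.82  # brightfield background, fraction of full scale
_CELL_LEVEL = 0.45
_PALLOR_LEVEL = 0.62  # central pallor of healthy discs
_STACK_LEVEL = 0.38  # pixels covered by more than one cell


class PlacementError(RuntimeError):
    """Raised when a cell cannot be placed within the attempt budget."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class CellSpec:
    """Geometry and class of a single synthetic cell."""

    cell_id: int
    cls: str
    center: tuple[int, int]  # (row, col)
    orientation: float
    size: float | tuple[float, float]  # radius, or (half_length, half_width)
    shape_seed: int
    bend: float = 0.0  # centerline arc half-angle (sickled only)

    def __post_init__(self) -> None:
        if self.cell_id <= 0:
            raise ValueError("cell_id must be a positive integer")
        if self.cls not in (HEALTHY, SICKLED):
            raise ValueError(f"unknown cell class {self.cls!r}")
        sizes = self.size if isinstance(self.size, tuple) else (self.size,)
        if any(s <= 0 for s in sizes):
            raise ValueError("cell size parameters must be positive")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic frame (or of a whole simulated sequence)."""

    frame_shape: tuple[int, int] = (512, 512)
    n_cells: int = 50
    target_overlap_rate: float = 0.3
    sickled_fraction: float = 0.5
    noise_level: float = 0.02
    illumination_gradient: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0.0 <= self.target_overlap_rate <= 1.0:
            raise ValueError("target_overlap_rate must lie in [0, 1]")
        if not 0.0 <= self.sickled_fraction <= 1.0:
            raise ValueError("sickled_fraction must lie in [0, 1]")
        if self.noise_level < 0 or self.illumination_gradient < 0:
            raise ValueError("noise_level and illumination_gradient must be >= 0")
        if len(self.frame_shape) != 2 or min(self.frame_shape) < 1:
            raise ValueError("frame_shape must be a positive (H, W) pair")


@dataclass
class GroundTruth:
    """Known truth for one frame: cells, per-cell masks, overlap involvement.

    Masks are full-frame boolean arrays and may mutually overlap; the
    semantic label map flattens them with sickled-over-healthy precedence.
    """

    cells: list[CellSpec]
    instance_masks: list[np.ndarray]
    overlap_flags: list[bool]
    frame_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if not (len(self.cells) == len(self.instance_masks) == len(self.overlap_flags)):
            raise ValueError("cells, masks and overlap_flags must have equal length")
        for cell, mask in zip(self.cells, self.instance_masks):
            if not mask.any():
                raise ValueError(f"cell {cell.cell_id} has an empty mask")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def count(self, cls: str) -> int:
        return sum(1 for c in self.cells if c.cls == cls)

    def centroids(self) -> np.ndarray:
        """(n, 2) array of mask centroids (row, col)."""
        if not self.instance_masks:
            return np.empty((0, 2))
        return np.array([ndi.center_of_mass(m) for m in self.instance_masks])

    def classes(self) -> list[str]:
        return [c.cls for c in self.cells]


@dataclass
class SicklingSchedule:
    """Target sickled-fraction trajectory on an ascending time grid (s)."""

    t_grid: np.ndarray
    r_target: np.ndarray
    conversion_times: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.r_target = np.asarray(self.r_target, dtype=float)
        if self.t_grid.ndim != 1 or self.t_grid.size == 0:
            raise ValueError("t_grid must be a non-empty 1-D array")
        if self.t_grid[0] < 0 or np.any(np.diff(self.t_grid) <= 0):
            raise ValueError("t_grid must be ascending and start at t >= 0")
        if self.r_target.shape != self.t_grid.shape:
            raise ValueError("r_target must match t_grid in length")
        if np.any(self.r_target < 0) or np.any(self.r_target > 1):
            raise ValueError("r_target values must lie in [0, 1]")
        if np.any(np.diff(self.r_target) < 0):
            raise ValueError("r_target must be non-decreasing (no un-sickling)")


def logistic_schedule(
    t_grid: Sequence[float], t_half: float | None = None, rate: float = 0.08
) -> SicklingSchedule:
    """Logistic 0 -> 1 sickling trajectory, pinned exactly to 0 and 1 at the ends."""
    t = np.asarray(t_grid, dtype=float)
    if t_half is None:
        t_half = 0.5 * (t[0] + t[-1])
    raw = 1.0 / (1.0 + np.exp(-rate * (t - t_half)))
    r = (raw - raw[0]) / (raw[-1] - raw[0])
    return SicklingSchedule(t_grid=t, r_target=r)


# ---------------------------------------------------------------------------
# mask templates
# ---------------------------------------------------------------------------


def _disc_template(radius: float, shape_seed: int) -> np.ndarray:
    """Boolean template of a jittered disc, centered in its own bounding box."""
    rng = np.random.default_rng(shape_seed)
    amps = rng.uniform(0.0, _JITTER_AMP, 3)
    phases = rng.uniform(0.0, 2 * np.pi, 3)
    half = int(math.ceil(radius * (1 + 3 * _JITTER_AMP))) + 1
    ax = np.arange(-half, half + 1, dtype=float)
    dy, dx = np.meshgrid(ax, ax, indexing="ij")
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    r_eff = radius * (
        1.0
        + amps[0] * np.cos(2 * theta + phases[0])
        + amps[1] * np.cos(3 * theta + phases[1])
        + amps[2] * np.cos(4 * theta + phases[2])
    )
    return rho <= r_eff


def _crescent_template(
    half_len: float, half_width: float, bend: float, orientation: float
) -> np.ndarray:
    """Boolean template of a bent, tapered capsule (crescent), box-centered.

    The centerline is a circular arc of half-angle ``bend``; the local
    half-width tapers as sqrt(1 - s^2) toward the tips (floored so tips stay
    >~1 px thick and connected). Tapering makes the distance transform peak
    at the cell middle, mirroring real crescents' pointed ends.
    """
    n_pts = 41
    s = np.linspace(-1.0, 1.0, n_pts)
    if bend > 1e-6:
        arc_r = half_len / bend
        ang = s * bend
        px = arc_r * np.sin(ang)
        py = arc_r * (1.0 - np.cos(ang))
    else:
        px = s * half_len
        py = np.zeros_like(s)
    py -= py.mean()
    ca, sa = math.cos(orientation), math.sin(orientation)
    rows = -sa * px + ca * py
    cols = ca * px + sa * py
    widths = half_width * np.sqrt(np.maximum(1.0 - s**2, 0.08))

    half = int(math.ceil(max(np.abs(rows).max(), np.abs(cols).max()) + half_width)) + 1
    ax = np.arange(-half, half + 1, dtype=float)
    gy, gx = np.meshgrid(ax, ax, indexing="ij")
    pts_r = rows[:, None]
    pts_c = cols[:, None]
    flat_y = gy.ravel()[None, :]
    flat_x = gx.ravel()[None, :]
    dist = np.hypot(flat_y - pts_r, flat_x - pts_c) - widths[:, None]
    return (dist.min(axis=0) <= 0.0).reshape(gy.shape)


def _template_for(cell: CellSpec) -> np.ndarray:
    if cell.cls == HEALTHY:
        return _disc_template(float(cell.size), cell.shape_seed)
    half_len, half_width = cell.size  # type: ignore[misc]
    return _crescent_template(half_len, half_width, cell.bend, cell.orientation)


_TOUCH_STRUCT = np.ones((3, 3), dtype=bool)  # 8-connected touching
_CLEAR_ITER = 2  # extra clearance (px) enforced between non-overlapping cells


def _dilate(template: np.ndarray, iterations: int) -> np.ndarray:
    padded = np.pad(template, iterations)
    return ndi.binary_dilation(padded, _TOUCH_STRUCT, iterations=iterations)


def _paste_window(
    frame_shape: tuple[int, int], center: tuple[int, int], template: np.ndarray
):
    """Slices mapping a box-centered template onto the frame, or None if it
    does not fit entirely inside the frame."""
    h = template.shape[0] // 2
    r0, c0 = center[0] - h, center[1] - h
    r1, c1 = r0 + template.shape[0], c0 + template.shape[1]
    if r0 < 0 or c0 < 0 or r1 > frame_shape[0] or c1 > frame_shape[1]:
        return None
    return (slice(r0, r1), slice(c0, c1))


def _intersects(
    frame_arr: np.ndarray,
    center: tuple[int, int],
    template: np.ndarray,
) -> bool:
    """Does ``template`` placed at ``center`` hit any True pixel of frame_arr?

    The template may extend past the frame edge (clipped)."""
    h = template.shape[0] // 2
    r0, c0 = center[0] - h, center[1] - h
    r1, c1 = r0 + template.shape[0], c0 + template.shape[1]
    fr0, fc0 = max(r0, 0), max(c0, 0)
    fr1 = min(r1, frame_arr.shape[0])
    fc1 = min(c1, frame_arr.shape[1])
    if fr0 >= fr1 or fc0 >= fc1:
        return False
    sub = template[fr0 - r0 : fr1 - r0, fc0 - c0 : fc1 - c0]
    return bool(np.any(frame_arr[fr0:fr1, fc0:fc1] & sub))


def _full_mask(
    frame_shape: tuple[int, int], center: tuple[int, int], template: np.ndarray
) -> np.ndarray:
    out = np.zeros(frame_shape, dtype=bool)
    win = _paste_window(frame_shape, center, template)
    if win is None:
        raise ValueError("template does not fit inside the frame")
    out[win] = template
    return out


def _contact_radius(cell: CellSpec) -> float:
    if cell.cls == HEALTHY:
        return float(cell.size)
    half_len, half_width = cell.size  # type: ignore[misc]
    return 0.5 * (half_len + half_width)


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------


def _draw_cell_geometry(rng: np.random.Generator, cell_id: int, cls: str) -> CellSpec:
    shape_seed = int(rng.integers(0, 2**31 - 1))
    orientation = float(rng.uniform(0.0, 2 * np.pi))
    if cls == HEALTHY:
        size: float | tuple[float, float] = float(rng.uniform(*HEALTHY_RADIUS_RANGE))
        bend = 0.0
    else:
        size = (
            float(rng.uniform(*SICKLED_HALF_LENGTH_RANGE)),
            float(rng.uniform(*SICKLED_HALF_WIDTH_RANGE)),
        )
        bend = float(rng.uniform(*SICKLED_BEND_RANGE))
    return CellSpec(
        cell_id=cell_id,
        cls=cls,
        center=(0, 0),
        orientation=orientation,
        size=size,
        shape_seed=shape_seed,
        bend=bend,
    )


def _overlap_clusters(
    rng: np.random.Generator, classes: list[str], n_overlap: int
) -> list[list[int]]:
    """Indices grouped into touching clusters (pairs, one triple if odd),
    same-class members paired together wherever possible."""
    n = len(classes)
    members = sorted(rng.choice(n, size=n_overlap, replace=False).tolist(), key=lambda i: (classes[i], i))
    clusters = [members[i : i + 2] for i in range(0, len(members) - 1, 2)]
    if len(members) % 2 == 1:
        if clusters:
            clusters[-1].append(members[-1])
        else:  # n_overlap == 1 cannot occur (bumped to 2 upstream), safety net
            clusters = [[members[-1]]]
    return clusters


def generate_scene(spec: SceneSpec) -> GroundTruth:
    """Place ``spec.n_cells`` cells with the requested class mix and overlap.

    Deterministic for a fixed seed. Exactly ``round(sickled_fraction *
    n_cells)`` cells are sickled. ``round(target_overlap_rate * n_cells)``
    cells (bumped to 2 when rounding yields 1) are placed in touching
    clusters; all other cells keep a >= 2 px clearance from everything.

    Raises
    ------
    PlacementError
        If a cell cannot be placed within 10,000 rejection-sampling
        attempts (frame too small / packing too dense), naming the first
        unplaceable cell.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    shape = spec.frame_shape
    if n == 0:
        return GroundTruth([], [], [], shape)

    n_sickled = _round_half_up(spec.sickled_fraction * n)
    sick_ids = set(rng.permutation(n)[:n_sickled].tolist())
    classes = [SICKLED if i in sick_ids else HEALTHY for i in range(n)]
    cells = [_draw_cell_geometry(rng, i + 1, classes[i]) for i in range(n)]

    n_overlap = _round_half_up(spec.target_overlap_rate * n)
    if n_overlap == 1:
        n_overlap = 2 if n >= 2 else 0
    clusters = _overlap_clusters(rng, classes, n_overlap) if n_overlap else []
    clustered = {i for cl in clusters for i in cl}
    singles = [i for i in range(n) if i not in clustered]

    templates = [_template_for(c) for c in cells]
    touch_templates = [_dilate(t, 1) for t in templates]
    clear_templates = [_dilate(t, 1 + _CLEAR_ITER) for t in templates]

    occupied = np.zeros(shape, dtype=bool)  # all placed cells
    placed_center: dict[int, tuple[int, int]] = {}
    placed_mask: dict[int, np.ndarray] = {}

    def _place(idx: int, center: tuple[int, int]) -> None:
        placed_center[idx] = center
        mask = _full_mask(shape, center, templates[idx])
        placed_mask[idx] = mask
        occupied[mask] = True

    def _random_center(idx: int) -> tuple[int, int]:
        half = templates[idx].shape[0] // 2
        if shape[0] - half <= half or shape[1] - half <= half:
            raise PlacementError(
                f"frame {shape} too small for cell {cells[idx].cell_id}"
            )
        return (
            int(rng.integers(half, shape[0] - half)),
            int(rng.integers(half, shape[1] - half)),
        )

    def _fits(idx: int, center: tuple[int, int]) -> bool:
        return _paste_window(shape, center, templates[idx]) is not None

    # Touching clusters first: anchor clear of everything, partners touching
    # the cluster but clear of every other cell.
    for cluster in clusters:
        anchor = cluster[0]
        for attempt in range(_MAX_ATTEMPTS):
            center = _random_center(anchor)
            if not _intersects(occupied, center, clear_templates[anchor]):
                _place(anchor, center)
                break
        else:
            raise PlacementError(
                f"could not place cell {cells[anchor].cell_id} (cluster anchor) "
                f"within {_MAX_ATTEMPTS} attempts"
            )
        cluster_mask = placed_mask[anchor].copy()
        for partner in cluster[1:]:
            others = occupied & ~cluster_mask
            ra = _contact_radius(cells[anchor])
            rb = _contact_radius(cells[partner])
            for attempt in range(_MAX_ATTEMPTS):
                theta = rng.uniform(0.0, 2 * np.pi)
                # touching to moderately overlapping; near-total engulfment is
                # ambiguous even for manual counting and is not emulated
                f = rng.uniform(0.62, 0.95)
                d = f * (ra + rb)
                cr = placed_center[anchor][0] + int(round(d * math.sin(theta)))
                cc = placed_center[anchor][1] + int(round(d * math.cos(theta)))
                center = (cr, cc)
                if not _fits(partner, center):
                    continue
                if not _intersects(cluster_mask, center, touch_templates[partner]):
                    continue  # must touch/intersect its cluster
                if _intersects(others, center, clear_templates[partner]):
                    continue  # must stay clear of everything else
                cand = _full_mask(shape, center, templates[partner])
                inter = int(np.count_nonzero(cand & cluster_mask))
                # Deformable discs may stack up to ~30% in projection;
                # polymerized crescents are rigid and only graze (~8%).
                # Deeply fused unions are ambiguous even for manual
                # counting and are not emulated.
                rigid = SICKLED in (cells[anchor].cls, cells[partner].cls)
                depth_cap = 0.08 if rigid else 0.3
                if inter > depth_cap * min(cand.sum(), cluster_mask.sum()):
                    continue
                _place(partner, center)
                cluster_mask |= cand
                break
            else:
                raise PlacementError(
                    f"could not attach cell {cells[partner].cell_id} to its "
                    f"overlap cluster within {_MAX_ATTEMPTS} attempts"
                )

    # Isolated cells: clearance from every placed pixel.
    for idx in singles:
        for attempt in range(_MAX_ATTEMPTS):
            center = _random_center(idx)
            if not _intersects(occupied, center, clear_templates[idx]):
                _place(idx, center)
                break
        else:
            raise PlacementError(
                f"could not place cell {cells[idx].cell_id} within "
                f"{_MAX_ATTEMPTS} attempts"
            )

    final_cells = [
        replace(cells[i], center=placed_center[i]) for i in range(n)
    ]
    masks = [placed_mask[i] for i in range(n)]
    flags = [i in clustered for i in range(n)]
    return GroundTruth(final_cells, masks, flags, shape)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_semantic_map(
    gt: GroundTruth, frame_shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Flatten ground-truth masks to a {0,1,2} label map.

    Pixels covered by at least one sickled mask get 2 (sickled precedence);
    otherwise pixels covered by a healthy mask get 1. Touching same-class
    instances therefore merge into a single connected region.
    """
    shape = frame_shape or gt.frame_shape
    out = np.zeros(shape, dtype=np.uint8)
    for cell, mask in zip(gt.cells, gt.instance_masks):
        if cell.cls == HEALTHY:
            out[mask & (out == 0)] = 1
    for cell, mask in zip(gt.cells, gt.instance_masks):
        if cell.cls == SICKLED:
            out[mask] = 2
    return out


def render_brightfield(gt: GroundTruth, spec: SceneSpec) -> np.ndarray:
    """Render an 8-bit brightfield-like frame: dark cells on a bright
    background, a multiplicative illumination ramp, and additive Gaussian
    noise. Deterministic for a fixed ``spec.seed``."""
    h, w = gt.frame_shape
    img = np.full((h, w), _BG_LEVEL, dtype=float)
    coverage = np.zeros((h, w), dtype=np.int16)
    for mask in gt.instance_masks:
        coverage += mask
    img[coverage >= 1] = _CELL_LEVEL
    img[coverage >= 2] = _STACK_LEVEL
    # central pallor of healthy discs (biconcave profile in projection)
    for cell, mask in zip(gt.cells, gt.instance_masks):
        if cell.cls != HEALTHY:
            continue
        rows, cols = np.where(mask)
        sl = (slice(rows.min(), rows.max() + 1), slice(cols.min(), cols.max() + 1))
        local = mask[sl]
        edt = ndi.distance_transform_edt(local)
        pallor = edt > 0.55 * edt.max()
        region = img[sl]
        region[pallor & (coverage[sl] == 1)] = _PALLOR_LEVEL
    if spec.illumination_gradient > 0:
        rr, cc = np.meshgrid(
            np.linspace(-0.5, 0.5, h), np.linspace(-0.5, 0.5, w), indexing="ij"
        )
        img *= 1.0 + spec.illumination_gradient * (rr + cc) / 2.0
    if spec.noise_level > 0:
        noise_rng = np.random.default_rng(spec.seed + 7919)
        img += noise_rng.normal(0.0, spec.noise_level, size=img.shape)
    return np.rint(np.clip(img, 0.0, 1.0) * 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# time sequences
# ---------------------------------------------------------------------------


def simulate_sequence(
    spec: SceneSpec, schedule: SicklingSchedule
) -> list[tuple[float, GroundTruth]]:
    """Simulate a deoxygenation episode: cells convert healthy -> sickled,
    never back, so that the sickled count at frame k is exactly
    ``round(r_target[k] * n_cells)``.

    Cell identities and centers persist across frames; a converting cell
    swaps its crescent mask for an area-matched disc while still healthy.
    Overlap involvement is recomputed per frame from the frame's masks.
    ``schedule.conversion_times`` is filled in place (cell_id -> seconds).
    """
    from .quantify import overlap_flags_from_masks

    n = spec.n_cells
    counts = [_round_half_up(r * n) for r in schedule.r_target]
    m_final = counts[-1]
    final_spec = replace(spec, sickled_fraction=(m_final / n) if n else 0.0)
    base = generate_scene(final_spec)

    conv_rng = np.random.default_rng(spec.seed + 104729)
    convertible = [i for i, c in enumerate(base.cells) if c.cls == SICKLED]
    order = [convertible[j] for j in conv_rng.permutation(len(convertible))]
    conv_rank = {idx: rank for rank, idx in enumerate(order)}

    # healthy-state companion template: area-matched disc at the same center
    healthy_templates: dict[int, np.ndarray] = {}
    healthy_masks: dict[int, np.ndarray] = {}
    for idx in convertible:
        area = int(base.instance_masks[idx].sum())
        radius = max(math.sqrt(area / math.pi), 3.0)
        tmpl = _disc_template(radius, base.cells[idx].shape_seed)
        healthy_templates[idx] = tmpl
        healthy_masks[idx] = _full_mask(spec.frame_shape, base.cells[idx].center, tmpl)

    schedule.conversion_times.clear()
    for idx in convertible:
        ks = [k for k, m in enumerate(counts) if conv_rank[idx] < m]
        if ks:
            schedule.conversion_times[base.cells[idx].cell_id] = float(
                schedule.t_grid[ks[0]]
            )

    frames: list[tuple[float, GroundTruth]] = []
    for k, t in enumerate(schedule.t_grid):
        m = counts[k]
        cells_k: list[CellSpec] = []
        masks_k: list[np.ndarray] = []
        for i, cell in enumerate(base.cells):
            sickled_now = cell.cls == SICKLED and conv_rank[i] < m
            if cell.cls == SICKLED and not sickled_now:
                cells_k.append(replace(cell, cls=HEALTHY))
                masks_k.append(healthy_masks[i])
            else:
                cells_k.append(cell)
                masks_k.append(base.instance_masks[i])
        flags_k = overlap_flags_from_masks(masks_k)
        frames.append((float(t), GroundTruth(cells_k, masks_k, flags_k, spec.frame_shape)))
    return frames


# ---------------------------------------------------------------------------
# perturbation of semantic maps
# ---------------------------------------------------------------------------


def perturb_semantic_map(
    sem: np.ndarray,
    boundary_px: float,
    class_flip_rate: float,
    seed: int,
    field_scale: float = 2.0,
) -> np.ndarray:
    """Degrade an ideal semantic map into a segmenter-like prediction.

    ``boundary_px`` displaces class boundaries by a random field of
    amplitude < boundary_px (in signed-distance units) and correlation
    length ``field_scale`` px (small values imitate the jagged contours of
    learned segmenters), so the perturbed foreground lies strictly between
    the erosion and dilation of the original by ``boundary_px``.
    ``class_flip_rate`` flips whole connected
    regions (not single pixels) between healthy and sickled. Identity when
    both are zero; deterministic for a fixed seed.
    """
    if boundary_px < 0:
        raise ValueError("boundary_px must be >= 0")
    if not 0.0 <= class_flip_rate <= 1.0:
        raise ValueError("class_flip_rate must lie in [0, 1]")
    sem = np.asarray(sem)
    rng = np.random.default_rng(seed)
    out = sem.copy()

    if boundary_px > 0:
        out = np.zeros_like(sem)
        for value in (1, 2):  # healthy first, sickled overwrites (precedence)
            mask = sem == value
            field_arr = ndi.gaussian_filter(rng.standard_normal(sem.shape), field_scale)
            if not mask.any():
                continue
            peak = np.abs(field_arr).max()
            if peak > 0:
                field_arr *= 0.999 / peak
            signed = ndi.distance_transform_edt(mask) - ndi.distance_transform_edt(~mask)
            new_mask = (signed + boundary_px * field_arr) > 0
            out[new_mask] = value

    if class_flip_rate > 0:
        flipped = out.copy()
        for value, other in ((1, 2), (2, 1)):
            lbl, n_reg = ndi.label(out == value, structure=_TOUCH_STRUCT)
            for region in range(1, n_reg + 1):
                if rng.random() < class_flip_rate:
                    flipped[lbl == region] = other
        out = flipped
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_ground_truth(gt: GroundTruth, out_dir: str | Path, stem: str) -> tuple[Path, Path]:
    """Write a 16-bit instance-ID PNG plus a JSON sidecar table.

    At mutually overlapping pixels the higher cell_id wins in the PNG (the
    flat image cannot store two ids); the sidecar keeps exact per-cell
    centroids, areas, classes and overlap flags.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inst = np.zeros(gt.frame_shape, dtype=np.uint16)
    records = []
    for cell, mask, flag in zip(gt.cells, gt.instance_masks, gt.overlap_flags):
        inst[mask] = cell.cell_id
        r, c = ndi.center_of_mass(mask)
        records.append(
            {
                "cell_id": cell.cell_id,
                "class": cell.cls,
                "centroid": [float(r), float(c)],
                "area": int(mask.sum()),
                "overlap_flag": bool(flag),
            }
        )
    png_path = out_dir / f"{stem}_instances.png"
    Image.fromarray(inst).save(png_path)
    json_path = out_dir / f"{stem}_cells.json"
    json_path.write_text(json.dumps(records, indent=1))
    return png_path, json_path


def scene_spec_to_yaml(spec: SceneSpec, path: str | Path) -> None:
    data = {
        "frame_shape": list(spec.frame_shape),
        "n_cells": spec.n_cells,
        "target_overlap_rate": spec.target_overlap_rate,
        "sickled_fraction": spec.sickled_fraction,
        "noise_level": spec.noise_level,
        "illumination_gradient": spec.illumination_gradient,
        "seed": spec.seed,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def scene_spec_from_yaml(path: str | Path) -> SceneSpec:
    data = yaml.safe_load(Path(path).read_text())
    data["frame_shape"] = tuple(data.get("frame_shape", (512, 512)))
    return SceneSpec(**data)
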