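"""Evaluation suite: pixel metrics, instance matching, series error, sweeps.

Pixel agreement is scored on the foreground union of both cell classes,

    DSC = 2|P n G| / (|P| + |G|),    IoU = |P n G| / |P u G|,

instance-level classification uses greedy one-to-one nearest-neighbor
matching of instance centroids with sickled as the positive class, and the
time-series accuracy of the sickled fraction is the mean absolute error
over sampled frames. ``sweep_watershed`` reproduces the hyperparameter
sensitivity analysis: absolute per-class counting error as one watershed
parameter varies, against the no-watershed (connected components only)
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .separation import WatershedParams, refine_mask, separate_instances

__all__ = [
    "PixelMetrics",
    "MatchTally",
    "ClassificationMetrics",
    "SeriesError",
    "pixel_metrics",
    "greedy_match",
    "classification_metrics",
    "mae_series",
    "no_watershed_counts",
    "sweep_watershed",
]


@dataclass(frozen=True)
class PixelMetrics:
    dsc: float
    iou: float
    n_pred: int
    n_gt: int
    n_inter: int
    degenerate: bool = False  # both foregrounds empty


@dataclass
class MatchTally:
    TP: int
    FN: int
    FP: int
    TN: int
    matches: list[tuple[int, int, float]] = field(default_factory=list)
    unmatched_gt: list[int] = field(default_factory=list)
    unmatched_pred: list[int] = field(default_factory=list)


@dataclass(frozen=True)
class ClassificationMetrics:
    sensitivity: float | None
    precision: float | None
    f1: float | None


@dataclass(frozen=True)
class SeriesError:
    mae: float
    per_frame: np.ndarray
    times: np.ndarray
    n_excluded: int = 0


def pixel_metrics(pred: np.ndarray, gt: np.ndarray) -> PixelMetrics:
    """Foreground DSC and IoU between two {0,1,2} semantic maps.

    Foreground is the union of healthy and sickled pixels. When both
    foregrounds are empty the metrics are defined as 1.0 and flagged
    degenerate (rather than crashing batch evaluation).
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    p = pred > 0
    g = gt > 0
    n_p = int(p.sum())
    n_g = int(g.sum())
    n_i = int((p & g).sum())
    if n_p == 0 and n_g == 0:
        return PixelMetrics(1.0, 1.0, 0, 0, 0, degenerate=True)
    dsc = 2.0 * n_i / (n_p + n_g)
    iou = n_i / (n_p + n_g - n_i)
    return PixelMetrics(dsc, iou, n_p, n_g, n_i)


def greedy_match(
    gt_centroids: Sequence[Sequence[float]],
    gt_classes: Sequence[str],
    pred_centroids: Sequence[Sequence[float]],
    pred_classes: Sequence[str],
    max_dist: float = np.inf,
) -> MatchTally:
    """Greedy one-to-one nearest-neighbor matching of instance centroids,
    then TP/FN/FP/TN tallies with sickled as the positive class.

    All gt-pred pairs are visited in order of ascending Euclidean distance
    (ties broken by lower gt index, then lower pred index); a pair is
    accepted iff both ends are still unmatched and the distance is
    <= ``max_dist``. Tally definitions:

    * TP - gt sickled, matched, predicted sickled
    * FN - gt sickled, unmatched or matched to a predicted healthy
    * TN - gt healthy, matched, predicted healthy
    * FP - predicted sickled, unmatched or matched to a gt healthy
    """
    gt_c = np.asarray(gt_centroids, dtype=float).reshape(-1, 2)
    pr_c = np.asarray(pred_centroids, dtype=float).reshape(-1, 2)
    n_gt, n_pr = len(gt_c), len(pr_c)
    if n_gt != len(gt_classes) or n_pr != len(pred_classes):
        raise ValueError("centroid and class lists must have equal lengths")

    gt_match: dict[int, int] = {}
    pred_match: dict[int, int] = {}
    matches: list[tuple[int, int, float]] = []
    if n_gt and n_pr:
        d = np.hypot(
            gt_c[:, 0:1] - pr_c[None, :, 0], gt_c[:, 1:2] - pr_c[None, :, 1]
        )
        order = np.lexsort(
            (np.tile(np.arange(n_pr), n_gt), np.repeat(np.arange(n_gt), n_pr), d.ravel())
        )
        for flat in order:
            i, j = divmod(int(flat), n_pr)
            dist = float(d[i, j])
            if dist > max_dist:
                break
            if i in gt_match or j in pred_match:
                continue
            gt_match[i] = j
            pred_match[j] = i
            matches.append((i, j, dist))

    tp = fn = fp = tn = 0
    for i, cls in enumerate(gt_classes):
        j = gt_match.get(i)
        if cls == "sickled":
            if j is not None and pred_classes[j] == "sickled":
                tp += 1
            else:
                fn += 1
        else:  # healthy ground truth
            if j is not None and pred_classes[j] == "healthy":
                tn += 1
    for j, cls in enumerate(pred_classes):
        if cls != "sickled":
            continue
        i = pred_match.get(j)
        if i is None or gt_classes[i] == "healthy":
            fp += 1

    return MatchTally(
        TP=tp,
        FN=fn,
        FP=fp,
        TN=tn,
        matches=matches,
        unmatched_gt=[i for i in range(n_gt) if i not in gt_match],
        unmatched_pred=[j for j in range(n_pr) if j not in pred_match],
    )


def classification_metrics(t: MatchTally) -> ClassificationMetrics:
    """Sensitivity, precision and F1 for sickled-cell identification;
    a metric whose denominator is zero is returned as None."""
    sens = t.TP / (t.TP + t.FN) if (t.TP + t.FN) > 0 else None
    prec = t.TP / (t.TP + t.FP) if (t.TP + t.FP) > 0 else None
    if sens is not None and prec is not None and (sens + prec) > 0:
        f1 = 2 * sens * prec / (sens + prec)
    else:
        f1 = None
    return ClassificationMetrics(sensitivity=sens, precision=prec, f1=f1)


def mae_series(
    pred_r: Sequence[float | None],
    manual_r: Sequence[float | None],
    t_grid: Sequence[float] | None = None,
) -> SeriesError:
    """Mean absolute error of the sickled fraction over sampled frames.

    Frames where either series is undefined (None/NaN) are excluded
    pairwise and counted in ``n_excluded``. Symmetric in its arguments.
    """
    pred = np.array([np.nan if v is None else float(v) for v in pred_r])
    man = np.array([np.nan if v is None else float(v) for v in manual_r])
    if pred.shape != man.shape:
        raise ValueError("series lengths differ")
    t = (
        np.asarray(t_grid, dtype=float)
        if t_grid is not None
        else np.arange(len(pred), dtype=float)
    )
    valid = ~(np.isnan(pred) | np.isnan(man))
    if not valid.any():
        raise ValueError("no frame has both series defined")
    errs = np.abs(pred[valid] - man[valid])
    return SeriesError(
        mae=float(errs.mean()),
        per_frame=errs,
        times=t[valid],
        n_excluded=int((~valid).sum()),
    )


def no_watershed_counts(sem: np.ndarray, p: WatershedParams) -> tuple[int, int]:
    """Baseline counting without watershed: one instance per connected
    component of each refined class mask."""
    out = []
    struct = p._structure
    for value in (1, 2):
        refined = refine_mask(np.asarray(sem) == value, p.min_area, p.connectivity)
        _, n = ndi.label(refined, structure=struct)
        out.append(n)
    return out[0], out[1]


def _counting_errors(
    sem_maps: Sequence[np.ndarray],
    true_counts: Sequence[tuple[int, int]],
    params: WatershedParams,
) -> tuple[float, float]:
    errs_h, errs_s = [], []
    for sem, (th, ts) in zip(sem_maps, true_counts):
        inst = separate_instances(sem, params)
        classes = inst.classes()
        errs_h.append(abs(classes.count("healthy") - th))
        errs_s.append(abs(classes.count("sickled") - ts))
    return float(np.mean(errs_h)), float(np.mean(errs_s))


def sweep_watershed(
    sem_maps: Sequence[np.ndarray],
    true_counts: Sequence[tuple[int, int]],
    param_name: str,
    grid: Sequence[float],
    base_params: WatershedParams | None = None,
) -> pd.DataFrame:
    """Absolute per-class counting error as one watershed parameter varies.

    ``param_name`` is one of ``sigma``, ``rel_peak_height``,
    ``min_peak_dist``; other parameters stay at ``base_params``. The
    returned table has one row per grid value plus a ``baseline`` row
    giving the error of connected-component counting without watershed.
    Columns: param, value, err_healthy, err_sickled, baseline.
    """
    if base_params is None:
        base_params = WatershedParams()
    if param_name not in ("sigma", "rel_peak_height", "min_peak_dist"):
        raise ValueError(f"unknown sweep parameter {param_name!r}")
    grid = list(grid)
    if not grid:
        raise ValueError("empty parameter grid")
    if len(sem_maps) != len(true_counts):
        raise ValueError("sem_maps and true_counts lengths differ")

    rows = []
    for value in grid:
        params = replace(base_params, **{param_name: value})
        err_h, err_s = _counting_errors(sem_maps, true_counts, params)
        rows.append(
            {
                "param": param_name,
                "value": float(value),
                "err_healthy": err_h,
                "err_sickled": err_s,
                "baseline": False,
            }
        )

    base_h, base_s = [], []
    for sem, (th, ts) in zip(sem_maps, true_counts):
        nh, ns = no_watershed_counts(sem, base_params)
        base_h.append(abs(nh - th))
        base_s.append(abs(ns - ts))
    rows.append(
        {
            "param": param_name,
            "value": np.nan,
            "err_healthy": float(np.mean(base_h)),
            "err_sickled": float(np.mean(base_s)),
            "baseline": True,
        }
    )
    return pd.DataFrame(rows)
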