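"""Evaluation metrics against independent oracles."""

import numpy as np
import pytest

from rbcq.evaluate import (
    classification_metrics,
    greedy_match,
    mae_series,
    no_watershed_counts,
    pixel_metrics,
    sweep_watershed,
)
from rbcq.separation import WatershedParams, separate_instances
from rbcq.synthetic import SceneSpec, generate_scene, render_semantic_map


def greedy_match_bruteforce(gt_c, gt_cls, pr_c, pr_cls, max_dist=np.inf):
    """Independent replay of the greedy rule: rescan all pairs each step,
    take the globally smallest distance among unmatched ends (ties by lower
    gt index, then pred index)."""
    gt_c = [tuple(map(float, p)) for p in gt_c]
    pr_c = [tuple(map(float, p)) for p in pr_c]
    un_gt, un_pr = set(range(len(gt_c))), set(range(len(pr_c)))
    matches = []
    while un_gt and un_pr:
        best = None
        for i in sorted(un_gt):
            for j in sorted(un_pr):
                d = np.hypot(gt_c[i][0] - pr_c[j][0], gt_c[i][1] - pr_c[j][1])
                key = (d, i, j)
                if best is None or key < best:
                    best = key
        d, i, j = best
        if d > max_dist:
            break
        matches.append((i, j, d))
        un_gt.remove(i)
        un_pr.remove(j)
    tp = fn = fp = tn = 0
    matched_gt = {i: j for i, j, _ in matches}
    matched_pr = {j: i for i, j, _ in matches}
    for i, cls in enumerate(gt_cls):
        j = matched_gt.get(i)
        if cls == "sickled":
            if j is not None and pr_cls[j] == "sickled":
                tp += 1
            else:
                fn += 1
        elif j is not None and pr_cls[j] == "healthy":
            tn += 1
    for j, cls in enumerate(pr_cls):
        if cls == "sickled" and (j not in matched_pr or gt_cls[matched_pr[j]] == "healthy"):
            fp += 1
    return matches, (tp, fn, fp, tn)


def _random_instances(rng, n_max=6):
    n = int(rng.integers(0, n_max + 1))
    pts = rng.uniform(0, 20, size=(n, 2))
    cls = rng.choice(["healthy", "sickled"], size=n).tolist()
    return pts, cls


class TestPixelMetrics:
    def test_perfect_agreement(self):
        sem = np.zeros((20, 20), dtype=np.uint8)
        sem[5:10, 5:10] = 1
        pm = pixel_metrics(sem, sem)
        assert pm.dsc == 1.0 and pm.iou == 1.0 and not pm.degenerate

    def test_disjoint_foregrounds(self):
        a = np.zeros((20, 20), dtype=np.uint8)
        b = np.zeros((20, 20), dtype=np.uint8)
        a[:5] = 1
        b[10:] = 2
        pm = pixel_metrics(a, b)
        assert pm.dsc == 0.0 and pm.iou == 0.0

    def test_known_counts(self):
        # |P| = |G| = 100, |P n G| = 50 -> DSC 0.5, IoU 1/3
        p = np.zeros((20, 20), dtype=np.uint8)
        g = np.zeros((20, 20), dtype=np.uint8)
        p.ravel()[:100] = 1
        g.ravel()[50:150] = 2
        pm = pixel_metrics(p, g)
        assert pm.dsc == pytest.approx(0.5)
        assert pm.iou == pytest.approx(1 / 3)

    def test_both_empty_defined_as_one_with_flag(self):
        pm = pixel_metrics(np.zeros((5, 5)), np.zeros((5, 5)))
        assert pm.dsc == 1.0 and pm.iou == 1.0 and pm.degenerate

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            pixel_metrics(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_dsc_iou_identity_and_confusion_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pred = rng.integers(0, 3, (32, 32))
            gt = rng.integers(0, 3, (32, 32))
            pm = pixel_metrics(pred, gt)
            assert pm.dsc == pytest.approx(2 * pm.iou / (1 + pm.iou), abs=1e-12)
            # per-pixel confusion-count oracle
            tp = sum(1 for a, b in zip(pred.ravel(), gt.ravel()) if a > 0 and b > 0)
            fp = sum(1 for a, b in zip(pred.ravel(), gt.ravel()) if a > 0 and b == 0)
            fn = sum(1 for a, b in zip(pred.ravel(), gt.ravel()) if a == 0 and b > 0)
            assert pm.dsc == pytest.approx(2 * tp / (2 * tp + fp + fn), abs=1e-12)
            assert pm.iou == pytest.approx(tp / (tp + fp + fn), abs=1e-12)


class TestGreedyMatch:
    def test_identical_sets_all_matched_at_zero(self):
        pts = [(0.0, 0.0), (5.0, 5.0), (9.0, 1.0)]
        cls = ["sickled", "healthy", "sickled"]
        t = greedy_match(pts, cls, pts, cls)
        assert (t.TP, t.FN, t.FP, t.TN) == (2, 0, 0, 1)
        assert all(d == 0.0 for _, _, d in t.matches)

    def test_unmatched_ground_truth_becomes_fn(self):
        t = greedy_match(
            [(0.0, 0.0), (10.0, 0.0)], ["sickled", "sickled"],
            [(1.0, 0.0)], ["sickled"],
        )
        assert (t.TP, t.FN, t.FP, t.TN) == (1, 1, 0, 0)
        assert t.matches[0][:2] == (0, 0)
        assert t.unmatched_gt == [1]

    def test_healthy_gt_matched_to_sickled_pred_is_fp_not_tn(self):
        t = greedy_match([(0.0, 0.0)], ["healthy"], [(0.0, 0.0)], ["sickled"])
        assert (t.TP, t.FN, t.FP, t.TN) == (0, 0, 1, 0)

    def test_max_dist_cap(self):
        t = greedy_match([(0.0, 0.0)], ["sickled"], [(30.0, 0.0)], ["sickled"], max_dist=5)
        assert t.matches == []
        assert (t.TP, t.FN, t.FP, t.TN) == (0, 1, 1, 0)

    def test_empty_sides(self):
        t = greedy_match([], [], [(1.0, 1.0)], ["sickled"])
        assert (t.TP, t.FN, t.FP, t.TN) == (0, 0, 1, 0)
        t = greedy_match([(1.0, 1.0)], ["sickled"], [], [])
        assert (t.TP, t.FN, t.FP, t.TN) == (0, 1, 0, 0)

    def test_matches_exhaustive_greedy_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            gt_c, gt_cls = _random_instances(rng)
            pr_c, pr_cls = _random_instances(rng)
            t = greedy_match(gt_c, gt_cls, pr_c, pr_cls)
            om, otally = greedy_match_bruteforce(gt_c, gt_cls, pr_c, pr_cls)
            assert [(i, j) for i, j, _ in t.matches] == [(i, j) for i, j, _ in om]
            assert (t.TP, t.FN, t.FP, t.TN) == otally

    def test_tp_fn_conservation(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            gt_c, gt_cls = _random_instances(rng)
            pr_c, pr_cls = _random_instances(rng)
            t = greedy_match(gt_c, gt_cls, pr_c, pr_cls)
            assert t.TP + t.FN == gt_cls.count("sickled")


class TestClassificationMetrics:
    def test_worked_example(self):
        from rbcq.evaluate import MatchTally

        m = classification_metrics(MatchTally(TP=8, FN=2, FP=1, TN=5))
        assert m.sensitivity == pytest.approx(0.8)
        assert m.precision == pytest.approx(8 / 9)
        assert m.f1 == pytest.approx(2 * 0.8 * (8 / 9) / (0.8 + 8 / 9))

    def test_no_sickled_anywhere_all_undefined(self):
        from rbcq.evaluate import MatchTally

        m = classification_metrics(MatchTally(TP=0, FN=0, FP=0, TN=4))
        assert m.sensitivity is None and m.precision is None and m.f1 is None

    def test_perfect_tally(self):
        from rbcq.evaluate import MatchTally

        m = classification_metrics(MatchTally(TP=10, FN=0, FP=0, TN=3))
        assert m.sensitivity == m.precision == m.f1 == 1.0


class TestMaeSeries:
    def test_identical_series_zero(self):
        r = [0.0, 0.1, 0.5, 1.0]
        assert mae_series(r, r).mae == 0.0

    def test_constant_offset(self):
        a = [0.1 * k for k in range(13)][:9]
        b = [v + 0.1 for v in a]
        assert mae_series(a, b).mae == pytest.approx(0.1)

    def test_single_discrepant_frame(self):
        a = [0.0] * 13
        b = [0.0] * 13
        b[4] = 0.13
        assert mae_series(a, b).mae == pytest.approx(0.01)

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(10), rng.random(10)
        assert mae_series(a, b).mae == mae_series(b, a).mae

    def test_undefined_frames_excluded_pairwise(self):
        a = [0.5, None, 0.5]
        b = [0.5, 0.9, None]
        err = mae_series(a, b)
        assert err.mae == 0.0 and err.n_excluded == 2

    def test_no_common_frames_rejected(self):
        with pytest.raises(ValueError):
            mae_series([None, 0.2], [0.1, None])


@pytest.fixture(scope="module")
def scene_maps():
    maps, counts = [], []
    for seed in (1, 2):
        gt = generate_scene(
            SceneSpec(n_cells=40, target_overlap_rate=0.4, seed=seed)
        )
        maps.append(render_semantic_map(gt))
        counts.append((gt.count("healthy"), gt.count("sickled")))
    return maps, counts


class TestSweepWatershed:

    def test_single_value_grid_matches_direct_run(self, scene_maps):
        maps, counts = scene_maps
        df = sweep_watershed(maps, counts, "sigma", [1.5])
        row = df[~df["baseline"]].iloc[0]
        errs_h, errs_s = [], []
        for sem, (th, ts) in zip(maps, counts):
            cls = separate_instances(sem, WatershedParams(sigma=1.5)).classes()
            errs_h.append(abs(cls.count("healthy") - th))
            errs_s.append(abs(cls.count("sickled") - ts))
        assert row["err_healthy"] == pytest.approx(np.mean(errs_h))
        assert row["err_sickled"] == pytest.approx(np.mean(errs_s))

    def test_baseline_row_is_component_counting(self, scene_maps):
        maps, counts = scene_maps
        df = sweep_watershed(maps, counts, "sigma", [1.5])
        base = df[df["baseline"]].iloc[0]
        errs = [
            abs(no_watershed_counts(sem, WatershedParams())[0] - th)
            for sem, (th, _) in zip(maps, counts)
        ]
        assert base["err_healthy"] == pytest.approx(np.mean(errs))

    def test_empty_grid_rejected(self, scene_maps):
        maps, counts = scene_maps
        with pytest.raises(ValueError, match="empty"):
            sweep_watershed(maps, counts, "sigma", [])

    def test_unknown_param_rejected(self, scene_maps):
        maps, counts = scene_maps
        with pytest.raises(ValueError, match="unknown"):
            sweep_watershed(maps, counts, "min_area", [10])
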