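# Methods

## Problem setting

A deoxygenation episode in a microfluidic sickling assay is recorded as a
brightfield time-lapse (typically 4 frames/s over 0–120 s). A semantic
segmenter assigns each pixel one of three classes — background (0), healthy
(1), sickled (2) — but carries no instance identity: same-class cells that
touch or overlap appear as one connected region, so naive
connected-component counting underestimates both class counts and distorts
the sickled fraction r(t) = n_sickled/(n_healthy + n_sickled). This package
post-processes such label maps into instances, counts them, and evaluates
the result.

## Marker-controlled watershed

For each class mask independently:

1. **Refinement.** Connected components with area < `min_area` are removed
   (spurious segmentation specks). Nothing is ever added.
2. **Seed detection.** The Euclidean distance transform of the mask is
   smoothed with a Gaussian of width `sigma`; within each connected region,
   candidate seeds are the local maxima of the smoothed map. A candidate is
   retained only if its height is at least `rel_peak_height` (H) times the
   regional maximum, and retained seeds are thinned greedily (highest peak
   first, ties row-major) so that no two lie closer than `min_peak_dist`.
   Every region keeps at least one seed (its global maximum): a valid
   region must never vanish from the counts at this stage.
3. **Separation.** A watershed floods the negated smoothed distance map
   from the seeds, restricted to the region; fronts meet at the shared
   edges of merged cells. The number of instances equals the number of
   seeds, instances are disjoint, and their union reproduces the refined
   region exactly (pixel conservation — asserted throughout the tests).
4. **Labeling.** Instances get globally unique IDs across classes, with
   per-instance class, area, centroid, parent region, and a `split_flag`
   marking instances whose parent produced more than one seed.

### Parameters and defaults

All lengths are in pixels at the 1000×1000-equivalent working resolution,
where healthy cells have radius ≈ 9–12 px.

| parameter         | default | meaning / rationale |
|-------------------|---------|---------------------|
| `min_area`        | 50      | ~20% of a healthy cell's area; removes specks without touching real cells |
| `sigma`           | 1.5     | suppresses discretization ripple in the distance map; well below the cell radius, so genuine two-cell peaks survive |
| `rel_peak_height` | 0.4     | rejects shallow maxima near region boundaries |
| `min_peak_dist`   | 10      | ≈ 0.8 × cell radius; two genuine cell centers are rarely closer |
| `connectivity`    | 8       | regions and touching are 8-connected, matching the merge behavior of label maps |
| `peak_prominence` | 0.02    | numerical tolerance (see below) |

The defaults sit in the center of the stable regime identified by the
sensitivity sweep on synthetic scenes; all are configurable per run.

`peak_prominence` is not a model parameter but a numerical guard: on a
pixel grid the distance ridge of an elongated cell is flat up to
discretization noise, and a raw `value == neighborhood max` test yields
several near-equal duplicate maxima along it. Candidates are therefore
taken as h-maxima of the smoothed map with a small h (0.02 px of distance
height), which merges sub-tolerance ripples into one candidate while
leaving genuine inter-cell saddles (depth of order 1 px) untouched. The
suppression radius `min_peak_dist` is enforced within each connected
region; seeds of different regions never suppress one another (the
constraint exists to prevent over-segmentation inside one merged region,
and a global rule would conflict with the one-seed-per-region guarantee).

Degenerate settings reproduce the no-watershed baseline exactly: with
H = 1 or `min_peak_dist` → ∞ each region keeps a single seed and the
instance count equals the connected-component count.

### Known limitations

- Only homogeneous (same-class) merges are split; contacts between a
  healthy and a sickled cell are already separated by the class boundary
  of the semantic map, and no attempt is made to re-segment them.
- Distance-transform seeding assumes each cell contributes a local
  thickness maximum. Two thin cells fused side-by-side over most of their
  length produce a single thick blob with one maximum and cannot be split
  by this (or any distance-based) method; such configurations are also
  ambiguous for human counters.
- Greedy centroid matching in the evaluator is order-dependent and does
  not minimize total match distance (a minimum-cost assignment can pair
  differently); it is used because it is the standard, cheap choice for
  detection scoring, and its tie-breaking (distance, then gt index, then
  prediction index) is fully deterministic.

## Frame handling

Sampling modes: all frames; every Nth frame; or "every S seconds", which
takes the frame temporally nearest each t = 0, S, 2S, … up to the duration
inclusive, ties resolved to the earlier frame. Frame 0 is defined to lie at
t = 0, so a 120 s recording sampled every 10 s yields 13 frames.
Preprocessing converts to grayscale, applies CLAHE and then resizes to
1000×1000. CLAHE uses scikit-image's `equalize_adapthist` with its
normalized clip limit (default 0.01, 8×8 tiles); a constant image is passed
through unchanged, and `clahe_clip=None` disables contrast normalization
entirely (useful where idempotent preprocessing is required). Images are
resized with bilinear/area interpolation; label maps are never
interpolated (nearest-neighbor only) so no non-integer class can appear.

Video containers are read through imageio when a decoder plugin is
available; frame directories and multi-page TIFF stacks are read natively
and require an explicit frame rate, since they carry no fps metadata.

## Synthetic scenes

The generator emulates the features of dense brightfield fields that drive
the counting problem, with exact ground truth:

- **Shapes.** Healthy cells are near-circular discs (radius 9–12 px, mild
  low-order radial jitter) with a central pallor in the brightfield render
  (biconcave profile in projection). Sickled cells are bent capsules
  (half-length 11–14 px, half-width 3.2–4.2 px, arc half-angle 0.4–0.7 rad)
  whose width tapers toward the tips; their moment-based aspect ratio is
  ≥ 2.5, so shape-dependent behavior (elongation classification, ridge-like
  distance transforms) is exercised.
- **Overlap by construction.** `round(target_overlap_rate · n_cells)` cells
  are placed in touching clusters (pairs, plus one triple when odd), the
  rest with a ≥ 2 px clearance; the achieved overlap rate therefore equals
  the target up to rounding, and the generator's involvement flags agree
  exactly with brute-force pairwise mask testing. Partners are placed at
  0.62–0.95 × the summed contact radii. Contact depth is class-dependent:
  disc–disc intersections may reach 30% of the smaller cell (deformable
  discocytes stack in projection), while contacts involving a crescent are
  capped at 8% — polymerized sickled cells are rigid and graze rather than
  interpenetrate. Deeply fused unions, which are ambiguous even for manual
  counting, are deliberately not emulated.
- **Rendering.** The semantic map sets a pixel to 2 if any sickled mask
  covers it, else 1 if any healthy mask does (a flat map cannot hold two
  classes per pixel; sickled is the positive class and takes precedence).
  The brightfield render adds a multiplicative illumination ramp and
  additive Gaussian noise, seeded.
- **Time courses.** A sickling schedule prescribes a non-decreasing target
  fraction r*(t) on an ascending grid; cells convert healthy → sickled and
  never back, the sickled count at frame k is exactly round(r*(t_k)·n), and
  identities and centers persist. A converting cell swaps its crescent for
  an area-matched disc while still healthy. Overlap involvement is
  recomputed per frame.
- **Degradation.** `perturb_semantic_map` turns an ideal map into a
  segmenter-like prediction: boundaries are displaced by a random field of
  amplitude < `boundary_px` (in signed-distance units) with a 2 px
  correlation length — imitating the jagged contours of learned segmenters
  — so the result lies strictly between the erosion and dilation of the
  original; class errors flip whole connected regions, never single pixels.

What passing tests on these scenes does **not** show: performance on real
micrographs (texture, debris, focus drift, echinocytes and other
intermediate morphologies), segmenter errors beyond boundary jitter and
whole-region class flips, or cell motion between frames. The generator's
role is to verify the counting and evaluation machinery under controlled,
exactly known conditions, not to certify a trained segmenter.

## Evaluation suite

Pixel agreement is scored on the foreground union of both classes
(DSC and IoU; the algebraic identity DSC = 2·IoU/(1+IoU) is verified in the
tests). When both foregrounds are empty the metrics are defined as 1.0 and
flagged degenerate rather than crashing batch runs. Instance-level
classification uses greedy one-to-one nearest-neighbor centroid matching
(unbounded by default; an optional distance cap is provided) followed by
TP/FN/FP/TN tallies with sickled as the positive class; sensitivity,
precision and F1 with zero denominators are reported as explicit undefined
flags, never NaN. The r(t) series error is the mean absolute difference
over sampled frames, with undefined frames excluded pairwise and counted.

The hyperparameter sweep varies one watershed parameter at a time and
reports the mean absolute per-class counting error next to the
no-watershed (connected-component) baseline. Sweeps are run on
boundary-perturbed maps rather than ideal renders: the over-segmentation
arm of the min-inter-peak-distance trade-off only exists when boundaries
carry segmentation noise, which is the operating condition of a real
pipeline.

## Problem sizes used in the automated checks

Scenes are 512×512 px with 50 cells (100 for time courses) — the same
cell-to-frame scale as the 1000×1000 working resolution at roughly half the
field of view, which keeps every check a desk-scale computation. Frame
sampling uses synthetic 481-frame stacks at 4 fps (120 s). The acceptance
script builds 20-cell fields for the overlap-rate boundary cases.
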