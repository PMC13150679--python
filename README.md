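# rbcq — quantifying red blood cell sickling in dense suspensions

In microfluidic sickling assays, red blood cells from sickle-cell-disease
samples transform from biconcave discocytes into elongated, crescent-shaped
cells as oxygen is withdrawn. The biological readout is the time-resolved
**sickled fraction**

r(t) = n_sickled(t) / (n_healthy(t) + n_sickled(t)),

measured over a 0–120 s deoxygenation window. At physiologically useful
densities, cells touch and overlap, so a semantic segmentation (per-pixel
classes: background 0, healthy 1, sickled 2) merges neighboring same-class
cells into single connected regions and instance counts are biased low.

`rbcq` implements the counting side of such an assay pipeline:

- **frame I/O** — decoding recordings into timestamped frames (all frames,
  every Nth, or the frame nearest each t = 0, S, 2S, …), grayscale + CLAHE
  contrast normalization, resize to the 1000×1000 working resolution, and
  label-map PNGs in the {0,1,2} integer encoding;
- **segmentation seam** — an adapter contract for an external trained
  segmenter, plus a classical fallback (dark-object thresholding + an
  elongation classifier) so the pipeline runs end-to-end without weights;
- **marker-controlled watershed** (the core): each class mask is refined by
  an area filter, seeds are the local maxima of the Gaussian-smoothed
  Euclidean distance transform — kept only if their height is ≥ H × the
  regional maximum and spaced ≥ a minimum inter-peak distance — and the
  watershed floods the negated distance map from those seeds, splitting
  merged regions into instances at their shared edges;
- **quantification** — per-frame class counts, r(t), the overlap rate
  R_overlap(t) = N_overlap(t)/N_total(t) (fraction of cells touching or
  intersecting another cell), and assembled time series;
- **evaluation** — foreground Dice/IoU (DSC = 2|P∩G|/(|P|+|G|),
  IoU = |P∩G|/|P∪G|), greedy one-to-one centroid matching with TP/FN/FP/TN
  tallies (sickled = positive class), sensitivity/precision/F1, MAE of the
  r(t) series, and counting-error sweeps over the watershed
  hyperparameters against a no-watershed baseline;
- **synthetic scenes** — a seeded generator of dense disc/crescent fields
  with exact ground truth (instance masks, classes, overlap involvement,
  sickling schedules), so every stage is testable without microscope data.

## Worked example

Generate a 50-cell scene (40% of cells in touching clusters, half sickled),
then count it from its semantic label map alone:

```bash
rbcq synth --out-dir demo/scene --n-cells 50 --overlap 0.4 --seed 7
# scene: 25 healthy, 25 sickled -> demo/scene

mkdir -p demo/labels && cp demo/scene/frame_000000.png demo/labels/
rbcq count --labels-dir demo/labels --out-dir demo/counts --no-overlays
# counted 1 frames -> demo/counts/counts.csv

cat demo/counts/counts.csv
# frame_index,time_s,n_healthy,n_sickled,r,R_overlap,R_overlap_is_estimate
# 0,0.0,25,25,0.5,0.36,True
```

The watershed recovers exactly 25 healthy and 25 sickled instances from the
merged label map, giving r = 0.5. `R_overlap = 0.36` is the *estimated*
overlap rate (fraction of instances that came out of a split region, hence
flagged as an estimate — true involvement needs ground-truth instances; the
split-based estimate reads slightly below the generator's 0.4 target
because grazing contacts of different-class cells never merge).

The same stages are importable:

```python
from rbcq import SceneSpec, generate_scene, render_semantic_map
from rbcq import separate_instances, count_instances, sickled_fraction

gt = generate_scene(SceneSpec(n_cells=50, target_overlap_rate=0.4, seed=7))
inst = separate_instances(render_semantic_map(gt))
n_h, n_s = count_instances(inst)       # (25, 25)
r = sickled_fraction(n_h, n_s)         # 0.5
```

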