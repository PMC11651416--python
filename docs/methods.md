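# Methods

## Problem and data model

The package targets field images of maize in which each organ of interest is
annotated as a *dotted line*: an ordered list of 2-D points tracing the stalk
axis or a leaf midrib, with a class label (`leaf` or `stalk`). No boxes or
masks exist in the source annotations. Two consequences drive the design:

1. detection boxes must be *derived* — the min/max of an instance's points,
   padded outward by a fixed offset (default 20 px in working coordinates) so
   the organ's width, not just its centerline, is covered, then clipped to the
   image;
2. trajectory points are positionally interchangeable along the path, so a
   keypoint detector need not (and should not) assign identities to them.

Raw frames (6016×4016 in the source imagery) are worked at quarter
resolution (1504×1004); annotation coordinates are divided by the same
factor. The padding offset is applied *after* downsampling — the offset and
the working resolution are quoted together in the source workflow, and
applying it beforehand would quarter its effective size.

## Preprocessing

Hand-placed trajectory points are sparse and unevenly spaced. They are first
densified by piecewise-linear arc-length interpolation (default spacing 5 px;
outputs lie exactly on the original polyline, consecutive points at most one
spacing apart, vertices retained), then subsampled at equal index intervals to
a fixed fraction (default 30%), always retaining both endpoints:
k = max(2, round(0.3·n)). These k points are the ground-truth keypoints and
double as the ground-truth polyline for evaluation. Linear interpolation is
the simplest scheme consistent with on-trajectory points; index-space (rather
than arc-length) subsampling is used because the input is already
arc-length-uniform after densification, making the two equivalent up to
rounding. Datasets are split 7:2:1 (train/val/test) by a seeded shuffle with
largest-remainder apportionment.

## Detector

Two-stage, Faster R-CNN-style, implemented on an in-repo numpy autodiff core
(`pointline.nn`: im2col convolution, bilinear RoIAlign with exact gradients,
fused stable losses, SGD with momentum; gradient correctness is covered by
central-difference tests).

* **Backbone/FPN.** A bottom-up conv trunk with a top-down pathway (1×1
  laterals, nearest-neighbour upsampling, 3×3 smoothing). Profiles:
  `tiny_fpn` (8–32 channels, two pyramid levels at strides 8/16) for
  CPU-scale work, and `mobilenet_fpn` / `resnet50_fpn` / `resnet101_fpn`
  (residual trunks, four levels) carrying the full-scale hyperparameters.
  Only the tiny profile is exercised by the test suite; the larger profiles
  are configuration-complete but impractical to train without accelerators.
* **Anchors.** Full-scale default: five areas (32², 64², 128², 256², 512²)
  at aspect ratios (0.5, 1, 2), distributed across pyramid levels by size.
  The tiny profile uses three areas (24², 48², 96²) with ratios extended to
  (0.25, 0.5, 1, 2, 4): stalk boxes remain tall and narrow even after the
  20 px padding, and ratio 4 anchors are needed for IoU-0.5 positives at
  256 px scale.
* **RPN.** Shared 3×3 conv, per-level 1×1 objectness/regression heads.
  Training samples up to 128 anchors per image (≤64 positives at IoU ≥ 0.6 or
  per-GT argmax; negatives below 0.3); proposal filtering keeps the top
  4000/2000 (pre/post NMS at IoU 0.7) for the full profile, 600/128 for tiny.
  The raised proposal budget reflects scenes with many mutually close targets.
* **Box head.** RoIAlign (14 full-scale, 7 tiny) → 256-unit FC → softmax over
  {background, leaf, stalk} + class-agnostic box regression. Ground-truth
  boxes are appended to the proposals during training; 48 RoIs sampled per
  image (≤16 positives at IoU ≥ 0.5).
* **Keypoint branch.** For each positive RoI (the same RPN proposals the box
  branch consumes), RoIAlign at half the heatmap resolution → two 3×3 convs
  (32 ch) → 2× upsample → 1×1 conv → a *single* logit grid (56×56 full-scale,
  28×28 tiny). The target heatmap places an unnormalized Gaussian (σ = 2
  cells) at every ground-truth keypoint of the matched instance, combined by
  per-cell max, each peak exactly 1 at its (nearest-cell-snapped) location.
  The loss is mean per-cell sigmoid binary cross-entropy, weighted 4× against
  the detection losses so the branch is not drowned out early in training. A
  per-keypoint spatial softmax cannot represent a variable number of peaks in
  one channel; per-cell sigmoid BCE can, which is the point of the
  single-heatmap design.
* **Optimisation.** SGD with momentum 0.9, weight decay 1e-4, StepLR
  (lr·γ^⌊epoch/step⌋). Full-scale defaults: lr 1e-3, γ 0.66, step 10, 200
  epochs, random horizontal flip (coordinates included) and colour jitter.
  The tiny-profile recipe used by the experiments module is lr 0.01, γ 0.66,
  step 4, ≤10 epochs — the same schedule shape at a rate suited to a small
  trunk trained from scratch. The best epoch by validation mAP50 is retained.

## Postprocessing

Inference order matters and is fixed: box-level suppression first, then peak
extraction on surviving detections only.

* **Suppression modes.** `hard` (greedy removal above an IoU threshold),
  `soft` (Gaussian decay s ← s·exp(−o²/σ), σ = 0.5, floor 0.001 — the
  reference Soft-NMS defaults, since the source text specifies the mechanism
  but not the constants), and `soft_diou`, where the decay argument is the
  distance-IoU clamped at 0 (a far-away box with negative D-IoU should decay
  nothing). Suppression is class-wise. Because DIoU ≤ IoU always, D-IoU decay
  is never stronger than IoU decay; the D-IoU penalty ρ²/c² is what separates
  stacked neighbours.
* **Peak extraction.** Strict 8-neighbourhood local maxima above a value
  threshold (default 0.3), greedily thinned to a Chebyshev separation of ≥ 2
  cells, capped at 32 points, ties broken lexicographically by (row, col) for
  determinism. Cell centers map back to image coordinates through the inverse
  of the box-to-grid affine map. The defaults bound the keypoint count well
  above typical annotation density after 30% subsampling; predicted points
  are left unordered because the evaluation metric needs no ordering.

## Evaluation

* **Detection.** Per-class AP with all-point interpolation (monotone precision
  envelope) at box-IoU 0.5 and 0.75, matched greedily in score order,
  one-to-one, class-aware; mAP is the unweighted class mean. Classes absent
  from both ground truth and predictions are excluded from the mean.
* **mLD.** The point-to-segment distance uses the projection parameter
  t = ⟨AP, AB⟩/‖AB‖² with the three-case rule (closest endpoint when the foot
  falls outside the segment, perpendicular foot otherwise); all returned
  distances are Euclidean pixels. LD_k averages over a detection's M
  keypoints the minimum distance to the matched ground-truth polyline's G−1
  segments; mLD averages LD_k over matched pairs. The pairing rule is the
  same greedy score-ordered one-to-one box-IoU matching used for AP (at 0.5),
  class-aware; unmatched detections and ground truths are excluded from mLD
  but reported alongside it, since a distance metric on unpaired targets is
  undefined. Zero-length polyline segments are skipped. mLD is scale-covariant:
  scaling all coordinates by s scales mLD by s.

## Synthetic scenes

Each plant is a 5-point jittered near-vertical stalk polyline plus 2–7 leaves,
each leaf a quadratic Bézier (20 samples) rooted on the stalk, arcing outward
and drooping. Curves are drawn as thick anti-aliased strokes (2× supersampled)
in green-dominant palettes over a plain soil background or procedural clutter
(low-frequency mottling plus distractor blobs). Growth-stage presets emulate
the season: `early` (2 plants, 2–3 leaves), `middle` (3 plants, 3–5 leaves),
`late` (5 plants, 5–7 leaves, tighter spacing) — `late` measurably raises
inter-instance box overlap. All randomness flows from one seed through
per-scene substreams; identical configs give pixel-identical scenes.

What the scenes emulate: the annotation dialect, derived-box geometry, organ
topology (leaves rooted on stalks), class imbalance, inter-instance occlusion,
background clutter. What they do not: photorealistic texture and lighting,
perspective, wind-blown blur, soil/vegetation confusers with leaf-like
geometry. Tests passing on these scenes validate the pipeline's mechanics and
the metric implementations — not field-level accuracy of any trained weights.

## Desk-scale experiment sizes

The standard end-to-end exercise (`pointline.experiments.run_end_to_end`,
also run by `scripts/acceptance.py`) uses 200 scenes at 256×256 alternating
early/middle presets — 160 train / 20 val / 20 test — and 10 epochs of the
tiny profile. These sizes were chosen so the whole exercise, including the
hard-NMS versus D-IoU-Soft-NMS comparison on the same checkpoint, completes
in a few minutes on a single CPU while leaving a wide margin over its
acceptance thresholds (mAP50 ≥ 0.5, mLD ≤ 15 px on held-out scenes).

## Numerical and degenerate-input choices

* Boxes are 0-based, inclusive-corner (x1, y1, x2, y2), area (x2−x1)(y2−y1);
  derived boxes are clipped to the image after padding and rejected if
  degenerate. IoU of a zero-area union is defined as 0; D-IoU of two boxes
  degenerate at the same point is an error (c² = 0).
* A zero-length segment degenerates to its point (case "foot before A"); a
  polyline of identical points degenerates to a single point.
* Subsample rounding uses banker's rounding on an even index grid including
  both endpoints; densify appends exact vertices rather than interpolating at
  t = 1, avoiding floating-point drift on extreme coordinates.
* Heatmap keypoints snap to the nearest grid cell before rendering, so the
  render→extract round trip is exact at grid-cell level for peaks ≥ 3 cells
  apart; off-box keypoints clip to boundary cells.
* All detector arithmetic is float32; evaluation geometry is float64.

## Known limitations

* The full-scale backbone profiles are faithful in configuration (anchor
  areas, proposal budgets, RoIAlign size, schedule) but are this package's
  own conv/residual trunks, not weight-compatible with any pretrained model,
  and are untested at full scale on CPU.
* mLD depends on the detection-to-ground-truth pairing rule; the one-to-one
  IoU-0.5 rule here is a documented choice, and numbers are only comparable
  between runs using the same rule and image scale.
* Soft-NMS retains many low-score duplicates by design; consumers reading
  raw prediction files should threshold scores or rely on ranking metrics.
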