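# Methods

This note documents the models and procedures `avgrade` implements, the
choices made where the design was genuinely open, and what the synthetic
test bed does and does not establish.

## Problem setting

At a retinal arterio-venous crossing where the artery passes over the vein,
arteriolosclerotic hardening compresses the vein and narrows its caliber at
the crossing edges. Scheie-style grading maps that morphology to four
ordered classes — none, mild, moderate, severe. The package's pipeline
mirrors the clinical reading process: find candidate crossings from vessel
maps, keep only true artery-over-vein crossings, then grade the survivors
from image appearance rather than from segmentation geometry (segmentation
is generally too coarse to capture the narrowing itself).

## Synthetic scene generator

Real cohort images with specialist annotations are private, so all tests
run on generated scenes. Each scene plants `n_crossings` pairs of vessel
tubes on an orange fundus-like background:

* **Geometry.** Tubes are parabolic centerlines (random tangent, bow up to
  8 px over a 120 px length) stamped with discs, artery caliber 6 px and
  vein caliber 9 px by default (arteries are thinner than veins in fundus
  images). Crossing angles are at least 45° by default. Crossings are
  placed by rejection sampling with a minimum separation that keeps one
  crossing's tubes from touching another's; an overcrowded specification
  raises an explicit error rather than degrading silently.
* **Z-order.** With probability `z_order_artery_over_prob` (default
  2507/4240 ≈ 0.591, the empirical true-crossing fraction of the kind of
  annotated corpus the pipeline targets) the artery is drawn last: its
  pixels overwrite the vein's in the label map and its color overpaints the
  vein's in the fundus image. Otherwise the vein is drawn over the artery
  and the crossing is invalid (no grade).
* **Grades.** Valid crossings draw a grade from `grade_distribution`
  (default (1177, 816, 457, 57)/2507, an empirical, strongly imbalanced
  distribution). The grade's narrowing factors — none (1, 1), mild
  (0.85, 0.85), moderate (0.6, 1.0), severe (0.6, 0.6) by default — scale
  the vein radius on each side of the crossing over the 5–45 px arclength
  window from the crossing center. No morphometric convention exists for
  how much narrowing "mild" denotes, so these factors are package
  conventions, configurable per scene.
* **Appearance.** Vessels are darker than the background (veins darker
  than arteries) and carry a brighter central light reflex along their
  centerline, as real vessels do; the over-vessel's reflex runs unbroken
  through the crossing, giving classifiers the same continuity cue a human
  reader uses for z-order. Gaussian pixel noise (default σ = 8 on the
  8-bit scale) is added last.
* **Subjects.** `generate_dataset` assigns scenes to synthetic subjects
  round-robin; subject ids exist purely to exercise group-aware splitting.

What the generator does *not* emulate: vessel trees and branching,
illumination gradients and vignetting, pathology other than crossing
phenomena, segmentation-model failure modes (it emits clean masks), and
optic-disc anatomy (the cup mask is a supplied disc, never detected).
Passing tests therefore demonstrate that the machinery is correct and that
the models can learn the planted signal — not clinical performance.

## Preprocessing

Per-pixel artery/vein classifiers are noisier than vessel segmenters, so
A/V labels are refined against the vessel mask: (i) labels outside the mask
are dropped; (ii) the skeleton (topology-preserving thinning,
8-connectivity throughout) is split at branch points (degree ≥ 3), each
remaining skeleton component defines a vessel segment, every vessel pixel
joins its nearest segment, and each segment takes the majority of its
original nonzero labels. Exact ties and unlabeled segments become 0
(unknown) — deliberately conservative, since a fabricated label would
create phantom contacts downstream. The procedure is idempotent and never
alters the vessel mask.

## Crossing detection

1. Contact pixels: artery pixels with a vein pixel among their
   8-neighbours; 8-connected clusters of contact pixels become candidates
   (score = cluster size).
2. Skeleton traversal: within a disc of radius `check_radius_px`
   (default 15) around the candidate, the artery skeleton and the vein
   skeleton must each meet the disc boundary in at least two places —
   i.e. both vessels pass *through* the neighbourhood. This rejects
   T-junctions, where a vessel terminates on the other.
3. Candidates closer than `merge_radius_px` (default 20) merge to their
   score-weighted centroid (total score conserved).
4. Candidates inside the cup mask are discarded.

Defaults are set relative to the 150 px patch and typical vein calibers;
both radii are exposed in configuration. The detector makes no attempt to
decide z-order geometrically — validity is judged from appearance by the
learned classifier, which is the point of the pipeline's second stage.

Patches are 150×150 crops centered on the candidate; the crop spans
`[r − 75, r + 75)` (floor convention for the even size) and reflect-pads at
image borders so the output size is invariant.

## Losses and class weighting

The focal loss −Σ α_l t_l (1−y_l)^γ log y_l is implemented with an ε-floor
(default 1e-7) on probabilities before the logarithm; γ = 0 recovers
weighted cross-entropy exactly (this equivalence, and monotonicity in γ and
in true-class confidence, are asserted by tests). Batch reduction is the
mean, keeping the loss scale independent of batch size. Class weights
α_l = ln N_l / ln N are computed from **training-split** counts only, so no
information from validation or test samples leaks into the training
objective. Weighting is applied in both the cross-entropy and focal
sub-models; the validity task runs unweighted by default (its classes are
nearly balanced), controlled by a flag.

## Sub-models and the fused team

Four compact CNN architectures are registered (`tiny`, `compact-wide`,
`compact-deep`, `compact-smooth`), differing in depth, width, pooling style
and penultimate ("feature") width (64/96/80/72). They run on an in-package
numpy layer toolkit with explicit backward passes and an Adam optimizer —
deterministic on one CPU for a fixed seed, with no accelerator or
pretrained weights required. `tiny` and `compact-wide` flatten their last
feature map before the head (the crossing sits at the patch center, so
spatial layout is informative); the other two use global average pooling.

Training uses Adam at a configured learning rate (default 1e-4; the
experiments below use 1e-3–3e-3, which suits these small from-scratch
networks), evaluates validation accuracy (plus Cohen's kappa for the
4-class task) after every epoch, and restores the best-on-validation
checkpoint.

The team (MDTNet) combines a base module (distinct architectures, CE loss)
with a focal module of `n_focal ∈ {0,1,2,3}` sub-models sharing one
architecture — by default the best-performing base architecture on
validation — trained with γ = 1..n. Fusion concatenates the frozen
penultimate features (width = Σ feature dims) and trains only a two-layer
head (hidden width default 256, ReLU between, softmax on top, best-on-
validation selection). Features are precomputed once, so sub-model
parameters are untouched by construction; tests assert bit-exact equality
anyway. Prediction returns the softmax vector and the argmax label with
lowest-index tie-breaking.

Grad-CAM explanations target the last spatial layer of the designated
sub-model (the first base sub-model for an ensemble, with gradients routed
through the fusion head): channel weights are the spatial means of the
gradients, the weighted activation sum is rectified, normalized to [0, 1]
and bilinearly upsampled to the patch size.

## Augmentation

Eleven operators — vertical/horizontal flip, crop-and-pad, scale,
translate, rotate, shear, Gaussian blur, additive pixel noise, additive
low-frequency field noise, hue/saturation shift — each fire independently
with probability 0.5 during training, in that fixed order. Parameter
ranges (rotation ±30°, scale 0.8–1.2, translation ±10 %, shear ±10°, blur
σ ≤ 1.5, noise σ ≤ 8/255, hue/sat shift ≤ 10 %) are conventions chosen to
keep the crossing in frame, all configuration-exposed. Geometric operators
fill borders by reflection to avoid black corners. Outputs preserve size,
dtype and labels; a fixed seed gives byte-identical outputs.

## Evaluation

Confusion matrices (rows = truth), per-class precision/recall (NaN with a
warning on empty denominators), macro averages, and Cohen's kappa
κ = (p_o − p_e)/(1 − p_e) with the degenerate p_e = 1 case defined as 1 for
perfect agreement and 0 otherwise. Kappa is verified against a brute-force
pair-enumeration oracle over all small 2×2 matrices. Splits are assigned
at the subject level (8:1:1 by largest-remainder rounding of subject
counts, seeded shuffle), because patches from one examinee are correlated;
ratios therefore apply to subjects, not patches. Pipeline evaluation
matches reported crossings to truth greedily one-to-one within 5 px, scores
validity over matched pairs and grading over pairs both sides call valid —
grading quality is thus conditioned on correct detection, mirroring how
such pipelines are assessed.

## Problem sizes in the acceptance script

`scripts/acceptance.py` uses desk-scale study conditions chosen to make
each quantity statistically meaningful while remaining reproducible on one
CPU: 150 detector scenes (450 planted crossings, plus 30 cup-masked scenes
in the test suite), 400 validity patches and 1000 grading patches per seed
(split 8:1:1 by subject, three training seeds for the ensemble), 100
split-hygiene seeds, 1000 random pairs for the loss-equivalence check and
all 1295 non-empty 2×2 matrices for the kappa oracle. The strong-signal
grading conditions use noise-free scenes, balanced grades and narrowing
factors (1, 1)/(0.75, 0.75)/(0.5, 1)/(0.5, 0.5), i.e. a regime where the
grade classes are cleanly separable by construction.

## Known limitations

* The vessel segmenter and A/V pixel classifier that produce the input
  rasters are upstream tools outside this package's scope; the pipeline
  consumes their output (or the generator's stand-ins).
* Detection is a declared convention (contact pixels + skeleton traversal);
  other morphological definitions of "crossing candidate" exist.
* The compact CNNs are sized for CPU-scale experiments. The architecture
  registry and checkpoint format accommodate larger backbones, but none
  ship with the package.
* Synthetic results bound nothing about clinical data; they validate
  machinery and learnability of a planted signal only.
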