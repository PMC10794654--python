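# Methods

`oktopo` grades corneal topographies of orthokeratology (OK) lens wearers.
The pipeline has four stages: (1) semantic segmentation of the pupil and
the treatment zone by a U-Net-family network, (2) geometric indicator
computation from the binary masks, (3) rule-based assignment of one of four
topography classes, and (4) an evaluation harness (held-out metrics and
k-fold cross-validation).  Because clinical Tomey-style tangential exports
are not freely available, a synthetic topography generator with exact
ground truth stands in for training and validation data; this note states
precisely what that substitution does and does not demonstrate.

## Indicators

**Decentration.**  Each region is first denoised to its largest connected
component (8-connectivity; ties broken toward the component whose first
positive pixel comes earliest in row-major order, for determinism).  Its
center is the midpoint of the axis-aligned circumscribed rectangle of the
region — not the centroid — matching the circumscribed-rectangle
convention of the clinical procedure.  Decentration is the Euclidean
distance between the two centers,

    D = sqrt((x1 − x2)^2 + (y1 − y2)^2),

in pixels, divided by the image scale (default 50 px/mm) for millimetres.
Coordinates are x = column, y = row, origin at the top-left pixel.
`px_per_mm` is a parameter rather than a constant so exports from other
topographers can be graded after retraining.

**EDCR.**  The defocus zone is the pupil minus its intersection with the
treatment zone.  A positive pixel is a *four-neighborhood boundary* pixel
iff one of its up/down/left/right neighbours is zero or off-image
(off-image counts as zero, so a region touching the frame still has a
boundary there).  With C the pupil boundary pixel count and ECV the number
of pupil boundary pixels that are simultaneously defocus-zone boundary
pixels, the effective defocusing contact range is EDCR = ECV / C ∈ [0, 1].
Shared boundary membership is the discrete counterpart of the arc of the
pupil circle not covered by the treatment-zone disk; the continuous
counterpart (below) is used as an oracle in the tests.

**Classes.**  With decentration D (mm) and EDCR f:
Class III if D > 1; else Class I if f > 3/4; else Class II if
1/4 ≤ f ≤ 3/4; else Class IV if D ≤ 0.5.  The rules as stated leave
D ∈ (0.5, 1] with f < 1/4 unassigned; such cases are reported as
`UNCLASSIFIED` instead of being silently folded into a neighbouring class,
so the under-specification is surfaced, not hidden.  Endpoints: f = 1/4 and
f = 3/4 both belong to Class II; D = 1 is not Class III.

## Segmentation networks

All three architectures share a four-stage encoder (widths w, 2w, 4w, 8w,
bottleneck 16w; w = `base_width`) and produce two output channels through a
final 1×1 convolution with per-channel sigmoids.  Segmentation is
**multi-label** (two independent binary channels, not a 3-class softmax)
because the pupil physically overlaps the treatment zone.

* **U-Net** — plain long skips; exactly 19 3×3 convolutions, 4 max-pools,
  4 nearest-neighbour upsamplings and one 1×1 output convolution (the
  19th 3×3 convolution sits after the last decoder stage, before the
  head).
* **U-Net++** — nested dense skip pathways; each full-resolution
  intermediate node carries a 1×1 deep-supervision head.
* **U-Net3+** — full-scale skips: decoder D_i fuses branch-convolved
  copies of all shallower encoder stages (max-pooled to scale i) and all
  deeper decoders plus the bottleneck.  Aggregation convolutions run at
  the **source** scale and their output is upsampled, which is cheaper
  than convolving upsampled maps and leaves the skip topology unchanged.
  Branch width equals w; the fused decoder width is 5w.  An optional
  classification-guided gate (global max-pool on the bottleneck → 1×1
  convolution → sigmoid) can multiply the predicted probabilities by a
  per-channel presence score; it is off by default because both regions
  are always present in this data.

Deep-supervision heads (U-Net++ and U-Net3+) are upsampled to full
resolution and averaged into the loss with equal weights; prediction always
uses the full-resolution head.

Three further architectural choices matter at the small training budgets
this package targets:

* **Coordinate channels.**  The normalised pixel coordinates (x, y) are
  appended to the RGB input.  The regions are near-circular and the part
  of the treatment zone occluded by the pupil must be extrapolated from
  its visible arc and ring; coordinate channels make that geometric
  completion expressible by small convolutions.
* **Input standardisation.**  Network inputs are scaled to zero mean and
  roughly unit variance.  With He initialisation this sets a healthy
  activation scale, which directly controls how far a bounded Adam step
  can move the output logits.
* **Batch normalisation is available but off by default**
  (``SegModelConfig.use_bn``).  The published U-Net++/3+ blocks carry BN;
  at the short, small-learning-rate schedules used here it measurably
  slowed convergence (standardised activations cap logit mobility), so
  plain conv+ReLU blocks are the default.

The engine underneath is a compact NumPy CNN library (`oktopo.nn`):
float32 NHWC tensors, stride-1 convolutions via im2col + BLAS GEMM (the
input gradient is computed as a full correlation with the flipped kernel,
so backward is two GEMMs and no scatter), reverse-mode autodiff with an
explicit tape, and Adam.  Every op is validated against central finite
differences in the test suite.  It supports exactly what these networks
need and nothing more.

## Loss and metrics

The loss is mean binary cross-entropy over all pixels of both channels,

    CE = −(1/N) Σ_n [ r_n log p_n + (1 − r_n) log(1 − p_n) ],

with probabilities clamped to [ε, 1−ε], ε = 1e-7.  Useful calibration
points: CE = ln 2 for a uniform 0.5 prediction regardless of the target,
and −ln p for a single positive pixel predicted at p.

Per region, pixel counts TP/FP/FN give precision, recall,
F1 = 2PR/(P+R) and IoU = TP/(TP+FP+FN).  Degenerate denominators follow
the convention that an empty prediction of an empty truth is perfect
(precision = recall = IoU = 1) and otherwise a zero denominator scores 0 —
so degenerate synthetic cases cannot crash cross-validation.  IoU and F1
satisfy the Dice–Jaccard identity IoU = F1/(2−F1), which the tests assert
exactly.

**Training defaults** mirror the clinical configuration: Adam, initial
learning rate 1e-4, batch size 32, inputs resized to 224×224, 100 epochs,
seeded 80/20 train/test split.  The synthetic experiments use the reduced
configuration (base width 8, 64×64 inputs, batch 16, ≤ 40 epochs), which
trains in minutes on one CPU core; these problem sizes are the package's
chosen desk-scale defaults.  Augmentation (seeded rotation ±15°, crop to
≥ 85% area with resize-back, image-only Gaussian noise) is available but
off by default — the synthetic generator already randomises geometry,
colour and noise.

**Sub-grid boundaries.**  Training targets are fractional-coverage
downsamples of the ground-truth masks (values in [0, 1] along region
edges), and at inference the per-channel probability maps are interpolated
bilinearly back to the native image resolution *before* thresholding at
0.5.  Geometry always runs at native resolution because the 50 px/mm scale
is defined on the original export, not on the network grid.  The
alternative — thresholding on the network grid and nearest-neighbour
upsampling the binary mask — caps attainable pupil precision at about
0.978 for the 384→64 resolution ratio even for a perfect network, so
boundary information must survive the round trip in probability space
(ceiling ≈ 0.998).

**K-fold.**  The harness implements standard disjoint k-fold (seeded
shuffle, each fold validates exactly once, a fresh model per fold) and
reports per-fold and mean precision/recall/F1/IoU per region,
micro-averaging pixel counts within a fold.  A `repeated_random` flag
switches to independent random splits of the same size, since the clinical
protocol description admits both readings.

## Synthetic topographies

One case is: a background linear colour gradient (warm palette), an
annular "steepened" ring hugging the treatment zone (hot palette), the
treatment-zone disk (cool palette), and the pupil drawn last — layer order
matters because the pupil overlaps the treatment zone — plus additive
Gaussian pixel noise.  The pupil is rendered as strong attenuation of the
underlying map (8–18% transmission, i.e. a circle of near-black pixels),
in the manner of alpha-blended map-over-photo topographer exports: the
regions remain separable by contrast alone, which is all the stand-in is
meant to require of the networks.  Ground-truth masks are the
exact rasterised disks; the true indicators come from continuous geometry:
decentration is the center distance, and EDCR has the closed form

    EDCR = 1 − arccos((d² + r_p² − r_t²) / (2 d r_p)) / π

when the circles cross (law of cosines on the center distance d), with
containment and tangency resolved by radius comparison.  The true class is
the grading rules applied to these exact indicators.  All randomness flows
from explicit integer seeds; no global RNG state is touched.

**Default study conditions** (chosen on clinical plausibility): 384×384 px
canvas at 50 px/mm (a 7.7 mm field), pupil radius 1.1–2.0 mm (pediatric
mesopic pupils at topography capture), ring width 25–50 px (the 0.5–1 mm
paracentral steepened annulus), noise SD 2–8 intensity levels, centers
jittered up to 0.25 mm around the canvas center; the ring may clip at the
canvas edge, as in clinical exports, while both disks always lie fully
inside.  Dataset sampling cycles the four
classes in equal proportion; within a class, decentration and target EDCR
are drawn uniformly inside the class region with a safety margin from the
decision boundaries (0.10 mm and 0.08 respectively; 0.04 on the EDCR side
of the Class IV/gap band, where the discretisation bias is strictly
downward, away from the 1/4 boundary), and the treatment-zone radius is
solved from the target EDCR by inverting the closed form above.  Cases
from the unassigned gap region can be interleaved with `include_gap=True`.

**Discretisation feasibility.**  The generator's contract is that its
analytic ground truth survives rasterisation: mask-level recovery within
1 px of decentration and 0.05 of EDCR.  Near-tangent or near-concentric
circle pairs provably violate this — boundary pixels sit up to about one
pixel inside the ideal circle, so the covered/uncovered crossing shifts by
an angle that grows as the crossing becomes grazing.  The sampler
therefore rejects draws whose first-order bound on that shift (the
crossing-angle change at effective pupil radius r_p − 1 px) exceeds
0.045, and the rare draws where bounding-box quantisation of the two
rasterised disks moves the discrete center distance more than 0.9 px from
the analytic one.  Both filters use only continuous geometry and the raw
rasterised disks, not the indicator implementation they protect.

**What the generator does not emulate:** Placido-ring texture,
dioptre-faithful colour scales, elliptical or ragged treatment zones,
eyelid occlusion, specular highlights, or inter-device colour variation.
Passing tests on this data therefore demonstrate that the pipeline's
*geometry, learning mechanics and plumbing* are correct and that the
networks can learn high-contrast region segmentation; they do not
demonstrate clinical-grade segmentation of real topographies, which would
require the original labelled exports and full-scale training.

## Numerical choices

* Probabilities are clamped at ε = 1e-7 in the loss; logit clipping at
  ±60 prevents overflow in the sigmoid.
* Threshold 0.5 for mask binarisation; mask PNGs binarise at > 127.
* Equal-area component ties break toward the earliest row-major pixel.
* The concentric d = 0 circle pair resolves EDCR by radius comparison
  (no arccos); the dataset sampler keeps d ≥ 2 px to avoid the unstable
  regime around exact concentricity.
* Checkpoints are NumPy `.npz` archives with the model configuration
  embedded as JSON; loading rebuilds the architecture and restores
  parameters positionally.

## What the desk-scale training can and cannot reach

The reduced protocol (width 8, 64×64 inputs, batch 16, ≤ 40 epochs at
learning rate 1e-4) performs exactly 400 optimiser steps.  Adam's update
magnitude is bounded by the learning rate, so total parameter movement is
bounded by about 0.04 per weight — a structural cap on how much function
can be learned, independent of implementation.  Under the default study
conditions this run reaches mean held-out pupil precision ≈ 0.96,
treatment-zone precision ≈ 0.88 and end-to-end class accuracy ≈ 70%; a
diagnostic run at three times the epoch budget shows all three still
rising (≈ 0.99 / 0.91 / —), i.e. the reduced protocol is
optimisation-budget-limited, not geometry-limited.  The hardest residual
is Class I, where the treatment zone lies almost entirely behind the
pupil and must be completed from its faint attenuated contrast and the
ring.  The clinical-scale configuration (width 64, 224×224, ~2000 steps,
transfer learning) is substantially richer on every one of these axes.
The indicator and classification stages, by contrast, are exact: on
ground-truth masks they recover decentration within 1 px and EDCR within
0.05 with 100% class agreement across seeded 200-case sweeps.

## Known limitations

* Training is CPU-NumPy; it is sized for reduced widths and 64×64 inputs,
  not for the full 64-channel 224×224 clinical configuration.
* Transfer learning from pre-trained weights is not used (the original
  source weights are unspecified); a checkpoint-loading hook exists.
* The grading rules are applied exactly as stated, including their gap;
  cohort-specific conventions for gap cases are unknown.
* Spatial/channel attention variants are deliberately out of scope (they
  reportedly did not improve segmentation), as are axial-elongation
  statistics and topographer export tooling.
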