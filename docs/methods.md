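# Methods

This note documents the models implemented in `sijkit`, the choices made
where the design was genuinely open, and what the synthetic test bed does
and does not establish.

## Open-contour delineation by unit vector fields

A sacroiliac joint (SIJ) is the space between two bones, so it is
annotated as an *open* polyline rather than a closed region. Segmentation
masks handle open curves poorly; instead each slice is mapped to a
regression target from which a contour can be extracted deterministically:

* **Unit vector field (UVF).** At every off-contour pixel the target
  vector is the unit vector toward the nearest annotated vertex. Within a
  band of `on_contour_radius` around the polyline, vectors point *along*
  the contour toward the next vertex (the band beyond the final vertex
  reuses the last segment's direction), preserving directionality.
* **Source/sink heatmaps.** Two isotropic Gaussians (maximum 1) mark the
  contour's start and end points. Their scale is proportional to the
  task region: `sigma = c_a * sqrt(area)` with the area between the two
  joints (the sacrum), or `c_l * length` of the contour when no area is
  available.
* **Extraction.** A walker starts at the source argmax and repeats
  `p <- p + step * v(p)` with unit step, where `v` is the bilinearly
  interpolated, renormalised field; it stops within `stop_radius`
  (default: the sink sigma) of the sink argmax, which is appended as the
  final vertex.

One network predicts all 8 planes per slice (2 field components + 2
heatmaps, for each of the left and right SIJ); slices without a visible
joint carry all-zero targets so the model learns to suppress false
positives, and a source peak below `presence_threshold` (0.3) at
inference declares the contour absent.

### Numerical choices that matter

* **On-contour band keyed to the polyline, width 1.5 px.** Keying the
  band to vertex distance alone deadlocks the walker mid-segment: two
  off-contour points on either side of a vertex pull toward the same
  vertex and a unit-step walker oscillates between them forever. The band
  therefore surrounds the whole polyline, and its width matters twice:
  on the analytic field, band pixels must dominate the bilinear
  interpolation in the walker's corridor (a 0.5 px band with plain Euler
  steps recovers only ~31% of 200 random test polylines; 1.5 px recovers
  ~97%), and on *learned* fields a thin band is simply blurred away by
  the network, leaving a field that points at the contour but not along
  it — the walker then bounces in place. 1.5 px survives both.
* **Midpoint (Heun) step direction.** Each step's direction is the
  renormalised mean of the field at the current point and at a half-step
  ahead; the step magnitude is always exactly `step_length`. This damps
  the overshoot oscillation a discrete walker suffers next to attracting
  vertices. Plain Euler stepping remains available (`midpoint=False`).
* **Minimum walk progress.** The sink test arms only after
  `2 * stop_radius` of walked distance, so an imperfect predicted source
  peak that happens to lie within `stop_radius` of the sink cannot
  truncate the contour to two vertices.
* **Stall detection.** A walk whose net displacement over the last 8
  steps falls below 2 step lengths is bouncing in place and is cut off
  (flagged `stalled`); it can never progress, only pad the contour with
  an oscillation tail.
* **Sigma coefficients 0.1 (both rules) in target construction.** At the
  64 px desk resolution a coefficient of 0.05 yields sigma ~1.7 px, whose
  two-pixel peaks are too sparse to regress stably in a short training
  budget; 0.1 gives sigma ~3 px, about 5% of the image side — the same
  *proportion* a 224 px scan with a typical inter-joint area yields under
  0.05. `suggest_sigma` itself defaults to 0.05; the target builder
  passes 0.1.
* **Quantile convention.** `error_quantiles` uses linear interpolation
  between order statistics.
* **Closest-point RMS direction.** Distances run from ground-truth
  landmarks to the nearest predicted vertex (the prediction is dense, one
  vertex per unit step); a symmetric variant is available.

## The delineation network

A small U-Net style encoder–decoder (configurable depth/width; desk
profile: 64 px inputs, depth 3, width 8, ~134k parameters) regresses the
8 planes. Field planes are linear outputs renormalised to unit vectors at
use time; heatmap planes pass through a logistic.

* **Coordinate channels.** Two normalised x/y coordinate planes are
  concatenated to the input. Which joint is "left" and which "right" is a
  function of absolute position, which translation-equivariant
  convolutions can only sense through border effects; the two joints look
  locally identical (the relationship between a joint and the brighter
  sacrum beside it is mirror-symmetric), so absolute position is the only
  disambiguator.
* **Robust inference.** Three inference-time measures guard the
  short-budget model against its observed failure modes. (1) Predictions
  are averaged over the left/right mirror: the model runs on the image
  and its mirror, the mirrored planes are mapped back (flip x, swap side
  groups, negate the x-component), and the mean is decoded — modes that
  are not mirror-consistent cancel. (2) Decoding is endpoint-symmetric
  and multi-start: a joint counts as present when *either* endpoint
  heatmap clears the presence threshold (a visible joint produces both
  endpoint signals, and a short training run occasionally grows one much
  faster than the other), and walks start from up to three local maxima
  of the source plane with the best contour kept — converged beats
  non-converged, longer arc length beats shorter, because a walk that
  enters the contour corridor midway is necessarily shorter than one
  entering at the true source. (3) Because the side labels are positional
  by definition, the extracted left/right pair is projected onto x-order:
  if the "left" contour lies at larger x than the "right" one, the labels
  are swapped.
* **Deterministic head start.** The output head's weights initialise at
  zero and its heatmap biases at -3, so every seed begins from the same
  output: field planes 0, heatmaps at background level. A randomly scaled
  head start varies the initial loss several-fold across seeds and a bad
  draw can consume most of a short training budget; with the logistic
  starting near background, the budget goes to the peaks rather than to
  suppressing the background.
* **Loss.** Plain L2 on the field planes plus weighted L2 on the heatmap
  planes with per-pixel weight `1 + alpha * target` (alpha 10), which
  counteracts the overwhelming background fraction of heatmap pixels.
* **Optimisation.** Adam, lr 1e-3, beta1 0.9, beta2 0.999; desk batch 16
  (at batch 8 the fixed step budget leaves the walker unstable). Training
  runs a fixed step count or early-stops when a validation loss has not
  improved for `patience` evaluations.
* **Augmentation.** Translation ±20%, scale ±20%, rotation ±15°,
  left/right flips, additive Gaussian noise, Gaussian blur. Geometric
  transforms are applied to landmarks and the targets are *regenerated*
  from the transformed landmarks — warping a unit vector field directly
  would corrupt both norms and directions. A flip swaps the left/right
  channel groups; a side whose landmarks leave the frame is marked
  absent. Intensities are robustly rescaled per slice to [0, 1] by the
  1st/99th percentiles; non-square slices are zero-padded right/bottom
  and bicubically resampled to the square input size.

**Baseline.** The comparison model predicts 21 per-landmark Gaussian
heatmaps per side (42 planes) with the same backbone and budget;
annotations with fewer vertices are up-sampled by linear arclength
interpolation, and landmarks decode as per-plane argmaxes.

## ROI extraction

The upper and lower extreme vertices of each side, aggregated over all
slices, define two lines (upper-left to upper-right, lower-left to
lower-right); the volume is rotated by the negative of their mean angle
so the joints sit level. One static, margin-free bounding box per side is
the floor/ceil-snapped min/max over every slice's vertices (half-open
integer convention, exclusive edge `floor(max) + 1`). The same box cuts
both the T1-weighted and STIR volumes — registration is assumed at
acquisition and only in-plane shape equality is asserted; per-sequence
slice counts may differ and all slices are kept. Left crops are mirrored
to a canonical right-like orientation, recorded in a flag so quadrant
labels can be unflipped downstream.

## Multi-reader lesion classification

Each SIJ yields 14 binary tasks: bone-marrow oedema, fatty lesions and
erosions per quadrant (upper/lower ilium, upper/lower sacrum), plus
sclerosis and ankylosis at joint level — 28 predictions per left/right
pair. A shared encoder processes every slice of both sequence crops;
slice embeddings are pooled (mean by default), the two sequence
embeddings concatenated, and 14 linear heads produce per-task simplices.
The desk encoder is a three-stage CNN whose final 4x4 feature map is
*flattened*, not globally pooled — quadrant-level heads need to know
where in the joint a signal sits. A checkpoint-loading hook substitutes
for pre-trained weights.

### Annotator matrices and the consensus tree

Labels come from R readers x S blinded sessions. A base prediction p is
branched through a tree of rank-1 annotator matrices

    A = a ⊗ b,   B = I + A,   p_node = normalise(clamp(B p_parent)),

with the root modelling the inter-reader consensus, its children the
per-reader consensus, and their children the individual sessions (9 nodes
for R=2, S=3; with S=1 the reader nodes are the root's children). The
loss sums cross-entropy of each node against the label that node stands
for — raw session labels at leaves, intra-reader consensus at reader
nodes (a reader's label where they agree with themselves across all
sessions), inter-reader consensus at the root — plus λ times the summed
traces of all annotator matrices (λ = 1, i.e. unit weight against the
batch-summed cross-entropy). At inference the root prediction is the
estimate compared against inter-consensus ground truth.

Design choices:

* `a` and `b` pass through `0.5 * tanh`, bounding entries to (-0.5, 0.5)
  so B stays near the identity and the trace term is bounded below.
* Initialisation is LoRA-style — `a` small random, `b` zero — giving the
  exact identity annotator at the start while keeping gradients alive:
  `a = b = 0` is a saddle of the bilinear product with zero gradient on
  both factors.
* Each task owns an independent tree; the trace term sums over nodes and
  tasks.
* After `B p` the result is clamped to >= 1e-6 and renormalised, keeping
  every node prediction a valid simplex.

### Evaluation

Per task: AUC as the Mann–Whitney rank statistic with ties averaged;
sensitivity and specificity at an operating threshold (default 0.5) on
the root-node positive probability; balanced accuracy their mean. Only
samples with an inter-consensus label enter the metrics. Cross-validation
splits are per-patient (all scans of a subject share a fold; fold sizes
differ by at most one). Per-lesion summaries pool a lesion's quadrant
tasks into a single score/label set.

## Synthetic test bed

No clinical data ships with the package; generators in `sijkit.synth`
are pure functions of a spec and a seed.

* **Slices/volumes.** Two smoothed random, roughly vertical open
  contours in disjoint lanes (so they cannot intersect) flank a brighter
  inter-contour "sacrum"; contours render as dark intensity ridges with
  blur and noise. Vertex counts span 2–21 with spacing >= 2 px; each side
  is absent with probability 0.1, emulating joints outside the field of
  view. Volumes drift the same contours smoothly across slices with a
  bounded per-slice displacement.
* **Lesion corpus.** Per patient, left/right ROI pairs (6 x 32 x 32 per
  sequence) with latent Bernoulli truths per task (prevalences 0.2–0.35)
  and localised image effects: STIR-bright blob (oedema), T1-bright blob
  (fatty), dark notch on the quadrant's side of the joint margin
  (erosion), dark para-articular band (sclerosis), bright bridge across
  the joint (ankylosis). Blob centres keep a 4 px margin from quadrant
  boundaries so effects do not leak into a neighbour quadrant's
  statistics; a linear model on subregion means recovers every truth
  (checked in the test suite), so the classification benchmark is
  achievable by construction.
* **Readers.** Session labels flip the latent truth i.i.d. per reader,
  session and task at reader-specific rates in [0, 0.5); a correlation
  knob can make a reader's flips persist across sessions.

What passing tests show — and do not. The synthetic images exercise every
geometric and learning code path and make the statistical machinery
falsifiable (noise recovery, consensus coverage, separability), but they
are far easier than clinical MRI: lesion appearance is idealised,
contrast is stable, and anatomy does not vary. Desk-scale results say
nothing quantitative about performance on real scans.

## Problem sizes and profiles

The desk profile used throughout the tests and the acceptance script
trains the delineator on 200 synthetic 64 px slices for 300 Adam steps
with left/right flip augmentation (and the landmark baseline
identically), the classifier on 80 of 100 patients for 400 steps, and fits the reader-noise experiment on 2000
samples — sizes chosen so every experiment runs in minutes on one CPU
core. The full profile (224 px inputs, deeper network) matches the
published setup and is selectable through the same configuration objects.

All trainable components run on a small vectorised reverse-mode autodiff
engine over numpy arrays (`sijkit.nn`) with explicit seeding; runs are
bit-reproducible at a fixed thread count.

## Known limitations

* The walker extracts one open contour per side per slice; closed-contour
  loop search is out of scope.
* T1↔STIR registration is assumed; only shape equality is checked.
* Desk-scale training budgets leave absent-side suppression imperfect
  (false-positive contours on joint-free slices); the budget is sized for
  contour accuracy, not presence calibration.
* Quadrant labels are predicted from the whole-SIJ crop (no quadrant
  cropping), and the left-crop mirror flag is recorded but task identity
  is kept unchanged under mirroring.
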