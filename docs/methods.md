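# Methods

This note documents the models implemented in `lungrpn`, the parameter
choices that matter, what the synthetic phantoms do and do not emulate, and
the numerical conventions used throughout.

## Preprocessing model

CT radiodensity is expressed in Hounsfield units via the standard linear
calibration HU = raw·slope + intercept (water 0, air −1000).  The lung-field
pipeline assumes an axial thorax slice in which the lungs are near-air
regions enclosed by soft tissue:

1. **Binarization** at −400 HU marks air-like pixels.  The threshold is a
   declared default chosen inside the wide gap between lung parenchyma
   (≈ −850 HU) and soft tissue (≈ +40 HU); any value in roughly
   (−700, −300) behaves identically on both phantoms and real lung windows.
2. **Border removal** deletes components connected to the image border
   (exterior air), using 8-connectivity.
3. **Left/right grouping and expansion.**  Interior air components are
   grouped by centroid side, each group is morphologically closed with a
   disk of radius 5 px and replaced by its convex hull.  Expansion exists to
   cover juxtapleural nodules: a nodule attached to or embedded in the lung
   wall punches a soft-tissue hole into the air region, and the convex hull
   restores it.  The hull was chosen over pure dilation because it
   guarantees coverage of any interior concavity regardless of nodule size;
   the cost is a slight over-segmentation near the mediastinum (mask area on
   phantoms is ~1.02× the true lung area; the toolkit asserts ≤ 1.3×).
4. **8-bit windowing** maps (−1200, 600) HU linearly onto [0, 255] with
   clipping and half-up rounding; the window spans lung air to bone with
   soft tissue near mid-grey.
5. **Masking** multiplies the 8-bit image by the binary mask.
6. **Bone removal** blanks pixels above +300 HU together with nearby edge
   pixels (Sobel gradient magnitude, Otsu threshold, restricted to a 2-px
   halo around bone) so bright cortical rims do not survive as spurious
   high-contrast structures.

All steps are flip-equivariant and deterministic; the composite is a pure
function of the input slice.

## Anchor priors

Anchor shapes are fitted to the (width, height) population of ground-truth
boxes, in pixel units, with Euclidean distance (1 − centred-IoU distance is
available as an option).  Fuzzy c-means assigns box j a membership in
cluster i of

    u_ij = [ Σ_k (d_ij / d_kj)^(2/(m−1)) ]^(−1)

and updates centres as u^m-weighted means; both updates are coordinate
descent on the objective Σ_ij u_ij^m d_ij², so the objective trace is
non-increasing (asserted in tests).  Conventions:

- fuzzifier m = 2 (the customary default for box clustering);
- zero distance ⇒ crisp membership at the nearest centre, ties to the
  lowest index;
- initialisation by k-means++ seeding from the given seed; stopping when the
  largest centre displacement falls below 1e−5 or at 300 iterations;
- k-means itself is Lloyd's algorithm (scikit-learn) with 10 restarts, and
  on every instance small enough to enumerate all partitions (n ≤ 8, k ≤ 3)
  it attains the exhaustive optimum in the test suite.

Anchor quality is summarised by `mean_best_iou`: the mean over boxes of the
best centred IoU against any anchor.  This is the toolkit's own
instrumentation for comparing anchor sets (e.g. across K); detection
indicators, not this score, are the end-to-end quantity.

## Proposal geometry

Boxes are 0-based, half-open pixel rectangles.  Anchor grids place every
shape at `((j+0.5)·stride, (i+0.5)·stride)`.  Labelling uses the standard
double rule: IoU ≥ 0.7 against any ground truth ⇒ positive, < 0.3 against
all ⇒ negative, otherwise ignored — plus the argmax rescue (the
best-overlapping anchor of each ground truth is positive regardless), which
guarantees every object recruits a training positive.  Offsets use the
conventional `(Δcx/w_a, Δcy/h_a, log(w_g/w_a), log(h_g/h_a))`
parameterisation; encode/decode is an exact inverse pair.  NMS is greedy by
descending score with ties broken lexicographically on coordinates, making
the survivor set independent of input order.

## Attention blocks

All three blocks gate a C×H×W feature map element-wise with sigmoid factors
and run in inference mode (normalisation uses stored statistics), so each
forward pass is deterministic.  The bottleneck width is max(C/r, 4) with
r = 16 by default.  The nonlinearity is hard-swish, the customary choice in
the coordinate-attention family.  Design choice for CA-II: the directional
average and maximum descriptors are combined by their arithmetic mean
before the shared transform.  Summation was considered, but the mean is the
only affine combiner under which CA-II degenerates exactly to CA-I on
spatially constant inputs (where max = avg) — a property the test suite
relies on and a sensible consistency requirement for a pooling
generalisation.

## Classifiers and the demo trainer

The four backbone families are faithful in kind and reduced in size: the
residual stages are bottleneck blocks with identity shortcuts whose output
is literally `transform(x) + x`; dense stages grow their input channel
count linearly with a fixed growth rate; the mobile family uses
depthwise-separable convolutions (provably fewer parameters than the dense
twin); the mixed family splits channels across 1/3/5 depthwise kernels.
Every model ends in global average pooling and a fully connected layer with
exactly two outputs.  Attention blocks, when requested, are inserted after
every stage.  3-D patches are folded into the channel axis at the stem
(2.5-D); no volumetric convolution is implemented.

The demo trainer is a **linear probe**: the randomly initialised extractor
is frozen and the two-neuron head is fitted by full-batch gradient descent
on the softmax cross-entropy (exact analytic gradient, L2 1e−4, learning
rate 0.5, 40 epochs).  This keeps training deterministic, seconds-fast on
one CPU, and sufficient for the linearly separable patch tasks the toolkit
evaluates; it does not claim to reproduce full fine-tuning.  Divergence
(non-finite loss) raises a structured error carrying the partial trace.

Fusion of two branches is score-level: `union_positive` flags a candidate
positive when either branch exceeds the threshold (0.5, strict), which can
only add positives and therefore never lowers sensitivity; `mean_score`
thresholds the branch average.  Both readings are implemented and
selectable because the fusion step admits either interpretation.

## Metrics

Confusion counts come from greedy score-descending one-to-one IoU matching.
True negatives are meaningful only at candidate level, so the number of
evaluated negative candidates is an explicit argument — the toolkit never
invents a negative universe.  Zero-denominator indicators are reported as
NaN (serialised as null), never as 0.  `f1_from_pr` is the harmonic mean
and is asserted, on 40 published indicator rows, to reproduce the printed
F1 column to ±0.0001; one row (MobileNet, k-means anchors, K = 5) is
internally inconsistent in its source (printed 0.9218 vs 0.9169 recomputed)
and is flagged as such in the fixture — `lungrpn check-tables` reports it
as the single expected failure.

K-fold splitting shuffles deterministically under a seed and produces folds
whose sizes differ by at most one.

## Synthetic phantoms

A phantom slice is a body ellipse of soft tissue (+40 HU) on background air
(−1000 HU), two lung ellipses of lung air (−850 HU), optional rib-like bone
arcs (+700 HU), and inserted nodule disks (−50 HU, diameter ≥ 3 mm, placed
analytically inside a lung).  The default raster is 512×512 at 0.7 mm/px,
matching the slice geometry of public lung-screening volumes; datasets are
written as MetaImage (.mhd/.raw) plus an annotation CSV
(`seriesuid, coordX, coordY, coordZ, diameter_mm`) with the world origin at
the volume corner and axes aligned with array indices.  Additive Gaussian
HU noise is available but off by default so preprocessing tests are exact.

What the phantoms do **not** emulate: vascular and airway texture, partial
volume effects, juxtapleural nodule shapes, scanner noise spectra, or
anatomic variability.  Passing tests therefore demonstrate algorithmic
correctness (geometry, masking, clustering, gating, counting), not clinical
detection performance on real scans.

## The demo pipeline

The end-to-end profile runs 200 slices at 160×160 px and 2.2 mm/px (a
~35 cm field of view), 1–2 nodules of 9–26 mm per slice.  Stages: phantom
synthesis → preprocessing → FCM anchors (K = 5, m = 2) on the ground-truth
box shapes → a stride-4 anchor grid scored by centre–surround contrast
(mean 8-bit intensity inside the box minus the surrounding 1.5× ring; the
contrast peaks when the box matches the bright object's extent, making the
score a scale selector) → recentring of each surviving proposal on its
local intensity centroid (a stand-in for learned offset regression) →
NMS at IoU 0.15 (aggressive, because co-centred multi-scale anchors must
deduplicate without a learned regressor) with 12 proposals per slice →
ResNet- and DenseNet-family patch classifiers (CA-I attention) trained on
ground-truth positives plus hard-negative candidates → union fusion →
candidate-level confusion counting at IoU 0.3 (appropriate for
grid-snapped proposals; never-proposed nodules count as false negatives).

Every stage derives its randomness from one seed; a rerun reproduces the
report exactly.

## Known limitations

- No learned RPN objectness or offset regression; the contrast heuristic
  and recentring stand in for them at demo scale.
- The linear-probe trainer cannot express features beyond the random
  extractor's span; real fine-tuning is out of scope.
- Morphology is 2-D per slice; no volumetric mask continuity.
- The FCM/IoU-distance option lacks a closed-form centre update and reuses
  the weighted mean, so its objective trace is not guaranteed monotone
  (the default Euclidean distance is).
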