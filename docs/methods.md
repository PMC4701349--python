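# Methods

This note records the modeling and numerical decisions behind `lfareader`:
what the synthetic data emulate, which parameters matter, and where the
design was genuinely open.

## The reading model

A test card is photographed roughly fronto-parallel inside a light box, so
the transformation between the stored template and a capture is close to a
similarity but is modeled as a full homography. Registration is ORB
(oriented FAST-9, 256-bit rBRIEF) with mutual-nearest-neighbor Hamming
matching and RANSAC. The capture is warped *into the template frame* before
any analysis: the alternative — analyzing in the capture frame — would make
the geometric segmentation rules ("upper half of the region", window
offsets in pixels) pose-dependent. Defaults: 500 keypoints, 8 pyramid
levels at scale 1.2, RANSAC reprojection threshold 3 px, 2000 iterations,
minimum 10 inliers; all in `RegistrationParams`. Matching ties break toward
the lowest descriptor index so registration is deterministic given the
RANSAC seed.

Segmentation keys on the printed strip labels, not the strips themselves:
they are the only large saturated blobs in the upper half of the strip
region. Per-channel Otsu takes the *darker* class as foreground (labels and
lines are darker than the white membrane; the darker class includes the
threshold value itself, matching `skimage.filters.threshold_otsu`'s
convention that the bright class is strictly above threshold). For panels
without an alcohol strip the R and B dark classes are OR-ed — every label
ink is dark in at least one of them. With an alcohol strip the two
conjunctions (G∧B) and (G∧R) are merged by **union**; the alternative
(intersection) is available via `SegmentationParams.alcohol_combination`,
but union is recall-preserving and never drops a label that either
conjunction found. Closing uses a 3×3 square, one pass; the 10%
column-occupancy filter runs after closing. The relative-area filter
(A_i < 0.5·A_max drops i) computes A_max *after* the position filter so a
large lower-half artifact (e.g. a fully blue alcohol pad) cannot suppress
genuine labels.

The histogram window hangs below each label's bottom-middle point: 0.6×
label width (narrower than the strip, avoiding edge shadows), from 0.2
label heights below the label down another 2.5 label heights. These
multipliers are package choices (`WindowGeometry`); nothing in the assay
specifies them.

## Histogram preprocessing

The lateral histogram averages intensity across the strip width for each
position along the flow axis, on the Rec. 601 luminance by default (the
channel is configurable per deployment; the lines are gray, so any channel
works). Resampling to 100 bins uses a quadratic (order-2) interpolating
spline over normalized position — "quadratic interpolation" admits several
schemes; the spline is exact on globally quadratic inputs and preserves
endpoints, which is what the tests pin down. The illumination baseline is
fitted by RANSAC with a linear model y = a·i + b, inlier band 5% of the
profile's dynamic range, 500 trials, refit on inliers by least squares;
a constant profile short-circuits to (a, b) = (0, c). The linear model is
also exactly what the synthetic generator's illumination ramp produces, so
baseline correction is unbiased on the synthetic suite by construction.

Peak alignment splits the 100-bin profile into bins 1–50 and 50–100 (the
middle bin shared), takes each half's minimum (ties toward the lowest
index) and keeps ±15 bins around each, shifting the 31-bin window inward
when a minimum sits within 15 bins of a segment border. The alcohol path
resamples directly to 62 bins and subtracts the mean of the first 15 bins
(bare membrane that tracks illumination); it applies **no** baseline
correction by default — the leading-bin offset already absorbs the linear
ramp over the short pad window — but `HistogramParams.alcohol_baseline`
can enable it.

## Classifiers

All three classifiers share one chain: per-bin z-score against training
statistics; affine map of the training range onto [−1, 1] (no clipping —
out-of-range inputs extrapolate); an all-tansig MLP; reverse affine map
onto the class-indicator scale; reject threshold. Targets are one-per-class
indicators encoded ±1 for the network, so the reverse map lands on [0, 1]
and the default threshold 0.9 means "the winning tanh output exceeds 0.8".
The threshold value is a package choice, per-class configurable.

Architectures are fixed: 62-5-2 (alcohol), 31-1-2 (control line),
31-7-7-5 (test line). Training is full-batch Adam (lr 0.02, ≤ 4000 epochs)
on squared error, with two additions beyond plain backpropagation:
**class-balanced sample weights** (the alcohol data are ~22% positive, and
unweighted MSE lets the majority class dominate the fit) and a small **L2
weight penalty** (1e-4). Without the penalty the 62-input network, fitted
to saturation on ~240 samples, develops erratic extrapolation and
occasionally rejects or flips the shallowest held-out positives despite a
huge class gap; 1e-4 removes this failure mode without affecting training
accuracy. Early stopping keeps the weights with the best validation
success (loss as tie-break), patience 300. Splits are 70/15/15, stratified
per class, seeded.

The five test-line classes stay internal to the classifier; the pipeline
collapses them to the reported result (light classes → positive, dark
classes → negative) with a configurable policy for "doubtful"
(default: undetermined, i.e. refer to a human). An undetermined control
classification dominates the strip result; an invalid control makes the
strip invalid regardless of the test region.

## Synthetic data: what it emulates and what it does not

The generator renders 640×480 frames: a white card (intensity 245) with
seeded printed texture for registration, one colored label per strip
(palette chosen so every ink is dark in G and in at least one of R/B,
visible to both channel-combination rules), transverse lines whose darkness
∈ [0, 1] scales a 190-level intensity drop, an optional blue pad whose
luminance drop scales with the alcohol level, a linear illumination ramp
along the flow axis (default 0.03 intensity/px), additive Gaussian sensor
noise (default sd 2.0 on the 8-bit scale), and an in-plane pose
(translation up to ~12 px, rotation to ~±10°) applied as a homography.
The card pixel geometry is entirely a generator choice — the vendor
publishes none — with line centers placed so the aligned dips fall near the
middle of each profile half.

Test-line darkness intervals per class are adjacent-overlapping on purpose
(e.g. positive 0.04–0.26, doubtful 0.24–0.50): mean darkness increases
strictly with class order, but neighbors are confusable, reproducing a
test-line classifier that errs only between adjacent classes. The alcohol
and control datasets are well separated (positive pads at level ≥ 0.35
versus ≤ 0.03; valid control dips 40–170 intensity units versus none),
which is the regime in which the binary classifiers are expected to be
perfect. Histogram datasets are emitted at the preprocessed stage each
classifier consumes, generated by building 100-bin residual profiles
(Gaussian dips + noise, sd 1.5) and passing them through the package's own
peak alignment, so dataset and image-derived histograms share one
convention by construction.

What the generator does **not** model: chemistry (migration kinetics,
cutoff concentrations, timing), lens distortion, motion blur, shadows,
non-white cards, multi-row panels, and nonlinear illumination (available
only as an explicit contamination hook for robustness experiments).
Passing tests therefore demonstrate the correctness and internal
consistency of the reading chain under controlled capture conditions, not
field performance on photographed assays.

## Problem sizes and determinism

Dataset sizes mirror the published evaluation protocol: 338 alcohol
histograms (~22% positive), 2358 control histograms (~84% valid), 1955
test-line histograms. The end-to-end suite reads 200 seeded cards
(alternating 4-strip and 3-strip-with-alcohol panels, 10% invalid strips,
unambiguous test-line classes); registration robustness uses 60 rotated
cards and the segmentation census 200 zero-pose cards. Every stochastic
component (generators, RANSAC, weight initialization, splits) takes an
explicit seed, and identical inputs produce byte-identical result JSON.

## Known limitations

* The reader assumes exactly one card per image and a template whose
  printed design matches the captured card (`CardGeometry.design_seed`).
* Strip identities come from panel order (left to right), mirroring how
  batch configuration is known in advance; a shuffled panel is
  undetectable.
* The alcohol strip is binary + undetermined; the five-level color chart
  for quantifying blood alcohol concentration is not modeled.
* Classifiers trained on the synthetic datasets transfer to synthetic
  card images because both come from the same generator conventions; real
  photographs would require retraining on real labeled histograms (the CSV
  format and `lfa train` support this directly).
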