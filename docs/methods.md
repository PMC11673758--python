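# Methods

This note documents the models and procedures groomkit implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Problem setting

Experimental pain studies in rodents use self-grooming — repetitive licking,
scratching or rubbing of the head, vibrissae, limbs or abdomen, and in
particular licking of a chemically injected hind limb — as a behavioral pain
indicator. The recordings are day-long, monochrome, top-view videos at
1 frame/s and 320x240 px, each frame showing two side-by-side cages (left:
experimental animal, right: control). Manual review of such recordings is
the bottleneck; groomkit implements a two-stage screen-then-classify
pipeline plus a statistics layer over the resulting grooming-episode
durations.

## Stage 1: frame-difference screening

For one cage half of width W and height H, the motion index for the frame
pair (t, t+1) is the fraction of super-threshold pixels

    dp(t) = (1 / (W·H)) · #{(i,j) : |I_t(i,j) − I_{t+1}(i,j)| > α},

where α (default **10** gray levels of 255) absorbs sensor noise. A
50%-overlapping moving window (size **w = 10** frames, step **k = 5**)
averages dp into Dp(s); a window is flagged likely-grooming when Dp lies
strictly inside the band (**θmin = 0.009**, **θmax = 0.08**). Below the band
the animal is resting; above it, the motion is whole-body locomotion.
A width-3 median filter applied twice (replicate end-padding) removes
isolated single-window interruptions in either direction, and each maximal
run of S flagged windows becomes a clip of (S−1)·k + w frames; clips
shorter than **10 frames** are dropped.

Numerical conventions, chosen once and used everywhere:

* pixels and frame indices are 0-based; window s covers dp entries
  [s·k, s·k + w);
* the band comparisons are strict on both sides, so Dp exactly equal to a
  threshold is not flagged;
* isolated 5-s flagged windows are excluded rather than interpolated —
  exclusion is deterministic and parameter-free;
* the midline column W/2 splits the frame (left-closed/right-open); rigs
  with an off-center divider can pass an explicit split column.

Windows that straddle a regime boundary average motion from both sides, so
an extracted clip can extend a few frames (at most ~w) past a true episode
boundary; this is inherent to the windowing, not an implementation artifact.

## Stage 2: multistream recurrent ConvNet (MSRC)

Each clip is divided into **Ns = 3** equal segments. Per segment, three
randomly drawn frames (sorted, without replacement when possible) form a
3-channel image — the monochrome frames fill the channels directly — and a
run of **Nf + 1 = 11** consecutive frames starting at a random in-segment
offset yields Nf dense optical-flow fields, stacked separately by x- and
y-component. Segments shorter than Nf + 1 frames behave as if the final
frame were repeated, so padded pairs contribute identically zero flow.
Images are scaled to [0, 1]; flow is clamped to ±20 px and rescaled to
[−1, 1]. The flow estimator is pluggable; the default is the dense
iterative Lucas–Kanade estimator from scikit-image (`ilk`, radius 5), with
TV-L1 available as `tvl1`. All sampling randomness is keyed by
(clip id, epoch, seed), so batches are reproducible and per-epoch
resampling acts as data augmentation.

The network runs three convolutional streams — spatial over the images,
temporal-x and temporal-y over the flow stacks — each feeding a per-stream
LSTM (**64** tanh hidden units) over the Ns segment features. The three
final hidden states are concatenated (length 192), batch-normalized, and
linearly mapped to 2 class scores; the decision is the argmax. The two
temporal streams share an architecture but default to independent weights
(the x- and y-flow statistics differ); a shared-weight mode exists behind a
config flag. "Final hidden state" means h_T, the conventional reading.

The layers (convolution via im2col, LSTM with backpropagation through time,
1-D batch normalization, Adam) are implemented directly on NumPy in the
`groomkit.nn` subpackage, so the package builds, trains and tests anywhere
Python runs — no GPU, no deep-learning runtime, no pretrained-weight
download. Analytic gradients are verified against central finite
differences in the test suite. The `tiny_test_cnn` backbone (three
conv-relu blocks with 2x2 max-pooling twice and a global average pool;
~6k parameters per stream, 32-dim features) is the tested contract.
The `resnet50` backbone id is reserved for externally supplied pretrained
weights and raises a clear error otherwise; the transfer-learning
mechanisms are nevertheless fully implemented and tested generically:

* `init_temporal_from_rgb` adapts pretrained 3-channel first-layer kernels
  to an Nf-channel input by replicating the per-filter channel mean and
  scaling by 3/Nf, preserving expected activation magnitude;
* `finetune_scope="last_block"` freezes every conv block except the last in
  all streams; frozen parameters receive identically zero gradients and the
  optimizer never updates them.

Training uses Adam with learning rate **0.0005**, batch size **25**, at most
**30** epochs, shuffled mini-batches, and early stopping on validation loss
with a patience of 5 epochs (the patience value is this package's choice);
the best epoch's weights are restored. No class re-weighting is applied;
class imbalance is surfaced in the history instead. Default network input
size is 32x32 (the sampler resizes frames), which keeps a 200-clip training
run on one CPU core in the low minutes; larger inputs are a config change,
not a code change.

## Evaluation protocols

Three split schemes, all deterministic under a seed:

* **dataset-dependent** — per-dataset, per-class 4:1 stratified split
  (largest-remainder rounding), pooled and shuffled;
* **dataset-independent** — leave-one-dataset-out, one fold per dataset;
* **group-independent** — leave-one-group-out over a dataset→group map
  (in the pain studies: 3% carrageenan, 1% carrageenan, 5% formalin).

Reports carry confusion counts (positive = grooming) and accuracy,
sensitivity, specificity, precision; undefined ratios are NaN with a
warning. Multi-fold summaries are macro-averaged (mean of per-fold
metrics), with pooled micro counts also emitted.

## Statistics layer

Episode durations (seconds = frames at 1 fps) are analysed per
(dataset, side, condition) cell. Episodes longer than **100 s** are excluded
first. Pre-drug cells pool two recording days, so histogram counts carry a
per-observation weight of **0.5**; the KDE is unweighted because a
normalized density is invariant to a uniform weight. The PDF is a Gaussian
KDE with fixed bandwidth **3 s** (in data units), normalized over the whole
real line, evaluated on the 1..100 s grid, without boundary correction.

The dual-duration response metric reads the PDF ordinates at **16 s**
(short, ordinary grooming) and **40 s** (long grooming, consistent with
sustained licking of an injected limb); pain shifts mass from the short to
the long mode. Distribution comparisons use the two-sided two-sample
Kolmogorov–Smirnov test (asymptotic p by default, exact behind a flag);
totals use the Wilcoxon signed-rank test with zero-difference pairs dropped
and p = 1 returned when all pairs tie. (y16, y40) points are clustered with
K-means (10 seeded restarts, best inertia), reported with the mean
silhouette coefficient and a 2-SD covariance ellipse per cluster.

## Synthetic generator

The generator emulates exactly the statistical structure the two stages
consume, with all randomness flowing from one spec-level seed through named
generators (fixed seed ⇒ bit-identical frames):

* two-cage geometry: even-width frames split at the midline, default
  320x240 at 1 fps;
* a rat-shaped blob per cage: a filled ellipse (semi-axes ≈ 0.31·W/2 and
  0.15·H) carrying a fixed high-contrast texture on a static speckled
  background, plus additive per-frame Gaussian sensor noise (default
  σ = 2 gray levels, below α);
* three motion regimes per side on a user-given schedule (gaps default to
  motionless): **motionless** (sensor noise only), **grooming**
  (a textured head patch of radius ≈ 0.095·W/2 oscillates with 1–3 px
  amplitude, changing ≈2% of the cage half per frame pair — strictly inside
  the stage-1 band at default geometry), **drastic** (the whole blob
  ping-pongs ≥10 px/frame, changing ≈15% — above the band).

Because the moving part's *area* controls the changed-pixel fraction, the
generator gives exact knowledge of where each regime sits relative to the
stage-1 thresholds, which is what the ground-truth-recovery tests rely on.
Episode-duration fixtures come from a truncated-positive Gaussian mixture
sampler; modes near 16 s and 40 s reproduce the short/long structure the
response metric targets (a zero-SD component is a legal degenerate spike).

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: rat appearance and posture, occlusion and
rearing, illumination drift, the day/night activity rhythm, cage-cleaning
gaps between sessions, and ambiguous motion whose changed-pixel fraction
sits near the thresholds. Tests against the generator validate the
*mechanics* of the pipeline (definitions, algebra, recovery under known
conditions, reproducibility), not field performance on animal video.

## Problem sizes used by the tests and acceptance script

Chosen to exercise every code path at desk scale: stage-1 oracle checks on
8x8 frames (1000 pairs); ground-truth recovery on a 2-hour (7200-frame)
two-cage recording; classifier training on 200 balanced 20-frame clips
rendered at 64x64 (32x32 network inputs), which reaches validation accuracy
1.0 on the separable synthetic classes; statistics checks on samples of
30–600 durations. The mixed-regime retention scenario allocates 22.2% of
frames to grooming and measures the retained fraction stage 1 reports.

## Known limitations

* No bundled pretrained backbone: matching the accuracy reported for
  ImageNet-initialised ResNet-50 on real rat video requires supplying such
  weights; the tiny backbone is a correctness and plumbing contract, not a
  performance claim.
* Video containers are read through imageio's plugin mechanism and depend
  on an available ffmpeg/pyav backend; the PNG frame-directory dialect is
  the tested path.
* The stage-1 screen is threshold-based; animals whose grooming produces a
  changed-pixel fraction outside (θmin, θmax) — e.g. very small or very
  large animals relative to the frame — need re-tuned thresholds.
* Whole-frame (unsplit) processing is intentionally unsupported; analysis
  is always per cage side.
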