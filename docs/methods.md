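# Methods

## Problem

Surgical gesture recognition is temporal action segmentation: every frame of
an operative recording is assigned one of four suturing gesture classes —
*entering* (inserting the needle with the needle driver), *gripping*
(gripping the needle with tweezers), *passing* (passing the needle back to
the tissue), and *other* (non-suturing activity).  The toolkit covers the
full multimodal pipeline: cleaning 6-DoF tool-pose and 3-D hand-pose
streams, temporal segmentation with MS-TCN++, fusing modalities by feature
concatenation and by logit averaging, segmental evaluation, and
leave-one-user-out (LOUO) cross-validation with paired significance
testing.  Because no public dataset with this structure exists, a synthetic
operating-room simulator generates multi-surgeon datasets with the same
statistical skeleton, and the whole pipeline is validated end to end on it.

## Pose cleaning

**Symmetry-flip disambiguation.**  Tool-pose estimators of rotationally
symmetric instruments may return, at any frame, the pose composed with a
symmetry element (for these tools a 180° rotation about the tool's y-axis;
the simultaneous 180° flips about x and z produce the same global rotation,
so the default ambiguity group is {I, Ry(180°)}, configurable).  The
corrector walks the track in frame order and right-multiplies each detected
rotation by the symmetry element minimizing the geodesic angle to the
previously corrected frame.  This greedy rule is linear-time; on tracks
whose true motion between frames is smaller than the π gap between symmetry
elements it recovers the underlying track exactly up to one global symmetry
element (property-tested on 100 corrupted tracks, and checked against a
brute-force minimum-path search over all 2^T assignments at T = 8).

**Gap imputation.**  Missing tool detections are filled by
last-observation-carried-forward for gaps of at most `max_gap_frames`
(default 10 frames, i.e. 1/3 s at 30 FPS); hand-joint gaps are filled by
linear interpolation under the same bound, requiring observations on both
sides.  Leading/trailing gaps and longer gaps stay missing; imputed frames
are flagged so the feature layer can expose a validity bit.

**Smoothing.**  Savitzky–Golay filtering (window 9, order 2 by default — a
mild setting that preserves gesture-scale dynamics at 30 FPS) is applied
per coordinate within each contiguous observed span; spans shorter than the
window pass through.  Quaternions are made hemisphere-continuous (sign
flip when the dot product with the previous frame is negative), filtered
componentwise, and renormalized — avoiding Euler-angle singularities.  The
filter is exact on polynomials up to the fit order, which the tests assert
to 1e-9.

**Augmentation** (training-time): whole-video 180° flips about y and about
x-and-z (each with probability 0.5), additive Gaussian noise on positions
(σ = 0.01 track units) and random-axis rotation perturbations of the same
magnitude in radians; hand joints get one whole-video rotation about the
vertical axis with angle uniform in [0, 2π).  All augmentations are rigid
per video, so inter-frame relative motion is preserved.

**Feature layout.**  Tools: per tool (sorted by id) 3 position + 4
quaternion + 1 validity flag; two tools give D = 16.  Hands: 2 × 21 × 3 =
126 coordinates + 2 validity flags, D = 128.  Invalid frames are zero-filled
with flag 0.  Rotation is encoded as a unit quaternion; no input
normalization is applied by default (the model comparison below showed the
pipeline performs better without it).

## Temporal model

MS-TCN++: a prediction-generation stage of L dual-dilated residual layers
(layer l applies two kernel-3 convolutions with dilations 2^l and
2^(L−1−l), concatenates, fuses 1×1, ReLU, dropout, residual), followed by
S−1 refinement stages that consume the previous stage's softmax through L
single-dilation residual layers.  Each stage has a 1×1 output head; the
final stage is the prediction.  An optional per-feature 1-D batch
normalization can precede the input projection (`input_batchnorm`, default
off).

The loss sums over stages the frame-mean cross-entropy plus
λ · truncated MSE, where the truncated MSE averages
min(τ, |log p_t,c − log p_{t−1,c}|)² over frames t ≥ 1 and classes, with
the previous frame's log-probability treated as a constant for gradients.
Defaults λ = 0.15, τ = 4 — the standard constants for this loss family.
The truncation matters: it penalizes frame-to-frame probability jitter
(over-segmentation) without letting genuine gesture boundaries dominate.
Because of the deliberate detachment, the backward pass is not the
derivative of the loss *value*; the gradient checks therefore validate the
cross-entropy path against central finite differences in float64 and the
detachment semantics separately.

The network, its reverse-mode gradients, and Adam are implemented
self-contained on numpy (sequences stored channel-major so convolutions are
BLAS products), which keeps the package dependency-light and fully
CPU-trainable.  Training uses Adam (default moments), one full video per
optimization step, early stopping on validation frame accuracy with
configurable patience, and is bit-reproducible given the config seed.
Long videos are subsampled to every 2nd frame (`stride=2`); metrics are
computed at the native stride by default, with an upsampling helper
(`upsample_predictions`, frame repetition) when source-grid metrics are
needed.

## Fusion

The *straightforward* route concatenates per-frame features of the chosen
modalities and trains one model.  The *ensemble* route averages the final
stage logits of the single-modality models plus the concatenated model —
logits rather than softmax probabilities, because confident models produce
larger-norm logits and should dominate the average.  Argmax ties break
toward the lowest class index.  Since averaging can reintroduce temporal
jitter, predictions are then smoothed: every interior run shorter than
`min_run` (default 3 frames at 30 FPS) is absorbed into the longer adjacent
run (ties to the left), iterated to a fixed point; runs touching either
sequence end are exempt because they lack a two-sided neighborhood.

Logit-norm binning quantifies the confidence–accuracy relationship: frames
are sorted by logit norm and split into equal-size quantile bins (remainder
to the lowest bins); per bin the mean norm, accuracy and count are
reported, and a paired variant reports per-bin accuracy deltas between two
runs on the reference run's bins.

## Metrics and statistics

Frame accuracy; frame-wise macro-F1 over classes present in ground truth or
prediction (absent classes excluded, zero-division inside an occurring
class counts 0); segmental edit score 100·(1 − Levenshtein(pred segments,
gt segments)/max(#segments)), floored at 0; and overlap F1 at IoU
thresholds 0.10/0.25/0.50 with greedy temporal-order matching of predicted
to unmatched same-class ground-truth segments.  Greedy matching is the
field-standard definition; on realistic (boundary-jittered) segmentations
it coincides with the exhaustive-optimal assignment, which the tests verify
at toy scale.  'other' is a regular class in all metrics.

Paired comparisons use the Wilcoxon signed-rank test (zeros dropped,
midranks, exact null for n ≤ 20 without ties, tie-corrected normal
approximation otherwise), one-sided where the hypothesis is directional
("A is better than B"), two-sided for difference hypotheses.  The paired
unit is one value per (video, fold-with-that-video-in-test).  Fold
aggregation reports mean ± sample (n−1) standard deviation; a flag switches
to population std.

## LOUO cross-validation

Folds are all ordered (validation surgeon, test surgeon) pairs — n·(n−1)
folds for n surgeons, 20 for five — with remaining surgeons training.  This
avoids validating on a surgeon seen in training, which matters because
surgeons have individual style.  Hyper-parameters are fixed per (model,
modality combination) across folds.  Per fold the harness trains one model
per single modality plus one on the concatenation, evaluates both fusion
routes, and persists per-(video, fold) values for the paired tests.

## Synthetic data

The simulator emulates the printed statistical structure of a 13-video,
5-surgeon open-surgery suturing dataset:

- **Labels**: repeated cycles entering → gripping → passing; after each
  cycle an 'other' segment with probability 0.3 (reproducing ≈ 259 'other'
  per ≈ 850 cycles).  Segment durations are negative-binomial with means
  138/41/66/259 frames (dispersion 10, minimum 1 frame); means are the
  dataset's reported values, the distribution family and dispersion are
  simulator choices since only means are published.
- **Tools** (needle driver, tweezers): class-templated smooth position
  paths (phase-parameterized within segments) and rotation paths (class
  target rotation vectors, box-smoothed over 15 frames so template geodesic
  steps stay small), plus per-frame symmetry flips (rate 0.02), detection
  dropout (5% in geometric-length gaps, mean 4 frames), and noise.
- **Hands**: a canonical 21-joint hand whose wrist follows the
  corresponding tool and whose shape (finger curl and pitch) depends on the
  gesture class; within a class the shape is rigid.
- **Video features**: fixed per-class prototype embeddings (norm 2,
  dimension 64 — desk-scale rather than a production embedding width) plus
  surgeon style offset plus noise.
- **Noise model**: all measurement noise is temporally correlated (white
  noise box-filtered over 9 frames, rescaled to the target per-frame
  variance).  This mimics slowly drifting estimator errors and is the
  harder, more realistic case: i.i.d. frame noise is trivially averaged
  away by a temporal model.  Hands get a shared wrist-level drift plus
  smaller per-joint jitter.  One `snr` knob divides every modality's noise
  scale.  Noises are drawn independently per modality, so models trained on
  different modalities make complementary errors — the regime where logit
  ensembling pays off (per-frame error indicators across modalities
  correlate below 0.2).
- **Surgeon style**: additive offsets in trajectory and embedding space
  (σ = 0.3), shared across a surgeon's videos — this is what makes LOUO
  genuinely harder than random splits.

What the simulator does *not* model: camera-angle and lighting variation
beyond style offsets, biomechanically valid hand kinematics, realistic
video content (features are prototype-plus-noise, not embeddings of real
frames), and duration distributions beyond the published means.  Passing
the end-to-end tests therefore demonstrates that the pipeline recovers
structure it is designed for under controlled conditions; it is not
evidence about any specific real dataset.

## End-to-end study conditions

The recovery study uses 5 surgeons × 3 videos of ~9 cycles (~2,900 frames)
each, stride-2 subsampling, and a small MS-TCN++ (L = 5, S = 2, width 32,
dropout 0.5, lr 3·10⁻³) — problem sizes chosen so the full 20-fold LOUO
matrix trains comfortably on one CPU core.  Training applies the pipeline's
noise augmentation to pose feature entries (σ = 0.5 track units per step on
tool positions/quaternions and hand joints; validity flags and video
embeddings untouched).  This augmentation is load-bearing for LOUO
generalization: on clean high-SNR data the pose branches otherwise memorize
surgeon-specific absolute positions and fail on the held-out surgeon, while
the video branch — whose class prototypes are shared across surgeons — is
unaffected.  Noise on the video embeddings was found to only corrupt that
reliable branch and is not applied, consistent with the method's
augmentation of the pose modalities only.

At high SNR (snr = 8) the concatenated three-modality model is trained to
convergence (≤ 30 epochs, patience 8) and reaches ≥ 90% test frame accuracy
on every fold.  At low SNR (snr = 1) four models per fold (three singles +
concatenation) are trained at a fixed 8-epoch budget across 5 dataset
seeds; the smoothed logit ensemble's mean test accuracy over the 20 folds
consistently exceeds the best single modality.  The learning rate and
augmentation strength sit above the production-scale ranges because the
desk-scale model and dataset are far smaller; both were fixed once from the
high-SNR convergence study.

## Hyper-parameter presets

`suturesegkit.presets` ships per-modality-combination production-scale
configurations (hidden width 128; L, S and learning rate per combination as
selected on real multi-surgeon footage from the L ∈ {3,5,8,12},
S ∈ {2,3,5}, lr ∈ {1e-3,1e-4,1e-5} grid), the desk-scale configuration the
synthetic study uses, and a `grid_search` helper that redoes the selection
on any dataset by validation frame accuracy (also reachable as
`suturesegkit crossval --grid`).  Hyper-parameters are held fixed across
folds for a given model and modality combination.

## Numerical notes and edge cases

- Quaternions are scalar-first (qw, qx, qy, qz), right-handed; readers
  renormalize within 1e-3 of unit norm and reject beyond.
- Frame indexing is 0-based; all intervals (segments, events mapped to
  frames) are half-open; event rasterization assigns frame f to the event
  covering time f/fps.
- Geodesic angles computed via arccos have a precision floor around 3·10⁻⁸
  rad; exact-recovery tests assert 10⁻⁶.
- Degenerate inputs: empty training sets, all-zero Wilcoxon differences,
  n_bins > T, overlapping events, non-contiguous segmentations and
  mismatched lengths all raise `ValidationError` with a named message.
- Training aborts with a diagnostic on non-finite loss rather than
  continuing silently.
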