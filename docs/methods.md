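# Methods

## Problem and approach

`safefall` implements a vision-derived fall-prediction pipeline for
continuous monitoring of older adults. The input is not video but the output
of a pose-extraction step: per frame, the image-space coordinates of three
anatomical key points — nose (N), left shoulder (LSh) and left hip (LH) — in
a frame whose origin is the outer left corner of the image with the y-axis
pointing down toward the floor, sampled at roughly 18 Hz. From these, three
kinds of per-frame kinematic quantities are derived:

* the angle of each keypoint-to-origin line with the x-axis,
  `A_i = arctan(y_i / x_i)` (radians);
* its finite-difference rate between consecutive frames,
  `dw_i = ΔA_i / Δt_i` (rad/s);
* the nose-to-hip height ratio `R = N_y / LH_y`, which is below 1 while the
  nose is above the hip and crosses 1 exactly when the head reaches hip
  height.

The discriminative logic: a falling body rotates its trunk far faster than
any deliberate movement (`dw_N` spikes), drags shoulder and hip lines along
with it (`dw_LSh`, `dw_LH` rise together with `dw_N`, which deliberate
bending does not do), and carries the head below hip height (`R` crosses 1),
which neither bending nor a recovered stumble does. Three classifier
variants consume fixed subsets of `{N_x, N_y, dw_N, dw_LSh, dw_LH, R}`:
4p (N_x, N_y, dw_N, R), 5p (N_x, N_y, dw_N, dw_LSh, dw_LH) and
6p (all six).

## Data preparation

Frames are filtered per trial before feature computation: the retained
stream is everything strictly before the first frame flagged `excluded`.
The flag covers both unreadable poses and the post-impact annotation; in
both cases later frames are discarded, because a fall that has reached the
floor is over and a gap in the stream would corrupt the finite-difference
rates. This is deliberately conservative: a transiently unreadable frame in
mid-trial truncates the trial rather than splicing across the gap.

Timestamps are authoritative for `Δt`; the nominal rate (default 18 Hz) is
used only when constructing synthetic data. The first frame of each trial
takes `dw_i = 0` by convention so feature rows stay aligned with frames.

Class balance is restored by down-sampling only: whole contiguous tail
blocks of majority-class trials are removed (seeded choice of trial per
round) until the two row counts agree to within one window length. Rows are
never synthesized, no trial acquires an internal gap, and trials ending in
minority-class rows are never touched.

The stream is then cut, per trial, into non-overlapping windows of 18
consecutive frames (~1 s); a trailing remainder is dropped. A window is
labeled *fall* if any of its frames carries a fall label — the system's
purpose is alarming, so the rule favors recall; a majority-vote rule is
available via `label_rule="majority"`. Splitting is positional by default
(no shuffling): the first 69% of windows form train+validation (the last
20% of that block is validation) and the remainder is the test set, with
round-half-up sizing. An absolute pack count (`train_count`) can replace
the fraction, so either a fraction-based or an absolute accounting of the
same corpus is reproducible. A seeded shuffled split is available but off
by default.

## Classifier

Each variant uses the same architecture: LSTM(100, return sequences) →
LSTM(100) → dropout(0.3) → dense(1, sigmoid), on an (18 × m) window input.
The implementation is NumPy throughout: standard four-gate cells (logistic
gates; the candidate and cell-output nonlinearity defaults to relu and can
be set to tanh), Glorot-uniform input kernels, orthogonal recurrent
kernels, unit forget-gate bias, full backpropagation through time, and Adam
(lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-7) on the mean natural-log binary cross
entropy. Batches of 64 are taken in temporal order by default
(`shuffle_batches` enables a seeded permutation per epoch). Inverted
dropout is applied to the final hidden state at train time only. Gradients
are clipped at global norm 5.0 — a numerical safeguard, since relu cells
can diverge early in training. Scores ≥ 0.5 (configurable) predict *fall*.

Trainable parameters follow the closed form `4·(H·(m+H+1))` for the first
layer, `4·(H·(2H+1))` for the second, plus `H+1` for the output unit
(H = 100). With a fixed seed on one platform, initialization, dropout and
batch order — hence the trained weights — are bit-reproducible.

## Evaluation

Fall is the positive class. Precision, recall, F1 (harmonic mean) and
accuracy are reported as percentages from the confusion counts. A metric
whose denominator vanishes is reported as *undefined* and flagged, never
coerced to 0. The reported cross entropy is the base-2 (bits) sum of the
information the predicted class distribution assigns to the truth; it is a
reporting quantity, distinct from the natural-log loss used in training.

## Synthetic data generator

The generator exists so the whole pipeline is testable without video. It
emulates a lateral-camera recording campaign: trials of seven scenarios
(stand, walk, sit, intentional bend, recovered near-fall, forward fall,
sideward fall) in a seeded interleaved order, so a temporal split sees
every scenario on both sides. Defaults: 18 Hz, 48 trials per scenario
(roughly the per-activity trial count of a 17-subject, 3-repetition
campaign), per-coordinate Gaussian jitter of 0.004 image units standing in
for pose-estimation error, and ~1.5 ms timestamp jitter.

The body is a two-rod chain — hip→shoulder (0.30 units) → nose (0.15
units), held collinear — pivoting about the hip with smooth raised-cosine
lean profiles; falls additionally translate and drop the hip and rotate to
~105°, past horizontal, so `R` crosses 1 before impact. Frames after
impact are flagged `excluded` (about 0.4 s of lying still). Fall trials
carry their fall activity code on every frame, as activity-labeled
recordings do; their standing lead-in is kept to 6–9 frames so the single
window a fall trial yields always contains the fall motion itself.

Two design choices deserve emphasis:

* **Rate knobs are defined on the observable.** `fall_peak_angular_rate`
  (default 1.5 rad/s) and `adl_max_angular_rate` (default 0.5 rad/s) refer
  to the *nose-to-origin line* rate — the quantity the features measure —
  not the trunk's rotation rate. Each trial's motion duration is calibrated
  numerically (fine-grid evaluation of the analytic profile, exploiting the
  1/T scaling of rates under time reparametrization) so the noiseless peak
  lands on the configured value, with fall durations clamped to 0.5–1.5 s.
  The class separation is therefore a single directly meaningful knob.
* **All leans orient away from the image origin.** `arctan(y/x)` is
  singular at x = 0; a nose trajectory toward the origin conflates
  closeness-to-origin with angular speed and cannot match a configured peak
  rate within a realistic fall duration. The simulator keeps subjects on
  trajectories leaning in +x.

What the generator does *not* emulate: biomechanical realism (masses,
forces, joint articulation — the rods are rigid and collinear), temporal
correlation in pose-estimation error, occlusions or tracking dropouts,
multi-person scenes, and the full 5-fall/6-ADL activity taxonomy. Passing
tests therefore demonstrate that the pipeline recovers the kinematic
contrasts it encodes — not performance on real video-derived streams.

## Study-scale defaults and runtimes

The end-to-end experiment used by the test suite and by
`scripts/acceptance.py` runs 48 trials × 7 scenarios, balances and windows
to roughly 180 windows (about half fall), and trains each variant for 15
epochs — enough for the well-separated synthetic classes; the reference
50-epoch setting remains the `ModelConfig` default. One full
simulate→train→evaluate pass over all three variants takes a few seconds on
one CPU core; the five-seed averaged experiment takes about half a minute.

## Known limitations

* The angle features are anisotropic in the image frame (origin-relative),
  so performance depends on where the subject stands; the simulator's
  +x-lean convention sidesteps rather than solves this.
* Relu cell activations can saturate dead under aggressive inputs; gradient
  clipping plus the bounded feature scales keep training stable in the
  shipped conditions, and tanh is available as a fallback.
* The truncate-at-first-exclusion filter discards everything after a single
  unreadable frame; producers with gappy pose tracks should pre-segment
  trials.
* Window labels inherit activity-level tags; with trial-level tagging a
  window overlapping only the pre-fall lead-in of a fall recording would be
  labeled fall. The generator bounds lead-ins so such windows always
  contain fall motion, but real activity-tagged data may not.
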