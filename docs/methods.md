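# Methods

## Problem and estimation targets

The package estimates five per-frame gait kinetics from smartphone-video
joint centers: knee adduction moment (KAM) and knee flexion moment (KFM),
both normalized by body weight × height and expressed in percent, and the
three ground-reaction-force components (mediolateral, vertical,
anterior-posterior) in units of body weight.  Inputs are windows of ΔT = 50
frames at 100 Hz.  The video observation is 11 joint centers seen by two
cameras (sagittal and frontal), 2 image axes each — 44 channels per frame,
height-normalized and re-centered per frame at the mid-point of the two hip
projections so the representation is independent of where the subject is in
the image.  The privileged modalities available only to the teacher are 8
body-worn IMUs × 3-axis acceleration and angular velocity (24 + 24
channels).

## Augmented joint kinematics

Velocity and acceleration modalities are derived from positions by backward
finite differences with fixed edge rules: `v[0] = 0`;
`a[0] = a[1] = a[T-1] = 0`.  No smoothing or low-pass filtering is applied
before differencing.  By default derivatives are raw first differences
(position units per frame); a `scale_by_rate` flag multiplies by the
sampling rate.  The default is unscaled because every modality is
batch-normalized before encoding, which absorbs any fixed channel scale.
Differencing is done per whole trial before windowing, so window-interior
frames carry real derivatives and only a trial's own edge frames are
zeroed.

Backward differences are the unique choice consistent with zeroing only the
initial velocity sample.  The trailing acceleration sample is zeroed as
well; that rule is applied verbatim even though backward differencing would
define it.

## Student and teacher networks

Both networks are built from the same blocks, implemented on the package's
own reverse-mode autodiff engine (numpy arrays, float64; see
"Numerical choices" below):

* **Batch normalization** per modality over batch × time, running statistics
  (momentum 0.1) applied at evaluation; zero-variance channels are clamped
  at 1e-5 with a warning.
* **Bi-LSTM encoder**: two stacked bidirectional LSTM layers with dropout
  after each; output width C per modality (default 64; each direction gets
  C/2 hidden units; forget-gate bias initialized to 1).
* **Attention-GCN branch** (student only): each frame's 44 video channels
  are reshaped to 11 joint nodes × 4 view-coordinates; a per-node linear
  score with softmax over the node axis yields attention weights (sum to 1
  per frame) that scale the node features; one graph convolution
  `ReLU(A V W + b)` over the skeleton adjacency follows, then a linear map
  back to width C per modality.  The adjacency is the 11-joint skeleton
  tree with self-loops, row-normalized (a raw binary option exists).  Each
  modality has its own attention/GCN parameters by default; a flag shares
  them.
* **Gated fusion**: `gate = σ(FC([x_bilstm, x_gcn]))`,
  `fused = gate ⊙ x_bilstm + (1-gate) ⊙ x_gcn` — an elementwise convex
  combination, so equal branches pass through unchanged.
* **Multi-fusion module (MFM)**: a composite of four shape-preserving
  fusion submodules on the fused [B, ΔT, 3C] features, any subset
  selectable for ablations, combined as a residual: the input plus the
  average of the selected submodule outputs.  The submodules are this
  package's own designs: only their roster and joint contract (names,
  shape-invariance, ablation grid) are externally specified, not their
  internals, so each is constructed here from what its name denotes:
  - **LWF** (learnable weighted fusion): one softmax-normalized scalar
    weight per modality block, rescaled by the block count;
  - **WFF** (weighted feature fusion): per-channel sigmoid gate
    `σ(FC(x)) ⊙ x`;
  - **MHAF** (multi-head attention fusion): scaled dot-product attention
    across the three modality blocks (4 heads by default);
  - **TMF** (temporal multi-modal fusion): each frame fused with the
    window-averaged context through a two-layer ReLU map.
* **Heads**: the student head is one hidden ReLU layer then a linear map to
  the 5 outputs per frame; the teacher head is a single linear layer.

The student consumes (velocity, acceleration, position) in that fixed
concatenation order; the teacher consumes (acceleration, angular velocity,
position).  The full ablation grid (8 student variants, 4 teacher variants)
is exposed through `build_variant`; early-fusion variants concatenate raw
modalities before a single encoder, GCN-only variants omit the Bi-LSTM
branch, and the "add" variant sums the two encoder streams.

Widths not fixed by the published architecture are configuration defaults:
C = 64, dropout 0.2, GCN node-feature width M′ = 16, projection width 128,
head hidden width 64.  The full-width student has ≈ 0.5 M parameters, well
under the ~4.6 M of the full-scale architecture, which is deliberate for
desk-scale training.

## Two-step knowledge transfer

Step 1 (feature alignment): with a trained teacher frozen in eval mode, the
student encoder and a linear projection of its fused features are trained
to minimize the RMSE to a linear projection of the teacher's concatenated
encoder features.  The teacher-side projection is **fixed at its random
initialization**.  This is a deliberate deviation from training both
projections: if both are free, the alignment loss has a trivial minimum in
which both projections shrink toward zero and the best-validation
checkpoint is the most collapsed one (observed directly at desk scale).
With projection width ≥ encoder width the frozen random projection is
injective, so matching it pins the student features to a linear image of
the teacher's.

Step 2 (head fine-tuning): the pre-trained encoder is frozen — weights and
batch-norm statistics — and only the MFM and head train on the RMSE to
ground-truth kinetics.  Freeze contracts are enforced as parameter-hash
equalities in the tests.

The knowledge-distillation baseline instead trains the whole student on
`L_student + α·L_KD`, where `L_KD` is the RMSE between student and teacher
predictions ("vanilla") optionally plus the RMSE between projected encoder
features ("vanilla+layer loss"); `α = 0` reduces exactly to plain training.
The α sweep grid defaults to {0.1, 0.3, 0.5, 0.7, 0.9} for both variants.

## Training loop

Adam (lr 0.001), RMSE loss, batch size 64, up to 40 epochs with early
stopping at patience 10, retaining the weights with the smallest validation
loss — these defaults mirror the published training protocol.  Validation
is one held-out training subject by default (prevents window-level
leakage); a random-fraction policy is available.  All randomness (data
generation, weight init, dropout, batching) flows from explicit seeds, so
identical configurations reproduce identical histories bit for bit.

## Synthetic gait generator

The simulator emulates the structure of a 17-subject treadmill dataset so
the pipeline is testable without external data:

* **Kinematics**: each joint-axis channel is a truncated Fourier series
  (3 harmonics, amplitudes ∝ 1/h²) around a standing skeleton, with
  leg-dominant amplitude scales, a per-trial gait frequency drawn from
  0.8–1.2 Hz, and subject-level jitter (sd 10%) of every coefficient.
  Each channel's fundamental is detuned by a relative sd of 2%, emulating
  step-to-step variability.  The detuning also makes the 90 kinematic
  features of the forward model linearly independent over a sufficiently
  long trial; with one exactly shared frequency they would span a
  ~7-dimensional function space and the forward coefficients would be
  unidentifiable by any estimator.  Derivatives are analytic, so true
  velocity/acceleration are exact.
* **Cameras**: camera 1 projects the sagittal plane, camera 2 the frontal
  plane; projections are divided by subject height, perturbed by i.i.d.
  Gaussian noise (sd 0.005 normalized units ≈ 0.9 cm), then re-centered at
  the mid-hip point per frame.
* **IMUs**: 8 sensors at trunk, pelvis, hips, knees and ankles report the
  true acceleration of their site plus gravity, and a synthetic periodic
  segment angular velocity, each with low noise (sd 0.02).
* **Kinetics**: a per-subject linear map — positions and velocities of all
  joints plus a term proportional to the true IMU-site accelerations —
  with small output noise (sd 0.02).  The acceleration term is the
  privileged signal: the IMUs observe it essentially directly, while the
  cameras can only approach it by double-differencing noisy positions,
  which at these noise levels is correlation-destroying.  Coefficient
  scales (0.5 / 0.3 / 0.05 for position / velocity / acceleration blocks)
  are chosen so each term contributes order-one variation to the targets
  for typical simulated gait.

What the generator does **not** model: soft-tissue artifact, pose-tracker
failure modes (occlusion, identity switches), non-periodic events, real
inverse-dynamics nonlinearity, and foot-strike impact transients.  Passing
tests on this generator demonstrate that the pipeline's mechanics (shapes,
training, transfer, evaluation protocol) are correct and that the expected
orderings emerge when the forward model is as designed — not that the
published accuracy numbers transfer to real gait data.

## Evaluation protocol

NRMSE = 100 · RMSE / (max − min of the test subject's ground-truth series
per component); PCC is the Pearson correlation over the subject's
concatenated frames.  Leave-one-subject-out: one fold per subject, a
validation subject drawn from the fold's training subjects.  Per-component
values are averaged across subjects; the overall metric is the unweighted
mean of the five component means (this convention exactly reproduces the
published overall values from the published per-component tables, to the
printed precision).  Model comparison is a paired t-test on per-subject
overall metrics with Bonferroni correction — a deliberate surrogate for
repeated-measures ANOVA with post-hoc tests in commercial software, and
labelled as such.  Exact ties give p = 1; a constant nonzero difference
(zero variance) is treated as maximally significant.

## Numerical choices

* Everything runs in float64 on the package's own tape-based autodiff
  engine; gradients are verified against central differences in the tests.
* RMSE loss carries a 1e-24 guard inside the square root so its gradient
  is finite at a perfect fit.
* Batch-norm variance is clamped at 1e-5; the first training batch
  initializes the running statistics directly (no zero-mean prior).
* NRMSE and PCC raise on degenerate inputs (zero range, constant series)
  instead of returning infinities.
* Overlapping-window predictions are averaged per frame before metrics.
* Where two encoder streams are combined, ties in the gate are impossible
  by construction (sigmoid is strictly inside (0,1)).

## Desk-scale experiment profiles

The verification experiments are scaled down so the whole pipeline runs on
one CPU core:

* **Noiseless sanity**: 5 subjects × 4 × 6 s trials with every stochastic
  perturbation (measurement noise, subject jitter, frequency detuning) at
  zero, C = 32, dropout 0, lr 0.003, 150 epochs.  A trained teacher
  reaches < 2% mean NRMSE on a held-out subject.  Detuning is excluded
  here because per-subject frequency patterns are themselves a
  generalization burden: a network can exploit the training subjects'
  quasi-periodic structure, and the held-out subject's different detune
  pattern then dominates the error even though the underlying map is
  exactly linear.
* **Knowledge-transfer benefit**: 10 subjects × 2 × 3 s trials at default
  noise, C = 32, 15 epochs per training stage, batch size 16, lr 0.005,
  5 seeds.  The expected ordering is teacher ≤ student+KT ≤
  student-without-KT on seed-averaged mean NRMSE, with KT beating no-KT in
  most seeds.
* The smoke profiles use a higher learning rate and smaller batches than
  the full-scale defaults because the desk-scale datasets provide only a
  handful of Adam updates per epoch; the full-scale defaults remain the
  published protocol.

## Known limitations

* The MFM submodules follow the documented contract but are this package's
  own constructions; ablation numbers for individual submodules are not
  comparable to previously reported submodule ablations.
* The simulator's linear forward model makes the task easier than real
  inverse dynamics; absolute NRMSE values on synthetic data are not
  comparable to published values on real data.
* The paired-t surrogate is anti-conservative relative to a full
  repeated-measures ANOVA when comparing many models at once; the
  Bonferroni factor must be supplied by the caller.
* Training is single-threaded numpy; full-scale widths (C = 64, 17
  subjects, 40 epochs) are feasible but slow on one core.
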