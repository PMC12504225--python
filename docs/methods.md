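# Methods

## Problem and model

Joint moments — net torques about the lower-limb joint axes, normalized by
body mass (N·m/kg) — are the standard surrogate for joint loading in gait
analysis. Computing them classically requires inverse dynamics over marker
trajectories and ground-reaction forces, confining measurements to
instrumented laboratories. This package implements a two-stage,
self-supervised route that estimates moments from joint *angles* alone:

1. **Masked-reconstruction pre-training.** A transformer auto-encoder is
   trained on unlabeled multichannel joint-angle windows. Each window of
   W time steps over C channels is cut into W/patch_length patches; each
   patch is affinely embedded into d_model dimensions. A fixed fraction of
   patches (default 10%) is replaced by a learnable mask token — before
   sinusoidal positional encoding is added, so the encoder knows *where* a
   masked patch sits but nothing about its content — and the model minimizes
   the MSE between its reconstruction and the original values at the masked
   positions. The encoder is a stack of post-norm self-attention blocks
   (reference configuration: 8 blocks, 12 heads, d_model 24, 2048
   feed-forward units, ReLU, dropout 0.1, layer-norm eps 1e-5).
2. **Layer-frozen supervised fine-tuning.** For each joint (knee, ankle,
   hip), the left/right flexion-extension angle pair (2 channels) is mapped
   to the corresponding moment pair. The first 75% of encoder blocks stay
   frozen; a fresh 2-channel input projection and the regression head train
   together with the last blocks, with Adam, a reduce-on-plateau schedule
   (factor 0.5, patience 10), and early stopping on validation loss
   (patience 20, minimum delta 1e-6 (N·m/kg)²).

A from-scratch baseline with the identical architecture, trained
supervised with the pre-training optimizer settings (Adam + cosine
annealing), quantifies what pre-training adds.

Reference training settings: Adam lr 1e-4 (pre-training, 2000 epochs,
cosine annealing) and 1e-6 (fine-tuning, 500 epochs), batch size 64,
weight decay 1e-5. These remain the documented defaults of
`PretrainSpec`/`FinetuneSpec`; every desk-scale run documented below
overrides epochs and learning rate, since 1e-6 moves nothing in tens of
epochs.

Because no deep-learning framework is part of the runtime stack, the
model, Adam, the schedules and backpropagation are implemented on a small
reverse-mode autodiff engine over numpy arrays (`gait_ssl._nn`). Every
op's backward pass is verified against central differences in the test
suite; training is deterministic given the seed.

## Synthetic gait generator

The generator emulates the structure of a pediatric treadmill cohort: 55
(configurable) subjects in five age strata — allocated by largest-remainder
proportional assignment to the (11, 10, 15, 11, 8)/55 stratum weights, so a
55-subject cohort reproduces the composition exactly — each walking at
three speeds (slow/comfortable/fast), every gait cycle time-normalized to a
0–100% grid.

**Angles.** Each of the 18 kinematic channels is a truncated Fourier series
(K = 4 harmonics) with hand-set means and amplitudes giving realistic
ranges (knee flexion peak-to-peak ≈ 60°, hip ≈ 40°, ankle ≈ 20°, pelvis and
trunk a few degrees). Right-side channels are the left waveform shifted by
half a cycle. Subjects perturb amplitudes multiplicatively
(lognormal-clipped, sd 0.25) and phases additively (sd 0.45 rad) per
channel; walking speed scales amplitudes by 0.85/1.00/1.15. Gaussian
measurement noise (default 0.5°; the desk benchmark uses 3.0°, a realistic
magnitude for residual soft-tissue and marker artifact) is added to the
*observed* angles only.

**Moments.** Ground-truth moments come from a known forward model applied
to the clean (noise-free) kinematics — labels derive from the true motion
while inputs carry measurement noise, as with marker-based capture:

    moment_j = clip( a_j·θ_j + b_j·Δθ_j + Σ_{k≠j} c_jk·θ_k , ±s_j ) + ε

with stiffness gains a_j inversely proportional to each angle's template
spread (0.030 knee, 0.080 ankle, 0.048 hip (N·m/kg)/°) so all six moments
have comparable ≈0.7 N·m/kg scale; damping b_j = 0.10 (N·m/kg)/(°/sample)
(real moments depend on angular velocity, which rewards models with
temporal context); cross-joint coupling |c_jk| = 0.0025 with alternating
sign, an order of magnitude below the diagonal so the model is diagonally
dominant; saturation s_j = 1.6 N·m/kg; moment noise σ = 0.02 N·m/kg. A pure
linear variant (b = c = 0, no clipping, no noise) supports parameter
recovery tests. All randomness flows from one dataset seed through named
substreams, making regeneration bit-identical.

**What the generator does not emulate:** pathological gait, non-sagittal
moment components, event-detection artifacts, true inverse-dynamics
nonlinearities (segment inertia, GRF transients), or correlations between
anthropometrics and waveform shape. Passing the benchmark therefore shows
the *pipeline* behaves as designed under known ground truth — not that the
accuracy figures transfer to real cohorts.

## Preprocessing

Fixed order: zero-phase 4th-order Butterworth low-pass (the cutoff is a
parameter; 15 Hz at 100 Hz sampling in the reference configuration) →
linear-interpolation time normalization → sliding windows. Windows never
cross cycle boundaries; a cycle of length T yields floor((T−W)/step)+1
windows (897 cycles × 100 samples with W=64, step 1 give 33,189). Inputs
are z-scored per channel with training-partition statistics
(zero-variance channels clamp to scale 1); moment targets stay in N·m/kg.
Splits are 70/20/10 and can group by window, cycle or subject — window
grouping mirrors the reference protocol but leaks overlapping windows;
subject grouping is the conservative option.

## Desk-scale benchmark (`desk_demo`)

Study conditions, fixed once:

| quantity | value |
| --- | --- |
| cohort | 12 subjects × 3 speeds × 1 cycle, 100-sample grid |
| angle noise | 3.0° on observed angles; labels from clean kinematics |
| windows | W = 32, step 1 → 2,484 windows, z-scored |
| architecture | 4 blocks, d_model 16, 4 heads, ffn 64, window 32 |
| pre-training | 150 epochs, lr 1e-3 cosine, batch 256, mask 10%, channel-subset augmentation |
| labeled pool | 2 subjects (70/20/10 within pool); test = all windows of the 10 other subjects |
| supervised arms | 50 epochs, batch 64; SSL: lr 1e-3 plateau, 3/4 blocks frozen; baseline: lr 1e-3 cosine |
| label fractions | 5%, 20%, 100% of the labeled train partition; 5 seeds per cell |

The labeled-pool design reflects the practical premise of the method:
kinematics are cheap to record for everyone, while synchronized moment
labels exist only for subjects measured over an instrumented setup. The
pre-training set deliberately includes the test subjects' *unlabeled*
angles (the reference protocol likewise pre-trains on the full angle
corpus without a held-out split) — that exposure is precisely the
advantage self-supervision claims.

**Channel-subset augmentation.** Fine-tuning presents the encoder with
2-channel inputs, but a vanilla pre-trained encoder has only ever seen
18-channel patch embeddings, and its frozen blocks mangle
out-of-distribution tokens. During desk pre-training, each window keeps a
random channel subset (size uniform on {2..18}; dropped channels sit at
their standardized mean of zero) while the reconstruction target remains
the full channel set. The encoder thus learns to operate on any channel
subset — including single joint pairs — and fine-tuning stays in
distribution. The reference-scale defaults leave this augmentation off.

**Warm starts and freezing.** The fresh 2-channel input projection copies
the pre-trained embedding rows of the corresponding channels (exact for
patch length 1); the regression head warm-starts from the reconstruction
head's columns for those channels, whose output already tracks the joint
angle — a strong prior for a near-proportional moment. A freshly created
projection carries no pre-trained knowledge, so it always remains
trainable; a verbatim-copied embedding is frozen together with the prefix
blocks.

## Evaluation battery

MSE and MAE per joint over the fixed test set; per-time-step mean
absolute error curves; peak/valley tables (extrema located on the
observed cycle-mean curve by strict local comparison within a ±5%
neighbourhood, boundary samples excluded; relative error
100·|pred−obs|/|obs|); percent improvements
100·(baseline−improved)/baseline, one decimal (two for summary
statistics); data-efficiency curves with both arms on the identical test
set; a 6×6 cross-joint matrix (rows: input angle channel; columns: target
moment channel; one regression head fine-tuned per cell from the shared
encoder); multi-seed aggregation by element-wise means with per-seed
retention.

## Observed desk-scale behaviour

On the desk benchmark the SSL arm's mean test MSE is roughly half the
baseline's at 5% and 20% labels and matches or modestly beats it at 100%
— the label-efficiency ordering the method claims at full scale,
reproduced under known ground truth. The margin at 100% labels is small (the
synthetic angle→moment map is far easier than real inverse dynamics, so a
scratch transformer closes most of the gap given the full labeled pool),
and the strongest full-scale claim — SSL at 20% labels matching a
baseline trained on five times more labels — is not generally attained at
this scale: with a forward model simple enough for desk-size training,
five times more labels are worth more to the baseline than pre-trained
features are to the SSL arm. The cross-joint matrix shows the designed
diagonal dominance (same-joint cells are row minima), and with the pure
linear noise-free generator the fine-tuned model reaches test MSE below
5% of target variance, i.e. it recovers the ground-truth mapping.

## Numerical choices and edge cases

- Masked count per window is the fixed value round(ratio × n_patches)
  (6 of 64 at 10%), not i.i.d. Bernoulli — stable loss variance.
- Reconstruction loss on masked positions only; an all-positions mode is a
  flag. Ratio 0 with masked-only loss is rejected (empty loss set).
- Post-norm block ordering; attention scale 1/√d_head; Glorot-uniform
  initialization; float32 throughout.
- Adam with L2-style weight decay (decay added to the gradient).
- Early stopping and the plateau schedule ignore improvements below 1e-6
  (N·m/kg)²; the returned model is always the best-validation checkpoint.
- Group-level splits cut the shuffled group sequence where cumulative
  window counts best match the fractions, bending fractions by at most
  one group to keep every partition non-empty.
- CSV round trips use full float repr; window stores use npz archives.
- Degenerate inputs: cycles shorter than the window are skipped with a
  warning; flat observed curves yield an empty peak table with a warning;
  zero-variance channels standardize to zeros.

## Limitations

- Desk-scale conclusions are qualitative. Absolute desk MSEs are not
  comparable to full-scale figures obtained on real data with 2000/500
  epoch budgets.
- The efficiency comparison at 100% labels is a near-tie whose sign can
  flip across cohort seeds; only the scarce-label margins are robust.
- The autodiff engine is minimal by design: no GPU, no mixed precision,
  no graph reuse; wall-clock scales linearly with epochs × windows.
- Window-level splits leak overlapping windows between partitions; the
  benchmark therefore tests on held-out subjects, but the reference
  protocol's own split granularity is ambiguous and both modes are
  provided.
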