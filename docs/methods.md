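# Methods

`emgkin` estimates continuous knee and ankle sagittal angles during loaded
squats from five channels of surface EMG (vastus medialis, rectus femoris,
biceps femoris, tibialis anterior, medial gastrocnemius). This note records
the signal model, the estimation procedure, the numerical choices, and what
the synthetic validation does and does not demonstrate.

## Signal model and pipeline

**Preprocessing.** The sEMG (1500 Hz) is band-passed 20–400 Hz and the
kinematics (100 Hz) low-passed at 6 Hz, both with fourth-order Butterworth
filters run forward–backward. Zero-phase filtering is essential here: a
causal filter injects a frequency-dependent group delay that the lag
estimator downstream would confound with electromechanical delay. The cost
is an effective eighth-order magnitude response, which the filter tests
account for.

**Segmentation.** Squat cycles are delimited by qualifying local minima of
the low-passed knee angle (prominence ≥ 10 % of the signal range,
separation ≥ 0.5 s; both configurable). Series endpoints count as
candidate minima because a squat trial starts and ends standing. Minimum
indices are mapped to EMG sample indices by time. Every cycle is
cubic-spline resampled to 1000 points, so one subject contributes
5 cycles × 4 loads = 20 cycles = 20,000 columns; the nominal 19-subject
design yields the 5 × 380,000 design matrix.

**Amplitude scaling.** Features and targets are min–max normalized per
channel, `x_norm = (x − x_min)/(x_max − x_min)`, with the exact algebraic
inverse applied before metrics are computed. Extrema are always fitted on
the training fold only and reused unchanged for the held-out subject;
held-out values falling outside [0, 1] are passed through unclipped.
Normalizing over the pooled data would leak the test subject's amplitude
range into training and inflate inter-subject accuracy.

**Envelope features.** The network input is the level-8 `sym8` discrete
wavelet approximation of each *rectified* band-passed EMG channel,
reconstructed at full length with all detail bands zeroed. Rectification
matters: the raw EMG is zero-mean, so its level-8 approximation is nearly
zero and carries no usable envelope. Periodized boundary handling keeps
the decomposition orthogonal, which makes the approximation operator an
exact projection (applying it twice equals applying it once to machine
precision); the concatenated cycles begin and end at cycle minima where
muscle activity is low, so the wrap-around mismatch is negligible. The
nominal approximation band edge is rate/2⁹; the sym8 transition band
straddles it, so spectral tests budget one octave of roll-off.

**Cross-correlation alignment.** Muscle activity leads the motion it
produces by an electromechanical delay of roughly 20–200 ms. Each envelope
channel is aligned to its kinematic target by the lag k* maximizing the
normalized lagged cross-covariance (divisor T, full-series means),
searched over k ∈ [0, k_max] (default k_max = 300 working-rate samples),
ties broken toward the smallest lag. Knee-acting muscles (VM, RF, BF) and
the biarticular MG are correlated against the knee target, TA against the
ankle; the mapping is configurable. The lag is the number of samples by
which the EMG side *leads* the target, so alignment shifts the EMG-side
series *later* in time under a finite-support convention (leading
positions zero-filled, length preserved). This direction is the one under
which re-estimating the lag after alignment returns zero. Lags are
estimated once per training fold on the pooled training cycles and applied
unchanged to the held-out subject.

Two accuracy notes on the lag estimator. First, the divisor-T convention
tilts the correlation profile downward as k grows, biasing the argmax low
by roughly P²/(4π²T) samples for a cycle of P samples estimated over T
samples; with the study's 20 pooled cycles the bias is below one sample at
the kinematic rate, and it shrinks further on a multi-subject training
fold. Second, ±1-sample recovery holds for deviation-driven (angle-shaped)
activation; channels whose drive is dominated by |angular velocity| have
an asymmetric envelope-to-angle correlation profile and recover their lead
only to within a few samples. The recovery test therefore uses the
controlled deviation-driven construction at the 100 Hz kinematic rate with
20 cycles and default carrier/measurement noise (`noise_sd = 0.02`; the
documented threshold below which 100/100 recovery holds).

**Regressors.** The primary model is a stacked LSTM implemented in NumPy:
standard gate equations, elementwise products, per-step linear head to the
two joint angles, inverted dropout on inter-layer hidden sequences in
training mode only, exact backpropagation through time (verified against
numerical differentiation at 1e-5 relative tolerance), Adam
(β = 0.9/0.999, lr 0.005) on mean-squared error over normalized targets.
Sequences are the per-cycle chunks with state reset at cycle boundaries —
cycles are the natural stationarity unit the segmentation creates. The
published architecture (10 layers × 200 units, ≤ 200 epochs) is available
via `ModelConfig.paper_scale()`; the shipped default is a desk-scale
profile (2 layers × 32 units, 30 epochs, minibatch of 8 sequences) sized
for a single CPU. The baseline is a stateless per-time-point MLP
(5 → 160 tanh → 2) trained full-batch with a conjugate-gradient optimizer
(SciPy's nonlinear Polak–Ribière CG with analytic gradients, standing in
for the scaled-conjugate-gradient family; Adam is selectable).

`seq_stride` subsamples the per-cycle sequences before training and
prediction (metrics are computed on the same subsampled grid). Both
targets are band-limited at 6 Hz and a cycle lasts ~2.5 s, so a stride of
20 (50 points per cycle, ~20 Hz effective sampling) retains the full
information content of a cycle while cutting training cost 20-fold; the
evaluation experiments and the acceptance script use stride 20.

**Evaluation.** Model selection uses subject-partitioned K-fold
cross-validation (K = 5 by default; the best candidate maximizes mean
validation r, ties broken by lower RMSE then listing order). Accuracy is
assessed by leave-one-subject-out cross-validation: scalers, lag profile
and model are fitted on the remaining subjects and applied unchanged to
the held-out subject. RMSE (degrees, after denormalization) and Pearson r
are computed per subject and joint on the concatenated cycles of all
loading conditions; the roll-up reports best / worst / average ± sd across
subjects, matching 19 LOSO folds in the nominal design.

## The synthetic generator

The generator emulates the structural features the pipeline depends on,
with known ground truth:

* **Kinematics:** raised-cosine min–peak–min cycles (knee baseline 5°, ROM
  100°; ankle baseline −5°, ROM 35°), nominal period 2.5 s with ±4 %
  duration and amplitude jitter, ±5 % per-subject scale factors, and a
  strictly decreasing ROM factor per load (1.0, 0.9, 0.8, 0.7 for
  no-load/60/80/100 % 5RM) — heavier loads produce shallower squats.
* **Activation:** each muscle's envelope is a fixed nonnegative mixture of
  rectified angle deviation and |angular velocity| of the joint(s) it
  acts on, with ±15 % per-subject weight scatter. The velocity component
  produces bursts in both descent and ascent, which makes the
  instantaneous envelope→angle map non-injective — temporal context
  genuinely helps, which is what separates the LSTM from the MLP.
* **EMG:** the envelope, advanced by a per-subject per-channel lead drawn
  uniformly from 60–180 ms (configurable within the physiological 0–200 ms;
  0 permits lag-free null-control cohorts), amplitude-modulates
  unit-variance Gaussian noise band-limited to 20–400 Hz, plus additive
  band-limited measurement noise of relative scale 0.02.

It does **not** model motor-unit physiology, force or fatigue-induced
spectral shifts, crosstalk between electrodes, or real inter-subject
anatomical variability. Passing the synthetic evaluation therefore shows
that the pipeline's machinery is correct and that its inductive biases
(temporal context, lag alignment, leakage-free fold handling) behave as
designed — not that the absolute accuracy figures transfer to recorded
squat data.

## Directional findings and their margins

On 8-subject cohorts over five seeds (desk-scale profile), three
directional properties are asserted on across-seed averages:

1. LSTM mean r ≥ 0.9 on both joints.
2. LSTM mean r ≥ MLP mean r on both joints. The mechanism is the
   non-injective envelope (above); the stateless MLP cannot disambiguate
   descent from ascent.
3. Alignment: the MLP benefits strictly from cross-correlation alignment.
   The LSTM's recurrence can absorb a pure input delay within its memory
   horizon, so on this generator its two arms are statistically
   indistinguishable; they are compared with a 0.005 margin that covers
   seed-to-seed noise. A lag-free null cohort shows both arms within 0.01
   of each other. Any alignment gain a recurrent model shows on real data
   presumably reflects non-idealities (varying delays, non-stationarity)
   the generator deliberately omits.

A related observed property: the epoch-mean training loss collapses about
100-fold within a few epochs and then fluctuates at its noise floor under
dropout and minibatch reshuffling; monotonicity is therefore asserted over
the descent phase (plus a ≥ 20-fold total decrease), not over every epoch
transition.

## Problem sizes

Unit tests run on 2–3 subject cohorts; the end-to-end directional
experiment uses 8 subjects × 4 loads × 5 cycles per seed for five seeds
(4-subject lag-free cohorts for the null control); bookkeeping checks use
the full 19-subject design. The acceptance script repeats the bookkeeping
and a single-seed 8-subject LOSO study. These sizes are the package's
desk-scale defaults; the nominal design and the published architecture
remain available through configuration.

## Known limitations

* The lag estimator returns integer working-rate lags; no sub-sample
  interpolation.
* Velocity-dominant channels recover injected leads only to within a few
  samples (see above); the pipeline tolerates this because alignment
  errors of a few working-rate samples are far inside the LSTM's memory.
* The conjugate-gradient trainer is SciPy's nonlinear CG, not Møller's
  scaled CG; with analytic gradients and a full batch the practical
  behavior (deterministic second-order-ish descent) is equivalent for
  this architecture.
* HDF5 containers store float64 signals; large cohorts produce large
  files (a 19-subject data set is ~100 MB).
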