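# Methods

`gaitforce` estimates time-continuous vertical and anterior–posterior (A/P)
ground reaction forces (GRFs) during graded treadmill running from a
99-sensor pressure insole, and evaluates those estimates with summary
metrics and one-dimensional statistical parametric mapping (SPM). This note
documents the models, the synthetic-data generator that stands in for real
instrumented-treadmill recordings, the numerical choices, and what the test
results do and do not demonstrate.

## The estimation problem

An insole measures the pressure distribution under the foot at 100 Hz; an
instrumented treadmill measures the 3-axis GRF at 2400 Hz. The task is to
predict the gravity-frame vertical and A/P GRF, expressed in body weights
(BW), over each stance phase time-normalized to 101 nodes (0–100 % of
stance), using five mass-normalized pressure-region sums PR₁–PR₅
(heel → toe) as predictors.

Two estimator families are implemented:

* **Linear models.** For each GRF component, a single coefficient per
  region: GRF_vert(φ) = Σᵢ Aᵢ·PRᵢ(φ), GRF_A/P(φ) = Σᵢ Bᵢ·PRᵢ(φ), solved by
  ordinary least squares with all 101 nodes of all in-scope steps pooled as
  observations, without intercept (a flag adds one). `per_condition` scope
  fits one (A, B) pair per treadmill condition — speed and slope then act
  as independent predictors — while `pooled` scope solves one pair for all
  conditions.
* **BiLSTM sequence regressor.** A sequence-to-sequence network mapping a
  [101 × C] input (PR₁–₅, body mass, and optionally speed and slope, each
  replicated across nodes; C = 8 or 6) to the [101 × 2] GRF curves:
  BiLSTM(400) → 30 % dropout → BiLSTM(200) → 20 % dropout → FC(300, tanh) →
  FC(150, tanh) → FC(2, linear). The bidirectional recurrence means the
  prediction at node t uses the inputs at t−1, t and t+1 (and beyond).
  Inputs are Z-scored with statistics from the training split only.

Because no deep-learning framework is part of this package's dependency
set, the network — forward pass, backpropagation through time, dropout and
Adam — is implemented directly in numpy (`gaitforce.nn`). Gradients are
verified against finite differences in the test suite. A reduced "desk"
spec (32/16 BiLSTM, 48/24 FC) is the default for CPU-scale experiments;
the full 400/200 spec is available via `RNNSpec()`.

### Training

Adam on the mean squared error over both components and all nodes, with
shuffled sequences, an internal validation split (10 % of training steps)
and early stopping (patience 5 by default; best-validation weights are
restored). Defaults: learning rate 1e-3, batch 64, ≤30 epochs — all
configurable in `TrainOptions`. Desk-scale experiments in the tests and
acceptance script use lr 3e-3 and ≤40 epochs, which converges the reduced
spec on cohorts of a few hundred steps in tens of seconds per fold. Two
choices worth noting:

* the output layer's bias is initialized at the per-channel mean of the
  training targets, which removes the many epochs Adam would otherwise
  spend learning the DC level of the curves;
* the reduced spec defaults to 10 %/10 % dropout: the ~12×-smaller network
  needs correspondingly less regularization, and the full spec keeps the
  reference 30 %/20 %.

### Subject-specific fine-tuning

`finetune_subject` continues training a generic (leave-one-subject-out)
network on a small fraction (default 10 %) of the target subject's steps,
sampled without replacement stratified by condition with a stated seed, at
a reduced learning rate (3e-4, ≤30 epochs). Evaluation uses only the
disjoint held-out remainder; the split disjointness is asserted.

## Preprocessing chain

1. **Rotation.** GRFs are recorded in the treadmill (belt-aligned) frame;
   a planar rotation by the slope angle about the medial–lateral axis
   aligns the vertical component with gravity. Magnitude is preserved per
   sample.
2. **Filtering.** GRFs are low-pass filtered with a zero-phase bi-pass
   50 Hz third-order Butterworth. Numerically this is implemented as the
   exact squared Butterworth magnitude response 1/(1+(f/fc)⁶) applied in
   the frequency domain on a reflection-padded signal — the response two
   forward/backward time-domain passes realize — because a discrete IIR
   design would warp the frequency axis (≈2.5 % attenuation error at
   100 Hz for fs 2400 Hz) while the spectral implementation matches the
   closed form and has exactly zero phase. Pressure is left unfiltered.
3. **Synchronization.** The insole and force-plate clocks are aligned by
   cross-correlating the total pressure with the downsampled vertical GRF
   over the trial-start jump window; the integer lag maximizing the
   normalized correlation is applied. A peak correlation below 0.5 raises
   an explicit error rather than mis-aligning silently.
4. **Segmentation.** Stances are half-open intervals [on, off) where the
   filtered vertical force exceeds a 20 N threshold, debounced:
   suprathreshold blips shorter than 50 ms are discarded, sub-threshold
   dips shorter than 50 ms bridged, candidates shorter than 100 ms or
   never reaching a quarter of the window maximum rejected, and everything
   before the configured analysis start (the jump window; 25 s in the
   reference protocol) excluded. The 20 N threshold is a common
   force-plate convention; all parameters are configurable.
5. **Extraction.** Each stance's boundaries are refined to sub-sample
   precision by linearly interpolating the threshold crossing, and all
   seven channels (five region sums ÷ mass, two GRFs ÷ mass·g) are sampled
   at 101 equally spaced fractional positions. The sub-sample refinement
   matters: integer boundary jitter of ±1 sample would otherwise alias
   into ~1 %-of-peak errors at the impact transient.

All indices are 0-based; intervals are half-open; interpolation is linear
(avoiding spline overshoot on ~26-frame pressure stances).

## Synthetic-data generator

The generator (`gaitforce.synthetic`) emulates the measurement campaign
end to end so every stage is testable without external data: 11 speed/slope
conditions (level 2.6–3.8 m/s, ±6° graded), cohorts with mass ~N(65.9,
9.3²) kg — drawn by jittered stratified quantiles so that even a 6-subject
cohort reproduces the documented mass spread (leave-one-subject-out
evaluation otherwise degenerates into far-out-of-range extrapolation on
the mass channel when a small cohort's masses happen to cluster) —
rearfoot and forefoot strikers (uphill shifts subjects toward
forefoot, downhill toward rearfoot), three 2.5-BW jump bursts before
steady running, an unknown integer inter-stream lag, and additive Gaussian
noise (defaults 2 N on the force plate, 0.5 kPa per pressure sensor —
instrument-realistic levels).

**Waveforms** are raised-cosine lobe compositions on the stance-phase grid:
an asymmetric rise/fall vertical lobe with active peak growing 2.0→2.8 BW
over 2.6→3.8 m/s (peak at 45 % of stance for rearfoot, 38 % for forefoot),
an impact transient at ~13 % of stance for rearfoot strikers only, and
braking/propulsive A/P lobes of ±0.25–0.45 BW whose balance shifts with
slope (uphill → more propulsion). These amplitudes are physiologically
plausible design choices, not measured values.

**Pressure mapping.** With planted coefficient vectors A and B, region
curves are constructed as

    pr(φ) = vert(φ)·(g + Σⱼ ηⱼ mⱼ(φ) nⱼ) + ap(φ)·h

where g and h solve Aᵀg = 1, Bᵀg = 0 and Aᵀh = 0, Bᵀh = 1, and the nⱼ span
the null space of [A; B] with phase-localized bumps mⱼ and per-step random
amplitudes ηⱼ. The planted identity vert = Σ Aᵢ prᵢ then holds exactly at
every node by construction, while the null-space bumps (i) give the five
regions heel-early/toe-late phase structure and (ii) keep the node design
full-rank so least squares recovers A and B uniquely. Negative requested
pressures raise an explicit infeasibility error. In saturating mode each
region is compressed through L·tanh(pr/L) with L ≈ 1.2× the typical peak,
which leaves a best-linear-fit residual of ≈0.05 BW — enough that the
sequence model's advantage is identifiable. An `idiosyncratic_gain` per
subject scales the pressure-to-force relationship (insoles under-read for
gain > 1), creating the systematic subject-specific error that
fine-tuning experiments exploit.

The ledger accompanying every cohort records the planted coefficients,
per-trial lags, stance intervals and noise-free step curves. Ledger step
curves are defined as what a perfect extraction would record — the
filtered noise-free signal cut at the detection-convention crossings — so
comparisons against the ledger isolate the effect of noise.

**What the generator does not emulate:** sensor-level spatial dynamics
(each region's sensors share a fixed spatial profile), curved/overground
running, surface compliance, soft-tissue artifacts, drift or hysteresis in
the insole, or inter-step correlation beyond independent amplitude jitter.
Passing tests therefore demonstrate the correctness of the pipeline and
the identifiability of the models under the stated conditions — not
real-data error levels, which require real recordings.

## Evaluation stack

* **RMSE and Pearson r** over the 101 nodes, per step; per-condition
  summaries average per-step values over all steps of both feet, then
  across subjects (mean ± SD over the cohort).
* **Range-normalized percent error**: e(φ) = 100·|pred−true| / (max true −
  min true) per step, with mean and SD across steps per node; zero-range
  steps are excluded with a logged count. Early (0–20 %) and late
  (75–100 %) stance windows are summarized separately, since that is where
  linear-model bias concentrates.
* **SPM paired t-tests.** The node-wise paired t statistic forms a 1D
  random field; its smoothness (FWHM) is estimated from the gradients of
  the unit-variance-normalized residuals (FWHM = √(4 ln 2 / ⟨(dv/dφ)²⟩),
  clamped to [1, 101]), and the two-tailed critical height solves the
  expected-Euler-characteristic equation
  P(t > u) + R·(√(4 ln 2)/2π)·(1+u²/ν)^(−(ν−1)/2) = α/2 per tail with
  R = 100/FWHM resels, by bisection to 1e-6 (bracket widened adaptively
  for small ν, where the t tails are heavy). Clusters are maximal runs of
  |t| > u*; inference is at the set-level threshold only. Degenerate
  (zero-variance) difference fields report "no clusters" with a warning.
  Calibration is validated by simulation: the family-wise false-positive
  rate over smooth Gaussian nulls lands near 0.04 at α = 0.05, and the
  threshold agrees with a 10,000-permutation max-|t| oracle within ~2 %.
* **Cohort vs subject level.** Cohort SPM compares subject-mean predicted
  and measured curves paired over subjects; subject-level SPM draws 18
  random steps (seeded, without replacement) to keep power comparable,
  falling back to all available steps with a warning.

## Leave-one-subject-out validation

Each fold trains on all subjects but one — coefficients, network weights
and normalization statistics all come from the training subjects only
(asserted bit-for-bit in the tests) — and predicts the held-out subject.
RNN folds are seeded from (global seed, fold index), so runs are exactly
reproducible. Per-condition linear models skip (and count) test steps
whose condition was absent from training.

## Problem sizes

Desk-scale experiments use 6 subjects × 3 conditions × 2 feet × 6–10 steps
(216–360 steps) with the reduced spec, chosen so a full LOSO comparison,
the speed/slope ablation and a fine-tuning experiment each complete in
minutes on one CPU while remaining statistically meaningful. The
acceptance script reports, among others: linear-coefficient recovery error
(~1e-15), LOSO RMSE of the sequence model vs the pooled linear model on a
saturating cohort (ratio < 1 for both components), the ablation ΔRMSE
(≈0.01 BW), the fine-tuned/generic RMSE ratio for a gain-1.2 subject
(≈0.2–0.6), and the SPM type-I rate (≈0.04).

## Known limitations

* The sensor geometry is schematic (five contiguous bands of 19–21
  sensors); real insoles have anatomical region maps.
* The medial–lateral GRF is carried through as noise and never predicted.
* The full 400/200-node spec trains impractically slowly in pure numpy;
  conclusions about the architecture at full scale require a GPU framework.
* Linear interpolation of 26-frame pressure stances under-resolves the
  impact transient — a genuine property of 100 Hz insoles, and the reason
  early-stance errors dominate even for the sequence model.
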