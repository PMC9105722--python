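# gaitforce

Time-continuous ground reaction force (GRF) estimation from plantar-pressure
insoles during graded treadmill running — for biomechanists and
wearable-sensor researchers who want lab-grade vertical and
anterior–posterior (A/P) force curves without a force plate.

A 99-sensor insole samples the pressure distribution under the foot at
100 Hz; an instrumented treadmill samples the 3-axis GRF at 2400 Hz. After
synchronizing the two streams, segmenting stance phases and time-normalizing
them to 101 nodes, `gaitforce` predicts the gravity-frame GRFs (in body
weights, BW) from five mass-normalized pressure-region curves PR₁–PR₅ with
two estimator families:

* **linear least squares** — per component, one coefficient per region:
  GRF_vert(φ) = Σᵢ Aᵢ·PRᵢ(φ), GRF_A/P(φ) = Σᵢ Bᵢ·PRᵢ(φ), fitted per
  condition or pooled across all speeds and slopes;
* **a BiLSTM sequence regressor** (sequence input → BiLSTM(400) → 30 %
  dropout → BiLSTM(200) → 20 % dropout → FC 300 → FC 150 → FC 2, tanh
  activations, Z-scored inputs), implemented from scratch in numpy with
  verified backpropagation through time, plus a reduced desk-scale spec for
  CPU experiments and subject-specific fine-tuning on ~10 % of a new
  subject's steps.

Models are validated leave-one-subject-out (LOSO) and judged with RMSE,
Pearson r, range-normalized time-continuous percent error, and two-tailed
paired SPM t-tests with random-field-theory thresholds that localize *where*
in stance a model differs systematically from the force plate.

A fully ground-truthed synthetic-data generator emulates the measurement
campaign (11 speed/slope conditions, rearfoot/forefoot strikers,
synchronization jumps, unknown inter-stream lag, sensor noise, and a known —
optionally saturating — pressure→force mapping), so the entire pipeline is
testable end to end. See `docs/methods.md` for the models, assumptions and
numerical choices.

## Worked example

```python
import numpy as np
from gaitforce import (Condition, SimConfig, PreprocessConfig, assemble_trial,
                       make_subjects, preprocess_trial, fit_linear,
                       planted_coefficients)

cond = Condition(speed=3.0, slope=0.0)
cfg = SimConfig(n_subjects=1, conditions=(cond,), steps_per_trial=10,
                lag_samples=37, seed=1)
subject = make_subjects(1, seed=1)[0]
trial, truth = assemble_trial(cfg, subject, cond, "left", np.random.default_rng(1))
steps = preprocess_trial(trial, PreprocessConfig(analysis_start_s=4.5))
print(len(steps), steps[0].grf_vert.max())
```

prints `10 2.32...`: all ten stances are recovered (the planted 37-sample
lag is found by jump cross-correlation) and the first step peaks at 2.32 BW
— a typical vertical GRF for level running at 3.0 m/s. Fitting the linear
model on linear-mode synthetic steps recovers the generator's planted
coefficients:

```text
planted A: [0.009 0.011 0.01  0.012 0.008]
fitted  A: [0.009 0.011 0.01  0.012 0.008]
max relative error: 2.02e-15
```

On a saturating-mode cohort (where no linear model can be exact) the
reduced BiLSTM beats the pooled linear model on a held-out subject
(`examples/03_bilstm_training.py`):

```text
held-out vertical RMSE: BiLSTM 0.043 BW vs linear 0.059 BW
```

and fine-tuning a generic model with ~10 % of the steps of a subject whose
insoles under-read by 20 % (`examples/05_loso_and_finetuning.py`):

```text
generic model:          RMSE 0.208 BW, error 8.8%
subject-specific model: RMSE 0.060 BW, error 2.0%
```

The SPM stack localizes systematic bias: in `examples/04_spm_evaluation.py`
a late-stance over-prediction yields a single supra-threshold cluster at
75–101 % of stance (t* = 3.71, estimated FWHM 9.5 nodes) with a 6.1 % mean
error in that window.

Each script in `examples/` is a short narrative of one capability:
simulation & preprocessing, linear models, BiLSTM training, SPM evaluation,
LOSO & fine-tuning. A thin CLI mirrors the pipeline stages
(`gaitforce simulate | preprocess | fit-linear | train-rnn | evaluate |
spm | finetune | report`).

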