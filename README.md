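# icuward

Multi-horizon prediction of ICU adverse events — in-ICU death,
surveillance-defined sepsis, and KDIGO acute kidney injury — from hourly
EMR feature grids, built as a fully tested analysis pipeline: a
synthetic ICU cohort generator with planted, detectable events;
algorithmic event labelers; instance construction with carry-forward
imputation; a bidirectional-LSTM risk model with logistic / XGBoost
baselines and SOFA / APACHE-II comparators; and an input-error /
delayed-input robustness harness.

## Who this is for

Researchers building early-warning models on irregular clinical time
series who need (a) reference implementations of the surveillance sepsis
and KDIGO AKI labeling rules with exact, oracle-tested semantics, (b) a
multi-horizon instance-sampling and evaluation scaffold whose leakage
and fold-hygiene properties are enforced by tests, and (c) a synthetic
EMR generator for pipeline validation when hospital data cannot be
shared.

## The model

For each event a separate binary classifier predicts occurrence within
lead time T ∈ {T1, T2, T3} (3/6/12 h for mortality and AKI, 2/4/6 h for
sepsis).  An instance at prediction time t has dynamic input
X ∈ ℝ^{(⌊t⌋+1)×18} — hourly bins of 6 vitals, 11 labs and GCS from
admission to t, carry-forward imputed and min–max normalized — and age
as static input.  The scorer is

  p(y=1 | X, a) = σ( W₂ · φ( W₁ · [ h⃗_T ; h⃖_T ; ψ(a) ] ) ),

where h⃗_T, h⃖_T are the final hidden states of a bidirectional LSTM
with 20 units per direction and ψ is a small dense branch for age.
Training: Adam (lr 10⁻³), batch 32 balanced minibatches, L2 penalty,
early stopping on validation AUROC, patient-level splits throughout.
Positives are sampled in [onset − T, onset); negatives are time-matched
controls with an event-free (t, t+T] window.  Performance is reported as
AUROC, AUPRC, and specificity / F1 at a fixed sensitivity of 0.85;
robustness as the mean AUROC difference against Gaussian input noise
(scales 1/1000 … 1 on two random vital signs) and delayed charting
(0–10 h deleted, carry-forward re-imputed).

The LSTM, backpropagation through time, and Adam are implemented in
numpy (recurrence loops JIT-compiled with numba) and verified against
finite differences — no deep-learning framework is required.

## Worked example

```
$ python analysis/01_generate_cohort.py --n-patients 300
cohort: 300 patients, 139122 observations -> results/cohort
  death   planted   15 ( 5.00%)  target 3.60%
  sepsis  planted   11 ( 3.67%)  target 3.12%
  aki     planted   27 ( 9.00%)  target 9.10%

$ python analysis/02_label_events.py
labels -> results/labels.csv (53 events)
planted events recovered at the exact hour: 53, missed/shifted: 0, spurious: 0
```

The generator plants events at the development-cohort prevalences
(binomial draws — the realized 5.00% death rate is a small-sample
fluctuation around 3.6%), and the labelers recover every planted onset
at the exact hour with no false events: the planted signatures are
constructed to cross the labeling thresholds exactly at onset, and
non-event trajectories are clipped below every threshold.

Continuing the analysis (`03_build_instances.py`, `04_train_models.py`,
`05_robustness.py`) builds the instance sets, trains all models, and
writes `results/model_performance.csv`, `results/robustness.csv`, and
figures: a noise/delay AUROC-delta plot and a three-horizon alarm
timeline for one deteriorating synthetic patient.  On a 1,000-patient
cohort the biLSTM reaches held-out AUROC ≥ 0.99 at T1 for every event,
AUROC declines toward the distant horizon (the drift ramp is shorter a
T3 prediction away from onset), and under scale-1 input noise the
sequence model loses ~0.001 AUROC where the logistic baseline loses
~0.06 — the sequence model reads the whole trajectory, the baseline
only the corrupted abstracted value.

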