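# Methods

## Problem setting

`icuward` is an analysis pipeline for multi-horizon prediction of three
ICU adverse events — in-ICU death, surveillance-defined sepsis, and
KDIGO acute kidney injury — from routinely charted EMR data.  For each
event, three binary classifiers predict whether the event will occur
within a prespecified lead time: T1/T2/T3 = 3/6/12 h for mortality and
AKI, 2/4/6 h for sepsis.  Separate models per horizon address *temporal
skewness*: true-positive scores concentrate near the actual onset, so a
single "within 12 h" model gives no usable lead-time guarantee.

Hospital ICU cohorts of this kind are not publicly deposited, so the
pipeline is developed and validated against a synthetic cohort generator
whose planted events are detectable by construction (below).  Every
result the tests and the acceptance script report is computed on those
synthetic cohorts; none of it is a claim about real EMR data.

## Event working definitions

* **Mortality** — death time recorded within the ICU stay.  Patients
  whose event time falls after the stay are excluded upstream, together
  with patients under 18 and patients with no valid record of any of the
  five exclusion vitals (pulse rate, systolic/diastolic pressure,
  respiratory rate, temperature).
* **Sepsis** (clinical-surveillance style) — a *suspected serious
  infection* with concurrent acute organ dysfunction.  Suspected
  infection = a blood culture paired with a *sustained* course of a
  *new* antibiotic (same agent on ≥ 3 consecutive calendar days; not
  given in the prior 48 h; start within ±24 h of the culture).  Organ
  dysfunction = vasopressor or mechanical-ventilation initiation,
  lactate ≥ 2.0 mmol/L, creatinine ≥ 2× the lowest prior value,
  bilirubin ≥ 2.0 mg/dL and ≥ 2× the lowest prior value, or platelets
  < 100×10³/µL with a ≥ 50% decline from the prior peak — within
  [infection − 48 h, infection + 24 h].  The surveillance literature
  states the structure but not every threshold; the numbers above are
  shipped as an editable table (`labeling.SepsisThresholds`), and the
  onset convention — min(infection time, earliest in-window dysfunction)
  — is a declared choice, not an inferred one.
* **AKI** (KDIGO) — creatinine rise ≥ 0.3 mg/dL within 48 h, creatinine
  ≥ 1.5× the lowest value of the prior 7 days (pre-ICU values included),
  or urine output < 0.5 mL·kg⁻¹·h⁻¹ sustained for 6 h.  Onset anchors at
  the qualifying creatinine measurement (urine: end of the qualifying
  window).  Ties at the same hour resolve delta > ratio > urine, which
  affects the reported criterion only.

All labelers use earliest-time semantics and are tested for exact
equality against brute-force oracles that enumerate every measurement
pair, antibiotic course, and urine window.

## Synthetic cohort generator

Each patient's 18 dynamic channels (6 vitals incl. SpO2, 11 labs, GCS)
follow an AR(1) mean-reverting fluctuation around a patient-specific
baseline, observed at channel-typical cadence (vitals ~hourly, labs
every 8–12 h) with channel-specific missingness (defaults: 10% vitals,
20% labs/GCS).  Stay lengths are lognormal (mean 60 h, clipped to
36–96 h — desk-scale; real stays have a heavier tail).  Event
prevalences default to the development-cohort values (death 3.6%,
sepsis 3.12%, AKI 9.1%), with at most one planted event per patient
(events are treated as independent outcomes downstream).

A planted event adds a deterministic linear drift ramp starting
`drift_lead` hours before onset (16 h for death/AKI, 10 h for sepsis —
at least T3 in all cases, so even distant-horizon instances see signal),
plus a rule-crossing signature placed exactly at onset:

* **death** — vitals and GCS deteriorate along the ramp; death time =
  onset and the record truncates there.
* **sepsis** — culture at onset + a new 3-day antibiotic course;
  lactate crosses 2.0 at onset + 2 h (sub-threshold ramp before), so the
  labeled onset = min(onset, onset + 2) = onset exactly.
* **AKI** — creatinine ramps sub-threshold (≤ +0.22 over a 0.8–1.3
  baseline, noise clipped so no 48-h delta reaches 0.3 and no 7-day
  ratio reaches 1.5 early), then a protected measurement at onset jumps
  +0.6.  The wider renal syndrome (BUN +28 mg/dL, potassium +0.9 mmol/L,
  mild tachycardia/hypotension/tachypnea, labs re-ordered every 5–6 h as
  they would be in a deteriorating patient) carries the learnable
  signal, since none of those channels feed a labeling rule.

Two guarantees are structural, not statistical: signature observations
are `protected` (never dropped by the missingness simulator), so planted
onsets are always recoverable; and non-event patients are generated
inside sub-threshold clip bands (creatinine ±0.10 around baseline,
lactate ≤ 1.8, bilirubin ≤ 1.9, platelets ±20% of a ≥150 baseline, urine
rate ≥ 0.7), so no labeling rule can fire spuriously.  Decoy lone
cultures (10% of non-event patients) and unpaired antibiotic courses
(5%) keep the infection detector honest.  The urine criterion never
fires on generated cohorts (all rates ≥ 0.7) and is exercised by
hand-built fixtures instead.

What the generator does **not** emulate: inter-event correlation (a real
septic patient often develops AKI), treatment feedback, heavy-tailed
stay lengths, informative missingness, and measurement artifacts.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and that the model learns planted physiology; they do not
certify performance on real EMR data.

## Instances and preprocessing

An instance is (patient, prediction time, horizon).  Dynamic features
are hourly bins [h, h+1) from admission to the prediction time
(within-hour arithmetic mean; rows = floor(t)+1; minimum history 1 h);
age is the static feature.  Missing bins are filled by carry-forward,
and by an adult reference midpoint when no prior value exists (the
shipped normal-values table); imputation is idempotent and leaves no
missing cells.  Channels are min-max normalized to [0, 1] with clipping,
statistics fitted on training folds only.

Positive prediction times are drawn uniformly from [onset − T, onset) at
hourly resolution (up to 4 per patient).  Negative times must have an
event-free (t, t + T] window; they are drawn as **time-matched
controls**: each negative time is sampled near a randomly drawn positive
time and assigned to a random patient that admits it.  Without matching,
positives necessarily sit late in the stay (at least the drift lead past
admission) and a classifier can score on elapsed time alone — measured
here as length-as-score AUROC 0.61 under uniform negatives, 0.53 after
matching.  Uniform per-patient sampling remains available
(`match_positive_times=False`).

## Models

The sequence classifier is a bidirectional LSTM with 20 hidden units per
direction over the padded hourly grid (final hidden state of each
direction), a 1→8 tanh branch for age, and a 16-unit tanh head with a
sigmoid output (equivalent to the 2-way softmax it replaces).  Training:
Adam (lr 1e-3), batch 32 balanced minibatches (half positive with
replacement, each negative at most once per epoch), L2 weight penalty
1e-4, early stopping on validation AUROC — halt when no improvement for
`patience` epochs after the `warmup` epoch, restore best-epoch weights.
The reference schedule (300 epochs, patience 60 after epoch 100) is
impractical and unnecessary at desk scale; studies use max 24 epochs,
warmup 6, patience 6, under which the planted tasks converge.

No deep-learning framework is assumed: the network, BPTT, and Adam are
implemented in numpy with the two recurrence loops JIT-compiled via
numba, and the gradients are verified against central finite differences
in the test suite.  Training is single-threaded and seed-deterministic.

Baselines consume one abstracted value per channel — the post-imputation
grid row at the prediction time — plus age: logistic regression (L2,
C = 1) and gradient-boosted trees (200 rounds, depth 4, lr 0.1), both
untuned comparators.  Clinical comparators are SOFA (0–24) and APACHE-II
(0–71) computed from worst-in-24 h snapshots at the prediction time,
with two documented surrogates for panel gaps: respiratory components
scored from SpO2 bands, hematocrit ≈ 3×hemoglobin, and a flat 3
cardiovascular points for any vasopressor use (the binary flag cannot
resolve dose bands).

## Evaluation

AUROC is the Mann–Whitney probability with ties counted ½ (rank
formula); AUPRC is average precision with tied scores processed as one
block; both are verified to 1e-12 against exhaustive pairwise/threshold
brute force and against scikit-learn.  The operating point fixes
sensitivity at 0.85: the threshold is the largest score cut achieving
sensitivity ≥ 0.85 on the given set (so reported sensitivity lands at
the first crossing), at which specificity and F1 are reported.
Cross-validation splits by patient (all of a patient's instances share a
fold; fold sizes differ by ≤ 1 patient).

The permutation null for the learnability control shuffles held-out
labels against the trained model's scores (mean over 20 shuffles).
Retraining on shuffled labels is not a usable control on these cohorts:
the planted classes are well separated in feature space, so a network
fitted to label noise still assigns the two clusters different mean
scores with random sign — measured swings of ±0.15 per replicate.

## Robustness protocol

Input-error: additive Gaussian noise at the normalized feature scale
(SD ∈ {1/1000, 1/200, 1/100, 1/20, 1/10, 1/2, 1}) on two randomly drawn
vital signs, clipped to [0, 1].  For the sequence model the noise lands
on 10% of the grid rows (rounded, minimum 1, drawn without replacement);
for the summary baselines it lands on the abstracted (prediction-time)
value those models actually read.  Delayed input: the final 0–10 h of
two randomly drawn vital signs are deleted and re-imputed by
carry-forward.  Channels and rows are redrawn each repeat (default 20);
reported per setting: mean and SD of AUROC(original) − AUROC(perturbed),
positive = degradation.  Scale 0 and delay 0 short-circuit to exact
zero.  The monotonicity study runs the logistic baseline on mortality at
T3, where its margins are not saturated; at T1 the synthetic task is so
separable that even scale-1 noise reorders nothing.

## Study sizes and numerical choices

Acceptance-grade studies use: 1,000 patients (missingness-free) for
labeler recovery; 2,000 patients for learnability/horizon ordering (9
trained sequence models); 800 for the robustness study; ~10,000 sampled
instances for the hygiene sweep — sizes chosen so the full battery runs
in minutes on one CPU while keeping ≥ 50 positive patients per event.
All randomness flows from a single seed through `numpy.random.
SeedSequence` spawning; identical (config, seed) reproduces cohorts
bit-for-bit and training histories exactly.  Degenerate cases are
defined explicitly: zero-range channels pass through normalization
unchanged (with a warning), a fully missing channel imputes to its
normal value, an empty admissible-negative set warns rather than errors,
and single-repeat robustness SDs are reported as 0 with a flag.

## Known limitations

Single-event patients and clip-band specificity make the labeling task
cleaner than hospital reality, where baseline pathology (chronic kidney
disease, cirrhosis, thrombocytopenia) generates boundary cases the
surveillance rules must arbitrate.  The generator's drift is monotone
and deterministic in shape, which favors any model that tracks trends —
including the last-value baselines, which is why they are competitive
here while the reference analysis found them clearly inferior on real
data.  APACHE-II is computed from the current stay window rather than
the classical admission-time assessment, and its chronic-health item is
a flat flag.  SOFA's cardiovascular dose bands collapse to one value.
These are all per-design simplifications of comparators, not of the
contribution under test.
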