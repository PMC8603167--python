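"""Metrics, patient-level cross-validation, and input-robustness
experiments.

AUROC is the Mann–Whitney probability with ties counted 1/2 (rank
formula).  AUPRC is average precision computed by descending-score
traversal with tied scores processed as one block.  The operating point
for specificity and F1 fixes sensitivity at 0.85: the threshold is the
largest score cut achieving sensitivity >= 0.85 on the given set.

The robustness harness replays the reference protocol: additive
Gaussian noise at the normalized feature scale (factors 1/1000 ... 1)
on two randomly drawn vital signs over 10% of the time sequence, and
delayed charting simulated by deleting the final 0–10 hours of two
vital signs and re-imputing by carry-forward.  Reported per setting:
mean and SD of AUROC(original) − AUROC(perturbed) over repeats
(positive = degradation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .channels import CHANNEL_INDEX, VITAL_NAMES

NOISE_SCALES = (1 / 1000, 1 / 200, 1 / 100, 1 / 20, 1 / 10, 1 / 2, 1.0)
DELAY_HOURS = tuple(range(0, 11))
CORRUPT_FRACTION = 0.10
N_CORRUPT_CHANNELS = 2


class UndefinedMetricError(ValueError):
    pass


# ---------------------------------------------------------------------------
# metrics


def auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC needs both classes present")
    ranks = rankdata(scores)  # average ranks: ties count 1/2
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Average precision: sum over distinct descending thresholds of
    (recall step) x (precision at the threshold)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(labels == 1))
    if n_pos == 0:
        raise UndefinedMetricError("AUPRC needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # block boundaries: last index of each tied-score group
    distinct = np.nonzero(np.diff(s))[0]
    ends = np.append(distinct, len(s) - 1)
    tp = np.cumsum(y)[ends]
    fp = (ends + 1) - tp
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


@dataclass
class MetricsReport:
    auroc: float
    auprc: float
    threshold: float
    sensitivity: float
    specificity: float
    f1: float
    n_pos: int
    n_neg: int
    target_sensitivity: float = 0.85
    sensitivity_reachable: bool = True


def metrics_at_fixed_sensitivity(labels: np.ndarray, scores: np.ndarray,
                                 sensitivity: float = 0.85) -> MetricsReport:
    """Specificity and F1 at the largest threshold with sensitivity >=
    the target (classification rule: score >= threshold is positive)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0:
        raise UndefinedMetricError("needs at least one positive")
    best_thr = None
    for thr in np.unique(scores)[::-1]:
        pred = scores >= thr
        tp = int(np.sum(pred & (labels == 1)))
        if tp / n_pos >= sensitivity:
            best_thr = float(thr)
            break
    reachable = best_thr is not None
    if not reachable:
        best_thr = float(np.min(scores))
    pred = scores >= best_thr
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = n_pos - tp
    tn = n_neg - fp
    sens = tp / n_pos
    spec = tn / n_neg if n_neg else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return MetricsReport(auroc(labels, scores) if n_neg else float("nan"),
                         auprc(labels, scores), best_thr, sens, spec, f1,
                         n_pos, n_neg, sensitivity, reachable)


# ---------------------------------------------------------------------------
# patient-level cross-validation


def patient_folds(patient_ids: list[str], k: int,
                  rng: np.random.Generator) -> list[np.ndarray]:
    """Partition instance indices into k folds BY PATIENT: all of a
    patient's instances share a fold; fold sizes differ by <= 1 patient."""
    if k < 2:
        raise ValueError("k must be >= 2")
    unique = sorted(set(patient_ids))
    order = rng.permutation(len(unique))
    shuffled = [unique[i] for i in order]
    assignment = {pid: f for f, chunk in
                  enumerate(np.array_split(np.arange(len(shuffled)), k))
                  for i in chunk for pid in [shuffled[i]]}
    ids = np.array([assignment[p] for p in patient_ids])
    return [np.flatnonzero(ids == f) for f in range(k)]


def cross_validate(instances, fit_fn, k: int = 5, seed: int = 0,
                   ) -> list[MetricsReport]:
    """k-fold CV split by patient.  ``fit_fn(train_instances)`` must
    return a model with ``predict_risk(instances) -> scores`` and is
    responsible for fitting its own normalization statistics on the
    training instances only."""
    rng = np.random.default_rng(seed)
    folds = patient_folds([i.patient_id for i in instances], k, rng)
    event_patients = {i.patient_id for i in instances if i.label == 1}
    if len(event_patients) < k:
        raise ValueError(f"fewer event patients ({len(event_patients)}) "
                         f"than folds ({k})")
    reports = []
    for f in range(k):
        test_idx = set(folds[f].tolist())
        train = [inst for i, inst in enumerate(instances)
                 if i not in test_idx]
        test = [instances[i] for i in sorted(test_idx)]
        model = fit_fn(train)
        scores = model.predict_risk(test)
        y = np.array([i.label for i in test])
        reports.append(metrics_at_fixed_sensitivity(y, scores))
    return reports


# ---------------------------------------------------------------------------
# perturbations


@dataclass(frozen=True)
class PerturbationSpec:
    mode: str                      # "noise" | "delay"
    noise_scale: float = 0.0       # SD in normalized units
    delay_hours: int = 0
    corrupt_fraction: float = CORRUPT_FRACTION
    n_channels: int = N_CORRUPT_CHANNELS
    repeats: int = 20
    # "grid": corrupt 10% of the rows (sequence-model protocol);
    # "summary": corrupt the row at the prediction time, i.e. the
    # abstracted value the non-time-series baselines consume
    target: str = "grid"

    def __post_init__(self) -> None:
        if self.mode not in ("noise", "delay"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")
        if self.target not in ("grid", "summary"):
            raise ValueError(f"unknown noise target {self.target!r}")
        if self.noise_scale < 0 or self.delay_hours < 0:
            raise ValueError("scale and delay must be non-negative")


@dataclass
class RobustnessResult:
    spec: PerturbationSpec
    mean_delta: float      # AUROC(original) - AUROC(perturbed)
    sd_delta: float
    baseline_auroc: float
    repeats: int
    degenerate_sd: bool = False


def _draw_vital_channels(rng: np.random.Generator, n: int) -> np.ndarray:
    cols = [CHANNEL_INDEX[v] for v in VITAL_NAMES]
    return rng.choice(cols, size=n, replace=False)


def inject_noise_array(X: np.ndarray, lengths: np.ndarray, scale: float,
                       rng: np.random.Generator,
                       corrupt_fraction: float = CORRUPT_FRACTION,
                       n_channels: int = N_CORRUPT_CHANNELS,
                       target: str = "grid") -> np.ndarray:
    """Additive Gaussian noise (SD = scale, the normalized feature scale
    being 1) on ``n_channels`` randomly drawn vital signs, clipped back
    to [0, 1].

    ``target="grid"`` corrupts round(corrupt_fraction x rows) randomly
    drawn rows of each sequence (minimum 1, without replacement) — the
    sequence-model protocol.  ``target="summary"`` corrupts the row at
    the prediction time, which is exactly the abstracted value the
    summary baselines read.  ``scale = 0`` is the identity, exactly."""
    if scale == 0.0:
        return X
    out = X.copy()
    for b in range(X.shape[0]):
        cols = _draw_vital_channels(rng, n_channels)
        if target == "summary":
            rows = np.array([lengths[b] - 1])
        else:
            n_rows = max(1, int(round(corrupt_fraction * lengths[b])))
            rows = rng.choice(lengths[b], size=n_rows, replace=False)
        noise = rng.normal(0.0, scale, size=(len(rows), n_channels))
        out[b, rows[:, None], cols[None, :]] = np.clip(
            out[b, rows[:, None], cols[None, :]] + noise, 0.0, 1.0)
    return out


def delay_input_array(X: np.ndarray, lengths: np.ndarray, delay_hours: int,
                      rng: np.random.Generator,
                      n_channels: int = N_CORRUPT_CHANNELS) -> np.ndarray:
    """Simulated late charting: for ``n_channels`` randomly drawn vital
    signs, the final ``delay_hours`` rows before the prediction time are
    deleted and re-imputed by carry-forward (the value at the last
    untouched row).  ``delay_hours = 0`` is the identity, exactly."""
    if delay_hours == 0:
        return X
    out = X.copy()
    for b in range(X.shape[0]):
        cols = _draw_vital_channels(rng, n_channels)
        L = int(lengths[b])
        d = min(delay_hours, L - 1)
        if d <= 0:
            continue
        for c in cols:
            out[b, L - d:L, c] = out[b, L - d - 1, c]
    return out


def robustness_experiment(score_fn, X: np.ndarray, lengths: np.ndarray,
                          static: np.ndarray, y: np.ndarray,
                          specs: list[PerturbationSpec],
                          seed: int = 0) -> list[RobustnessResult]:
    """For each perturbation setting, repeat with fresh channel/row draws
    and report mean and SD of the paired AUROC difference.

    ``score_fn(X, lengths, static) -> scores`` closes over the trained
    model; the same held-out set is scored unperturbed once."""
    base_scores = score_fn(X, lengths, static)
    base = auroc(y, base_scores)
    results = []
    root = np.random.SeedSequence(seed)
    for spec, ss in zip(specs, root.spawn(len(specs))):
        identity = (spec.mode == "noise" and spec.noise_scale == 0.0) or \
                   (spec.mode == "delay" and spec.delay_hours == 0)
        if identity:
            results.append(RobustnessResult(spec, 0.0, 0.0, base,
                                            spec.repeats,
                                            spec.repeats <= 1))
            continue
        deltas = []
        for rep_ss in ss.spawn(spec.repeats):
            rng = np.random.default_rng(rep_ss)
            if spec.mode == "noise":
                Xp = inject_noise_array(X, lengths, spec.noise_scale, rng,
                                        spec.corrupt_fraction,
                                        spec.n_channels, spec.target)
            else:
                Xp = delay_input_array(X, lengths, spec.delay_hours, rng,
                                       spec.n_channels)
            deltas.append(base - auroc(y, score_fn(Xp, lengths, static)))
        deltas = np.array(deltas)
        degenerate = spec.repeats <= 1
        if degenerate:
            warnings.warn("SD over a single repeat reported as 0")
        results.append(RobustnessResult(
            spec, float(deltas.mean()),
            0.0 if degenerate else float(deltas.std(ddof=1)),
            base, spec.repeats, degenerate))
    return results
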