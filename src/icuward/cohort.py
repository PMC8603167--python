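"""Cohort assembly: exclusions, hourly feature grids, and multi-horizon
training instances.

A prediction instance is one (patient, prediction time, horizon) triple.
Its dynamic input is an hourly grid of the 18 dynamic channels from
admission up to the prediction time (half-open hourly bins, within-hour
arithmetic mean), its static input is age.  Missing bins are filled by
carry-forward, or by an adult reference value when no prior observation
exists; normalization is per-channel min-max fitted on training folds
only.

Positive instances for horizon T are drawn at hourly prediction times in
[onset - T, onset); negatives at times whose following T-hour window is
event-free (for event patients, strictly before onset).  Features are
always collected from admission to the prediction time only — no
future leakage by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .channels import (
    CHANNEL_INDEX,
    CHANNEL_NAMES,
    EXCLUSION_VITALS,
    N_DYNAMIC,
    NORMAL_VALUES,
)
from .records import EventLabel, PatientRecord

MIN_HISTORY_H = 1.0   # prediction time floor: at least one grid row
MAX_AGE_NORM = 100.0  # age is scaled by a fixed constant, not fold statistics


class DomainError(ValueError):
    pass


@dataclass
class FeatureGrid:
    """Hourly dynamic grid plus static features for one instance.

    ``values`` is (n_hours, 18) with NaN where unobserved; ``mask`` is
    True where a cell holds an original observation.  ``imputed`` /
    ``normalized`` record pipeline state.
    """

    values: np.ndarray
    mask: np.ndarray
    age: float
    prediction_time: float
    imputed: bool = False
    normalized: bool = False

    @property
    def n_hours(self) -> int:
        return self.values.shape[0]

    @property
    def static(self) -> np.ndarray:
        return np.array([self.age / MAX_AGE_NORM])

    def copy(self) -> "FeatureGrid":
        return FeatureGrid(self.values.copy(), self.mask.copy(), self.age,
                           self.prediction_time, self.imputed,
                           self.normalized)


@dataclass
class Instance:
    patient_id: str
    event: str
    tier: str                  # "T1" | "T2" | "T3"
    grid: FeatureGrid
    label: int
    prediction_time: float


# ---------------------------------------------------------------------------
# exclusions

EXCLUSION_RULES = ("age<18", "no_valid_vital", "event_after_stay")


def apply_exclusions(records: list[PatientRecord],
                     ) -> tuple[list[PatientRecord], dict[str, int]]:
    """Apply the cohort exclusion rules in their printed order: under 18,
    no valid record for any of the 5 named vital signs, event time after
    the ICU stay.  A patient failing several rules counts once, under
    the first failing rule."""
    report = {rule: 0 for rule in EXCLUSION_RULES}
    kept: list[PatientRecord] = []
    for r in records:
        if r.age < 18.0:
            report["age<18"] += 1
        elif all(len(r.channel(v)) == 0 for v in EXCLUSION_VITALS):
            report["no_valid_vital"] += 1
        elif r.death_time is not None and r.death_time > r.discharge_time:
            report["event_after_stay"] += 1
        else:
            kept.append(r)
    return kept, report


# ---------------------------------------------------------------------------
# grid construction


def build_feature_grid(record: PatientRecord,
                       prediction_time: float) -> FeatureGrid:
    """Hourly grid from admission to ``prediction_time``.

    Row h aggregates observations with time in [h, h+1) and time <=
    prediction_time by arithmetic mean; rows cover hours 0 ..
    floor(prediction_time).  Pre-ICU observations (negative times) are
    excluded.
    """
    if prediction_time < MIN_HISTORY_H:
        raise DomainError(
            f"prediction time {prediction_time} below the "
            f"{MIN_HISTORY_H}-hour minimum history floor")
    if prediction_time > record.discharge_time + 1e-9:
        raise DomainError("prediction time after discharge")
    n_rows = int(np.floor(prediction_time)) + 1
    values = np.full((n_rows, N_DYNAMIC), np.nan)
    mask = np.zeros((n_rows, N_DYNAMIC), dtype=bool)
    for name, j in CHANNEL_INDEX.items():
        s = record.channel(name)
        if len(s) == 0:
            continue
        sel = (s.times >= 0.0) & (s.times <= prediction_time)
        if not np.any(sel):
            continue
        bins = np.floor(s.times[sel]).astype(int)
        bins = np.minimum(bins, n_rows - 1)
        sums = np.bincount(bins, weights=s.values[sel], minlength=n_rows)
        counts = np.bincount(bins, minlength=n_rows)
        observed = counts > 0
        values[observed, j] = sums[observed] / counts[observed]
        mask[:, j] = observed
    return FeatureGrid(values, mask, record.age, float(prediction_time))


def impute(grid: FeatureGrid,
           normal_values: dict[str, float] | None = None) -> FeatureGrid:
    """Carry-forward within each channel; leading gaps (no prior
    observation) take the channel's normal value.  Idempotent."""
    if normal_values is None:
        normal_values = NORMAL_VALUES
    for name in CHANNEL_NAMES:
        if name not in normal_values:
            raise KeyError(
                f"channel {name!r} missing from the normal-values table")
    out = grid.copy()
    v = out.values
    for j, name in enumerate(CHANNEL_NAMES):
        col = v[:, j]
        missing = np.isnan(col)
        if not missing.any():
            continue
        # carry-forward: index of most recent observed row at or before i
        idx = np.where(~missing, np.arange(len(col)), -1)
        idx = np.maximum.accumulate(idx)
        filled = np.where(idx >= 0, col[np.maximum(idx, 0)],
                          normal_values[name])
        v[:, j] = filled
    out.imputed = True
    return out


@dataclass
class ChannelStats:
    """Per-channel min-max normalization statistics (training folds only)."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, grids: list[FeatureGrid]) -> "ChannelStats":
        if not grids:
            raise ValueError("cannot fit statistics on an empty set")
        lo = np.full(N_DYNAMIC, np.inf)
        hi = np.full(N_DYNAMIC, -np.inf)
        for g in grids:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                lo = np.fmin(lo, np.nanmin(g.values, axis=0))
                hi = np.fmax(hi, np.nanmax(g.values, axis=0))
        unseen = ~np.isfinite(lo)
        lo[unseen], hi[unseen] = 0.0, 1.0
        return cls(lo, hi)


def normalize(grid: FeatureGrid, stats: ChannelStats) -> FeatureGrid:
    """Affine min-max transform to [0, 1] with clipping; zero-range
    channels pass through unchanged (with a warning)."""
    out = grid.copy()
    span = stats.hi - stats.lo
    degenerate = span <= 0
    if degenerate.any():
        warnings.warn("zero-range channel(s) left untransformed: "
                      + ", ".join(np.array(CHANNEL_NAMES)[degenerate]))
    safe = np.where(degenerate, 1.0, span)
    scaled = (out.values - np.where(degenerate, 0.0, stats.lo)) / np.where(
        degenerate, 1.0, safe)
    out.values = np.clip(scaled, 0.0, 1.0)
    out.values[:, degenerate] = grid.values[:, degenerate]
    out.normalized = True
    return out


def denormalize(grid: FeatureGrid, stats: ChannelStats) -> FeatureGrid:
    out = grid.copy()
    out.values = stats.lo + out.values * (stats.hi - stats.lo)
    out.normalized = False
    return out


# ---------------------------------------------------------------------------
# instance sampling


def admissible_positive_hours(label: EventLabel, horizon_h: int,
                              discharge: float) -> np.ndarray:
    """Integer prediction times t with onset - T <= t < onset, within the
    stay and at or above the minimum history floor."""
    onset = label.onset
    hours = np.arange(int(np.ceil(onset - horizon_h)),
                      int(np.ceil(onset)))
    ok = (hours >= MIN_HISTORY_H) & (hours >= onset - horizon_h) & \
         (hours <= discharge)
    return hours[ok]


def admissible_negative_hours(record: PatientRecord,
                              label: EventLabel | None,
                              horizon_h: int) -> np.ndarray:
    """Integer prediction times whose (t, t + T] window is event-free;
    for event patients this means strictly before onset - T."""
    last = int(np.floor(record.discharge_time)) - horizon_h
    hours = np.arange(int(MIN_HISTORY_H), last + 1)
    if label is not None:
        hours = hours[hours + horizon_h < label.onset]
    return hours


def sample_instances(record: PatientRecord, label: EventLabel | None,
                     event: str, tier: str, horizon_h: int,
                     n_pos: int, n_neg: int,
                     rng: np.random.Generator) -> list[Instance]:
    """Draw up to ``n_pos`` positive and ``n_neg`` negative instances for
    one patient at one horizon (without replacement within the patient).
    Grids are raw (not yet imputed or normalized)."""
    out: list[Instance] = []
    if label is not None and label.event == event and n_pos > 0:
        hours = admissible_positive_hours(label, horizon_h,
                                          record.discharge_time)
        take = rng.choice(hours, size=min(n_pos, len(hours)), replace=False)
        for t in sorted(float(t) for t in take):
            out.append(Instance(record.patient_id, event, tier,
                                build_feature_grid(record, t), 1, t))
    if n_neg > 0:
        hours = admissible_negative_hours(
            record, label if (label and label.event == event) else None,
            horizon_h)
        if len(hours) == 0:
            warnings.warn(f"{record.patient_id}: no admissible negative "
                          f"hours at horizon {horizon_h}")
        else:
            take = rng.choice(hours, size=min(n_neg, len(hours)),
                              replace=False)
            for t in sorted(float(t) for t in take):
                out.append(Instance(record.patient_id, event, tier,
                                    build_feature_grid(record, t), 0, t))
    return out


@dataclass
class InstanceSamplingConfig:
    n_pos_per_patient: int = 4     # capped at the horizon's window width
    n_neg_per_patient: int = 2     # used when time matching is off
    max_negatives: int | None = None   # cohort-level negative budget
    match_positive_times: bool = True
    seed: int = 0


def build_instance_set(records: list[PatientRecord],
                       labels: dict[str, EventLabel | None],
                       event: str, tier: str, horizon_h: int,
                       config: InstanceSamplingConfig) -> list[Instance]:
    """Sample instances across a cohort for one (event, tier).

    Negative prediction times are, by default, drawn to match the
    empirical distribution of the positive prediction times
    (time-matched controls).  Positive instances necessarily sit late in
    the stay (at least the drift lead past admission); uniformly drawn
    negatives would let a classifier score on elapsed time alone rather
    than on physiology, so each negative time is sampled near a randomly
    drawn positive time and assigned to a random patient whose
    event-free window admits it.
    """
    rng = np.random.default_rng(config.seed)
    positives: list[Instance] = []
    n_pos = min(config.n_pos_per_patient, horizon_h)
    neg_hours: dict[str, np.ndarray] = {}
    by_pid: dict[str, PatientRecord] = {}
    for record in records:
        label = labels.get(record.patient_id)
        by_pid[record.patient_id] = record
        positives.extend(sample_instances(record, label, event, tier,
                                          horizon_h, n_pos, 0, rng))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hours = admissible_negative_hours(
                record, label if (label and label.event == event) else None,
                horizon_h)
        if len(hours):
            neg_hours[record.patient_id] = hours

    n_neg_total = config.max_negatives if config.max_negatives is not None \
        else config.n_neg_per_patient * len(records)
    pos_times = np.array([i.prediction_time for i in positives])
    negatives: list[Instance] = []
    taken: set[tuple[str, float]] = set()

    if config.match_positive_times and len(pos_times):
        # hour -> patients whose event-free window admits it
        admitting: dict[int, list[str]] = {}
        for pid, hours in neg_hours.items():
            for h in hours:
                admitting.setdefault(int(h), []).append(pid)
        attempts = 0
        while len(negatives) < n_neg_total and attempts < 20 * n_neg_total:
            attempts += 1
            t = int(rng.choice(pos_times)) + int(rng.integers(-2, 3))
            pids = admitting.get(t)
            if not pids:
                continue
            pid = pids[rng.integers(len(pids))]
            if (pid, float(t)) in taken:
                continue
            taken.add((pid, float(t)))
            negatives.append(Instance(
                pid, event, tier, build_feature_grid(by_pid[pid], float(t)),
                0, float(t)))
    else:
        pairs = [(pid, float(h)) for pid, hours in neg_hours.items()
                 for h in hours]
        take = rng.choice(len(pairs), size=min(n_neg_total, len(pairs)),
                          replace=False)
        for k in sorted(take):
            pid, t = pairs[k]
            negatives.append(Instance(
                pid, event, tier, build_feature_grid(by_pid[pid], t), 0, t))
    return positives + negatives


def check_instance_label(instance: Instance,
                         label: EventLabel | None,
                         horizon_h: int) -> bool:
    """Re-derive the binary label from the event label and the window
    rule; used by the hygiene checks."""
    t = instance.prediction_time
    if label is not None and label.event == instance.event:
        if label.onset - horizon_h <= t < label.onset:
            return instance.label == 1
        if t + horizon_h < label.onset:
            return instance.label == 0
        return False  # ambiguous zone should never be sampled
    return instance.label == 0
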