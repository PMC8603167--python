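"""Synthetic ICU cohort generator.

The hospital cohorts this pipeline was designed around are not publicly
deposited, so this module generates stand-in stays: multichannel
physiological time series with channel-specific sampling cadence and
missingness, demographics, and planted adverse events (death, sepsis,
AKI) at the development cohort's prevalences.

Two properties are guaranteed *by construction*, not statistically:

* **Detectability** — every planted event's signature crosses the
  corresponding labeling rule exactly at the planted onset (protected
  observations carry the signature and are never dropped by the
  missingness simulator).
* **Specificity** — patients without a planted event are generated inside
  sub-threshold clip bands, so no labeling rule can fire on them.

Each channel follows a mean-reverting (AR(1)) fluctuation around a
patient-specific baseline.  A planted event adds a deterministic linear
drift ramp to a set of channels, starting ``drift_lead`` hours before
onset, so that instances sampled at nearer horizons carry strictly more
signal — the mechanism behind horizon-ordered model performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .channels import CHANNELS, CHANNEL_NAMES, ChannelSpec
from .horizons import HORIZON_HOURS
from .records import (
    ChannelSeries,
    ClinicalEvent,
    GroundTruth,
    PatientRecord,
    UrineOutput,
)

EVENTS = ("death", "sepsis", "aki")


class ConfigurationError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Default prevalences follow the development cohort (death 3.6%,
    sepsis 3.12%, AKI 9.1%).  Stay lengths are lognormal with a mean
    near 2.5 days, clipped to [36 h, 96 h] to keep hourly grids at desk
    scale.  ``drift_lead_h`` must be at least the longest horizon (T3)
    for its event so that even distant-horizon instances see the ramp.
    """

    n_patients: int = 500
    prevalence: dict[str, float] = field(
        default_factory=lambda: {"death": 0.036, "sepsis": 0.0312,
                                 "aki": 0.091})
    stay_mean_h: float = 60.0
    stay_sigma: float = 0.45          # lognormal shape
    stay_min_h: float = 36.0
    stay_max_h: float = 96.0
    missing_rate: dict[str, float] = field(default_factory=dict)
    drift_lead_h: dict[str, float] = field(
        default_factory=lambda: {"death": 16.0, "sepsis": 10.0, "aki": 16.0})
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        for ev, p in self.prevalence.items():
            if ev not in EVENTS:
                raise ConfigurationError(f"unknown event in prevalence: {ev}")
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"prevalence[{ev}] = {p} outside [0, 1]")
        if sum(self.prevalence.values()) > 1.0 + 1e-12:
            raise ConfigurationError(
                "prevalence values must sum with the no-event fraction to 1 "
                f"(got sum {sum(self.prevalence.values()):.4f} > 1)")
        for ch, r in self.missing_rate.items():
            if ch not in CHANNELS:
                raise ConfigurationError(f"unknown channel in missing_rate: {ch}")
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(
                    f"missing_rate[{ch}] = {r} outside [0, 1]")
        for ev, lead in self.drift_lead_h.items():
            t3 = HORIZON_HOURS[ev][2]
            if lead < t3:
                raise ConfigurationError(
                    f"drift_lead_h[{ev}] = {lead} shorter than T3 = {t3}")


# Default channel-specific missingness emulating charting practice:
# vitals are near-continuous, labs sparser still after their cadence.
DEFAULT_MISSING_RATE: dict[str, float] = {
    **{c.name: 0.10 for c in CHANNELS.values() if c.kind == "vital"},
    **{c.name: 0.20 for c in CHANNELS.values() if c.kind == "lab"},
    "gcs": 0.20,
}


# drift ramp targets (delta reached at onset), per event, in channel units
DRIFT_TARGETS: dict[str, dict[str, float]] = {
    "death": {
        "heart_rate": 30.0, "sbp": -30.0, "dbp": -15.0, "resp_rate": 9.0,
        "temperature": 1.0, "spo2": -8.0, "gcs": -5.0, "lactate": 2.2,
    },
    "sepsis": {
        "heart_rate": 22.0, "sbp": -18.0, "dbp": -8.0, "resp_rate": 6.0,
        "temperature": 1.6, "spo2": -4.0, "wbc": 7.0, "gcs": -2.0,
        # lactate ramps separately (sub-threshold before onset)
    },
    "aki": {
        # creatinine handled by the dedicated signature; the rest of the
        # renal syndrome (azotemia, hyperkalemia, mild hemodynamic and
        # respiratory response) is free signal — no labeling rule reads it
        "bun": 28.0, "potassium": 0.9, "heart_rate": 12.0, "sbp": -12.0,
        "resp_rate": 4.0,
    },
}

# sub-threshold safety clips, relative to the patient baseline b, applied
# to every patient (event signatures override where stated)
_CREAT_BAND = 0.10          # non-AKI creatinine stays in b +/- 0.10
_LACTATE_CAP = 1.8          # below the 2.0 "elevated" threshold
_BILI_CAP = 1.9             # below the 2.0 dysfunction floor
_PLATE_BAND = 0.20          # +/- 20% of baseline (>= 150) floor 120 > 100
_AKI_RAMP = 0.22            # pre-onset creatinine drift (sub-threshold)
_AKI_JUMP = 0.55            # onset-time creatinine elevation above baseline
_AKI_CREAT_BASE = (0.8, 1.3)


def _obs_times(rng: np.random.Generator, interval: float, t_lo: float,
               t_hi: float) -> np.ndarray:
    """Observation times at roughly `interval` spacing with jitter."""
    if t_hi <= t_lo:
        return np.empty(0)
    n = max(1, int(np.ceil((t_hi - t_lo) / interval)) + 1)
    steps = interval * rng.uniform(0.7, 1.3, size=n)
    times = t_lo + interval * rng.uniform(0.0, 0.8) + np.cumsum(steps) - steps[0]
    return times[times <= t_hi]


def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    z = rng.normal(size=n)
    innov = sd * np.sqrt(max(1.0 - rho ** 2, 1e-12)) * z
    innov[0] = sd * z[0]
    return lfilter([1.0], [1.0, -rho], innov)


def _ramp(times: np.ndarray, onset: float, lead: float) -> np.ndarray:
    """Linear drift progress in [0, 1]: 0 before onset-lead, 1 from onset on."""
    return np.clip((times - (onset - lead)) / lead, 0.0, 1.0)


def _series(rng: np.random.Generator, spec: ChannelSpec, baseline: float,
            t_hi: float, drift: float = 0.0, onset: float = np.inf,
            lead: float = 1.0, lo: float | None = None,
            hi: float | None = None, t_lo: float = 0.0,
            interval: float | None = None) -> ChannelSeries:
    times = _obs_times(rng, interval or spec.interval_h, t_lo, t_hi)
    rho = float(np.exp(-spec.mean_reversion * spec.interval_h))
    vals = baseline + _ar1(rng, len(times), spec.noise_sd, rho)
    if drift != 0.0 and np.isfinite(onset):
        vals = vals + drift * _ramp(times, onset, lead)
    vals = np.clip(vals, spec.lo if lo is None else max(lo, spec.lo),
                   spec.hi if hi is None else min(hi, spec.hi))
    return ChannelSeries(times, vals, np.zeros(len(times), dtype=bool))


def _baseline(rng: np.random.Generator, spec: ChannelSpec) -> float:
    margin = 2.0 * spec.noise_sd
    return float(np.clip(rng.normal(spec.normal, spec.baseline_sd),
                         spec.lo + margin, spec.hi - margin))


def _generate_base_record(rng: np.random.Generator, pid: str,
                          stay_h: float) -> tuple[PatientRecord, dict[str, float]]:
    """An uneventful stay: all channels inside their sub-threshold bands."""
    age = float(np.clip(rng.normal(61.0, 15.0), 18.0, 99.0))
    sex = "M" if rng.random() < 0.57 else "F"
    baselines: dict[str, float] = {}
    obs: dict[str, ChannelSeries] = {}
    for name in CHANNEL_NAMES:
        spec = CHANNELS[name]
        b = _baseline(rng, spec)
        lo = hi = None
        if name == "creatinine":
            b = float(rng.uniform(0.6, 1.3))
            lo, hi = b - _CREAT_BAND, b + _CREAT_BAND
        elif name == "lactate":
            b = float(np.clip(rng.normal(1.0, 0.2), 0.4, 1.5))
            hi = _LACTATE_CAP
        elif name == "bilirubin":
            b = float(np.clip(rng.normal(0.7, 0.2), 0.2, 1.4))
            hi = _BILI_CAP
        elif name == "platelets":
            b = float(rng.uniform(150.0, 350.0))
            lo, hi = (1 - _PLATE_BAND) * b, (1 + _PLATE_BAND) * b
        baselines[name] = b
        obs[name] = _series(rng, spec, b, stay_h, lo=lo, hi=hi)
    if len(obs["gcs"]):
        obs["gcs"].values = np.round(obs["gcs"].values)

    hours = np.arange(1.0, np.floor(stay_h) + 1.0)
    rates = np.clip(rng.normal(1.0, 0.15, size=len(hours)), 0.7, 1.5)
    weight = float(np.clip(rng.normal(70.0, 12.0), 40.0, 120.0))
    urine = UrineOutput(hours, rates * weight, rates)

    record = PatientRecord(patient_id=pid, age=age, sex=sex,
                           discharge_time=float(stay_h), observations=obs,
                           urine=urine)
    return record, baselines


def _redraw_channel(rng: np.random.Generator, record: PatientRecord,
                    name: str, baseline: float, drift: float, onset: float,
                    lead: float, lo: float | None = None,
                    hi: float | None = None,
                    interval: float | None = None) -> None:
    spec = CHANNELS[name]
    s = _series(rng, spec, baseline, record.discharge_time, drift=drift,
                onset=onset, lead=lead, lo=lo, hi=hi, interval=interval)
    if name == "gcs":
        s.values = np.round(s.values)
    record.observations[name] = s


def plant_event(record: PatientRecord, event: str, onset: float,
                lead: float, rng: np.random.Generator,
                baselines: dict[str, float] | None = None) -> PatientRecord:
    """Overwrite a base record's trajectories with an event signature.

    * death — vitals and GCS deteriorate along the ramp; death time and
      discharge are set to the onset.
    * sepsis — a blood culture at onset paired with a new 3-day
      antibiotic course; lactate crosses the elevation threshold at
      onset + 2 h (the organ dysfunction), so the labeled onset
      min(infection, dysfunction) equals the planted onset exactly.
    * AKI — creatinine drifts sub-threshold along the ramp, then a
      protected measurement at onset jumps 0.55 mg/dL above baseline,
      crossing the 0.3 mg/dL-in-48-h rule at onset and nowhere earlier.
    """
    if event not in EVENTS:
        raise ValueError(f"unknown event {event!r}")
    if not 0.0 < onset <= record.discharge_time:
        raise ValueError(f"onset {onset} outside stay "
                         f"(0, {record.discharge_time}]")
    if onset - lead < 0:
        raise ValueError("onset minus drift lead precedes admission")
    record = record.copy()
    if baselines is None:
        baselines = {name: CHANNELS[name].normal for name in CHANNEL_NAMES}

    if event == "death":
        record.discharge_time = float(onset)
        record.death_time = float(onset)
        for name, series in record.observations.items():
            keep = series.times <= onset
            record.observations[name] = ChannelSeries(
                series.times[keep], series.values[keep], series.protected[keep])
        keep = record.urine.end_times <= onset
        record.urine = UrineOutput(record.urine.end_times[keep],
                                   record.urine.volumes_ml[keep],
                                   record.urine.rates_ml_kg_h[keep])
        for name, delta in DRIFT_TARGETS["death"].items():
            lo = hi = None
            if name == "lactate":
                lo, hi = None, None  # free: no infection, so no sepsis risk
            _redraw_channel(rng, record, name, baselines.get(
                name, CHANNELS[name].normal), delta, onset, lead, lo=lo, hi=hi)

    elif event == "sepsis":
        record.discharge_time = float(
            max(record.discharge_time, onset + 54.0))
        for name, delta in DRIFT_TARGETS["sepsis"].items():
            _redraw_channel(rng, record, name, baselines.get(
                name, CHANNELS[name].normal), delta, onset, lead)
        # lactate: sub-threshold ramp before onset+2, elevated after
        spec = CHANNELS["lactate"]
        b = baselines.get("lactate", 1.0)
        pre = _series(rng, spec, b, onset + 2.0, drift=0.9, onset=onset,
                      lead=lead, hi=_LACTATE_CAP)
        keep = pre.times < onset + 2.0
        post_t = _obs_times(rng, spec.interval_h, onset + 2.0,
                            record.discharge_time)
        post_v = np.clip(3.0 + 0.3 * rng.normal(size=len(post_t)), 2.2, 4.5)
        times = np.concatenate([pre.times[keep], [onset + 2.0], post_t])
        vals = np.concatenate([pre.values[keep], [3.2], post_v])
        prot = np.zeros(len(times), dtype=bool)
        prot[len(pre.times[keep])] = True  # the dysfunction-defining draw
        record.observations["lactate"] = ChannelSeries(times, vals, prot)
        agent = "cefepime"
        record.clinical_events = [e for e in record.clinical_events
                                  if e.kind not in ("antibiotic",
                                                    "blood_culture")]
        record.clinical_events.append(ClinicalEvent("blood_culture", onset))
        for k in range(3):
            record.clinical_events.append(
                ClinicalEvent("antibiotic", onset + 24.0 * k, agent))
        # extend urine cover to the (possibly extended) discharge
        hours = np.arange(1.0, np.floor(record.discharge_time) + 1.0)
        if len(hours) > len(record.urine.end_times):
            extra = len(hours) - len(record.urine.end_times)
            rates = np.concatenate([
                record.urine.rates_ml_kg_h,
                np.clip(rng.normal(1.0, 0.15, size=extra), 0.7, 1.5)])
            w = (record.urine.volumes_ml[0] / record.urine.rates_ml_kg_h[0]
                 if len(record.urine) else 70.0)
            record.urine = UrineOutput(hours, rates * w, rates)

    else:  # aki
        record.discharge_time = float(
            max(record.discharge_time, onset + 12.0))
        for name, delta in DRIFT_TARGETS["aki"].items():
            # labs are re-ordered more frequently in deteriorating patients
            interval = 6.0 if CHANNELS[name].kind == "lab" else None
            _redraw_channel(rng, record, name, baselines.get(
                name, CHANNELS[name].normal), delta, onset, lead,
                interval=interval)
        spec = CHANNELS["creatinine"]
        b = baselines.get("creatinine", 1.0)
        b = float(np.clip(b, *_AKI_CREAT_BASE))
        pre = _obs_times(rng, 5.0, 0.0, onset - 0.5)
        pre_v = np.clip(
            b + _AKI_RAMP * _ramp(pre, onset, lead)
            + np.clip(rng.normal(0.0, 0.02, size=len(pre)), -0.03, 0.03),
            b - 0.03, b + _AKI_RAMP + 0.03)
        post_t = _obs_times(rng, spec.interval_h, onset + 0.5,
                            record.discharge_time)
        post_v = np.clip(b + _AKI_JUMP + 0.05 * rng.normal(size=len(post_t)),
                         b + 0.5, b + 0.9)
        times = np.concatenate([pre, [onset], post_t])
        vals = np.concatenate([pre_v, [b + _AKI_JUMP], post_v])
        prot = np.zeros(len(times), dtype=bool)
        prot[len(pre)] = True                      # the onset measurement
        if len(pre):
            prot[len(pre) - 1] = True              # a sub-threshold anchor
        record.observations["creatinine"] = ChannelSeries(times, vals, prot)

    record.validate()
    return record


def apply_missingness(record: PatientRecord, rates: dict[str, float],
                      seed: int | np.random.Generator) -> PatientRecord:
    """Drop each observation independently at its channel's rate.

    Protected observations (event signatures) are always retained, so
    planted onsets stay recoverable.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    for r in rates.values():
        if not 0.0 <= r <= 1.0:
            raise ConfigurationError(f"missingness rate {r} outside [0, 1]")
    record = record.copy()
    for name, rate in rates.items():
        if rate == 0.0 or name not in record.observations:
            continue
        s = record.observations[name]
        keep = (rng.random(len(s)) >= rate) | s.protected
        record.observations[name] = ChannelSeries(
            s.times[keep], s.values[keep], s.protected[keep])
    return record


def generate_cohort(config: GeneratorConfig,
                    ) -> tuple[list[PatientRecord], GroundTruth]:
    """Generate ``config.n_patients`` stays with planted events.

    Event assignment is an independent categorical draw per patient at
    the configured prevalences (at most one event per patient; each event
    is treated as an independent outcome downstream).  Fully
    deterministic for a fixed config and seed.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_patients)
    p = [config.prevalence.get(ev, 0.0) for ev in EVENTS]
    p.append(1.0 - sum(p))

    records: list[PatientRecord] = []
    truth: dict[str, tuple[str, float] | None] = {}
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pid = f"P{i:06d}"
        stay_h = float(np.clip(
            np.exp(rng.normal(np.log(config.stay_mean_h), config.stay_sigma)),
            config.stay_min_h, config.stay_max_h))
        record, baselines = _generate_base_record(rng, pid, stay_h)
        choice = rng.choice(4, p=p)
        if choice < 3:
            event = EVENTS[choice]
            lead = config.drift_lead_h[event]
            onset = float(np.round(rng.uniform(
                lead + 2.0, max(lead + 8.0, stay_h - 4.0)), 1))
            record = plant_event(record, event, onset, lead, rng, baselines)
            truth[pid] = (event, onset)
        else:
            truth[pid] = None
            # decoys: lone cultures / unpaired antibiotic courses
            u = rng.random()
            if u < 0.10:
                record.clinical_events.append(ClinicalEvent(
                    "blood_culture", float(rng.uniform(2.0, stay_h - 2.0))))
            elif u < 0.15:
                t0 = float(rng.uniform(2.0, max(2.1, stay_h - 50.0)))
                for k in range(3):
                    record.clinical_events.append(ClinicalEvent(
                        "antibiotic", t0 + 24.0 * k, "vancomycin"))
                record.discharge_time = max(record.discharge_time, t0 + 49.0)
        if config.missing_rate:
            record = apply_missingness(record, config.missing_rate, rng)
        records.append(record)
    return records, GroundTruth(truth)
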