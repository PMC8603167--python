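"""Algorithmic event labeling from an ICU stay record.

Three working definitions are implemented:

* **Mortality** — an in-ICU death recorded in the EMR (death time within
  the stay).
* **Sepsis** (clinical-surveillance style) — a *suspected serious
  infection* (blood culture paired with sustained administration of a
  newly started antibiotic) with at least one concurrent acute organ
  dysfunction in the window from 48 hours before to 24 hours after the
  infection time.  Organ dysfunction is vasopressor or mechanical
  ventilation initiation, elevated lactate, or a significant change from
  baseline in creatinine, bilirubin, or platelet count.
* **AKI** (KDIGO) — serum creatinine rise >= 0.3 mg/dL within 48 hours,
  creatinine reaching >= 1.5x the lowest value in the prior 7 days, or
  urine output < 0.5 mL/kg/h sustained for 6 hours.  Onset is anchored at
  the qualifying creatinine measurement (urine: end of the qualifying
  6-hour window).

The surveillance definition leaves several thresholds unstated; the
defaults used here live in :data:`SepsisThresholds` and are deliberately
an editable table, not constants scattered through the code.  All
labelers use earliest-time semantics: the reported onset is the first
time any criterion holds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import EventLabel, PatientRecord

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class SepsisThresholds:
    """Surveillance-sepsis operational thresholds (editable defaults)."""

    lactate_mmol_l: float = 2.0           # "elevated lactate"
    creatinine_ratio: float = 2.0         # x stay baseline (lowest prior)
    bilirubin_mg_dl: float = 2.0          # absolute floor ...
    bilirubin_ratio: float = 2.0          # ... and x baseline (lowest prior)
    platelet_abs: float = 100.0           # 10^3/uL ceiling ...
    platelet_decline: float = 0.5         # ... and >= 50% drop from peak
    culture_pairing_window_h: float = 24.0  # |culture - new abx start|
    sustained_days: int = 3               # consecutive calendar days
    new_agent_lookback_h: float = 48.0    # "new" = not given in prior 48 h
    window_before_h: float = 48.0         # dysfunction window around infection
    window_after_h: float = 24.0


DEFAULT_SEPSIS = SepsisThresholds()

AKI_CREATININE_DELTA = 0.3        # mg/dL within 48 h
AKI_CREATININE_RATIO = 1.5        # x 7-day baseline
AKI_DELTA_WINDOW_H = 48.0
AKI_BASELINE_WINDOW_H = 7 * 24.0
AKI_URINE_RATE = 0.5              # mL/kg/h
AKI_URINE_HOURS = 6.0


@dataclass(frozen=True)
class SuspectedInfection:
    culture_time: float
    antibiotic_start: float
    infection_time: float     # min of the pair


@dataclass(frozen=True)
class OrganDysfunction:
    kind: str   # vasopressor_initiation | mechanical_ventilation |
    #             elevated_lactate | creatinine_change | bilirubin_change |
    #             platelet_decline
    time: float


# ---------------------------------------------------------------------------
# suspected infection


def _sustained_new_courses(record: PatientRecord,
                           thresholds: SepsisThresholds) -> list[float]:
    """Start times of antibiotic courses that are both *new* (same agent not
    given in the preceding lookback window) and *sustained* (same agent
    administered on >= `sustained_days` consecutive calendar days counted
    from the start's calendar day)."""
    by_agent: dict[str, list[float]] = {}
    for ev in record.events_of("antibiotic"):
        by_agent.setdefault(ev.detail, []).append(ev.time)
    starts: list[float] = []
    for times in by_agent.values():
        times = sorted(times)
        days = {int(np.floor(t / HOURS_PER_DAY)) for t in times}
        for i, t in enumerate(times):
            if i > 0 and t - times[i - 1] < thresholds.new_agent_lookback_h:
                continue  # not new: same agent given recently
            d0 = int(np.floor(t / HOURS_PER_DAY))
            if all(d0 + k in days for k in range(thresholds.sustained_days)):
                starts.append(t)
    return sorted(starts)


def detect_suspected_infection(
        record: PatientRecord,
        thresholds: SepsisThresholds = DEFAULT_SEPSIS,
) -> list[SuspectedInfection]:
    """Pair each blood culture with each qualifying new antibiotic course
    started within the pairing window; infection time is the earlier of
    the pair.  Sorted by infection time."""
    cultures = [ev.time for ev in record.events_of("blood_culture")]
    starts = _sustained_new_courses(record, thresholds)
    found = [
        SuspectedInfection(c, s, min(c, s))
        for c in cultures for s in starts
        if abs(c - s) <= thresholds.culture_pairing_window_h
    ]
    return sorted(found, key=lambda x: x.infection_time)


# ---------------------------------------------------------------------------
# organ dysfunction


def detect_organ_dysfunction(
        record: PatientRecord,
        thresholds: SepsisThresholds = DEFAULT_SEPSIS,
) -> list[OrganDysfunction]:
    """First time each dysfunction criterion holds.

    Baselines are running extremes over the stay so far: lowest prior
    creatinine/bilirubin, highest prior platelet count (the best value
    before the candidate measurement)."""
    out: list[OrganDysfunction] = []

    vaso = record.events_of("vasopressor")
    if vaso:
        out.append(OrganDysfunction("vasopressor_initiation", vaso[0].time))
    vent = record.events_of("ventilation_start")
    if vent:
        out.append(OrganDysfunction("mechanical_ventilation", vent[0].time))

    lact = record.channel("lactate")
    hit = np.nonzero(lact.values >= thresholds.lactate_mmol_l)[0]
    if hit.size:
        out.append(OrganDysfunction("elevated_lactate", lact.times[hit[0]]))

    creat = record.channel("creatinine")
    for i in range(1, len(creat)):
        base = creat.values[:i].min()
        if base > 0 and creat.values[i] >= thresholds.creatinine_ratio * base:
            out.append(OrganDysfunction("creatinine_change", creat.times[i]))
            break

    bili = record.channel("bilirubin")
    for i in range(1, len(bili)):
        base = bili.values[:i].min()
        if (bili.values[i] >= thresholds.bilirubin_mg_dl
                and base > 0
                and bili.values[i] >= thresholds.bilirubin_ratio * base):
            out.append(OrganDysfunction("bilirubin_change", bili.times[i]))
            break

    plate = record.channel("platelets")
    for i in range(1, len(plate)):
        base = plate.values[:i].max()
        if (plate.values[i] < thresholds.platelet_abs
                and plate.values[i] <=
                (1.0 - thresholds.platelet_decline) * base):
            out.append(OrganDysfunction("platelet_decline", plate.times[i]))
            break

    return sorted(out, key=lambda d: d.time)


# ---------------------------------------------------------------------------
# labelers


def label_sepsis(record: PatientRecord,
                 thresholds: SepsisThresholds = DEFAULT_SEPSIS,
                 ) -> EventLabel | None:
    """Sepsis iff some organ dysfunction lies within
    [infection - 48 h, infection + 24 h] for some suspected infection.

    Onset convention: min(infection time, earliest in-window dysfunction
    time), minimized over all qualifying (infection, dysfunction) pairs.
    """
    infections = detect_suspected_infection(record, thresholds)
    if not infections:
        return None
    dysfunctions = detect_organ_dysfunction(record, thresholds)
    if not dysfunctions:
        return None
    best: float | None = None
    best_kind = ""
    for inf in infections:
        lo = inf.infection_time - thresholds.window_before_h
        hi = inf.infection_time + thresholds.window_after_h
        for dys in dysfunctions:
            if lo <= dys.time <= hi:
                onset = min(inf.infection_time, dys.time)
                if best is None or onset < best:
                    best, best_kind = onset, dys.kind
    if best is None:
        return None
    return EventLabel("sepsis", best, best_kind)


def label_aki(record: PatientRecord) -> EventLabel | None:
    """Earliest KDIGO criterion crossing.

    Creatinine criteria are anchored at the qualifying measurement's time;
    pre-ICU values (negative times) contribute to baselines but are never
    themselves onsets.  Ties at the same hour resolve by criterion
    priority delta > ratio > urine (metadata only).
    """
    candidates: list[tuple[float, int, str]] = []  # (onset, priority, name)

    creat = record.channel("creatinine")
    for i in range(len(creat)):
        t, v = creat.times[i], creat.values[i]
        if t < 0:
            continue
        prior = creat.times < t
        in48 = prior & (creat.times >= t - AKI_DELTA_WINDOW_H)
        if np.any(in48) and v - creat.values[in48].min() >= AKI_CREATININE_DELTA:
            candidates.append((t, 0, "creatinine_delta"))
        in7d = prior & (creat.times >= t - AKI_BASELINE_WINDOW_H)
        if np.any(in7d) and v >= AKI_CREATININE_RATIO * creat.values[in7d].min():
            candidates.append((t, 1, "creatinine_ratio"))

    urine = record.urine
    if len(urine):
        n_hours = int(round(AKI_URINE_HOURS))
        below = urine.rates_ml_kg_h < AKI_URINE_RATE
        # qualifying window: n_hours consecutive hourly intervals all below
        run = 0
        for i in range(len(urine)):
            contiguous = (i > 0 and
                          abs(urine.end_times[i] - urine.end_times[i - 1] - 1.0)
                          < 1e-6)
            run = (run + 1 if below[i] and (run == 0 or contiguous) else
                   (1 if below[i] else 0))
            if run >= n_hours:
                candidates.append((urine.end_times[i], 2, "urine_output"))
                break

    if not candidates:
        return None
    onset, _, name = min(candidates)
    return EventLabel("aki", onset, name)


def label_mortality(record: PatientRecord) -> EventLabel | None:
    """In-ICU death: death time recorded and within the stay."""
    if record.death_time is None:
        return None
    if record.death_time > record.discharge_time + 1e-9:
        return None  # event after the ICU stay; such patients are excluded
    return EventLabel("death", record.death_time, "in_icu_death")


LABELERS = {
    "death": label_mortality,
    "sepsis": label_sepsis,
    "aki": label_aki,
}


def label_record(record: PatientRecord) -> dict[str, EventLabel | None]:
    """Apply all three labelers; each event is an independent outcome."""
    return {event: fn(record) for event, fn in LABELERS.items()}
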