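"""SOFA and APACHE-II severity scores as comparator risk rankings.

Both scores are computed from a :class:`ClinicalSnapshot` holding the
worst value of each component over the scoring window — by convention
here, the 24 hours preceding the prediction time, applied to both scores
for comparability.

Two documented surrogates adapt the published tables to the 18-channel
panel, which carries neither arterial PaO2 nor hematocrit:

* the respiratory components are scored from SpO2 bands (ventilation
  escalates the two worst SOFA bands, per the original table's intent);
* APACHE-II hematocrit is approximated as 3 x hemoglobin (g/dL).

A missing component scores 0 and lowers the completeness flag; a value
outside its scoring table's physiologic domain raises a domain error
naming the component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channels import CHANNELS
from .records import PatientRecord


class ScoreDomainError(ValueError):
    pass


@dataclass
class ClinicalSnapshot:
    """Worst-in-window component values; None marks missing."""

    spo2: float | None = None             # %
    on_ventilator: bool = False
    platelets: float | None = None        # 10^3/uL
    bilirubin: float | None = None        # mg/dL
    map_mmhg: float | None = None         # mean arterial pressure
    on_vasopressor: bool = False
    gcs: float | None = None
    creatinine: float | None = None       # mg/dL
    urine_ml_day: float | None = None
    # APACHE-II extras
    temperature: float | None = None      # degC
    heart_rate: float | None = None
    resp_rate: float | None = None
    ph: float | None = None
    sodium: float | None = None           # mmol/L
    potassium: float | None = None
    hematocrit: float | None = None       # %
    wbc: float | None = None              # 10^3/uL
    age: float | None = None              # years
    chronic_health: bool = False
    window_h: float = 24.0


def _check(name: str, value: float, lo: float, hi: float) -> None:
    if not lo <= value <= hi:
        raise ScoreDomainError(
            f"{name} = {value} outside scoring domain [{lo}, {hi}]")


def _band(value: float, bands: list[tuple[float, int]], default: int) -> int:
    """First (threshold, points) band whose threshold the value crosses."""
    for thr, pts in bands:
        if value >= thr:
            return pts
    return default


# ---------------------------------------------------------------------------
# SOFA


def sofa_score(s: ClinicalSnapshot) -> tuple[int, dict[str, int], bool]:
    """Total SOFA (0-24), per-organ subscores (each 0-4), completeness.

    Missing components score 0; completeness is False if any of the six
    organ systems lacked data."""
    sub: dict[str, int] = {}
    complete = True

    if s.spo2 is None:
        sub["respiration"], complete = 0, False
    else:
        _check("spo2", s.spo2, 0, 100)
        if s.spo2 >= 96:
            sub["respiration"] = 0
        elif s.spo2 >= 94:
            sub["respiration"] = 1
        elif s.spo2 >= 90:
            sub["respiration"] = 2
        elif s.spo2 >= 85:
            sub["respiration"] = 3 if s.on_ventilator else 2
        else:
            sub["respiration"] = 4 if s.on_ventilator else 2

    if s.platelets is None:
        sub["coagulation"], complete = 0, False
    else:
        _check("platelets", s.platelets, 0, 2000)
        p = s.platelets
        sub["coagulation"] = (0 if p >= 150 else 1 if p >= 100
                              else 2 if p >= 50 else 3 if p >= 20 else 4)

    if s.bilirubin is None:
        sub["liver"], complete = 0, False
    else:
        _check("bilirubin", s.bilirubin, 0, 80)
        b = s.bilirubin
        sub["liver"] = (0 if b < 1.2 else 1 if b < 2.0
                        else 2 if b < 6.0 else 3 if b < 12.0 else 4)

    if s.on_vasopressor:
        # a binary vasopressor flag cannot resolve the dose-dependent
        # 2/3/4 bands; any vasopressor scores 3 (documented simplification)
        sub["cardiovascular"] = 3
    elif s.map_mmhg is None:
        sub["cardiovascular"], complete = 0, False
    else:
        _check("map", s.map_mmhg, 0, 300)
        sub["cardiovascular"] = 0 if s.map_mmhg >= 70 else 1

    if s.gcs is None:
        sub["cns"], complete = 0, False
    else:
        _check("gcs", s.gcs, 3, 15)
        g = s.gcs
        sub["cns"] = (0 if g >= 15 else 1 if g >= 13
                      else 2 if g >= 10 else 3 if g >= 6 else 4)

    if s.creatinine is None and s.urine_ml_day is None:
        sub["renal"], complete = 0, False
    else:
        pts = 0
        if s.creatinine is not None:
            _check("creatinine", s.creatinine, 0, 30)
            c = s.creatinine
            pts = (0 if c < 1.2 else 1 if c < 2.0
                   else 2 if c < 3.5 else 3 if c < 5.0 else 4)
        if s.urine_ml_day is not None:
            _check("urine_ml_day", s.urine_ml_day, 0, 20000)
            u = s.urine_ml_day
            pts = max(pts, 4 if u < 200 else 3 if u < 500 else 0)
        sub["renal"] = pts

    return sum(sub.values()), sub, complete


# ---------------------------------------------------------------------------
# APACHE-II

_AGE_POINTS = [(75, 6), (65, 5), (55, 3), (45, 2)]


def _apache_physiology(s: ClinicalSnapshot) -> tuple[int, bool]:
    pts = 0
    complete = True

    def miss() -> None:
        nonlocal complete
        complete = False

    if s.temperature is None:
        miss()
    else:
        _check("temperature", s.temperature, 25, 46)
        t = s.temperature
        pts += (4 if t >= 41 else 3 if t >= 39 else 1 if t >= 38.5
                else 0 if t >= 36 else 1 if t >= 34 else 2 if t >= 32
                else 3 if t >= 30 else 4)
    if s.map_mmhg is None:
        miss()
    else:
        m = s.map_mmhg
        pts += (4 if m >= 160 else 3 if m >= 130 else 2 if m >= 110
                else 0 if m >= 70 else 2 if m >= 50 else 4)
    if s.heart_rate is None:
        miss()
    else:
        _check("heart_rate", s.heart_rate, 0, 300)
        h = s.heart_rate
        pts += (4 if h >= 180 else 3 if h >= 140 else 2 if h >= 110
                else 0 if h >= 70 else 2 if h >= 55 else 3 if h >= 40 else 4)
    if s.resp_rate is None:
        miss()
    else:
        _check("resp_rate", s.resp_rate, 0, 120)
        r = s.resp_rate
        pts += (4 if r >= 50 else 3 if r >= 35 else 1 if r >= 25
                else 0 if r >= 12 else 1 if r >= 10 else 2 if r >= 6 else 4)
    if s.spo2 is None:
        miss()
    else:
        # oxygenation via SpO2 surrogate bands (no PaO2/FiO2 in the panel)
        o = s.spo2
        pts += 0 if o >= 94 else 1 if o >= 90 else 3 if o >= 86 else 4
    if s.ph is None:
        miss()
    else:
        _check("ph", s.ph, 6.5, 8.0)
        p = s.ph
        pts += (4 if p >= 7.7 else 3 if p >= 7.6 else 1 if p >= 7.5
                else 0 if p >= 7.33 else 2 if p >= 7.25
                else 3 if p >= 7.15 else 4)
    if s.sodium is None:
        miss()
    else:
        _check("sodium", s.sodium, 90, 200)
        na = s.sodium
        pts += (4 if na >= 180 else 3 if na >= 160 else 2 if na >= 155
                else 1 if na >= 150 else 0 if na >= 130
                else 2 if na >= 120 else 3 if na >= 111 else 4)
    if s.potassium is None:
        miss()
    else:
        _check("potassium", s.potassium, 0.5, 12)
        k = s.potassium
        pts += (4 if k >= 7 else 3 if k >= 6 else 1 if k >= 5.5
                else 0 if k >= 3.5 else 1 if k >= 3
                else 2 if k >= 2.5 else 4)
    if s.creatinine is None:
        miss()
    else:
        c = s.creatinine
        pts += (4 if c >= 3.5 else 3 if c >= 2.0 else 2 if c >= 1.5
                else 0 if c >= 0.6 else 2)
    if s.hematocrit is None:
        miss()
    else:
        _check("hematocrit", s.hematocrit, 5, 80)
        h = s.hematocrit
        pts += (4 if h >= 60 else 2 if h >= 50 else 1 if h >= 46
                else 0 if h >= 30 else 2 if h >= 20 else 4)
    if s.wbc is None:
        miss()
    else:
        _check("wbc", s.wbc, 0, 200)
        w = s.wbc
        pts += (4 if w >= 40 else 2 if w >= 20 else 1 if w >= 15
                else 0 if w >= 3 else 2 if w >= 1 else 4)
    if s.gcs is None:
        miss()
    else:
        pts += int(15 - s.gcs)
    return pts, complete


def apache_ii_score(s: ClinicalSnapshot) -> tuple[int, bool]:
    """APACHE-II total (0-71): acute physiology + age + chronic health."""
    pts, complete = _apache_physiology(s)
    if s.age is None:
        complete = False
    else:
        _check("age", s.age, 0, 130)
        pts += _band(s.age, _AGE_POINTS, 0)
    if s.chronic_health:
        pts += 5  # severe chronic organ insufficiency, nonoperative
    return pts, complete


# ---------------------------------------------------------------------------
# snapshot assembly from a record


def _worst(record: PatientRecord, channel: str, t: float, window: float,
           mode: str) -> float | None:
    s = record.channel(channel)
    sel = (s.times >= t - window) & (s.times <= t)
    if not np.any(sel):
        return None
    v = s.values[sel]
    spec = CHANNELS[channel]
    if mode == "low":
        return float(v.min())
    if mode == "high":
        return float(v.max())
    # "deviant": farthest from the channel's reference midpoint
    return float(v[np.argmax(np.abs(v - spec.normal))])


def snapshot_at(record: PatientRecord, t: float,
                window: float = 24.0) -> ClinicalSnapshot:
    """Worst-in-window snapshot over the ``window`` hours preceding t."""
    sbp = _worst(record, "sbp", t, window, "low")
    dbp = _worst(record, "dbp", t, window, "low")
    map_mmhg = (sbp + 2 * dbp) / 3 if (sbp is not None and dbp is not None) \
        else None
    vaso = any(e.time <= t for e in record.events_of("vasopressor"))
    vent = any(e.time <= t for e in record.events_of("ventilation_start"))
    # an hourly collection ending exactly at t - window covers time
    # entirely outside the window, so the lower bound is strict
    urine_sel = ((record.urine.end_times > t - window)
                 & (record.urine.end_times <= t))
    urine_day = (float(record.urine.volumes_ml[urine_sel].sum())
                 * 24.0 / max(window, 1e-9)
                 if np.any(urine_sel) else None)
    hgb = _worst(record, "hemoglobin", t, window, "low")
    return ClinicalSnapshot(
        spo2=_worst(record, "spo2", t, window, "low"),
        on_ventilator=vent,
        platelets=_worst(record, "platelets", t, window, "low"),
        bilirubin=_worst(record, "bilirubin", t, window, "high"),
        map_mmhg=map_mmhg,
        on_vasopressor=vaso,
        gcs=_worst(record, "gcs", t, window, "low"),
        creatinine=_worst(record, "creatinine", t, window, "high"),
        urine_ml_day=urine_day,
        temperature=_worst(record, "temperature", t, window, "deviant"),
        heart_rate=_worst(record, "heart_rate", t, window, "deviant"),
        resp_rate=_worst(record, "resp_rate", t, window, "deviant"),
        ph=_worst(record, "ph", t, window, "deviant"),
        sodium=_worst(record, "sodium", t, window, "deviant"),
        potassium=_worst(record, "potassium", t, window, "deviant"),
        hematocrit=3.0 * hgb if hgb is not None else None,
        wbc=_worst(record, "wbc", t, window, "deviant"),
        age=record.age,
        window_h=window,
    )
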