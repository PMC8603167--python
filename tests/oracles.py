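"""Independent brute-force oracles for the labelers and metrics.

Everything here enumerates exhaustively — all positive/negative pairs,
all thresholds, all (culture, antibiotic, dysfunction) combinations, all
measurement pairs and urine windows — with no sliding-window shortcuts,
so the implementations can be checked against a structurally different
computation.
"""

from __future__ import annotations

import numpy as np

from icuward.labeling import (
    AKI_BASELINE_WINDOW_H,
    AKI_CREATININE_DELTA,
    AKI_CREATININE_RATIO,
    AKI_DELTA_WINDOW_H,
    AKI_URINE_HOURS,
    AKI_URINE_RATE,
    DEFAULT_SEPSIS,
)

# ---------------------------------------------------------------------------
# metric oracles


def auroc_brute(labels, scores) -> float:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def auprc_brute(labels, scores) -> float:
    """Average precision by explicit recount at every distinct threshold."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(labels == 1))
    thresholds = sorted(set(scores), reverse=True)
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 0)
        precision = tp / (tp + fp)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def fixed_sensitivity_brute(labels, scores, sensitivity=0.85):
    """(threshold, specificity, f1) by exhaustive threshold enumeration."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    best = None
    for t in sorted(set(scores), reverse=True):
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        if tp / n_pos >= sensitivity:
            best = t
            break
    if best is None:
        best = min(scores)
    tp = sum(1 for s, y in zip(scores, labels) if s >= best and y == 1)
    fp = sum(1 for s, y in zip(scores, labels) if s >= best and y == 0)
    fn = n_pos - tp
    tn = n_neg - fp
    spec = tn / n_neg if n_neg else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return best, spec, f1


# ---------------------------------------------------------------------------
# labeling oracles


def infections_brute(record, thr=DEFAULT_SEPSIS):
    """All (culture, antibiotic-course) pairs by direct enumeration."""
    abx = [(e.detail, e.time) for e in record.clinical_events
           if e.kind == "antibiotic"]
    cultures = [e.time for e in record.clinical_events
                if e.kind == "blood_culture"]
    found = []
    for agent, t in abx:
        is_new = all(not (other_t < t and t - other_t
                          < thr.new_agent_lookback_h)
                     for a2, other_t in abx if a2 == agent)
        days = {int(np.floor(t2 / 24.0)) for a2, t2 in abx if a2 == agent}
        d0 = int(np.floor(t / 24.0))
        sustained = all(d0 + k in days for k in range(thr.sustained_days))
        if not (is_new and sustained):
            continue
        for c in cultures:
            if abs(c - t) <= thr.culture_pairing_window_h:
                found.append((c, t, min(c, t)))
    return sorted(set(found), key=lambda x: x[2])


def dysfunctions_brute(record, thr=DEFAULT_SEPSIS):
    """First time each dysfunction criterion holds, by full scans."""
    out = []
    vaso = [e.time for e in record.clinical_events if e.kind == "vasopressor"]
    if vaso:
        out.append(("vasopressor_initiation", min(vaso)))
    vent = [e.time for e in record.clinical_events
            if e.kind == "ventilation_start"]
    if vent:
        out.append(("mechanical_ventilation", min(vent)))
    lact = record.channel("lactate")
    hits = [t for t, v in zip(lact.times, lact.values)
            if v >= thr.lactate_mmol_l]
    if hits:
        out.append(("elevated_lactate", min(hits)))
    creat = record.channel("creatinine")
    hits = []
    for k in range(len(creat)):
        prior = [creat.values[j] for j in range(len(creat))
                 if creat.times[j] < creat.times[k]]
        if prior and min(prior) > 0 and \
                creat.values[k] >= thr.creatinine_ratio * min(prior):
            hits.append(creat.times[k])
    if hits:
        out.append(("creatinine_change", min(hits)))
    bili = record.channel("bilirubin")
    hits = []
    for k in range(len(bili)):
        prior = [bili.values[j] for j in range(len(bili))
                 if bili.times[j] < bili.times[k]]
        if prior and bili.values[k] >= thr.bilirubin_mg_dl and \
                min(prior) > 0 and \
                bili.values[k] >= thr.bilirubin_ratio * min(prior):
            hits.append(bili.times[k])
    if hits:
        out.append(("bilirubin_change", min(hits)))
    plate = record.channel("platelets")
    hits = []
    for k in range(len(plate)):
        prior = [plate.values[j] for j in range(len(plate))
                 if plate.times[j] < plate.times[k]]
        if prior and plate.values[k] < thr.platelet_abs and \
                plate.values[k] <= (1 - thr.platelet_decline) * max(prior):
            hits.append(plate.times[k])
    if hits:
        out.append(("platelet_decline", min(hits)))
    return sorted(out, key=lambda d: d[1])


def sepsis_onset_brute(record, thr=DEFAULT_SEPSIS):
    """min over all qualifying (infection, dysfunction) pairs of
    min(infection time, dysfunction time); None if no pair qualifies."""
    onsets = []
    for _, _, inf_t in infections_brute(record, thr):
        for _, dys_t in dysfunctions_brute(record, thr):
            if inf_t - thr.window_before_h <= dys_t \
                    <= inf_t + thr.window_after_h:
                onsets.append(min(inf_t, dys_t))
    return min(onsets) if onsets else None


def aki_onset_brute(record):
    """min over all qualifying creatinine measurement pairs and all
    6-hour urine windows; None if nothing qualifies."""
    onsets = []
    creat = record.channel("creatinine")
    for k in range(len(creat)):
        t, v = creat.times[k], creat.values[k]
        if t < 0:
            continue
        for j in range(len(creat)):
            tj, vj = creat.times[j], creat.values[j]
            if not tj < t:
                continue
            if t - tj <= AKI_DELTA_WINDOW_H and \
                    v - vj >= AKI_CREATININE_DELTA:
                onsets.append(t)
            if t - tj <= AKI_BASELINE_WINDOW_H and \
                    v >= AKI_CREATININE_RATIO * vj:
                onsets.append(t)
    urine = record.urine
    n = int(AKI_URINE_HOURS)
    for k in range(len(urine)):
        window = []
        for j in range(len(urine)):
            if k - n < j <= k:
                window.append(j)
        if len(window) == n and all(
                urine.rates_ml_kg_h[j] < AKI_URINE_RATE for j in window) \
                and all(abs(urine.end_times[window[m]]
                            - urine.end_times[window[m - 1]] - 1.0) < 1e-6
                        for m in range(1, n)):
            onsets.append(urine.end_times[k])
    return min(onsets) if onsets else None


def mortality_onset_brute(record):
    if record.death_time is not None and \
            record.death_time <= record.discharge_time + 1e-9:
        return record.death_time
    return None
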