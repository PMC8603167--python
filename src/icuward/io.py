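"""Long-format table export/import for synthetic cohorts.

A cohort is a directory of five tables (CSV or Parquet): `observations`
(patient_id, channel, time_h, value, protected), `stays` (demographics,
discharge, death time), `clinical_events`, `urine`, and `ground_truth`.
Round-tripping through these tables reproduces the in-memory records
exactly up to float representation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .channels import CHANNEL_NAMES
from .records import (
    ChannelSeries,
    ClinicalEvent,
    GroundTruth,
    PatientRecord,
    UrineOutput,
)

TABLES = ("observations", "stays", "clinical_events", "urine",
          "ground_truth")


def cohort_to_frames(records: list[PatientRecord],
                     truth: GroundTruth | None = None,
                     ) -> dict[str, pd.DataFrame]:
    obs_rows, stay_rows, ev_rows, urine_rows = [], [], [], []
    for r in records:
        stay_rows.append({"patient_id": r.patient_id, "age": r.age,
                          "sex": r.sex, "discharge_h": r.discharge_time,
                          "death_h": r.death_time})
        for name, s in r.observations.items():
            for t, v, p in zip(s.times, s.values, s.protected):
                obs_rows.append({"patient_id": r.patient_id, "channel": name,
                                 "time_h": t, "value": v,
                                 "protected": bool(p)})
        for e in r.clinical_events:
            ev_rows.append({"patient_id": r.patient_id, "kind": e.kind,
                            "time_h": e.time, "detail": e.detail})
        for t, vol, rate in zip(r.urine.end_times, r.urine.volumes_ml,
                                r.urine.rates_ml_kg_h):
            urine_rows.append({"patient_id": r.patient_id, "end_time_h": t,
                               "volume_ml": vol, "rate_ml_kg_h": rate})
    frames = {
        "observations": pd.DataFrame(
            obs_rows, columns=["patient_id", "channel", "time_h", "value",
                               "protected"]),
        "stays": pd.DataFrame(
            stay_rows, columns=["patient_id", "age", "sex", "discharge_h",
                                "death_h"]),
        "clinical_events": pd.DataFrame(
            ev_rows, columns=["patient_id", "kind", "time_h", "detail"]),
        "urine": pd.DataFrame(
            urine_rows, columns=["patient_id", "end_time_h", "volume_ml",
                                 "rate_ml_kg_h"]),
    }
    truth_rows = []
    if truth is not None:
        for pid, v in truth.events.items():
            truth_rows.append({"patient_id": pid,
                               "event": v[0] if v else None,
                               "onset_h": v[1] if v else None})
    frames["ground_truth"] = pd.DataFrame(
        truth_rows, columns=["patient_id", "event", "onset_h"])
    return frames


def frames_to_cohort(frames: dict[str, pd.DataFrame],
                     ) -> tuple[list[PatientRecord], GroundTruth]:
    obs_by = dict(tuple(frames["observations"].groupby("patient_id"))) \
        if len(frames["observations"]) else {}
    ev_by = dict(tuple(frames["clinical_events"].groupby("patient_id"))) \
        if len(frames["clinical_events"]) else {}
    ur_by = dict(tuple(frames["urine"].groupby("patient_id"))) \
        if len(frames["urine"]) else {}
    records = []
    for row in frames["stays"].itertuples():
        obs = {}
        if row.patient_id in obs_by:
            for name, g in obs_by[row.patient_id].groupby("channel"):
                obs[name] = ChannelSeries(
                    g["time_h"].to_numpy(), g["value"].to_numpy(),
                    g["protected"].to_numpy(dtype=bool))
        events = []
        if row.patient_id in ev_by:
            for e in ev_by[row.patient_id].itertuples():
                events.append(ClinicalEvent(e.kind, e.time_h,
                                            e.detail if isinstance(
                                                e.detail, str) else ""))
        if row.patient_id in ur_by:
            g = ur_by[row.patient_id].sort_values("end_time_h")
            urine = UrineOutput(g["end_time_h"].to_numpy(),
                                g["volume_ml"].to_numpy(),
                                g["rate_ml_kg_h"].to_numpy())
        else:
            urine = UrineOutput.empty()
        death = None if pd.isna(row.death_h) else float(row.death_h)
        records.append(PatientRecord(
            patient_id=row.patient_id, age=float(row.age), sex=row.sex,
            discharge_time=float(row.discharge_h), observations=obs,
            clinical_events=sorted(events, key=lambda e: e.time),
            urine=urine, death_time=death))
    truth = {}
    for row in frames["ground_truth"].itertuples():
        truth[row.patient_id] = (None if pd.isna(row.event)
                                 else (row.event, float(row.onset_h)))
    for r in records:
        truth.setdefault(r.patient_id, None)
    return records, GroundTruth(truth)


def save_cohort(records: list[PatientRecord], truth: GroundTruth | None,
                out_dir: str | Path, fmt: str = "csv") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, frame in cohort_to_frames(records, truth).items():
        if fmt == "parquet":
            frame.to_parquet(out / f"{name}.parquet", index=False)
        else:
            # %.17g guarantees float64 round-trip through text
            frame.to_csv(out / f"{name}.csv", index=False,
                         float_format="%.17g")


def load_cohort(in_dir: str | Path,
                ) -> tuple[list[PatientRecord], GroundTruth]:
    path = Path(in_dir)
    frames = {}
    for name in TABLES:
        pq, csv = path / f"{name}.parquet", path / f"{name}.csv"
        frames[name] = (pd.read_parquet(pq) if pq.exists()
                        else pd.read_csv(csv,
                                         float_precision="round_trip"))
    return frames_to_cohort(frames)


def labels_to_frame(labels: dict[str, dict]) -> pd.DataFrame:
    """Flatten {patient_id: {event: EventLabel | None}} to a tidy table."""
    rows = []
    for pid, per_event in labels.items():
        for event, lab in per_event.items():
            if lab is not None:
                rows.append({"patient_id": pid, "event": event,
                             "onset_h": lab.onset,
                             "criterion": lab.criterion})
    return pd.DataFrame(rows, columns=["patient_id", "event", "onset_h",
                                       "criterion"])


# ---------------------------------------------------------------------------
# instance store


def save_instance_set(instances, out_dir: str | Path, *,
                      config_hash: str = "", seed: int | None = None,
                      folds: dict[str, int] | None = None,
                      fmt: str = "parquet") -> None:
    """Persist one (event, tier) instance bundle: an index table, a
    long-format grid-cell table, and a manifest recording provenance
    (config hash, seed, optional patient fold assignments)."""
    import hashlib
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index_rows, cell_rows = [], []
    for k, inst in enumerate(instances):
        index_rows.append({"instance_id": k, "patient_id": inst.patient_id,
                           "event": inst.event, "tier": inst.tier,
                           "label": inst.label,
                           "prediction_time_h": inst.prediction_time,
                           "age": inst.grid.age})
        hours, chans = np.nonzero(inst.grid.mask)
        for h, c in zip(hours, chans):
            cell_rows.append({"instance_id": k, "hour": int(h),
                              "channel": CHANNEL_NAMES[c],
                              "value": inst.grid.values[h, c]})
    index = pd.DataFrame(index_rows)
    cells = pd.DataFrame(cell_rows, columns=["instance_id", "hour",
                                             "channel", "value"])
    for name, frame in (("index", index), ("cells", cells)):
        if fmt == "parquet":
            frame.to_parquet(out / f"{name}.parquet", index=False)
        else:
            frame.to_csv(out / f"{name}.csv", index=False,
                         float_format="%.17g")
    manifest = {
        "config_hash": config_hash or hashlib.sha256(
            repr(sorted((r["instance_id"], r["patient_id"])
                        for r in index_rows)).encode()).hexdigest()[:16],
        "seed": seed,
        "n_instances": len(instances),
        "format": fmt,
        "folds": folds or {},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_instance_set(in_dir: str | Path):
    """Load a bundle written by :func:`save_instance_set`; returns
    (instances, manifest)."""
    import json

    from .cohort import FeatureGrid, Instance

    path = Path(in_dir)
    manifest = json.loads((path / "manifest.json").read_text())
    frames = {}
    for name in ("index", "cells"):
        pq, csv = path / f"{name}.parquet", path / f"{name}.csv"
        frames[name] = (pd.read_parquet(pq) if pq.exists()
                        else pd.read_csv(csv,
                                         float_precision="round_trip"))
    cells_by = dict(tuple(frames["cells"].groupby("instance_id"))) \
        if len(frames["cells"]) else {}
    from .channels import CHANNEL_INDEX, N_DYNAMIC
    instances = []
    for row in frames["index"].itertuples():
        n_rows = int(np.floor(row.prediction_time_h)) + 1
        values = np.full((n_rows, N_DYNAMIC), np.nan)
        mask = np.zeros((n_rows, N_DYNAMIC), dtype=bool)
        if row.instance_id in cells_by:
            g = cells_by[row.instance_id]
            hh = g["hour"].to_numpy()
            cc = np.array([CHANNEL_INDEX[c] for c in g["channel"]])
            values[hh, cc] = g["value"].to_numpy()
            mask[hh, cc] = True
        grid = FeatureGrid(values, mask, float(row.age),
                           float(row.prediction_time_h))
        instances.append(Instance(row.patient_id, row.event, row.tier,
                                  grid, int(row.label),
                                  float(row.prediction_time_h)))
    return instances, manifest
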