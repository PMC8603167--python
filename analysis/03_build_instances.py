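#!/usr/bin/env python
"""Build multi-horizon training instances for every (event, tier) and
summarize the class balance and prediction-time distributions.

Reads results/cohort/, writes results/instances_summary.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from icuward.cohort import InstanceSamplingConfig, apply_exclusions, \
    build_instance_set
from icuward.horizons import HORIZON_HOURS, TIERS
from icuward.io import load_cohort
from icuward.labeling import label_record
from icuward.synthetic import EVENTS

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=RESULTS / "cohort")
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", type=Path,
                    default=RESULTS / "instances_summary.csv")
    args = ap.parse_args()

    records, _ = load_cohort(args.cohort)
    records, report = apply_exclusions(records)
    print("exclusions:", report)
    labels = {}
    for r in records:
        per_event = label_record(r)
        present = [lab for lab in per_event.values() if lab is not None]
        labels[r.patient_id] = min(present, key=lambda l: l.onset) \
            if present else None

    rows = []
    for event in EVENTS:
        ev_labels = {pid: (lab if lab is not None and lab.event == event
                           else None) for pid, lab in labels.items()}
        for tier in TIERS:
            horizon = HORIZON_HOURS[event][TIERS.index(tier)]
            cfg = InstanceSamplingConfig(seed=args.seed)
            instances = build_instance_set(records, ev_labels, event, tier,
                                           horizon, cfg)
            y = np.array([i.label for i in instances])
            t = np.array([i.prediction_time for i in instances])
            rows.append({
                "event": event, "tier": tier, "horizon_h": horizon,
                "n_instances": len(instances),
                "n_pos": int(y.sum()), "n_neg": int((1 - y).sum()),
                "median_pred_time_pos": float(np.median(t[y == 1]))
                if y.sum() else np.nan,
                "median_pred_time_neg": float(np.median(t[y == 0]))
                if (1 - y).sum() else np.nan,
            })
            print(f"{event:7s} {tier}: {rows[-1]['n_pos']:4d} pos / "
                  f"{rows[-1]['n_neg']:4d} neg")
    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out, index=False)
    print(f"-> {args.out}")


if __name__ == "__main__":
    main()
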