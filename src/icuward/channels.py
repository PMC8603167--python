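"""Fixed feature dictionary for the ICU panel.

The classifier sees 19 features: 18 dynamic channels (6 vital signs, 11
laboratory tests, the Glasgow Coma Scale) sampled on an hourly grid, plus
age as a static feature.  Urine output and medication/culture/ventilation
events exist in the records for event labeling and severity scoring only;
they are never model inputs.

Each channel carries physiologic plausibility bounds (generation is clipped
to these, and validation checks them), an adult reference "normal value"
used when a grid has no prior observation to carry forward, a typical
inter-observation interval, and short-term variability used by the
synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ChannelSpec:
    name: str
    unit: str
    kind: str               # "vital" | "lab" | "neuro"
    lo: float                # physiologic plausibility lower bound
    hi: float                # physiologic plausibility upper bound
    normal: float            # adult reference midpoint (leading-gap fill)
    interval_h: float        # typical hours between observations
    baseline_sd: float       # between-patient spread of the resting level
    noise_sd: float          # within-patient short-term fluctuation
    mean_reversion: float = 0.5   # OU pull-back rate per hour


# 6 vitals.  The exclusion rule names 5 (pulse rate, systolic and diastolic
# blood pressure, respiratory rate, body temperature); the sixth vital in
# the panel is peripheral oxygen saturation.
VITALS: tuple[ChannelSpec, ...] = (
    ChannelSpec("heart_rate", "beats/min", "vital", 20, 220, 75, 1.0, 8.0, 3.0),
    ChannelSpec("sbp", "mmHg", "vital", 40, 250, 120, 1.0, 10.0, 4.0),
    ChannelSpec("dbp", "mmHg", "vital", 20, 150, 70, 1.0, 7.0, 3.0),
    ChannelSpec("resp_rate", "breaths/min", "vital", 4, 60, 16, 1.0, 2.0, 1.2),
    ChannelSpec("temperature", "degC", "vital", 33.0, 42.5, 36.8, 1.0, 0.3, 0.15),
    ChannelSpec("spo2", "%", "vital", 50, 100, 97, 1.0, 1.0, 0.8),
)

# 11 labs — the minimum panel that supports the sepsis/AKI labelers and the
# SOFA/APACHE-II comparators.
LABS: tuple[ChannelSpec, ...] = (
    ChannelSpec("creatinine", "mg/dL", "lab", 0.2, 15.0, 0.9, 8.0, 0.15, 0.04, 0.3),
    ChannelSpec("bilirubin", "mg/dL", "lab", 0.1, 40.0, 0.7, 12.0, 0.2, 0.08, 0.3),
    ChannelSpec("platelets", "10^3/uL", "lab", 5, 1000, 250, 12.0, 40.0, 10.0, 0.3),
    ChannelSpec("lactate", "mmol/L", "lab", 0.2, 20.0, 1.0, 8.0, 0.2, 0.12, 0.3),
    ChannelSpec("wbc", "10^3/uL", "lab", 0.1, 100.0, 8.0, 12.0, 1.5, 0.6, 0.3),
    ChannelSpec("hemoglobin", "g/dL", "lab", 3.0, 22.0, 12.5, 12.0, 1.2, 0.3, 0.3),
    ChannelSpec("sodium", "mmol/L", "lab", 110, 180, 140, 12.0, 2.0, 1.0, 0.3),
    ChannelSpec("potassium", "mmol/L", "lab", 1.5, 9.0, 4.2, 12.0, 0.3, 0.15, 0.3),
    ChannelSpec("glucose", "mg/dL", "lab", 20, 900, 110, 8.0, 15.0, 10.0, 0.3),
    ChannelSpec("bun", "mg/dL", "lab", 2, 180, 15, 12.0, 3.0, 1.0, 0.3),
    ChannelSpec("ph", "pH", "lab", 6.8, 7.8, 7.40, 8.0, 0.02, 0.01, 0.3),
)

GCS = ChannelSpec("gcs", "points", "neuro", 3, 15, 15, 4.0, 0.5, 0.4)

ALL_CHANNELS: tuple[ChannelSpec, ...] = VITALS + LABS + (GCS,)

CHANNELS: dict[str, ChannelSpec] = {c.name: c for c in ALL_CHANNELS}
CHANNEL_NAMES: tuple[str, ...] = tuple(c.name for c in ALL_CHANNELS)
CHANNEL_INDEX: dict[str, int] = {n: i for i, n in enumerate(CHANNEL_NAMES)}
VITAL_NAMES: tuple[str, ...] = tuple(c.name for c in VITALS)

# The five vitals named by the cohort exclusion rule (SpO2 is not among them).
EXCLUSION_VITALS: tuple[str, ...] = (
    "heart_rate", "sbp", "dbp", "resp_rate", "temperature",
)

N_DYNAMIC = len(CHANNEL_NAMES)   # 18
N_FEATURES = N_DYNAMIC + 1       # + age (static)

NORMAL_VALUES: dict[str, float] = {c.name: c.normal for c in ALL_CHANNELS}
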