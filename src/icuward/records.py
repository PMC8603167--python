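"""In-memory containers for one ICU stay and its ground truth.

Times are hours from ICU admission (admission = 0).  Pre-ICU laboratory
values (e.g. a ward creatinine drawn before transfer) may carry negative
times; they participate in labeling baselines but never in model features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .channels import CHANNELS, CHANNEL_NAMES

EVENT_TYPES = ("death", "sepsis", "aki")

# kinds of point clinical events used for labeling and severity scoring
CLINICAL_EVENT_KINDS = (
    "antibiotic", "vasopressor", "ventilation_start", "blood_culture",
)


@dataclass
class ChannelSeries:
    """Irregular observations of one channel: parallel arrays sorted by time.

    ``protected`` marks observations that define a planted event's onset;
    the missingness simulator never drops them.
    """

    times: np.ndarray
    values: np.ndarray
    protected: np.ndarray  # bool

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.protected = np.asarray(self.protected, dtype=bool)
        order = np.argsort(self.times, kind="stable")
        if not np.all(order == np.arange(len(order))):
            self.times = self.times[order]
            self.values = self.values[order]
            self.protected = self.protected[order]

    @classmethod
    def empty(cls) -> "ChannelSeries":
        return cls(np.empty(0), np.empty(0), np.empty(0, dtype=bool))

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class ClinicalEvent:
    kind: str            # one of CLINICAL_EVENT_KINDS
    time: float          # hours from admission
    detail: str = ""     # e.g. antibiotic agent name

    def __post_init__(self) -> None:
        if self.kind not in CLINICAL_EVENT_KINDS:
            raise ValueError(f"unknown clinical event kind: {self.kind!r}")


@dataclass
class UrineOutput:
    """Hourly urine collection: interval end times, volumes, and
    weight-normalized rates (mL/kg/h, as charted by the source system)."""

    end_times: np.ndarray
    volumes_ml: np.ndarray
    rates_ml_kg_h: np.ndarray

    @classmethod
    def empty(cls) -> "UrineOutput":
        return cls(np.empty(0), np.empty(0), np.empty(0))

    def __len__(self) -> int:
        return len(self.end_times)


@dataclass
class PatientRecord:
    patient_id: str
    age: float                     # years
    sex: str                       # "F" | "M"
    discharge_time: float          # hours; admission is 0
    observations: dict[str, ChannelSeries] = field(default_factory=dict)
    clinical_events: list[ClinicalEvent] = field(default_factory=list)
    urine: UrineOutput = field(default_factory=UrineOutput.empty)
    death_time: float | None = None

    def channel(self, name: str) -> ChannelSeries:
        return self.observations.get(name, ChannelSeries.empty())

    def events_of(self, kind: str) -> list[ClinicalEvent]:
        return sorted((e for e in self.clinical_events if e.kind == kind),
                      key=lambda e: e.time)

    def validate(self) -> None:
        """Check structural invariants: known channels, in-stay times
        (pre-ICU lab values excepted), plausibility bounds."""
        for name, series in self.observations.items():
            if name not in CHANNELS:
                raise ValueError(f"unknown channel {name!r}")
            spec = CHANNELS[name]
            if np.any(series.times > self.discharge_time + 1e-9):
                raise ValueError(
                    f"{self.patient_id}: {name} observed after discharge")
            if np.any(series.values < spec.lo - 1e-9) or \
               np.any(series.values > spec.hi + 1e-9):
                raise ValueError(
                    f"{self.patient_id}: {name} outside plausibility bounds")

    def copy(self) -> "PatientRecord":
        obs = {k: ChannelSeries(v.times.copy(), v.values.copy(),
                                v.protected.copy())
               for k, v in self.observations.items()}
        urine = UrineOutput(self.urine.end_times.copy(),
                            self.urine.volumes_ml.copy(),
                            self.urine.rates_ml_kg_h.copy())
        return replace(self, observations=obs, urine=urine,
                       clinical_events=list(self.clinical_events))


@dataclass(frozen=True)
class EventLabel:
    event: str           # "death" | "sepsis" | "aki"
    onset: float         # hours from admission
    criterion: str = ""  # which rule fired (metadata only)

    def __post_init__(self) -> None:
        if self.event not in EVENT_TYPES:
            raise ValueError(f"unknown event type: {self.event!r}")


@dataclass
class GroundTruth:
    """Planted event per patient: maps patient_id -> (event, onset) or None."""

    events: dict[str, tuple[str, float] | None]

    def event_of(self, patient_id: str) -> tuple[str, float] | None:
        return self.events.get(patient_id)

    def count(self, event: str) -> int:
        return sum(1 for v in self.events.values()
                   if v is not None and v[0] == event)


def empty_observations() -> dict[str, ChannelSeries]:
    return {name: ChannelSeries.empty() for name in CHANNEL_NAMES}
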