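"""Prediction horizons (hours before onset) per event.

Three models are trained per event, predicting it T1 (near), T2 (mid-term)
or T3 (distant) hours in advance: 3/6/12 h for mortality and AKI, 2/4/6 h
for sepsis — chosen around clinical response times and shift schedules.
"""

from __future__ import annotations

from dataclasses import dataclass

HORIZON_HOURS: dict[str, tuple[int, int, int]] = {
    "death": (3, 6, 12),
    "aki": (3, 6, 12),
    "sepsis": (2, 4, 6),
}

TIERS = ("T1", "T2", "T3")


@dataclass(frozen=True)
class HorizonConfig:
    event: str
    t1: int
    t2: int
    t3: int

    def __post_init__(self) -> None:
        if not (0 < self.t1 < self.t2 < self.t3):
            raise ValueError("horizons must satisfy 0 < T1 < T2 < T3")

    @classmethod
    def for_event(cls, event: str) -> "HorizonConfig":
        return cls(event, *HORIZON_HOURS[event])

    def hours(self, tier: str) -> int:
        return {"T1": self.t1, "T2": self.t2, "T3": self.t3}[tier]
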