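"""Core domain types shared across the evaluation pipeline.

The unit of analysis is one patient's intraoperative monitoring record:
mean arterial pressure (MAP, mmHg) and a 0-100 risk index, both sampled on
a nominal 20-second grid, plus demographics and a log of clinical
interventions (skin incision, vasopressor boluses).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Hypotension threshold: an event is MAP at or below this level (mmHg).
HYPOTENSION_THRESHOLD_MMHG = 65.0

#: Non-event segments require MAP strictly above this level (mmHg).
NONEVENT_MAP_FLOOR_MMHG = 75.0

#: Nominal sampling interval of the index/MAP series (seconds).
DEFAULT_SAMPLE_INTERVAL_S = 20

#: Kinds of charted interventions considered supportive evidence.
INTERVENTION_KINDS = ("incision", "ephedrine", "phenylephrine", "epinephrine")


class ValidationError(ValueError):
    """Raised when a record or cohort file violates its schema."""


@dataclass
class MonitoringRecord:
    """One patient's MAP and risk-index time series on a 20-s grid.

    Parameters
    ----------
    patient_id : str
        Unique patient identifier.
    times_s : ndarray of int
        Strictly increasing sample times in seconds from monitoring start.
        Each sample represents the interval ``[t, t + sample_interval_s)``.
    map_mmhg : ndarray of float
        Mean arterial pressure per sample, mmHg, strictly positive.
    index_value : ndarray of float
        Risk index in [0, 100]; NaN marks a missing value.
    age_years, sex, height_cm, weight_kg
        Demographics; carried through for reporting only.
    arm : str
        Trial arm label, ``"blinded"`` or ``"unblinded"``.
    sample_interval_s : int
        Nominal grid spacing in seconds.
    """

    patient_id: str
    times_s: np.ndarray
    map_mmhg: np.ndarray
    index_value: np.ndarray
    age_years: float = float("nan")
    sex: str = "U"
    height_cm: float = float("nan")
    weight_kg: float = float("nan")
    arm: str = "blinded"
    sample_interval_s: int = DEFAULT_SAMPLE_INTERVAL_S

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.int64)
        self.map_mmhg = np.asarray(self.map_mmhg, dtype=float)
        self.index_value = np.asarray(self.index_value, dtype=float)
        n = len(self.times_s)
        if n == 0:
            raise ValidationError(f"{self.patient_id}: empty record")
        if not (len(self.map_mmhg) == len(self.index_value) == n):
            raise ValidationError(
                f"{self.patient_id}: length mismatch "
                f"(times {n}, map {len(self.map_mmhg)}, index {len(self.index_value)})"
            )
        if n > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValidationError(f"{self.patient_id}: times not strictly increasing")
        if not np.all(self.map_mmhg > 0):
            raise ValidationError(f"{self.patient_id}: non-positive MAP value")
        present = ~np.isnan(self.index_value)
        if np.any((self.index_value[present] < 0) | (self.index_value[present] > 100)):
            raise ValidationError(f"{self.patient_id}: index outside [0, 100]")
        if self.sample_interval_s <= 0:
            raise ValidationError(f"{self.patient_id}: sample_interval_s must be > 0")

    @property
    def n_samples(self) -> int:
        return len(self.times_s)

    @property
    def monitoring_time_min(self) -> float:
        """Monitored span in minutes; each sample covers one interval."""
        return (self.times_s[-1] - self.times_s[0] + self.sample_interval_s) / 60.0

    def gap_mask(self, tolerance: float = 1.5) -> np.ndarray:
        """Boolean mask over inter-sample steps; True where the grid has a gap.

        A gap is a step larger than ``tolerance`` nominal intervals; runs of
        consecutive samples never bridge gaps.
        """
        dt = np.diff(self.times_s)
        return dt > tolerance * self.sample_interval_s


@dataclass(frozen=True)
class Intervention:
    """A charted clinical intervention relevant to blood-pressure rises."""

    patient_id: str
    time_s: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in INTERVENTION_KINDS:
            raise ValidationError(
                f"intervention kind {self.kind!r} not in {INTERVENTION_KINDS}"
            )


@dataclass
class CohortBundle:
    """A validated cohort: monitoring records plus the intervention log."""

    records: list[MonitoringRecord]
    interventions: list[Intervention]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {r.patient_id for r in self.records}
        orphans = {iv.patient_id for iv in self.interventions} - ids
        if orphans:
            raise ValidationError(
                f"interventions reference unknown patients: {sorted(orphans)}"
            )

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    def filter_arm(self, arm: str) -> "CohortBundle":
        """Restrict to one trial arm; ``"combined"`` returns the full bundle."""
        if arm == "combined":
            return self
        if arm not in ("blinded", "unblinded"):
            raise ValueError(f"unknown arm {arm!r}")
        keep = {r.patient_id for r in self.records if r.arm == arm}
        return CohortBundle(
            records=[r for r in self.records if r.patient_id in keep],
            interventions=[iv for iv in self.interventions if iv.patient_id in keep],
            provenance={**self.provenance, "arm": arm},
        )

    def interventions_for(self, patient_id: str) -> list[Intervention]:
        return sorted(
            (iv for iv in self.interventions if iv.patient_id == patient_id),
            key=lambda iv: iv.time_s,
        )
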